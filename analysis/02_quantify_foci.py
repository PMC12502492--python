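"""Quantify RAD51 foci on the simulated cohort images.

Reads results/cohort/*.tif, runs the full detection chain (organoids,
nuclei, Cyclin A2-positive calling, LoG focus detection, per-nucleus
counting) and writes results/foci.csv.  Also compares recovered counts to
the generator's ground truth.

Run after 01:  python analysis/02_quantify_foci.py
"""

from pathlib import Path

import pandas as pd

from recaplab.imaging import quantify_slide
from recaplab.io_utils import read_image_tiff, write_foci_csv

OUT = Path("results")


def main():
    parts = []
    for tif in sorted((OUT / "cohort").glob("*.tif")):
        model, cond = tif.stem.rsplit("_", 1)
        parts.append(quantify_slide(read_image_tiff(tif), model=model,
                                    condition=cond))
    foci = pd.concat(parts, ignore_index=True)
    write_foci_csv(OUT / "foci.csv", foci)

    truth = pd.read_csv(OUT / "truth_foci.csv")
    truth = truth[truth.cyca2_positive]
    got = foci.groupby(["model", "condition"]).focus_count.mean()
    want = truth.groupby(["model", "condition"]).focus_count.mean()
    cmp = pd.DataFrame({"recovered": got, "truth": want})
    cmp["abs_err"] = (cmp.recovered - cmp.truth).abs()
    print(f"quantified {len(parts)} fields, "
          f"{len(foci)} marker-positive nuclei -> {OUT / 'foci.csv'}")
    print(f"mean absolute error of per-field mean counts: "
          f"{cmp.abs_err.mean():.3f} foci/nucleus")


if __name__ == "__main__":
    main()
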