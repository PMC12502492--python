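"""Generate the synthetic study inputs: an imaging cohort of HRD and HRP
organoid models (three irradiation conditions each), viability plates,
paired tumor/organoid expression counts, a PFI survival table and a variant
table — all with ground truth recorded alongside.

Writes images + sidecars to results/cohort/ and tables to results/.
Run from the repository root:  python analysis/01_simulate_cohort.py
"""

import json
from pathlib import Path

from recaplab import synthgen
from recaplab.io_utils import write_ground_truth_json, write_image_tiff

OUT = Path("results")
SEED = 1


def main():
    img_dir = OUT / "cohort"
    img_dir.mkdir(parents=True, exist_ok=True)

    cohort = synthgen.gen_recap_cohort(5, 5, seed=SEED)
    for model, conds in cohort.images.items():
        for cond, (img, gt) in conds.items():
            write_image_tiff(img_dir / f"{model}_{cond}.tif", img)
            write_ground_truth_json(img_dir / f"{model}_{cond}.truth.json", gt)
    cohort.truth_foci_table().to_csv(OUT / "truth_foci.csv", index=False)
    (OUT / "truth_labels.json").write_text(json.dumps(cohort.labels, indent=1))

    plate = synthgen.gen_viability_plate(synthgen.PlateSpec(seed=SEED))
    plate.to_csv(OUT / "example_plate.csv", index=False)

    counts, pairing, _ = synthgen.gen_paired_expression(
        synthgen.PairedExpressionSpec(seed=SEED))
    counts.to_csv(OUT / "expression_counts.tsv", sep="\t")
    (OUT / "expression_pairs.csv").write_text(
        "tumor,organoid\n" + "\n".join(f"{t},{p}" for t, p in pairing.items()))

    synthgen.gen_survival_cohort({"HRD": 16.0, "HRP": 4.4},
                                 {"HRD": 8, "HRP": 13}, censor_frac=0.1,
                                 seed=SEED).to_csv(OUT / "pfi.csv", index=False)
    synthgen.gen_variant_table(seed=SEED).to_csv(OUT / "variants.csv",
                                                 index=False)

    rdi = cohort.truth_rdi()
    print(f"wrote {len(cohort.images) * 3} images to {img_dir}")
    print("ground-truth radiation-induced focus gain (RDI) per model:")
    for model, label in cohort.labels.items():
        print(f"  {model} ({label}): {rdi[model]:+.2f}")


if __name__ == "__main__":
    main()
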