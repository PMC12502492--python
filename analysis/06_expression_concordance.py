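"""Tumor/organoid transcriptomic concordance: VST, NMF on organoid samples
over a rank range, LCD projection onto all samples, seeded-UMAP embedding,
paired-distance rank selection, per-factor top-5% signatures and per-pair
R^2.

Run after 01:  python analysis/06_expression_concordance.py
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from recaplab import expression as ex

warnings.filterwarnings("ignore")

OUT = Path("results")
SEED = 1


def main():
    counts = pd.read_csv(OUT / "expression_counts.tsv", sep="\t", index_col=0)
    pairing = dict(pd.read_csv(OUT / "expression_pairs.csv")
                   .itertuples(index=False, name=None))

    sel = ex.select_rank(counts, pairing, ks=range(2, 11), seed=SEED)
    print("summed paired distance by NMF rank:")
    for k, d in sel.distances.items():
        marker = "  <- chosen" if k == sel.chosen_k else ""
        print(f"  k={k:2d}: {d:8.2f}{marker}")

    W = sel.models[sel.chosen_k].W
    sigs = ex.signature_top_genes(W, pct=5.0)
    (OUT / "nmf_signatures.json").write_text(json.dumps(sigs, indent=1))
    sel.embeddings[sel.chosen_k].to_csv(OUT / "nmf_embedding.csv")

    vst = ex.vst_transform(counts)
    r2 = {t: ex.paired_gene_correlation(vst[t], vst[p])[1]
          for t, p in pairing.items()}
    match = ex.min_distance_pair_matching(sel.embeddings[sel.chosen_k],
                                          pairing)
    print(f"\nper-pair transformed-expression R^2: "
          f"min {min(r2.values()):.3f}, mean {np.mean(list(r2.values())):.3f}, "
          f"max {max(r2.values()):.3f}")
    print(f"nearest-neighbour pair matching in embedding: {match:.0%}")
    pd.Series(r2, name="r2").to_csv(OUT / "paired_r2.csv")


if __name__ == "__main__":
    main()
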