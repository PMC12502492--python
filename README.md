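# recaplab

Functional precision-medicine analytics for patient-derived tumor organoids
(PDTO), centered on homologous-recombination (HR) status. The package
re-implements, as a tested pipeline exercised end to end on synthetic
cohorts with known ground truth, four bespoke computations used in
organoid studies of ovarian cancer:

1. **RECAP quantification** — automated counting of RAD51 foci in
   proliferating (Cyclin A2-positive) nuclei on multichannel
   immunofluorescence images of irradiated organoid sections:
   organoid/nucleus segmentation (Otsu + distance-transform watershed),
   difference-of-Gaussians marker calling with geodesic reconstruction,
   and Laplacian-of-Gaussian focus detection.
2. **RECAP scoring** — per-model indices from Gaussian smoothing of the
   per-nucleus count histograms at control, 2 h and 24 h after 5 Gy,

   `DI = μ_ctrl`, `RDI = μ_2h − μ_ctrl`, `RI = μ_24h − μ_2h`,

   then PCA of the standardized (DI, RDI, RI) matrix with an HRD call at
   `PC1 < −0.5` (proficient models, which induce foci, fall on the
   positive side by the sign convention `loading(RDI) ≥ 0`).
3. **Drug-screen scoring** — plate QC by the Z'-style score
   `z = 1 − 3(σ_neg + σ_pos)/(μ_neg − μ_pos)` (plates below 0.4
   non-exploitable), viability normalization to negative controls,
   4-parameter-logistic IC50, trapezoidal AUC of % viability over log10
   dose, panel-wide normalized AUC z-scores (sensitive < 0 < resistant),
   and exact-p Spearman correlations between drugs.
4. **HR-status integration and transcriptomic concordance** — genomic
   instability score (GIS) banding at 0.48 ± 0.25 (HRP < 0.23 ≤ HRDmid ≤
   0.73 < HRD), variant filtering (VAF ≥ 5% and oncogenic or
   inactivating), RECAP×GIS concordance, platinum-free-interval survival
   comparisons (Kaplan-Meier, log-rank, Gehan-Breslow-Wilcoxon,
   Mann-Whitney, 6-month sensitivity rule), and NMF-based tumor/organoid
   concordance: factorize organoid expression, project the programs onto
   all samples by non-negative least squares, embed, and choose the rank
   minimizing the summed embedded distance between matched pairs.

Everything runs on synthetic data from `recaplab.synthgen`, which renders
images, plates, paired count matrices, survival and variant tables with the
generating truth recorded — so each stage's recovery can be measured.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_quantify_foci.py
python analysis/03_recap_classification.py
```

generates a 10-model cohort (5 HR-deficient, 5 HR-proficient; 30 fields),
quantifies it, and classifies it. The third step prints:

```
SYN-001 -0.887    HRD   HRD
SYN-002 -0.939    HRD   HRD
SYN-003 -1.719    HRD   HRD
SYN-004 -1.446    HRD   HRD
SYN-005 -1.655    HRD   HRD
SYN-006  1.445    HRP   HRP
SYN-007  1.013    HRP   HRP
SYN-008  1.267    HRP   HRP
SYN-009  1.966    HRP   HRP
SYN-010  0.955    HRP   HRP

label recovery vs generating regime: 100%
```

Columns are model, PC1 score, call, and generating regime: the five
models rendered without radiation-induced focus formation land below the
−0.5 cutoff (HRD), the five with induced-then-resolved foci land above
it, and every call matches the regime that generated the images. The
remaining drivers (`04`–`06`) run the drug screen, the GIS/survival
integration and the NMF concordance the same way, each printing what it
found and writing tables under `results/`.

The same stages are available as a CLI
(`recaplab synth|quantify|recap-score|drugs|hr-integrate|nmf|run-full`)
and as one call, `recaplab.pipeline.run_full`, which emits a single
report with provenance.

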