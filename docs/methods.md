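# Methods

This note documents the models, parameter choices and numerical behavior of
`recaplab`, and what the synthetic-cohort results do and do not establish
about real data.

## Synthetic image model

A field is a 3-channel float32 image (DAPI, FITC, CY3). Nuclei are rotated
ellipses (semi-axes 8–12 px) placed by dart throwing with a minimum
center separation of `2·r_max + 2` px (up to 1000 retries per nucleus; a
field too small for the requested count raises `CapacityError` rather than
silently under-filling). The DAPI channel is the nucleus mask at amplitude
0.75 over a 0.05 background, lightly blurred; the FITC channel adds 0.5
inside the randomly chosen Cyclin A2-positive subset (default 60% of
nuclei); the CY3 channel renders RAD51 foci as isotropic Gaussian spots
(σ = 2 px, amplitude 0.16) at centers sampled inside a 3-px-eroded nucleus
mask with ≥ 6 px mutual separation. Per-nucleus focus counts are Poisson
with a condition-dependent mean; when a nucleus cannot geometrically hold
its Poisson draw, the recorded ground truth is the number actually
rendered, so the truth always equals what is in the image (closure).
Gaussian read noise (SD 0.02) gives the default spot SNR of 8;
`noise_sd=0` produces noiseless oracle images.

Default regimes (foci/nucleus at control / 2 h / 24 h after 5 Gy):
HR-proficient 1.0 / 8.0 / 3.0 (induction then partial resolution),
HR-deficient 1.0 / 1.6 / 1.2 (configured small gap). Per-model means are
jittered ±10%. These are parameter-recovery settings — chosen so the two
regimes are separated by several standard errors at 60 nuclei per field —
not estimates of any real cohort's biology; published work does not state
per-condition count distributions. What passing tests show is that the
quantification chain recovers what was rendered; they do not show
robustness to autofluorescence, sectioning artifacts, uneven illumination
or densely packed nuclei, none of which the generator emulates.

## Quantification chain

All steps are classical and deterministic. Organoids: heavy Gaussian blur
(σ = 12), Otsu, hole filling, minimum area 2000 px. Nuclei: blur σ = 1.5,
Otsu, distance-transform watershed (peak separation 5 px), minimum area
30 px, behind a `Segmenter` callable so trained models can be dropped in;
the package deliberately bundles no trained weights — the quantities under
test live downstream of segmentation. Marker positivity: DoG band-pass
(σ 2/8 px) with an amplitude floor of 2× the robust (MAD-based) background
SD — the floor exists because a threshold-free "positive difference" rule
only makes sense on noiseless data — then 8-connected morphological
reconstruction by dilation of the nucleus foreground from the
positive-inside-nucleus marker; any reconstructed pixel makes its nucleus
positive. Foci: scale-normalized negated Laplacian of Gaussian (σ = 2 px),
non-maximum suppression at radius σ, absolute response threshold 0.02,
plus a brightness gate (peak must exceed the median smoothed intensity)
that rejects the positive surround ring a *dark* blob produces — only
bright foci on dark background are detected. Foci are assigned to the
nucleus whose mask contains the rounded centroid; detections in background
or marker-negative nuclei are counted and reported but excluded
downstream. All σ values and thresholds are configuration with these
defaults; no claim is made that they match any particular acquisition
setup.

## Index computation and classification

Counts from marker-positive nuclei only. Histogram smoothing fits a
Gaussian mixture per condition (≥ 20 nuclei required; fewer raises an
error carrying the count); with one component — the default, since one
component is what the histograms support — the fit is exactly the sample
mean and ML (ddof = 0) SD, returned in closed form; multi-component fits
use EM (tol 1e−6, 500 iterations, fixed seed) and return the
largest-weight component. DI/RDI/RI are exact differences of those means,
with no rescaling.

Classification standardizes each index across models (sample SD) and
eigen-decomposes the correlation matrix. Standardization is a design
choice: the three indices share units but very different spreads, and it
makes the cutoff a score in SD-scaled units. Eigenvector sign is
arbitrary, so PC1 is oriented to `loading(RDI) ≥ 0`, putting
focus-inducing (proficient) models on the positive side; without an
orientation rule the printed cutoff would be meaningless. A model is HRD
iff `pc1 < −0.5`, strictly — a score exactly at the cutoff is proficient.
The −0.5 default is a calibration constant from a specific 23-model panel;
on any other panel it is a free parameter. Zero-variance index columns are
dropped with a warning. Note one consequence of standardizing: negating
the raw index matrix negates all PC1 scores while leaving loadings
unchanged, so calls against an asymmetric cutoff are *not* invariant under
data negation; the orientation rule canonicalizes the eigen-solver's sign,
nothing more.

## Drug screen

QC uses sample (ddof = 1) SDs in `z = 1 − 3(σ_neg+σ_pos)/(μ_neg−μ_pos)`;
the assay is degenerate (error) if the negative-control mean does not
exceed the positive-control mean, and non-exploitable strictly below 0.4.
Viability is signal over the negative-control mean. Replicates are
averaged per dose before fitting. The 4PL is fitted on log10 dose by
bounded least squares; IC50 is relative (midpoint of fitted asymptotes)
and undefined — with a diagnostic — when the fitted span is < 0.1 or the
midpoint falls > 1.5 decades outside the tested range (flat/resistant
curves). AUC is the trapezoid of % viability against log10 dose, the
GraphPad-style convention; a linear-dose variant is provided for
sensitivity analysis. Panel z-scores use the sample SD and therefore have
mean 0 and SD 1 by construction; the sensitive/resistant split is at 0.
Spearman p-values are exact (full permutation) for n ≤ 9 without ties,
t-approximate otherwise.

## HR integration

GIS banding treats the indeterminate band as the closed interval
[threshold − margin, threshold + margin] with defaults 0.48 ± 0.25; edge
semantics are a choice (closed) since interval notation alone does not fix
them. A two-way call (`gis_binary`) maps the band away at the 0.48
threshold for analyses needing binary status. Variant filtering keeps a
record iff VAF ≥ 0.05 (inclusive) and the call is oncogenic or predicted
inactivating, logging a per-row drop reason. "Reclassified" models are
those GIS calls proficient but the functional assay calls deficient.
Survival uses lifelines: product-limit KM (median = smallest t with
S(t) ≤ 0.5, undefined if never reached), the log-rank test, and its
Gehan-Breslow-Wilcoxon variant (weight = number at risk); the weighted
O−E numerator is also exposed directly, since without censoring it equals
minus the pairwise Gehan score — the identity the test suite checks by
brute force. Mann-Whitney is exact by enumeration for pooled n ≤ 12
without ties, else normal-approximate with tie correction. Platinum
sensitivity is PFI ≥ 6 months, inclusive. The CNV similarity metric is
plain Pearson over shared informative bins — an explicit stand-in, as no
standard bounded definition exists for that quantity.

## Expression concordance

The variance-stabilizing transform is `log2(count/size_factor + 1)` with
median-of-ratios size factors against the geometric-mean pseudo-reference;
all-zero gene rows are dropped with a log message, and a zero-total sample
is an error. Size factors are identified only relative to the
pseudo-reference: doubling one library doubles its factor *relative to the
others* (exactly so for proportional samples) while all factors shift by a
common constant — exact single-sample invariance would require a fixed
external reference.

NMF is multiplicative-update Frobenius NMF written in-package because the
per-iteration objective trace is an asserted invariant (monotone
non-increase at every update); sklearn's `mu` solver serves as an
independent cross-check in the tests, not as the implementation. Init is
seeded uniform; convergence at relative objective change < 1e−5 or 2000
iterations; after convergence W columns are rescaled to unit L2 norm
(scale moved into H) so exposures are comparable across ranks. Projection
(LCD) is per-sample non-negative least squares onto W's columns.

Rank selection fits NMF on organoid samples only for each k, projects all
samples, normalizes each sample's exposures to proportions, embeds in 2-D,
and picks the k minimizing the summed Euclidean distance between matched
tumor/organoid pairs (first hit on ties; ranks ≥ the organoid count are
skipped). Two choices here matter and were genuinely open:

* **Proportion normalization** removes the stromal-dilution scale
  difference between a tumor and its organoid (a tumor that is half
  stroma has all its tumor-program exposures halved; proportions undo
  that radial shift).
* **The embedding is seeded UMAP** (n_neighbors ≤ 8, median of 3
  embedding replicates per rank to damp near-ties). A linear PCA
  embedding is provided but is *not* suitable for rank selection: when
  pair members share expected profiles, within-pair distance is pure
  exposure-estimation noise, which grows with rank, and a linear
  embedding therefore always prefers the smallest tested rank. The
  interior optimum that makes the criterion meaningful arises from
  tumors carrying a stromal program absent from the organoid-trained
  factors: at low rank the embedding keeps the resulting tumor-offset
  direction (tumors cluster apart from organoids), while at sufficient
  rank pair-identity structure dominates the local geometry and matched
  pairs co-locate. UMAP's local-neighborhood emphasis is what expresses
  this; with it, the generating rank (k_true = 4, 15 pairs, 2000 genes,
  stromal weight 1.0) is recovered within ±1 across seeds.

The expression generator draws per-pair exposures over k_true programs
(one dominant program per pair, shared exactly within a pair), adds a
stromal program to tumors only, and emits Gamma-Poisson
(negative-binomial) counts at dispersion 0.02 and library size 2×10⁵.
Defaults (15 pairs, stromal weight 1.0) emulate a paired biobank in which
raw tumor and organoid profiles correlate well yet tumors cluster apart
until programs are factored out. With pairs sharing dominant programs,
nearest-neighbour pair matching in the 2-D embedding is inherently
ambiguous between same-program pairs; in the identifiable regime (one
program per pair) matching in full exposure space recovers every pair.
Per-factor signatures are the top 5% of genes by factor weight.

## Problem sizes and determinism

The test suite and acceptance script run everything at desk scale chosen
to keep the full run in minutes on one CPU while leaving comfortable
statistical margins: 384² px fields with 60 nuclei, 10-model cohorts
repeated over 5 seeds, 100-replicate dose-response Monte Carlo, 2000 × 30
expression matrices over ranks 2–10, and 200-per-group survival cohorts
for stable KM medians. Every stochastic step takes an explicit seed;
images, tables, NMF fits and UMAP embeddings are bit-reproducible given
the seed, and `run_full` writes a provenance block (config hash, seeds,
library versions) sufficient to reproduce a report byte for byte.

## Known limitations

Segmentation is classical and assumes well-separated, roughly elliptical
nuclei; the generator satisfies this by construction, so imaging accuracy
numbers are upper bounds on real-slide performance. The GIS score itself
is consumed, not computed (its generating logistic model is external).
The −0.5 PC1 cutoff, the 0.48 ± 0.25 band and the 6-month PFI rule are
calibration constants carried as defaults, not re-derived. Survival
cohorts are exponential with uniform early censoring — no competing risks
or covariates. The paired-distance rank criterion depends on a stromal
(or comparable tumor-only) component being present; on data where tumors
and organoids are exchangeable it degenerates toward the smallest rank,
and the package makes no attempt to hide that.
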