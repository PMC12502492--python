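"""Synthetic cohort generators with recorded ground truth.

Every input the analysis pipeline consumes — multichannel immunofluorescence
images of irradiated organoid sections, viability plates with control wells,
paired tumor/organoid expression matrices, survival tables and variant
tables — can be generated here with the quantities the pipeline is supposed
to recover recorded alongside.  All generators are deterministic given their
seed and never emit signal that is not in the returned ground truth.

Image model
-----------
Nuclei are ellipses placed by dart throwing with a minimum separation;
the DAPI channel shows all nuclei, the FITC channel is elevated only inside
nuclei positive for the S/G2 proliferation marker (Cyclin A2), and the CY3
channel carries punctate RAD51 foci rendered as isotropic Gaussian spots
whose per-nucleus counts are Poisson with a condition-dependent mean.
An HRP (homologous-recombination proficient) regime induces foci at 2 h
post-irradiation which partially resolve by 24 h; an HRD regime shows
almost no induction — that absence of radiation-induced focus formation is
the read-out the downstream classifier must recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

CONDITIONS = ("control", "post2h", "post24h")

CHANNEL_ORDER = ("DAPI", "FITC", "CY3")


class CapacityError(RuntimeError):
    """Raised when the requested objects cannot be placed in the field."""


@dataclass(frozen=True)
class ImageGroundTruth:
    """Everything rendered into one synthetic field, exactly as rendered."""

    nucleus_masks: np.ndarray          # labeled 2-D int map, 0 = background
    cyca2_positive_labels: frozenset
    foci_per_nucleus: dict             # label -> rendered focus count
    foci_positions: dict               # label -> list of (row, col) centers
    condition: str
    pixel_size_um: float = 0.325

    def __post_init__(self):
        labels = set(np.unique(self.nucleus_masks)) - {0}
        if not set(self.cyca2_positive_labels) <= labels:
            raise ValueError("cyca2_positive_labels not a subset of nucleus labels")
        if any(c < 0 for c in self.foci_per_nucleus.values()):
            raise ValueError("negative focus count in ground truth")

    @property
    def n_nuclei(self) -> int:
        return int(self.nucleus_masks.max())


@dataclass(frozen=True)
class RecapRegime:
    """Condition-dependent focus statistics for one HR regime."""

    name: str                              # "HRD" or "HRP"
    mean_foci: dict                        # condition -> mean foci per nucleus
    cyca2_fraction: float = 0.6
    nucleus_count: int = 60

    def __post_init__(self):
        if not 0 < self.cyca2_fraction <= 1:
            raise ValueError("cyca2_fraction must be in (0, 1]")
        if self.nucleus_count < 1:
            raise ValueError("nucleus_count must be positive")
        missing = [c for c in CONDITIONS if c not in self.mean_foci]
        if missing:
            raise ValueError(f"mean_foci missing conditions: {missing}")


#: Default regimes.  HRP induces ~7 extra foci per nucleus at 2 h which
#: partially resolve by 24 h; HRD shows a configured small gap only.
#: These are parameter-recovery settings, not estimates of any real cohort.
HRD_REGIME = RecapRegime("HRD", {"control": 1.0, "post2h": 1.6, "post24h": 1.2})
HRP_REGIME = RecapRegime("HRP", {"control": 1.0, "post2h": 8.0, "post24h": 3.0})


def _place_centers(rng, shape, n, min_sep, margin, max_retries=1000):
    """Dart-throwing placement of n centers with a minimum separation."""
    centers = []
    h, w = shape
    for _ in range(n):
        for attempt in range(max_retries + 1):
            cand = (margin + rng.random() * (h - 2 * margin),
                    margin + rng.random() * (w - 2 * margin))
            if all((cand[0] - r) ** 2 + (cand[1] - c) ** 2 >= min_sep ** 2
                   for r, c in centers):
                centers.append(cand)
                break
        else:
            raise CapacityError(
                f"placed {len(centers)}/{n} nuclei after {max_retries} retries; "
                f"field {shape} too small")
    return centers


def _rasterize_ellipse(shape, center, a, b, theta):
    """Boolean mask of a rotated filled ellipse."""
    r0, c0 = center
    half = int(math.ceil(max(a, b))) + 1
    rlo, rhi = max(0, int(r0) - half), min(shape[0], int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(shape[1], int(c0) + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rr - r0, cc - c0
    ct, st = math.cos(theta), math.sin(theta)
    x = dr * ct + dc * st
    y = -dr * st + dc * ct
    inside = (x / a) ** 2 + (y / b) ** 2 <= 1.0
    mask = np.zeros(shape, bool)
    mask[rlo:rhi, clo:chi] = inside
    return mask


def _sample_spot_centers(rng, nucleus_mask, n, min_sep=6.0, edge_margin=3,
                         max_retries=200):
    """Pick up to n spot centers inside an eroded nucleus mask.

    Returns the centers actually placed; the caller records that number as
    the ground truth so nothing unrecorded is rendered.
    """
    interior = ndi.binary_erosion(nucleus_mask, iterations=edge_margin)
    if not interior.any():
        interior = nucleus_mask
    coords = np.argwhere(interior)
    centers = []
    retries = 0
    while len(centers) < n and retries <= max_retries:
        r, c = coords[rng.integers(len(coords))]
        # sub-pixel jitter keeps spots off the integer grid
        cand = (r + rng.uniform(-0.4, 0.4), c + rng.uniform(-0.4, 0.4))
        if all((cand[0] - pr) ** 2 + (cand[1] - pc) ** 2 >= min_sep ** 2
               for pr, pc in centers):
            centers.append(cand)
        else:
            retries += 1
    return centers


def _render_spot(img, center, sigma, amplitude):
    r0, c0 = center
    half = int(math.ceil(4 * sigma))
    rlo, rhi = max(0, int(r0) - half), min(img.shape[0], int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(img.shape[1], int(c0) + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    img[rlo:rhi, clo:chi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma ** 2))


def gen_recap_image(regime: RecapRegime, condition: str, shape=(384, 384),
                    seed: int = 0, *, spot_sigma: float = 2.0,
                    spot_amplitude: float = 0.16, noise_sd: float = 0.02,
                    background: float = 0.05, pixel_size_um: float = 0.325):
    """Render one 3-channel field (DAPI, FITC, CY3) plus its ground truth.

    Spot amplitude defaults to 8x the background noise SD so that blob
    detection operates at a fair but non-trivial SNR; set ``noise_sd=0``
    for noiseless oracle images.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    h, w = shape
    r_max = 12.0
    centers = _place_centers(rng, shape, regime.nucleus_count,
                             min_sep=2 * r_max + 2, margin=r_max + 2)

    labels = np.zeros(shape, np.int32)
    for i, ctr in enumerate(centers, start=1):
        a = rng.uniform(8.0, r_max)
        b = rng.uniform(8.0, r_max)
        theta = rng.uniform(0, math.pi)
        labels[_rasterize_ellipse(shape, ctr, a, b, theta)] = i

    n = regime.nucleus_count
    n_pos = max(1, int(round(regime.cyca2_fraction * n)))
    if regime.cyca2_fraction >= 1.0:
        n_pos = n
    positive = frozenset(int(x) for x in
                         rng.choice(np.arange(1, n + 1), n_pos, replace=False))

    dapi = np.full(shape, background, np.float32)
    dapi[labels > 0] += 0.75
    dapi = ndi.gaussian_filter(dapi, 1.5)

    fitc = np.full(shape, background, np.float32)
    pos_mask = np.isin(labels, sorted(positive))
    fitc[pos_mask] += 0.5
    fitc = ndi.gaussian_filter(fitc, 1.5)

    cy3 = np.full(shape, background, np.float32)
    mean = float(regime.mean_foci[condition])
    foci_per_nucleus, foci_positions = {}, {}
    for lab in range(1, n + 1):
        want = int(rng.poisson(mean)) if mean > 0 else 0
        placed = _sample_spot_centers(rng, labels == lab, want) if want else []
        foci_per_nucleus[lab] = len(placed)
        foci_positions[lab] = [(float(r), float(c)) for r, c in placed]
        for ctr in placed:
            _render_spot(cy3, ctr, spot_sigma, spot_amplitude)

    if noise_sd > 0:
        dapi = dapi + rng.normal(0, noise_sd, shape).astype(np.float32)
        fitc = fitc + rng.normal(0, noise_sd, shape).astype(np.float32)
        cy3 = cy3 + rng.normal(0, noise_sd, shape).astype(np.float32)
    img = np.clip(np.stack([dapi, fitc, cy3]), 0, None).astype(np.float32)

    gt = ImageGroundTruth(nucleus_masks=labels,
                          cyca2_positive_labels=positive,
                          foci_per_nucleus=foci_per_nucleus,
                          foci_positions=foci_positions,
                          condition=condition,
                          pixel_size_um=pixel_size_um)
    return img, gt


@dataclass
class RecapCohort:
    """Per-model, per-condition images plus the generating truth."""

    images: dict                      # model -> condition -> (image, gt)
    labels: dict                      # model -> "HRD" | "HRP"
    regimes: dict = field(default_factory=dict)   # model -> RecapRegime

    def truth_foci_table(self) -> pd.DataFrame:
        rows = []
        for model, conds in self.images.items():
            for cond, (_, gt) in conds.items():
                for lab, cnt in gt.foci_per_nucleus.items():
                    rows.append((model, cond, lab,
                                 lab in gt.cyca2_positive_labels, cnt))
        return pd.DataFrame(rows, columns=["model", "condition", "nucleus",
                                           "cyca2_positive", "focus_count"])

    def truth_rdi(self) -> pd.Series:
        """Ground-truth radiation-induced focus gain per model."""
        t = self.truth_foci_table()
        t = t[t.cyca2_positive]
        m = t.groupby(["model", "condition"]).focus_count.mean().unstack()
        return m["post2h"] - m["control"]


def gen_recap_cohort(n_hrd: int, n_hrp: int, seed: int = 0, *,
                     shape=(384, 384), nucleus_count: int = 60,
                     noise_sd: float = 0.02, jitter: float = 0.1) -> RecapCohort:
    """Generate an imaging cohort of HRD and HRP models, three conditions each.

    Per-model focus means are jittered multiplicatively (up to ``jitter``)
    around the regime defaults so models are not identical replicates.
    """
    if n_hrd + n_hrp < 1:
        raise ValueError("need at least one model")
    rng = np.random.default_rng(seed)
    images, labels, regimes = {}, {}, {}
    plan = [("HRD", HRD_REGIME)] * n_hrd + [("HRP", HRP_REGIME)] * n_hrp
    for i, (name, base) in enumerate(plan):
        model = f"SYN-{i + 1:03d}"
        f = 1.0 + rng.uniform(-jitter, jitter)
        regime = replace(base, mean_foci={c: v * f for c, v in base.mean_foci.items()},
                         nucleus_count=nucleus_count)
        images[model] = {}
        for cond in CONDITIONS:
            sub = int(rng.integers(0, 2 ** 31 - 1))
            images[model][cond] = gen_recap_image(regime, cond, shape, sub,
                                                  noise_sd=noise_sd)
        labels[model] = name
        regimes[model] = regime
    return RecapCohort(images=images, labels=labels, regimes=regimes)


# ---------------------------------------------------------------------------
# viability plates


@dataclass(frozen=True)
class PlateSpec:
    """Layout and generating curve of one synthetic viability plate."""

    n_negative: int = 6
    n_positive: int = 6
    n_treated_per_dose: int = 3
    doses_uM: tuple = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)
    true_ic50_uM: float = 10.0
    hill: float = 1.0
    noise_cv: float = 0.05
    seed: int = 0
    neg_mean: float = 100.0
    pos_mean: float = 10.0
    top: float = 1.0
    bottom: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.doses_uM, float)
        if not (np.diff(d) > 0).all():
            raise ValueError("doses must be strictly increasing")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must be in [0, 1)")
        if self.true_ic50_uM <= 0:
            raise ValueError("true_ic50_uM must be positive")


def logistic4(dose, top, bottom, ic50, hill):
    """4-parameter logistic viability curve, decreasing in dose for hill > 0."""
    dose = np.asarray(dose, float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def gen_viability_plate(spec: PlateSpec) -> pd.DataFrame:
    """One plate table: well, role in {negative, positive, treated}, dose, signal."""
    rng = np.random.default_rng(spec.seed)
    rows = []

    def noisy(mu):
        if spec.noise_cv == 0:
            return float(mu)
        return float(max(mu * (1.0 + spec.noise_cv * rng.standard_normal()), 0.0))

    w = 0
    for _ in range(spec.n_negative):
        rows.append((f"W{w:03d}", "negative", np.nan, noisy(spec.neg_mean))); w += 1
    for _ in range(spec.n_positive):
        rows.append((f"W{w:03d}", "positive", np.nan, noisy(spec.pos_mean))); w += 1
    for dose in spec.doses_uM:
        frac = logistic4(dose, spec.top, spec.bottom, spec.true_ic50_uM, spec.hill)
        for _ in range(spec.n_treated_per_dose):
            rows.append((f"W{w:03d}", "treated", float(dose),
                         noisy(spec.neg_mean * frac))); w += 1
    return pd.DataFrame(rows, columns=["well", "role", "dose_uM", "signal"])


# ---------------------------------------------------------------------------
# paired expression


@dataclass(frozen=True)
class PairedExpressionSpec:
    """Latent-program model for paired tumor/organoid count matrices.

    Each tumor–organoid pair shares one exposure vector over ``k_true``
    non-negative programs (one program dominant per pair); tumors additionally
    load a common stromal program scaled by ``stroma_weight``, emulating the
    stromal compartment that organoid cultures lack.  Counts are
    negative-binomial via a Gamma–Poisson mixture.
    """

    n_genes: int = 2000
    n_pairs: int = 15
    k_true: int = 4
    stroma_weight: float = 1.0
    noise_dispersion: float = 0.02
    lib_size: float = 2e5
    seed: int = 0

    def __post_init__(self):
        if self.k_true < 2 or self.k_true >= 2 * self.n_pairs:
            raise ValueError("need 2 <= k_true < 2 * n_pairs")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion must be positive")


def gen_paired_expression(spec: PairedExpressionSpec):
    """Return (counts genes x samples, pairing map tumor->organoid, truth dict)."""
    rng = np.random.default_rng(spec.seed)
    g, k = spec.n_genes, spec.k_true

    base = rng.lognormal(0.0, 0.7, g)
    W = np.tile(base[:, None], (1, k)) * rng.uniform(0.2, 0.6, (g, k))
    block = g // (k + 1)
    for j in range(k):
        W[j * block:(j + 1) * block, j] *= 10.0          # marker genes
    stroma = base * rng.uniform(0.2, 0.6, g)
    stroma[k * block:(k + 1) * block] *= 10.0

    pairs = [(f"T{i + 1:02d}", f"P{i + 1:02d}") for i in range(spec.n_pairs)]
    exposures = {}
    for i, (t, p) in enumerate(pairs):
        e = rng.dirichlet(np.full(k, 0.3))
        e = 0.3 * e + 0.7 * np.eye(k)[i % k]             # dominant program
        exposures[t] = exposures[p] = e

    samples = [s for pair in pairs for s in pair]
    counts = np.zeros((g, len(samples)))
    expected = {}
    for j, s in enumerate(samples):
        mu = W @ exposures[s]
        if s.startswith("T"):
            mu = mu + spec.stroma_weight * stroma
        mu = mu / mu.sum() * spec.lib_size
        expected[s] = mu
        shape = 1.0 / spec.noise_dispersion
        lam = mu * rng.gamma(shape, 1.0 / shape, g)
        counts[:, j] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=[f"g{i:05d}" for i in range(g)],
                             columns=samples)
    pairing = dict(pairs)
    truth = {"W": W, "stroma": stroma, "exposures": exposures,
             "expected": expected}
    return counts_df, pairing, truth


# ---------------------------------------------------------------------------
# survival and variants


def gen_survival_cohort(group_medians_months: dict, n_per_group,
                        censor_frac: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Exponential event times with the stated per-group median PFI.

    ``n_per_group`` is an int, or a dict group -> size for unbalanced
    cohorts.
    """
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for group, med in group_medians_months.items():
        if med <= 0:
            raise ValueError(f"median for {group!r} must be positive")
        n = n_per_group[group] if isinstance(n_per_group, dict) else n_per_group
        scale = med / math.log(2)
        t = rng.exponential(scale, n)
        cens = rng.random(n) < censor_frac
        t = np.where(cens, t * rng.random(n), t)
        for i in range(n):
            rows.append((f"{group}-{i + 1:03d}", group, float(t[i]),
                         bool(not cens[i])))
    return pd.DataFrame(rows, columns=["patient", "group", "pfi_months", "event"])


def gen_variant_table(seed: int = 0, n_extra: int = 6) -> pd.DataFrame:
    """Variant fixture spanning the VAF-5% boundary and both annotation flags.

    The first rows pin the boundary cases (VAF exactly 0.05 kept; 0.049
    dropped; high-VAF benign dropped); extra rows are random but labeled.
    """
    rng = np.random.default_rng(seed)
    genes = ["BRCA1", "BRCA2", "ATM", "RAD51C", "PALB2", "CHEK2", "BRIP1",
             "BARD1", "CDK12", "FANCL"]
    rows = [
        ("BRCA1", 0.050, True, False),
        ("BRCA2", 0.049, True, False),
        ("TP53", 0.400, False, False),
    ]
    for _ in range(n_extra):
        rows.append((genes[rng.integers(len(genes))],
                     float(np.round(rng.uniform(0.0, 0.6), 3)),
                     bool(rng.random() < 0.5), bool(rng.random() < 0.3)))
    df = pd.DataFrame(rows, columns=["gene", "vaf", "oncogenic", "inactivating"])
    df["keep_truth"] = (df.vaf >= 0.05) & (df.oncogenic | df.inactivating)
    return df
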