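"""Plate QC, viability normalization and dose-response scoring.

A plate carries negative-control wells (vehicle), positive-control wells
(a staurosporine-like kill control) and treated wells.  Assay quality uses a
Z'-style score,

    z = 1 - (3*SD_neg + 3*SD_pos) / (mean_neg - mean_pos),

and plates with z < 0.4 are flagged non-exploitable.  Viability is each well
over the negative-control mean; summarization fits a four-parameter logistic
on log10 dose, reports the relative IC50 (midpoint of the fitted asymptotes)
and the trapezoidal AUC of percent viability over log10 dose, and z-scores
AUCs across the model panel (sensitive models fall below 0, resistant above).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

QC_MIN_ZSCORE = 0.4


class DegenerateAssayError(ValueError):
    pass


@dataclass(frozen=True)
class PlateQc:
    z_score: float
    exploitable: bool
    neg_mean: float
    neg_sd: float
    pos_mean: float
    pos_sd: float


@dataclass(frozen=True)
class DoseResponseFit:
    top: float
    bottom: float
    ic50_uM: Optional[float]   # None when the curve cannot be anchored
    hill: float
    ok: bool
    message: str = ""


def qc_zscore(neg_wells, pos_wells, *, qc_min: float = QC_MIN_ZSCORE) -> PlateQc:
    """Z'-style plate quality score from control wells (sample SD, ddof=1)."""
    neg = np.asarray(neg_wells, float)
    pos = np.asarray(pos_wells, float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("need >= 2 wells per control group")
    nm, pm = neg.mean(), pos.mean()
    if nm <= pm:
        raise DegenerateAssayError(
            f"negative-control mean ({nm:.3g}) must exceed positive-control "
            f"mean ({pm:.3g})")
    ns, ps = neg.std(ddof=1), pos.std(ddof=1)
    z = 1.0 - (3.0 * ns + 3.0 * ps) / (nm - pm)
    return PlateQc(float(z), bool(z >= qc_min), float(nm), float(ns),
                   float(pm), float(ps))


def normalize_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Add a ``viability`` column: signal over the negative-control mean."""
    neg = plate.loc[plate.role == "negative", "signal"]
    if neg.empty:
        raise ValueError("no negative-control wells on plate")
    ref = float(neg.mean())
    if ref == 0:
        raise ValueError("negative-control mean is zero")
    out = plate.copy()
    out["viability"] = out["signal"] / ref
    return out


def logistic4_log10(logd, top, bottom, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - log_ic50)))


def fit_dose_response(doses_uM, viabilities) -> DoseResponseFit:
    """Least-squares 4-parameter logistic on log10 dose.

    The IC50 is relative: the dose at the midpoint of the fitted top and
    bottom asymptotes.  A fit whose span is negligible or whose midpoint
    falls far outside the tested range yields ``ic50_uM=None`` with a
    diagnostic (typically a flat, resistant-beyond-range curve).
    """
    d = np.asarray(doses_uM, float)
    v = np.asarray(viabilities, float)
    if (d <= 0).any():
        raise ValueError("doses must be positive (log scale)")
    if len(np.unique(d)) < 4:
        raise ValueError("need >= 4 distinct doses")
    logd = np.log10(d)
    p0 = (float(v.max()), float(v.min()), float(np.median(logd)), 1.0)
    bounds = ([0.0, -0.2, logd.min() - 3, 0.05],
              [max(2.0, v.max() * 1.5), v.max(), logd.max() + 3, 10.0])
    try:
        popt, _ = optimize.curve_fit(logistic4_log10, logd, v, p0=p0,
                                     bounds=bounds, maxfev=20000)
    except RuntimeError as e:
        return DoseResponseFit(np.nan, np.nan, None, np.nan, False, str(e))
    top, bottom, log_ic50, hill = popt
    if top - bottom < 0.1:
        return DoseResponseFit(top, bottom, None, hill, False,
                               "flat curve; resistant beyond tested range")
    if not (logd.min() - 1.5 <= log_ic50 <= logd.max() + 1.5):
        return DoseResponseFit(top, bottom, None, hill, False,
                               "midpoint outside tested range")
    return DoseResponseFit(float(top), float(bottom), float(10 ** log_ic50),
                           float(hill), True)


def compute_auc(doses_uM, viabilities) -> float:
    """Trapezoidal area of viability over log10 dose.

    Callers pass viability on whatever scale they report (the panel pipeline
    uses percent); the units of the result are viability x log10-dose decades.
    """
    d = np.asarray(doses_uM, float)
    v = np.asarray(viabilities, float)
    if d.size < 2:
        raise ValueError("need >= 2 dose points")
    if (np.diff(d) <= 0).any():
        raise ValueError("doses must be sorted strictly ascending")
    return float(np.trapezoid(v, np.log10(d)))


def compute_auc_linear(doses_uM, viabilities) -> float:
    """Linear-dose AUC variant for sensitivity analyses."""
    d = np.asarray(doses_uM, float)
    if d.size < 2:
        raise ValueError("need >= 2 dose points")
    return float(np.trapezoid(np.asarray(viabilities, float), d))


def normalize_auc_zscores(aucs: dict) -> dict:
    """Panel z-scores: subtract the mean and divide by the sample SD."""
    if len(aucs) < 3:
        raise ValueError("need >= 3 models for panel z-scores")
    vals = np.array(list(aucs.values()), float)
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero AUC variance across panel")
    mu = vals.mean()
    return {k: float((v - mu) / sd) for k, v in aucs.items()}


def sensitivity_call(z: float) -> str:
    """Split the panel at normalized AUC z-score 0 (below = sensitive)."""
    return "sensitive" if z < 0 else "resistant"


def spearman_exact(x, y):
    """Spearman rho with an exact permutation p for n <= 9 (ties-free).

    For larger n, or in the presence of ties, falls back to the
    t-approximation.  Returns (rho, p, method).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    rho = stats.spearmanr(x, y).statistic
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= 9 and not ties:
        ry = stats.rankdata(y)
        obs = abs(rho)
        count = total = 0
        for perm in itertools.permutations(stats.rankdata(x)):
            r = np.corrcoef(perm, ry)[0, 1]
            count += abs(r) >= obs - 1e-12
            total += 1
        return float(rho), count / total, "exact"
    return float(rho), float(stats.spearmanr(x, y).pvalue), "t-approx"


def correlate_drugs(z_matrix: pd.DataFrame):
    """Pairwise Spearman correlation of drug z-score profiles across models.

    ``z_matrix`` is models x drugs; pairs are formed on complete rows.
    Constant columns yield NaN (flagged undefined).  Returns (r, p)
    DataFrames, drugs x drugs.
    """
    drugs = list(z_matrix.columns)
    r = pd.DataFrame(np.eye(len(drugs)), index=drugs, columns=drugs)
    p = pd.DataFrame(np.zeros((len(drugs), len(drugs))), index=drugs,
                     columns=drugs)
    for a, b in itertools.combinations(drugs, 2):
        sub = z_matrix[[a, b]].dropna()
        if len(sub) < 5:
            raise ValueError(f"fewer than 5 complete pairs for {a}/{b}")
        if sub[a].nunique() == 1 or sub[b].nunique() == 1:
            rho, pv = np.nan, np.nan
        else:
            rho, pv, _ = spearman_exact(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = rho
        p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def summarize_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Summarize a (model, drug, dose_uM, viability) panel table.

    Replicates are averaged per dose before fitting; AUC uses percent
    viability over log10 dose on the drug's common grid; z-scores are per
    drug across models.  Output: model, drug, ic50_uM, auc, auc_zscore, call.
    """
    rows = []
    for (model, drug), sub in panel.groupby(["model", "drug"], sort=True):
        per_dose = sub.groupby("dose_uM", sort=True)["viability"].mean()
        fit = fit_dose_response(per_dose.index, per_dose.to_numpy())
        auc = compute_auc(per_dose.index, 100.0 * per_dose.to_numpy())
        rows.append((model, drug, fit.ic50_uM, auc))
    out = pd.DataFrame(rows, columns=["model", "drug", "ic50_uM", "auc"])
    zs = []
    for drug, sub in out.groupby("drug"):
        z = normalize_auc_zscores(dict(zip(sub.model, sub.auc)))
        zs.append(pd.DataFrame({"model": list(z), "drug": drug,
                                "auc_zscore": list(z.values())}))
    out = out.merge(pd.concat(zs, ignore_index=True), on=["model", "drug"])
    out["call"] = out["auc_zscore"].map(sensitivity_call)
    return out
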