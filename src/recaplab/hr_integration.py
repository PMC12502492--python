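"""HR-status integration: GIS banding, variant filtering, concordance and
survival comparisons.

A genomic instability score (GIS) in [0, 1] — near 0 for HR-proficient,
near 1 for HR-deficient tumors — is banded around the FFPE-calibrated
decision threshold 0.48 with a +/-0.25 indeterminate margin, giving
HRP < 0.23 <= HRDmid <= 0.73 < HRD.  Variants feed the score only when
VAF >= 5% and the call is oncogenic or predicted inactivating.  The
functional RECAP call is cross-tabulated against the GIS band, and
platinum-free-interval (PFI) outcomes are compared between groups with
Kaplan-Meier curves, the log-rank test, its Gehan-Breslow-Wilcoxon
(early-weighted) variant and the Mann-Whitney test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

GIS_THRESHOLD = 0.48
GIS_MARGIN = 0.25
PFI_SENSITIVE_MONTHS = 6.0
MW_EXACT_MAX_N = 12

BANDS = ("HRP", "HRDmid", "HRD")


def classify_gis(score: float, threshold: float = GIS_THRESHOLD,
                 margin: float = GIS_MARGIN) -> str:
    """Band a GIS score: HRP below the band, HRD above, HRDmid on the
    closed interval [threshold - margin, threshold + margin]."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"GIS score {score} outside [0, 1]")
    lo, hi = threshold - margin, threshold + margin
    if score < lo:
        return "HRP"
    if score <= hi:
        return "HRDmid"
    return "HRD"


def gis_binary(score: float, threshold: float = GIS_THRESHOLD) -> str:
    """Two-way call for analyses that cannot carry an indeterminate band."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"GIS score {score} outside [0, 1]")
    return "HRD" if score >= threshold else "HRP"


def filter_variants(records: pd.DataFrame, min_vaf: float = 0.05) -> pd.DataFrame:
    """Apply the reporting rule: keep iff VAF >= min_vaf (inclusive) and the
    variant is oncogenic or predicted inactivating.

    Returns a copy with ``kept`` and ``drop_reason`` columns; the kept subset
    is ``out[out.kept]``.
    """
    for col in ("vaf", "oncogenic", "inactivating"):
        if col not in records.columns:
            raise ValueError(f"variant table missing column {col!r}")
    out = records.copy()
    low = out.vaf < min_vaf
    unannotated = ~(out.oncogenic | out.inactivating)
    out["kept"] = ~(low | unannotated)
    reason = np.where(low & unannotated, "low VAF; not oncogenic/inactivating",
                      np.where(low, "VAF below threshold",
                               np.where(unannotated,
                                        "not oncogenic or inactivating", "")))
    out["drop_reason"] = reason
    return out


def concordance_table(recap_status: dict, gis_band: dict):
    """Cross-tabulate RECAP calls against GIS bands on shared models.

    Returns ``(table, reclassified)`` where ``reclassified`` lists the
    models the functional assay moves out of genomic proficiency
    (GIS HRP but RECAP HRD) — the clinically interesting discordance.
    """
    shared = sorted(set(recap_status) & set(gis_band))
    if not shared:
        raise ValueError("no shared model ids between RECAP and GIS tables")
    df = pd.DataFrame({"model": shared,
                       "recap": [recap_status[m] for m in shared],
                       "gis": [gis_band[m] for m in shared]})
    table = pd.crosstab(df.recap, df.gis)
    reclassified = sorted(df.loc[(df.gis == "HRP") & (df.recap == "HRD"),
                                 "model"])
    return table, reclassified


@dataclass(frozen=True)
class KmEstimate:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: Optional[float]      # None when S(t) never reaches 0.5


def km_estimate(durations, events) -> KmEstimate:
    """Product-limit survival estimate; median is the smallest time with
    S(t) <= 0.5, undefined (None) if never reached."""
    durations = np.asarray(durations, float)
    events = np.asarray(events, bool)
    if not events.any():
        kmf = KaplanMeierFitter().fit(durations, events)
        t = kmf.survival_function_.index.to_numpy()
        s = kmf.survival_function_.iloc[:, 0].to_numpy()
        return KmEstimate(t, s, _at_risk(durations, t), None)
    kmf = KaplanMeierFitter().fit(durations, events)
    t = kmf.survival_function_.index.to_numpy()
    s = kmf.survival_function_.iloc[:, 0].to_numpy()
    med = kmf.median_survival_time_
    return KmEstimate(t, s, _at_risk(durations, t),
                      None if np.isinf(med) else float(med))


def _at_risk(durations, times):
    return np.array([(durations >= t).sum() for t in times])


def logrank_test(dur_a, evt_a, dur_b, evt_b):
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    res = _ll_logrank(dur_a, dur_b, event_observed_A=evt_a,
                      event_observed_B=evt_b)
    return float(res.test_statistic), float(res.p_value)


def gehan_weighted_oe(dur_a, evt_a, dur_b, evt_b) -> float:
    """Weighted observed-minus-expected numerator of the Gehan-Breslow-
    Wilcoxon test (weight = total number at risk at each event time).

    Without censoring this equals minus the pairwise Gehan score
    sum_{i in A, j in B} sign(t_i - t_j).
    """
    dur_a = np.asarray(dur_a, float); evt_a = np.asarray(evt_a, bool)
    dur_b = np.asarray(dur_b, float); evt_b = np.asarray(evt_b, bool)
    event_times = np.unique(np.concatenate([dur_a[evt_a], dur_b[evt_b]]))
    num = 0.0
    for t in event_times:
        na = (dur_a >= t).sum()
        nb = (dur_b >= t).sum()
        nt = na + nb
        oa = ((dur_a == t) & evt_a).sum()
        d = oa + ((dur_b == t) & evt_b).sum()
        num += nt * (oa - d * na / nt)
    return float(num)


def gehan_breslow_wilcoxon(dur_a, evt_a, dur_b, evt_b):
    """Gehan-Breslow-Wilcoxon test: log-rank family weighted by the number
    at risk, emphasizing early differences.  Returns (statistic, p)."""
    res = _ll_logrank(dur_a, dur_b, event_observed_A=evt_a,
                      event_observed_B=evt_b, weightings="wilcoxon")
    return float(res.test_statistic), float(res.p_value)


def mann_whitney(x, y):
    """Two-sided Mann-Whitney U; exact p by enumeration when the pooled
    sample is small (<= 12) and ties-free, normal approximation with tie
    correction otherwise.  Returns (U for x, p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= MW_EXACT_MAX_N and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def platinum_sensitive(pfi_months: float,
                       threshold: float = PFI_SENSITIVE_MONTHS) -> bool:
    """Platinum-sensitive iff PFI >= 6 months (printed rule)."""
    return pfi_months >= threshold


def cnv_similarity(profile_a, profile_b) -> float:
    """Similarity of two equal-length binned copy-number profiles.

    The metric is Pearson correlation on pairwise non-NaN bins — an explicit
    stand-in, since bounded similarity scores for CNV profiles are not
    standardized.
    """
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValueError("fewer than 2 shared informative bins")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def compare_pfi_by_status(survival: pd.DataFrame, group_col: str = "group"):
    """KM per group plus log-rank and Gehan-Breslow-Wilcoxon between the two
    groups of a survival table (patient, group, pfi_months, event)."""
    groups = sorted(survival[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    subs = [survival[survival[group_col] == g] for g in groups]
    kms = {g: km_estimate(s.pfi_months, s.event) for g, s in zip(groups, subs)}
    lr = logrank_test(subs[0].pfi_months, subs[0].event,
                      subs[1].pfi_months, subs[1].event)
    gbw = gehan_breslow_wilcoxon(subs[0].pfi_months, subs[0].event,
                                 subs[1].pfi_months, subs[1].event)
    return {"groups": groups,
            "km": kms,
            "median_pfi": {g: kms[g].median for g in groups},
            "logrank": {"statistic": lr[0], "p": lr[1]},
            "gehan_breslow_wilcoxon": {"statistic": gbw[0], "p": gbw[1]}}
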