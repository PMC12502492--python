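"""RECAP index computation and HR-status classification.

Per-nucleus RAD51 focus-count histograms for each condition (unirradiated
control, 2 h and 24 h after 5 Gy) are smoothed by fitting a Gaussian mixture;
in practice one component dominates, and with a single component the fit is
exactly the sample mean and SD.  Three indices summarize each model:

    DI  = mean(control)            damage index (basal foci)
    RDI = mean(2 h) - mean(control)  radiation-induced damage index
    RI  = mean(24 h) - mean(2 h)     reparation index

Models are then classified by PCA on the standardized (DI, RDI, RI) matrix:
PC1 is oriented so the RDI loading is non-negative (proficient models, which
induce foci, fall on the positive side) and a model is called HRD when its
PC1 score is strictly below the cutoff, -0.5 by default.  The cutoff is a
calibration constant; on a new panel it is a free parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .synthgen import CONDITIONS

HRD, HRP = "HRD", "HRP"
DEFAULT_PC1_CUTOFF = -0.5
MIN_NUCLEI = 20


class InsufficientNucleiError(ValueError):
    def __init__(self, n, minimum):
        self.n, self.minimum = n, minimum
        super().__init__(f"only {n} nuclei; need at least {minimum}")


class MissingConditionError(ValueError):
    pass


@dataclass(frozen=True)
class ConditionGaussian:
    """Dominant Gaussian component of one condition's focus-count histogram."""

    condition: str
    mean: float
    sd: float
    n_nuclei: int
    weight: float = 1.0


@dataclass(frozen=True)
class RecapIndices:
    model: str
    DI: float
    RDI: float
    RI: float


def fit_count_gaussian(counts, n_components: int = 1, *,
                       condition: str = "", min_nuclei: int = MIN_NUCLEI,
                       seed: int = 0) -> ConditionGaussian:
    """Fit a Gaussian mixture to per-nucleus focus counts; return the
    largest-weight component.

    With ``n_components=1`` the EM fixed point is the sample mean and the
    maximum-likelihood (ddof=0) SD, so those are returned in closed form.
    """
    counts = np.asarray(counts, float)
    if counts.size < min_nuclei:
        raise InsufficientNucleiError(counts.size, min_nuclei)
    if n_components == 1:
        return ConditionGaussian(condition, float(counts.mean()),
                                 float(counts.std(ddof=0)), counts.size, 1.0)
    gm = GaussianMixture(n_components=n_components, tol=1e-6, max_iter=500,
                         n_init=3, random_state=seed, reg_covar=1e-10)
    gm.fit(counts.reshape(-1, 1))
    j = int(np.argmax(gm.weights_))
    return ConditionGaussian(condition, float(gm.means_[j, 0]),
                             float(np.sqrt(gm.covariances_[j, 0, 0])),
                             counts.size, float(gm.weights_[j]))


def compute_indices(g_ctrl, g_2h, g_24h, *, model: str = "") -> RecapIndices:
    """DI/RDI/RI exactly as defined from the three condition Gaussians."""
    for name, g in (("control", g_ctrl), ("post2h", g_2h), ("post24h", g_24h)):
        if g is None:
            raise MissingConditionError(f"condition {name!r} missing")
    return RecapIndices(model=model, DI=float(g_ctrl.mean),
                        RDI=float(g_2h.mean - g_ctrl.mean),
                        RI=float(g_24h.mean - g_2h.mean))


def indices_from_foci_table(foci: pd.DataFrame, *, n_components: int = 1,
                            min_nuclei: int = MIN_NUCLEI, seed: int = 0
                            ) -> pd.DataFrame:
    """Per-model DI/RDI/RI from a FociTable, using Cyclin A2-positive nuclei only."""
    foci = foci[foci["cyca2_positive"]]
    rows = []
    for model, sub in foci.groupby("model", sort=True):
        gs = {}
        for cond in CONDITIONS:
            counts = sub.loc[sub.condition == cond, "focus_count"].to_numpy()
            if counts.size == 0:
                raise MissingConditionError(
                    f"model {model!r}: condition {cond!r} missing")
            gs[cond] = fit_count_gaussian(counts, n_components,
                                          condition=cond,
                                          min_nuclei=min_nuclei, seed=seed)
        idx = compute_indices(gs["control"], gs["post2h"], gs["post24h"],
                              model=model)
        rows.append((model, idx.DI, idx.RDI, idx.RI))
    return pd.DataFrame(rows, columns=["model", "DI", "RDI", "RI"])


def classify_recap(indices: pd.DataFrame,
                   cutoff: float = DEFAULT_PC1_CUTOFF):
    """PCA of the standardized index matrix and HRD/HRP call on PC1.

    Columns are z-standardized across models (sample SD), PCA is the
    eigen-decomposition of the resulting correlation matrix, and PC1 is
    sign-oriented so the RDI loading is >= 0.  Status is HRD iff
    ``pc1 < cutoff`` (strict; a score exactly at the cutoff is HRP).

    Returns ``(classification, loadings)``: a DataFrame
    (model, pc1, pc2, status) and a DataFrame of unit-norm loadings
    (features x components).
    """
    if len(indices) < 3:
        raise ValueError(f"PCA needs >= 3 models, got {len(indices)}")
    feats = ["DI", "RDI", "RI"]
    X = indices[feats].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(feats, keep) if not k]
        warnings.warn(f"zero-variance columns dropped from PCA: {dropped}")
    feats = [f for f, k in zip(feats, keep) if k]
    X = X[:, keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = (Z.T @ Z) / (len(Z) - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    # orient PC1 by the RDI loading; remaining components by largest element
    if "RDI" in feats and evecs[feats.index("RDI"), 0] < 0:
        evecs[:, 0] *= -1
    for j in range(1, evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] *= -1
    scores = Z @ evecs
    out = pd.DataFrame({
        "model": indices["model"].to_numpy(),
        "pc1": scores[:, 0],
        "pc2": scores[:, 1] if scores.shape[1] > 1 else 0.0,
    })
    out["status"] = np.where(out.pc1 < cutoff, HRD, HRP)
    loadings = pd.DataFrame(evecs, index=feats,
                            columns=[f"PC{j + 1}" for j in range(evecs.shape[1])])
    return out, loadings


def classify_cohort(foci: pd.DataFrame, cutoff: float = DEFAULT_PC1_CUTOFF,
                    **kw):
    """FociTable -> (indices, classification, loadings)."""
    idx = indices_from_foci_table(foci, **kw)
    cls, loadings = classify_recap(idx, cutoff)
    return idx, cls, loadings
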