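"""Tumor/organoid transcriptomic concordance via NMF program projection.

Counts are variance-stabilized (size-factor log transform), non-negative
matrix factorization is fitted on the organoid samples only over a range of
ranks, the learned programs (W) are projected onto every sample — tumors and
organoids — by non-negative least squares (linear combination decomposition),
samples are embedded in 2-D, and the rank minimizing the summed embedded
distance between matched tumor/organoid pairs is selected.  Per-program
signatures are the top few percent of genes by factor weight.

The NMF here is plain multiplicative-update Frobenius NMF with a per-
iteration objective trace, because the monotone non-increase of that
objective is an asserted invariant of the pipeline; sklearn's 'mu' solver
serves as an independent cross-check in the test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

DEFAULT_RANKS = tuple(range(2, 19))


# ---------------------------------------------------------------------------
# variance stabilization


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per-sample median ratio to the per-gene
    geometric-mean reference over genes expressed in all samples."""
    X = counts.to_numpy(float)
    if (X.sum(axis=0) == 0).any():
        bad = counts.columns[X.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    with np.errstate(divide="ignore"):
        logX = np.log(X)
    ref = logX.mean(axis=1)                      # -inf where any zero
    usable = np.isfinite(ref)
    if not usable.any():
        raise ValueError("no gene expressed in every sample")
    ratios = logX[usable] - ref[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def vst_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing transform: log2(count / size_factor + 1) with
    median-of-ratios size factors.  All-zero gene rows are dropped (logged)."""
    zero = counts.sum(axis=1) == 0
    if zero.any():
        logger.info("dropping %d all-zero gene rows", int(zero.sum()))
        counts = counts.loc[~zero]
    sf = median_of_ratios_size_factors(counts)
    return np.log2(counts.div(sf, axis=1) + 1.0)


# ---------------------------------------------------------------------------
# NMF


@dataclass
class FactorModel:
    rank: int
    W: pd.DataFrame                 # genes x k, columns unit L2 norm
    H: pd.DataFrame                 # k x samples
    error: float                    # final Frobenius norm of the residual
    n_iter: int
    error_history: np.ndarray = field(repr=False, default=None)

    @property
    def monotone(self) -> bool:
        return bool(np.all(np.diff(self.error_history) <= 1e-9))


def fit_nmf(matrix: pd.DataFrame, k: int, seed: int = 0, *,
            tol: float = 1e-5, max_iter: int = 2000) -> FactorModel:
    """Multiplicative-update NMF minimizing the Frobenius error.

    Random non-negative init from the seed; stops when the relative change
    of the objective drops below ``tol``.  After convergence W columns are
    rescaled to unit L2 norm (scale moved into H) so exposures are
    comparable across ranks.
    """
    X = np.asarray(matrix, float)
    if (X < 0).any():
        raise ValueError("matrix must be non-negative (clip after VST)")
    if not k < min(X.shape):
        raise ValueError(f"rank {k} must be < min(matrix dims) {min(X.shape)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W = rng.uniform(1e-3, 1.0, (X.shape[0], k)) * scale
    H = rng.uniform(1e-3, 1.0, (k, X.shape[1])) * scale
    eps = 1e-12
    errs = [np.linalg.norm(X - W @ H)]
    for it in range(1, max_iter + 1):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ (H @ H.T) + eps)
        err = np.linalg.norm(X - W @ H)
        errs.append(err)
        if errs[-2] > 0 and (errs[-2] - errs[-1]) / errs[-2] < tol:
            break
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = H * norms[:, None]
    genes = matrix.index if isinstance(matrix, pd.DataFrame) else range(X.shape[0])
    samples = matrix.columns if isinstance(matrix, pd.DataFrame) else range(X.shape[1])
    factors = [f"F{j + 1}" for j in range(k)]
    return FactorModel(rank=k,
                       W=pd.DataFrame(W, index=genes, columns=factors),
                       H=pd.DataFrame(H, index=factors, columns=samples),
                       error=float(errs[-1]), n_iter=it,
                       error_history=np.array(errs))


def project_lcd(W: pd.DataFrame, matrix: pd.DataFrame) -> pd.DataFrame:
    """Linear combination decomposition: non-negative least squares of each
    sample's profile onto the columns of W.  Returns samples x factors."""
    missing = W.index.difference(matrix.index)
    if len(missing):
        raise ValueError(f"matrix missing {len(missing)} genes from W, e.g. "
                         f"{missing[:5].tolist()}")
    A = W.to_numpy(float)
    X = matrix.loc[W.index].to_numpy(float)
    expo = np.stack([nnls(A, X[:, j])[0] for j in range(X.shape[1])])
    return pd.DataFrame(expo, index=matrix.columns, columns=W.columns)


# ---------------------------------------------------------------------------
# embedding and rank selection


def embed_exposures(exposures: pd.DataFrame, method: str = "umap",
                    seed: int = 0, n_neighbors: int = 8) -> pd.DataFrame:
    """2-D embedding of a samples x factors exposure matrix.

    'umap' (default, used by rank selection) is a seeded, hence
    deterministic, UMAP emphasizing local neighborhood structure — which is
    what lets matched pairs co-locate once the rank suffices.  'pca' is a
    fully linear deterministic alternative: centered SVD scores with a fixed
    sign convention.
    """
    if len(exposures) < 3:
        raise ValueError("need >= 3 samples to embed")
    X = exposures.to_numpy(float)
    if method == "pca":
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for j in range(min(2, Vt.shape[0])):
            if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
                U[:, j] *= -1
        coords = U[:, :2] * s[:2]
        if coords.shape[1] < 2:
            coords = np.column_stack([coords, np.zeros(len(X))])
    elif method == "umap":
        import umap
        coords = umap.UMAP(n_components=2, random_state=seed,
                           n_neighbors=min(n_neighbors, len(X) - 1)
                           ).fit_transform(X)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=exposures.index, columns=["e1", "e2"])


@dataclass
class RankSelection:
    distances: dict                 # rank -> summed paired distance
    chosen_k: int
    models: dict = field(repr=False, default_factory=dict)
    embeddings: dict = field(repr=False, default_factory=dict)


def paired_distances(embedding: pd.DataFrame, pairing: dict) -> float:
    """Sum of Euclidean distances between matched pairs in an embedding."""
    total = 0.0
    for tumor, organoid in pairing.items():
        if tumor not in embedding.index or organoid not in embedding.index:
            raise ValueError(f"unpaired or missing sample: {tumor}/{organoid}")
        d = embedding.loc[tumor] - embedding.loc[organoid]
        total += float(np.hypot(d.iloc[0], d.iloc[1]))
    return total


def select_rank(counts: pd.DataFrame, pairing: dict,
                ks=DEFAULT_RANKS, seed: int = 0, *,
                embed_method: str = "umap",
                normalize_exposures: bool = True,
                n_embed_reps: int = 3,
                already_transformed: bool = False) -> RankSelection:
    """Choose the NMF rank minimizing the summed embedded distance between
    matched tumor/organoid pairs.

    For each candidate rank: fit NMF on the organoid columns of the
    stabilized matrix, project the factors onto all samples by NNLS,
    normalize each sample's exposures to proportions (removing the
    stromal-dilution scale difference between a tumor and its organoid),
    embed in 2-D, and sum the pair distances.  With the UMAP embedding the
    per-rank score is the median over ``n_embed_reps`` seeded embedding
    replicates, which damps near-ties caused by embedding stochasticity.
    The chosen rank is the argmin over the tested range (first hit on ties).
    """
    organoids = list(pairing.values())
    missing = [s for s in list(pairing) + organoids if s not in counts.columns]
    if missing:
        raise ValueError(f"samples missing from matrix: {missing}")
    mat = counts if already_transformed else vst_transform(counts)
    mat = mat.clip(lower=0.0)
    valid = [k for k in ks if k < len(organoids)]
    if not valid:
        raise ValueError("no tested rank is below the organoid sample count")
    if len(valid) < len(list(ks)):
        logger.info("ranks >= %d skipped (only %d organoid samples)",
                    len(organoids), len(organoids))
    distances, models, embeddings = {}, {}, {}
    for k in valid:
        fm = fit_nmf(mat[organoids], k, seed=seed)
        expo = project_lcd(fm.W, mat)
        if normalize_exposures:
            totals = expo.sum(axis=1)
            expo = expo.div(totals.where(totals > 0, 1.0), axis=0)
        reps = n_embed_reps if embed_method == "umap" else 1
        ds, embs = [], []
        for r in range(reps):
            emb = embed_exposures(expo, method=embed_method,
                                  seed=seed + 1000 * r)
            ds.append(paired_distances(emb, pairing))
            embs.append(emb)
        distances[k] = float(np.median(ds))
        models[k], embeddings[k] = fm, embs[int(np.argsort(ds)[len(ds) // 2])]
    chosen = min(distances, key=distances.get)
    return RankSelection(distances=distances, chosen_k=chosen,
                         models=models, embeddings=embeddings)


def signature_top_genes(W: pd.DataFrame, pct: float = 5.0) -> dict:
    """Per-factor signatures: the top ``pct`` percent of genes by weight,
    descending."""
    if not 0 < pct <= 100:
        raise ValueError("pct must be in (0, 100]")
    n = max(1, int(round(len(W) * pct / 100.0)))
    return {f: W[f].sort_values(ascending=False).head(n).index.tolist()
            for f in W.columns}


def paired_gene_correlation(tumor_col, organoid_col):
    """Pearson R and R^2 between one tumor's and its organoid's profiles."""
    x = np.asarray(tumor_col, float)
    y = np.asarray(organoid_col, float)
    if x.shape != y.shape:
        raise ValueError("profiles must share the gene set")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r


def min_distance_pair_matching(embedding: pd.DataFrame, pairing: dict) -> float:
    """Fraction of tumors whose nearest organoid in the embedding is their
    own matched organoid (a parameter-recovery diagnostic)."""
    organoids = list(pairing.values())
    correct = 0
    for tumor, organoid in pairing.items():
        d = [(np.linalg.norm(embedding.loc[tumor] - embedding.loc[o]), o)
             for o in organoids]
        correct += min(d)[1] == organoid
    return correct / len(pairing)
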