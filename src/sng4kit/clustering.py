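"""The identity-imputation stack.

This module owns the transforms and clusterers used to call the cell type of
single-cell clusters from their aggregate G4 signal:

* pairwise Spearman correlation of library RPM profiles;
* the z-score / 75th-quantile-cap / [0, 1]-rescale signal transform;
* PAM and CLARA k-medoids, implemented from scratch (BUILD + best-improvement
  SWAP; CLARA subsamples carry the incumbent medoids);
* average-linkage hierarchical clustering of the correlation matrix;
* an LSI (TF-IDF + truncated SVD) embedding plus k-medoids as a functional
  stand-in for the original graph-based cell clustering — cluster recovery is
  claimed, algorithmic fidelity is not.

All stochastic operations take an explicit seed; nothing touches global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform

from .signal import CellRegionMatrix, LibrarySignalMatrix

__all__ = [
    "CorrelationMatrix",
    "ClusterAssignment",
    "IdentityCall",
    "IdentityResult",
    "spearman_matrix",
    "transform_signal_matrix",
    "pam_kmedoids",
    "clara",
    "hierarchical_cluster",
    "impute_cluster_identity",
    "lsi_embed",
    "cluster_cells",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman correlation matrix with unit diagonal.

    constant_labels flags libraries with zero-variance profiles, whose
    correlations are recorded as 0 rather than NaN.
    """

    values: pd.DataFrame
    constant_labels: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # cluster index per item
    medoids: np.ndarray         # item indices, ascending
    total_dissimilarity: float


@dataclass
class IdentityCall:
    cluster: str
    label: str
    r_s: float
    margin: float
    low_confidence: bool


@dataclass
class IdentityResult:
    calls: list[IdentityCall]
    correlations: CorrelationMatrix
    locus_archetypes: ClusterAssignment | None = None


def _as_rpm_frame(signal) -> pd.DataFrame:
    if isinstance(signal, LibrarySignalMatrix):
        return signal.rpm
    return pd.DataFrame(signal)


def spearman_matrix(signal) -> CorrelationMatrix:
    """Pairwise Spearman correlation across library columns.

    Ties receive average ranks. A constant column correlates 0 against
    everything (flagged in constant_labels); the diagonal is exactly 1.
    """
    rpm = _as_rpm_frame(signal)
    if rpm.shape[1] < 2:
        raise ValueError("need >= 2 libraries")
    if rpm.shape[0] < 3:
        raise ValueError("need >= 3 regions for a meaningful correlation")
    X = rpm.to_numpy(dtype=float)
    constant = X.std(axis=0) == 0
    ranks = np.apply_along_axis(stats.rankdata, 0, X)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    labels = list(rpm.columns)
    return CorrelationMatrix(
        pd.DataFrame(corr, index=labels, columns=labels),
        [l for l, c in zip(labels, constant) if c],
    )


def transform_signal_matrix(signal) -> pd.DataFrame:
    """z-score rows, cap at the global 75th percentile, rescale to [0, 1].

    Step 1 z-scores each region row across libraries (sample sd, ddof=1).
    Rows with zero variance carry no locus pattern; they are mapped to the
    global minimum z-value so that "flat" reads as "low signal" on the final
    0-1 scale. Step 2 computes the 75th percentile (linear interpolation)
    over all entries and caps values above it. Step 3 min-max rescales the
    whole matrix to [0, 1] (all-equal input maps to all zeros).
    """
    rpm = _as_rpm_frame(signal)
    if rpm.shape[1] < 2:
        raise ValueError("z-score undefined for a single library")
    X = rpm.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    Z = np.zeros_like(X)
    np.divide(X - mu, sd, out=Z, where=sd > 0)
    if flat.all():
        return pd.DataFrame(np.zeros_like(X), index=rpm.index, columns=rpm.columns)
    Z[flat, :] = Z[~flat, :].min()
    q = np.percentile(Z, 75)
    Z = np.minimum(Z, q)
    lo, hi = Z.min(), Z.max()
    if hi == lo:
        Z = np.zeros_like(Z)
    else:
        Z = (Z - lo) / (hi - lo)
    return pd.DataFrame(Z, index=rpm.index, columns=rpm.columns)


def _validate_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0):
        raise ValueError("dissimilarity diagonal must be zero")
    if (d < 0).any():
        raise ValueError("dissimilarity must be non-negative")
    return d


def pam_kmedoids(dissimilarity: np.ndarray, k: int, seed: int | None = None
                 ) -> ClusterAssignment:
    """Partitioning Around Medoids: greedy BUILD then best-improvement SWAP.

    SWAP scans every (medoid, non-medoid) exchange and applies the single
    best strictly improving one until a local optimum; ties break toward the
    lowest item index. Deterministic given the input (seed accepted for API
    uniformity, unused).
    """
    d = _validate_dissimilarity(dissimilarity)
    n = d.shape[0]
    if not (1 <= k < n):
        raise ValueError(f"require 1 <= k < n, got k={k}, n={n}")
    # BUILD: start with the 1-medoid optimum, greedily add
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        costs = np.minimum(nearest[:, None], d).sum(axis=0)
        costs[medoids] = np.inf
        medoids.append(int(np.argmin(costs)))
    medoids = sorted(medoids)
    best_cost = float(d[:, medoids].min(axis=1).sum())
    # SWAP
    while True:
        best_swap = None
        best_new = best_cost
        for mi in range(len(medoids)):
            others = medoids[:mi] + medoids[mi + 1:]
            base = (
                d[:, others].min(axis=1) if others else np.full(n, np.inf)
            )
            cand = np.setdiff1d(np.arange(n), medoids)
            costs = np.minimum(base[:, None], d[:, cand]).sum(axis=0)
            j = int(np.argmin(costs))  # first occurrence = lowest item index
            if costs[j] < best_new:
                best_new = float(costs[j])
                best_swap = (mi, int(cand[j]))
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        medoids = sorted(medoids)
        best_cost = best_new
    med = np.asarray(sorted(medoids), dtype=np.int64)
    labels = np.argmin(d[:, med], axis=1).astype(np.int64)
    total = float(d[np.arange(n), med[labels]].sum())
    return ClusterAssignment(labels, med, total)


def _euclidean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return cdist(np.atleast_2d(a), np.atleast_2d(b))


def clara(
    items: np.ndarray,
    k: int,
    n_samples: int = 5,
    sample_size: int | None = None,
    seed: int = 0,
    dissimilarity_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = _euclidean,
) -> ClusterAssignment:
    """CLARA: PAM on random subsamples, scored over all items.

    Each of n_samples subsamples (default size 40 + 2k, the original CLARA
    convention) includes the best medoids found so far; candidate medoid sets
    are evaluated by total dissimilarity over the full data set and the best
    kept. With sample_size >= n this reduces exactly to PAM on all items.
    """
    items = np.asarray(items, dtype=float)
    if items.ndim == 1:
        items = items[:, None]
    n = len(items)
    if sample_size is None:
        sample_size = 40 + 2 * k
    if sample_size < k:
        raise ValueError("sample_size must be >= k")
    if n < k + 1:
        raise ValueError("need more items than medoids")
    ss = min(sample_size, n)
    rng = np.random.default_rng(seed)
    best: ClusterAssignment | None = None
    best_meds: np.ndarray = np.empty(0, dtype=np.int64)
    for _ in range(n_samples):
        if ss >= n:
            idx = np.arange(n)
        else:
            pool = np.setdiff1d(np.arange(n), best_meds)
            extra = rng.choice(pool, size=ss - len(best_meds), replace=False)
            idx = np.sort(np.concatenate([best_meds, extra]))
        sub = items[idx]
        res = pam_kmedoids(dissimilarity_fn(sub, sub), k)
        meds = np.sort(idx[res.medoids])
        dall = dissimilarity_fn(items, items[meds])
        labels = np.argmin(dall, axis=1).astype(np.int64)
        total = float(dall[np.arange(n), labels].sum())
        if best is None or total < best.total_dissimilarity:
            best = ClusterAssignment(labels, meds, total)
            best_meds = meds
        if ss >= n:
            break  # deterministic reduction to PAM; further samples identical
    assert best is not None
    return best


def hierarchical_cluster(corr: CorrelationMatrix) -> np.ndarray:
    """Average-linkage agglomeration on distance d = 1 - r_s.

    Returns the scipy linkage matrix (merge order and heights).
    """
    d = 1.0 - corr.values.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def impute_cluster_identity(
    signal: LibrarySignalMatrix,
    cluster_columns: Sequence[str],
    reference_labels: Mapping[str, str],
    min_margin: float = 0.05,
    clara_k: int = 4,
    clara_seed: int = 0,
    run_locus_clustering: bool = True,
) -> IdentityResult:
    """Assign each single-cell cluster the reference label whose library
    correlates best (Spearman) with its aggregate profile.

    margin is best minus second-best label-level correlation; calls under
    min_margin are flagged low-confidence, not rejected. For concordance the
    transformed joint matrix is also clustered by CLARA (K=4 locus
    archetypes) and reported.
    """
    rpm = _as_rpm_frame(signal)
    missing = set(cluster_columns) - set(rpm.columns)
    missing |= set(reference_labels) - set(rpm.columns)
    if missing:
        raise ValueError(f"columns absent from signal matrix: {sorted(missing)}")
    if not set(reference_labels.values()):
        raise ValueError("no reference labels")
    corr = spearman_matrix(rpm)
    calls = []
    for cl in cluster_columns:
        # best correlation per candidate label (max over that label's refs)
        per_label: dict[str, float] = {}
        for ref, lab in reference_labels.items():
            r = float(corr.values.loc[cl, ref])
            per_label[lab] = max(per_label.get(lab, -np.inf), r)
        ordered = sorted(per_label.items(), key=lambda kv: (-kv[1], kv[0]))
        best_label, best_r = ordered[0]
        second = ordered[1][1] if len(ordered) > 1 else -1.0
        margin = best_r - second
        calls.append(
            IdentityCall(str(cl), best_label, best_r, float(margin),
                         margin < min_margin)
        )
    archetypes = None
    if run_locus_clustering:
        transformed = transform_signal_matrix(rpm)
        archetypes = clara(
            transformed.to_numpy(), k=clara_k, seed=clara_seed
        )
    return IdentityResult(calls, corr, archetypes)


def lsi_embed(
    matrix: CellRegionMatrix,
    n_dims: int = 15,
    drop_first: bool = True,
) -> tuple[np.ndarray, list[str], dict]:
    """Latent semantic indexing of a cells x regions count matrix.

    Counts are binarized, TF-IDF weighted (term frequency x
    log(1 + n_cells / region_cell_count)), row-L2 normalized and projected
    onto the top singular directions. Component 1 tracks sequencing depth
    and is dropped by default. Deterministic: signs follow the
    largest-magnitude-loading-positive convention. All-zero cells are
    dropped and reported.
    """
    X = (matrix.counts > 0).astype(float).toarray()
    row_tot = X.sum(axis=1)
    keep_cells = row_tot > 0
    col_tot = X[keep_cells].sum(axis=0)
    keep_regions = col_tot > 0
    X = X[np.ix_(keep_cells, keep_regions)]
    barcodes = [b for b, k in zip(matrix.barcodes, keep_cells) if k]
    n_cells = X.shape[0]
    n_comp = n_dims + (1 if drop_first else 0)
    if n_cells <= n_comp or X.shape[1] <= n_comp:
        raise ValueError("not enough non-empty cells/regions for n_dims")
    tf = X / X.sum(axis=1, keepdims=True)
    idf = np.log(1 + n_cells / X.sum(axis=0))
    W = tf * idf
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    W = W / norms
    U, S, Vt = np.linalg.svd(W, full_matrices=False)
    # fixed-sign convention: largest-|loading| entry of each component > 0
    for i in range(n_comp):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    emb = U[:, :n_comp] * S[:n_comp]
    if drop_first:
        emb = emb[:, 1:]
    report = {
        "n_cells_dropped": int((~keep_cells).sum()),
        "n_regions_dropped": int((~keep_regions).sum()),
        "n_components": int(emb.shape[1]),
    }
    return emb, barcodes, report


def cluster_cells(
    embedding: np.ndarray,
    k: int = 2,
    seed: int = 0,
    clara_threshold: int = 2000,
) -> ClusterAssignment:
    """k-medoids on Euclidean embedding distances.

    PAM up to clara_threshold cells, CLARA beyond (keeps the swap scan
    tractable on large runs).
    """
    embedding = np.asarray(embedding, dtype=float)
    n = len(embedding)
    if k > n:
        raise ValueError("k exceeds number of cells")
    if n > clara_threshold:
        return clara(embedding, k=k, seed=seed)
    return pam_kmedoids(cdist(embedding, embedding), k)
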