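"""Sample-weighted statistics for metacell data.

Each metacell stands for size(i) original cells, so downstream statistics
weight every metacell by its size: a weighted z-scoring, a weighted PCA
(SVD of (1/N_c) X'WX with W the diagonal size matrix), Ward hierarchical
clustering with pre-formed group sizes, a weighted silhouette, a weighted
Welch t-test for differential expression, weighted Pearson correlation,
gene-signature scoring and AUC. With unit weights every statistic reduces
to its classical counterpart, and with integer weights it matches the
classical statistic computed on the multiplicity-expanded sample — the
central correctness property of this module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import Embedding

logger = logging.getLogger(__name__)

__all__ = [
    "SilhouetteResult",
    "select_variable_genes_weighted",
    "cluster_metacells",
    "weighted_scale",
    "weighted_pca",
    "weighted_hclust",
    "weighted_silhouette",
    "weighted_ttest",
    "weighted_de",
    "weighted_pearson",
    "signature_score",
    "score_auc",
]


def _check_weights(w, n: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have shape ({n},), got {w.shape}")
    if np.any(w <= 0):
        raise ValueError("all weights must be positive")
    return w


def weighted_scale(
    matrix: np.ndarray,
    w: np.ndarray,
    convention: str = "frequency",
) -> np.ndarray:
    """Weighted z-scoring of a metacells x genes matrix.

    Per gene, subtract the weighted mean and divide by the weighted SD.
    ``convention="frequency"`` (default) treats weight w_i as a
    multiplicity — variance Sum w (x - mu)^2 / (Sum w - 1) — and therefore
    agrees exactly with classical z-scoring of the multiplicity-expanded
    sample. ``convention="reliability"`` uses the normalized-weight
    unbiased factor 1 / (1 - Sum w_hat^2) instead. Zero-variance genes are
    set to 0 and logged.
    """
    x = np.asarray(matrix, dtype=float)
    w = _check_weights(w, x.shape[0])
    what = w / w.sum()
    mu = what @ x
    xc = x - mu
    wss = what @ xc**2
    if convention == "frequency":
        var = wss * w.sum() / (w.sum() - 1.0)
    elif convention == "reliability":
        var = wss / (1.0 - np.sum(what**2))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    sd = np.sqrt(np.maximum(var, 0.0))
    # relative threshold: round-off on a constant gene leaves sd ~ eps|x|
    degenerate = sd <= 1e-10 * np.maximum(np.abs(x).max(axis=0), 1.0)
    if degenerate.any():
        logger.info("weighted_scale: %d zero-variance gene(s) set to 0", degenerate.sum())
        sd = sd.copy()
        sd[degenerate] = 1.0
    out = xc / sd
    out[:, degenerate] = 0.0
    return out


def select_variable_genes_weighted(
    values: np.ndarray, w: np.ndarray, n_genes: int
) -> np.ndarray:
    """Indices of the ``n_genes`` genes with the largest size-weighted
    variance across metacells, ties broken by lower gene index."""
    x = np.asarray(values, dtype=float)
    w = _check_weights(w, x.shape[0])
    if n_genes > x.shape[1]:
        raise ValueError(f"requested {n_genes} genes but matrix has {x.shape[1]}")
    what = w / w.sum()
    mu = what @ x
    var = what @ (x - mu) ** 2
    order = np.lexsort((np.arange(x.shape[1]), -var))
    return order[:n_genes]


def cluster_metacells(
    values: np.ndarray,
    w: np.ndarray,
    n_clusters: int,
    n_hvg: int | None = None,
    n_pcs: int = 10,
    scale: bool = True,
) -> np.ndarray:
    """Cluster metacells the way cells are clustered at full resolution:
    variable genes -> (weighted scaling +) weighted PCA -> size-weighted
    Ward, cut at ``n_clusters``. ``n_hvg=None`` uses all genes."""
    x = np.asarray(values, dtype=float)
    w = _check_weights(w, x.shape[0])
    if n_hvg is not None and n_hvg < x.shape[1]:
        x = x[:, select_variable_genes_weighted(x, w, n_hvg)]
    n_pcs = min(n_pcs, min(x.shape) - 1)
    emb = weighted_pca(x, w, n_components=n_pcs, scale=scale)
    return weighted_hclust(emb.coords, w, n_clusters=n_clusters)


def weighted_pca(
    values: np.ndarray,
    w: np.ndarray,
    n_components: int = 10,
    scale: bool = True,
) -> Embedding:
    """Sample-weighted PCA of a metacells x genes matrix.

    With X the (weighted-)scaled matrix and W = diag(w), the principal
    axes V are the top eigenvectors of (1/N_c) X'WX and the metacell
    embedding is X_PCA = X V. Component signs are fixed so the
    largest-magnitude loading per component is positive.
    """
    x = np.asarray(values, dtype=float)
    w = _check_weights(w, x.shape[0])
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite entries")
    limit = min(x.shape[1], x.shape[0]) - 1
    if n_components > limit:
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, metacells) - 1 = {limit}"
        )
    if scale:
        x = weighted_scale(x, w)
    n_c = w.sum()
    s_mat = (x.T * w) @ x / n_c
    evals, evecs = np.linalg.eigh(s_mat)
    order = np.argsort(evals)[::-1][:n_components]
    basis = evecs[:, order]
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    basis = basis * flip
    coords = x @ basis
    return Embedding(
        coords=coords,
        basis=basis,
        gene_subset=np.arange(x.shape[1]),
        gene_mean=np.zeros(x.shape[1]),
        explained_variance=np.maximum(evals[order], 0.0),
    )


def weighted_hclust(
    coords: np.ndarray,
    w: np.ndarray,
    n_clusters: int,
    linkage: str = "ward",
) -> np.ndarray:
    """Ward agglomeration where metacell i enters as a pre-formed group of
    size(i) observations located at its coordinates.

    Merge cost between clusters u, v of total weight n_u, n_v at centroids
    c_u, c_v is the within-cluster sum-of-squares increase
    n_u n_v / (n_u + n_v) * ||c_u - c_v||^2; centroids and weights update
    exactly, which is equivalent to running classical Ward on the
    multiplicity-expanded point set. Deterministic: cost ties are broken
    by the lower cluster-index pair. Returns labels relabeled contiguously
    by first occurrence; a dendrogram cut at ``n_clusters`` clusters.
    """
    if linkage != "ward":
        raise ValueError("only ward linkage is supported")
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    m = pts.shape[0]
    w = _check_weights(w, m)
    if not (1 <= n_clusters <= m):
        raise ValueError(f"n_clusters={n_clusters} out of range [1, {m}]")
    centroids = {i: pts[i].copy() for i in range(m)}
    weights = {i: float(w[i]) for i in range(m)}
    members = {i: [i] for i in range(m)}
    active = sorted(centroids)
    while len(active) > n_clusters:
        best = None
        for a_pos, i in enumerate(active):
            ci, wi = centroids[i], weights[i]
            for j in active[a_pos + 1 :]:
                diff = ci - centroids[j]
                cost = wi * weights[j] / (wi + weights[j]) * float(diff @ diff)
                if best is None or cost < best[0] - 1e-15:
                    best = (cost, i, j)
        _, i, j = best
        weights_new = weights[i] + weights[j]
        centroids[i] = (weights[i] * centroids[i] + weights[j] * centroids[j]) / weights_new
        weights[i] = weights_new
        members[i] = members[i] + members[j]
        del centroids[j], weights[j], members[j]
        active.remove(j)
    labels = np.empty(m, dtype=int)
    for cluster_id, i in enumerate(sorted(active, key=lambda i: min(members[i]))):
        labels[members[i]] = cluster_id
    return labels


@dataclass
class SilhouetteResult:
    """Per-metacell silhouettes s(i) and the size-weighted overall S."""

    s: np.ndarray
    overall: float


def weighted_silhouette(
    coords: np.ndarray,
    labels: np.ndarray,
    w: np.ndarray,
    distances: np.ndarray | None = None,
) -> SilhouetteResult:
    """Size-weighted silhouette coefficient over metacells.

    With |C| the total cell count of cluster C (sum of member sizes),
    a(i) = Sum_{j in C_m, j != i} d(i,j) size(j) / (|C_m| - size(i)),
    b(i) = min_{k != m} Sum_{j in C_k} d(i,j) size(j) / |C_k|,
    s(i) = (b - a) / max(a, b); s(i) = 0 for a cluster holding a single
    metacell. Overall S = Sum s(i) size(i) / N_c. Distances are Euclidean
    on ``coords`` unless a precomputed matrix is given.
    """
    labels = np.asarray(labels)
    m = labels.size
    w = _check_weights(w, m)
    if distances is None:
        pts = np.atleast_2d(np.asarray(coords, dtype=float))
        d = np.sqrt(
            np.maximum(
                np.sum(pts**2, axis=1)[:, None]
                - 2 * pts @ pts.T
                + np.sum(pts**2, axis=1)[None, :],
                0.0,
            )
        )
    else:
        d = np.asarray(distances, dtype=float)
        if d.shape != (m, m):
            raise ValueError("distance matrix shape mismatch")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError(
            "silhouette requires at least 2 clusters; got a single cluster"
        )
    cluster_w = {c: w[labels == c].sum() for c in uniq}
    s = np.zeros(m)
    for i in range(m):
        c = labels[i]
        in_mask = labels == c
        n_metacells_in = int(in_mask.sum())
        if n_metacells_in == 1:
            s[i] = 0.0
            continue
        denom = cluster_w[c] - w[i]
        a_i = np.sum(d[i, in_mask] * w[in_mask]) / denom  # d(i,i)=0 drops out
        b_i = min(
            np.sum(d[i, labels == k] * w[labels == k]) / cluster_w[k]
            for k in uniq
            if k != c
        )
        top = b_i - a_i
        bot = max(a_i, b_i)
        s[i] = 0.0 if bot == 0 else top / bot
    overall = float(np.sum(s * w) / w.sum())
    return SilhouetteResult(s=s, overall=overall)


def weighted_ttest(
    x1: np.ndarray,
    x2: np.ndarray,
    w1: np.ndarray,
    w2: np.ndarray,
) -> tuple[float, float, float, float]:
    """Sample-weighted Welch t-test between two groups of metacells.

    Frequency-weight convention: n_g = Sum w, weighted mean m_g, variance
    s_g^2 = Sum w (x - m)^2 / (Sum w - 1); t = (m1 - m2) /
    sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite df and a two-tailed
    p-value. Returns (t, df, p, logFC) with logFC = m1 - m2 (difference of
    weighted means in log space). Matches Welch's t-test on the
    multiplicity-expanded samples for integer weights.
    """
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    w1 = _check_weights(w1, x1.size)
    w2 = _check_weights(w2, x2.size)
    n1, n2 = w1.sum(), w2.sum()
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs total weight >= 2")
    m1, m2 = np.sum(w1 * x1) / n1, np.sum(w2 * x2) / n2
    v1 = np.sum(w1 * (x1 - m1) ** 2) / (n1 - 1.0)
    v2 = np.sum(w2 * (x2 - m2) ** 2) / (n2 - 1.0)
    logfc = m1 - m2
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if logfc == 0:
            return 0.0, n1 + n2 - 2.0, 1.0, 0.0
        return float(np.sign(logfc) * np.inf), n1 + n2 - 2.0, 0.0, float(logfc)
    t = logfc / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1.0) + (v2 / n2) ** 2 / (n2 - 1.0))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p), float(logfc)


def _group_moments(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted per-gene mean and frequency-convention variance for a
    metacells x genes block."""
    n = w.sum()
    mean = w @ x / n
    var = w @ (x - mean) ** 2 / (n - 1.0)
    return mean, var, float(n)


def weighted_de(
    values: np.ndarray,
    w: np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """One-vs-rest weighted differential expression across all groups.

    For every group, each gene is tested group-vs-union-of-others with the
    sample-weighted Welch t-test; p-values are Benjamini-Hochberg adjusted
    across genes within each comparison. Returns a tidy table with columns
    gene, group, mean_in, mean_out, logFC, t, p, p_adj, rank (rank 1 =
    largest logFC among that group's genes).
    """
    x = np.asarray(values, dtype=float)
    w = _check_weights(w, x.shape[0])
    labels = np.asarray(labels)
    if labels.size != x.shape[0]:
        raise ValueError("labels must match the number of metacells")
    gene_ids = gene_ids or [f"gene{i:05d}" for i in range(x.shape[1])]
    frames = []
    for group in np.unique(labels):
        mask = labels == group
        if w[mask].sum() < 2 or w[~mask].sum() < 2:
            raise ValueError(f"group {group!r} has total weight < 2 on one side")
        m_in, v_in, n_in = _group_moments(x[mask], w[mask])
        m_out, v_out, n_out = _group_moments(x[~mask], w[~mask])
        logfc = m_in - m_out
        se2 = v_in / n_in + v_out / n_out
        with np.errstate(divide="ignore", invalid="ignore"):
            t = logfc / np.sqrt(se2)
            df = se2**2 / (
                (v_in / n_in) ** 2 / (n_in - 1.0) + (v_out / n_out) ** 2 / (n_out - 1.0)
            )
            p = 2.0 * stats.t.sf(np.abs(t), df)
        both_flat = se2 == 0
        t = np.where(both_flat, np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf), t)
        p = np.where(both_flat, np.where(logfc == 0, 1.0, 0.0), p)
        p = np.nan_to_num(p, nan=1.0)
        p_adj = multipletests(p, method="fdr_bh")[1]
        rank = np.empty(x.shape[1], dtype=int)
        rank[np.lexsort((gene_ids, -logfc))] = np.arange(1, x.shape[1] + 1)
        frames.append(
            pd.DataFrame(
                {
                    "gene": gene_ids,
                    "group": group,
                    "mean_in": m_in,
                    "mean_out": m_out,
                    "logFC": logfc,
                    "t": t,
                    "p": p,
                    "p_adj": p_adj,
                    "rank": rank,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def weighted_pearson(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Sample-weighted Pearson correlation with a t-approximation p-value.

    rho is computed from the weighted covariance and SDs (normalized
    weights; the normalization cancels in the ratio); the p-value uses
    t = rho * sqrt((Sum w - 2) / (1 - rho^2)) with df = Sum w - 2, which
    matches the classical test on the multiplicity-expanded sample.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    w = _check_weights(w, x.size)
    if y.size != x.size:
        raise ValueError("x and y must have the same length")
    what = w / w.sum()
    mx, my = what @ x, what @ y
    cov = what @ ((x - mx) * (y - my))
    sx = np.sqrt(what @ (x - mx) ** 2)
    sy = np.sqrt(what @ (y - my) ** 2)
    if sx == 0 or sy == 0:
        return 0.0, 1.0
    rho = float(np.clip(cov / (sx * sy), -1.0, 1.0))
    df = w.sum() - 2.0
    if df <= 0:
        return rho, 1.0
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


def signature_score(
    values: np.ndarray,
    gene_ids: list[str],
    gene_set: list[str],
) -> np.ndarray:
    """Gene-signature score per column: sum of max-normalized expression.

    ``values`` is genes x columns (cells or metacells). Each signature
    gene is divided by its maximum across columns, then the normalized
    rows are summed. Signature genes absent from the matrix are skipped
    with a warning; an empty intersection is an error.
    """
    x = np.asarray(values, dtype=float)
    index = {g: i for i, g in enumerate(gene_ids)}
    present = [g for g in gene_set if g in index]
    missing = [g for g in gene_set if g not in index]
    if not present:
        raise ValueError("no signature gene found in the matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from matrix: {missing[:5]}",
            stacklevel=2,
        )
    rows = x[[index[g] for g in present], :]
    maxes = rows.max(axis=1, keepdims=True)
    maxes[maxes == 0] = 1.0
    return (rows / maxes).sum(axis=0)


def score_auc(
    scores: np.ndarray,
    binary_labels: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Rank-based AUC of a score against a binary label; with metacell
    weights each metacell counts size(i) times."""
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels)
    if weights is not None:
        weights = _check_weights(weights, scores.size)
    return float(roc_auc_score(y, scores, sample_weight=weights))
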