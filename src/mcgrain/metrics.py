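"""Evaluation metrics for metacell partitions.

Purity (per-metacell majority-label fraction), rare-cell-type assignment
and weighted purity, adjusted Rand index between clusterings,
differential-expression recovery (reference set M, recovered set M~, TPR),
the GO match score ratio of top correlated gene pairs, and RNA-velocity
purity/similarity of pooled velocity fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .coarse import MetacellPartition

logger = logging.getLogger(__name__)

__all__ = [
    "purity",
    "rare_type_purity",
    "majority_annotation",
    "adjusted_rand_index",
    "de_reference_set",
    "de_recovered_set",
    "tpr",
    "go_match_score_ratio",
    "velocity_purity",
    "velocity_similarity",
    "velocity_similarity_subsampled",
]


def purity(partition: MetacellPartition, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-metacell purity (fraction of cells of the most abundant cell
    type) and the median across metacells."""
    labels = np.asarray(labels)
    if labels.size != partition.n_cells:
        raise ValueError("labels must cover every cell")
    out = np.empty(partition.n_metacells)
    for mc in range(partition.n_metacells):
        members = labels[partition.cells_of(mc)]
        _, counts = np.unique(members, return_counts=True)
        out[mc] = counts.max() / members.size
    return out, float(np.median(out))


def majority_annotation(partition: MetacellPartition, labels: np.ndarray) -> list[str]:
    """Majority-vote cell-type annotation per metacell; count ties are
    broken by lexicographic label order."""
    labels = np.asarray(labels).astype(str)
    ann = []
    for mc in range(partition.n_metacells):
        members = labels[partition.cells_of(mc)]
        uniq, counts = np.unique(members, return_counts=True)  # uniq sorted
        ann.append(str(uniq[np.argmax(counts)]))
    return ann


def rare_type_purity(
    partition: MetacellPartition,
    labels: np.ndarray,
    target_label: str,
) -> tuple[float, float]:
    """Conservation of a rare cell type in metacells.

    ``assignment_fraction``: fraction of target-type cells that end up in
    metacells whose majority-vote annotation is the target type.
    ``weighted_purity``: over target-annotated metacells, the target-cell
    fraction averaged with weights equal to the number of target cells in
    each metacell (0.0 when no metacell is annotated to the target).
    """
    labels = np.asarray(labels).astype(str)
    target_cells = labels == str(target_label)
    if not target_cells.any():
        raise ValueError(f"no cell carries label {target_label!r}")
    ann = majority_annotation(partition, labels)
    target_mcs = [mc for mc, a in enumerate(ann) if a == str(target_label)]
    in_target_mc = np.isin(partition.membership, target_mcs)
    assignment_fraction = float(
        np.sum(target_cells & in_target_mc) / np.sum(target_cells)
    )
    if not target_mcs:
        return 0.0, 0.0
    num = 0.0
    den = 0.0
    for mc in target_mcs:
        members = labels[partition.cells_of(mc)]
        n_target = int(np.sum(members == str(target_label)))
        frac = n_target / members.size
        num += frac * n_target
        den += n_target
    return assignment_fraction, float(num / den)


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    ARI = (RI - E[RI]) / (max RI - E[RI]) computed from the pair counts of
    the contingency table; 1 for identical partitions, ~0 for independent
    ones.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("partitions must cover the same items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n = a.size
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0  # both partitions trivial (all-in-one or all-singletons)
    return float((sum_ij - expected) / (max_index - expected))


def de_reference_set(
    de_table: pd.DataFrame,
    p_thr: float = 0.05,
    lfc_thr: float = 0.5,
) -> set[str]:
    """Reference DE set M: union over clusters of significantly upregulated
    genes (BH-adjusted p < p_thr and logFC > lfc_thr)."""
    sig = de_table[(de_table["p_adj"] < p_thr) & (de_table["logFC"] > lfc_thr)]
    m = set(sig["gene"])
    if not m:
        raise ValueError(
            "no gene passes the reference DE thresholds; the recovery rate "
            "is undefined"
        )
    return m


def de_recovered_set(
    de_table: pd.DataFrame,
    n: int,
    p_thr: float = 0.05,
) -> set[str]:
    """Recovered DE set M~: among genes significantly upregulated in any
    cluster (BH-adjusted p < p_thr, logFC > 0), the top ``n`` ranked by
    logFC descending (ties by gene id; a gene significant in several
    clusters counts once, at its best logFC). If fewer than ``n`` genes
    are significant, all are returned and the shortfall is logged."""
    if n < 0:
        raise ValueError("n must be non-negative")
    sig = de_table[(de_table["p_adj"] < p_thr) & (de_table["logFC"] > 0)]
    best = (
        sig.sort_values(["logFC", "gene"], ascending=[False, True])
        .drop_duplicates("gene", keep="first")
        .sort_values(["logFC", "gene"], ascending=[False, True])
    )
    genes = list(best["gene"])
    if len(genes) < n:
        logger.warning(
            "de_recovered_set: only %d significant genes for requested n=%d",
            len(genes),
            n,
        )
    return set(genes[:n])


def tpr(m: set[str], m_tilde: set[str]) -> float:
    """DE recovery rate TPR = |M intersect M~| / |M|."""
    if not m:
        raise ValueError("reference set M is empty; TPR undefined")
    return len(m & m_tilde) / len(m)


def _pairwise_pearson(x: np.ndarray, w: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (weighted) Pearson correlations among the rows of a
    genes x columns matrix; returns (rho, p) square matrices."""
    from scipy import stats

    if w is None:
        w = np.ones(x.shape[1])
    what = w / w.sum()
    mu = x @ what
    xc = x - mu[:, None]
    cov = (xc * what) @ xc.T
    sd = np.sqrt(np.diag(cov))
    sd_safe = np.where(sd == 0, 1.0, sd)
    rho = cov / sd_safe[:, None] / sd_safe[None, :]
    rho[sd == 0, :] = 0.0
    rho[:, sd == 0] = 0.0
    np.clip(rho, -1.0, 1.0, out=rho)
    df = w.sum() - 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def _top_pairs(
    rho: np.ndarray,
    p: np.ndarray,
    gene_ids: list[str],
    top_n: int,
    p_thr: float,
    by_magnitude: bool = False,
) -> list[tuple[str, str]]:
    iu = np.triu_indices(rho.shape[0], k=1)
    pvals = p[iu]
    padj = multipletests(pvals, method="fdr_bh")[1]
    keep = padj < p_thr
    rr = rho[iu][keep]
    ii, jj = iu[0][keep], iu[1][keep]
    key = np.abs(rr) if by_magnitude else rr
    pair_ids = [
        (gene_ids[int(a)], gene_ids[int(b)]) for a, b in zip(ii, jj)
    ]
    order = sorted(range(len(pair_ids)), key=lambda t: (-key[t], pair_ids[t]))
    return [pair_ids[t] for t in order[:top_n]]


def go_match_score_ratio(
    expr_sc: np.ndarray,
    gene_ids: list[str],
    profile_mc: np.ndarray,
    w: np.ndarray,
    go_map: dict[str, set[str]],
    expressed_frac: float = 0.5,
    top_n: int = 1000,
    p_thr: float = 0.05,
    by_magnitude: bool = False,
) -> float:
    """Ratio of GO match scores of level-exclusive top correlated pairs.

    Genes expressed (> 0) in more than ``expressed_frac`` of single cells
    are kept; the top ``top_n`` significantly correlated gene pairs
    (BH-adjusted p < ``p_thr``, ranked by correlation, or by magnitude
    with ``by_magnitude``) are selected at the single-cell level (Pearson)
    and the metacell level (size-weighted Pearson). Each pair's GO match
    score is the Jaccard coefficient of the two genes' GO id sets; the
    returned ratio is the mean score over metacell-exclusive pairs divided
    by the mean over single-cell-exclusive pairs (> 1 means metacell
    correlations are more functionally coherent).
    """
    x_sc = np.asarray(expr_sc, dtype=float)  # genes x cells
    keep = np.mean(x_sc > 0, axis=1) > expressed_frac
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes pass the expressed-fraction filter")
    kept_ids = [g for g, k in zip(gene_ids, keep) if k]
    rho_sc, p_sc = _pairwise_pearson(x_sc[keep], None)
    x_mc = np.asarray(profile_mc, dtype=float).T[keep]  # genes x metacells
    rho_mc, p_mc = _pairwise_pearson(x_mc, np.asarray(w, dtype=float))
    pairs_sc = set(_top_pairs(rho_sc, p_sc, kept_ids, top_n, p_thr, by_magnitude))
    pairs_mc = set(_top_pairs(rho_mc, p_mc, kept_ids, top_n, p_thr, by_magnitude))
    only_mc = pairs_mc - pairs_sc
    only_sc = pairs_sc - pairs_mc
    if not only_mc or not only_sc:
        raise ValueError(
            "no level-exclusive gene pairs on one side; the GO match score "
            "ratio is degenerate (identical pair lists?)"
        )

    def jaccard(a: str, b: str) -> float:
        sa = go_map.get(a, set())
        sb = go_map.get(b, set())
        union = sa | sb
        return len(sa & sb) / len(union) if union else 0.0

    mc_score = float(np.mean([jaccard(a, b) for a, b in only_mc]))
    sc_score = float(np.mean([jaccard(a, b) for a, b in only_sc]))
    if sc_score == 0:
        raise ValueError("single-cell-exclusive pairs share no GO terms; ratio undefined")
    return mc_score / sc_score


def _cosine_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity; cosine with a zero vector is 0."""
    v = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = v / safe[:, None]
    cos = unit @ unit.T
    cos[norms == 0, :] = 0.0
    cos[:, norms == 0] = 0.0
    return np.clip(cos, -1.0, 1.0)


def velocity_purity(partition: MetacellPartition, v: np.ndarray) -> np.ndarray:
    """Velocity purity per metacell:
    max over members x of the median over members y of cos(v(x), v(y)).

    The median includes y = x (cos = 1 for nonzero vectors) and uses the
    midpoint convention for even counts; a singleton metacell has purity 1.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[0] != partition.n_cells:
        raise ValueError("one velocity vector per cell is required")
    out = np.empty(partition.n_metacells)
    for mc in range(partition.n_metacells):
        cos = _cosine_matrix(v[partition.cells_of(mc)])
        out[mc] = np.median(cos, axis=1).max()
    return out


def _cosine_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = np.where((na == 0) | (nb == 0), 1.0, na * nb)
    cos = np.sum(a * b, axis=1) / denom
    cos[(na == 0) | (nb == 0)] = 0.0
    return np.clip(cos, -1.0, 1.0)


def velocity_similarity(
    v_cells: np.ndarray,
    v_metacells: np.ndarray,
    partition: MetacellPartition,
) -> float:
    """Median over cells of cos(v(x), V(C(x))), the cosine between each
    cell's velocity and the velocity of its metacell."""
    v_cells = np.asarray(v_cells, dtype=float)
    v_metacells = np.asarray(v_metacells, dtype=float)
    if v_cells.shape[0] != partition.n_cells:
        raise ValueError("one velocity vector per cell is required")
    if v_metacells.shape[0] != partition.n_metacells:
        raise ValueError("one velocity vector per metacell is required")
    paired = v_metacells[partition.membership]
    return float(np.median(_cosine_rows(v_cells, paired)))


def velocity_similarity_subsampled(
    v_cells: np.ndarray,
    v_subsample: np.ndarray,
    coords: np.ndarray,
    subsample_idx: np.ndarray,
) -> float:
    """Subsampling counterpart of the velocity similarity: median over all
    cells of cos(v(x), v'(x')), where x' is the retained cell nearest to x
    (Euclidean distance in ``coords``)."""
    v_cells = np.asarray(v_cells, dtype=float)
    coords = np.asarray(coords, dtype=float)
    subsample_idx = np.asarray(subsample_idx, dtype=int)
    sub_coords = coords[subsample_idx]
    d2 = (
        np.sum(coords**2, axis=1)[:, None]
        - 2 * coords @ sub_coords.T
        + np.sum(sub_coords**2, axis=1)[None, :]
    )
    nearest = np.argmin(d2, axis=1)
    return float(np.median(_cosine_rows(v_cells, np.asarray(v_subsample)[nearest])))
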