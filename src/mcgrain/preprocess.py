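"""Single-cell preprocessing: log-normalization, variable genes, PCA, cell graph.

The coarse-graining pipeline starts from a log-normalized genes x cells
expression matrix, embeds cells with PCA on the most variable genes, and
links each cell to its k nearest neighbors (Euclidean distance in PCA
space) to obtain the single-cell graph that is later partitioned into
metacells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "Embedding",
    "CellGraph",
    "normalize_log",
    "select_variable_genes",
    "embed_pca",
    "build_cell_graph",
]


@dataclass
class ExpressionMatrix:
    """Genes x cells expression matrix with identifiers.

    ``values`` holds log-normalized expression when ``is_lognorm`` is set;
    rows are genes, columns are cells (the 10x on-disk convention).
    """

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    is_lognorm: bool = True

    def __post_init__(self) -> None:
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} columns but {len(self.cell_ids)} cell ids"
            )
        if n_cells < 1:
            raise ValueError("expression matrix must contain at least one cell")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)


@dataclass
class Embedding:
    """Low-dimensional cell embedding with the gene loadings that produced it.

    ``coords`` is cells x d; ``basis`` (genes x d, orthonormal columns) and
    ``gene_mean``/``gene_scale`` (per-gene centering/scaling used before
    projection) are retained so that new cells can be projected into the
    same space.
    """

    coords: np.ndarray
    basis: np.ndarray
    gene_subset: np.ndarray
    gene_mean: np.ndarray
    gene_scale: np.ndarray | None = None
    explained_variance: np.ndarray | None = None

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def project(self, expr_values: np.ndarray) -> np.ndarray:
        """Project new genes x cells values into this embedding's space."""
        x = np.asarray(expr_values, dtype=float)[self.gene_subset, :].T
        x = x - self.gene_mean
        if self.gene_scale is not None:
            x = x / self.gene_scale
        return x @ self.basis


@dataclass
class CellGraph:
    """Undirected, unweighted single-cell similarity graph."""

    n_nodes: int
    edges: set[tuple[int, int]] = field(default_factory=set)
    k: int = 5
    mode: str = "knn"

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i}, {j}) out of range")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def to_igraph(self):
        import igraph as ig

        return ig.Graph(n=self.n_nodes, edges=sorted(self.edges), directed=False)


def normalize_log(
    counts: np.ndarray | sp.spmatrix,
    gene_ids: list[str] | None = None,
    cell_ids: list[str] | None = None,
    scale_target: float = 10_000.0,
) -> ExpressionMatrix:
    """Library-size normalize each cell to ``scale_target`` counts and log1p.

    Raises if any cell has zero total counts (such a cell cannot be
    normalized and usually indicates an upstream filtering problem).
    """
    if scale_target <= 0:
        raise ValueError("scale_target must be positive")
    dense = np.asarray(counts.todense()) if sp.issparse(counts) else np.asarray(counts)
    if np.any(dense < 0):
        raise ValueError("counts must be non-negative")
    n_genes, n_cells = dense.shape
    gene_ids = gene_ids or [f"gene{i:05d}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"cell{i:05d}" for i in range(n_cells)]
    totals = dense.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts cannot be normalized: "
            f"{[cell_ids[i] for i in zero[:5]]}"
        )
    values = np.log1p(dense / totals * scale_target)
    return ExpressionMatrix(values, list(gene_ids), list(cell_ids), is_lognorm=True)


def select_variable_genes(expr: ExpressionMatrix, n_genes: int) -> np.ndarray:
    """Indices of the ``n_genes`` most variable genes, variance descending.

    Ties are broken by lower gene index so the selection is deterministic.
    """
    if n_genes > expr.n_genes:
        raise ValueError(
            f"requested {n_genes} variable genes but matrix has {expr.n_genes}"
        )
    x = expr.dense()
    var = x.var(axis=1, ddof=1) if expr.n_cells > 1 else np.zeros(expr.n_genes)
    order = np.lexsort((np.arange(expr.n_genes), -var))
    return order[:n_genes]


def embed_pca(
    expr: ExpressionMatrix,
    gene_subset: np.ndarray | None = None,
    n_components: int = 10,
    scale: bool = False,
) -> Embedding:
    """PCA embedding of cells on a gene subset.

    Genes are centered across cells; unit-variance scaling is off by
    default. The sign of each component is fixed so that its
    largest-magnitude gene loading is positive, making results
    reproducible across linear-algebra backends.
    """
    if gene_subset is None:
        gene_subset = np.arange(expr.n_genes)
    gene_subset = np.asarray(gene_subset, dtype=int)
    limit = min(gene_subset.size, expr.n_cells) - 1
    if n_components > limit:
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, cells) - 1 = {limit}"
        )
    x = expr.dense()[gene_subset, :].T.astype(float)  # cells x genes
    mean = x.mean(axis=0)
    xc = x - mean
    gene_scale = None
    if scale:
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
        gene_scale = sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    basis = vt[:n_components].T  # genes x d
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    basis = basis * flip
    coords = xc @ basis
    explained = (s[:n_components] ** 2) / max(x.shape[0] - 1, 1)
    return Embedding(
        coords=coords,
        basis=basis,
        gene_subset=gene_subset,
        gene_mean=mean,
        gene_scale=gene_scale,
        explained_variance=explained,
    )


def _knn_lists(coords: np.ndarray, k: int) -> np.ndarray:
    """Exact k nearest neighbors per row (self excluded), distance ties broken
    by lower index. Returns an (n, k) array of neighbor indices."""
    n = coords.shape[0]
    idx = np.empty((n, k), dtype=int)
    chunk = max(1, int(2e7) // max(n, 1))
    order_cols = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = (
            np.sum(coords[start:stop] ** 2, axis=1)[:, None]
            - 2.0 * coords[start:stop] @ coords.T
            + np.sum(coords**2, axis=1)[None, :]
        )
        for r, row in enumerate(d2):
            row = row.copy()
            row[start + r] = np.inf  # exclude self
            ordering = np.lexsort((order_cols, row))
            idx[start + r] = ordering[:k]
    return idx


def build_cell_graph(
    embedding: Embedding,
    k: int = 5,
    mode: str = "knn",
    snn_jaccard_min: float = 1.0 / 15.0,
) -> CellGraph:
    """Build the single-cell graph from the PCA embedding.

    knn mode: each cell is linked to its k nearest cells; the directed
    neighbor lists are symmetrized by union into an undirected edge set.
    snn mode: cells sharing at least one of their k nearest neighbors are
    linked when the Jaccard overlap of their neighbor lists exceeds
    ``snn_jaccard_min``.
    """
    coords = np.asarray(embedding.coords, dtype=float)
    n = coords.shape[0]
    if not np.all(np.isfinite(coords)):
        raise ValueError("embedding contains non-finite coordinates")
    if not (1 <= k < n):
        raise ValueError(f"k={k} must satisfy 1 <= k < n_cells={n}")
    if mode not in ("knn", "snn"):
        raise ValueError(f"unknown graph mode {mode!r}")
    nbrs = _knn_lists(coords, k)
    edges: set[tuple[int, int]] = set()
    if mode == "knn":
        for i in range(n):
            for j in nbrs[i]:
                edges.add((min(i, int(j)), max(i, int(j))))
    else:
        sets = [set(map(int, nbrs[i])) for i in range(n)]
        # candidate pairs: cells appearing in a common neighbor list, plus
        # mutual membership; restrict to pairs sharing >= 1 neighbor
        members: dict[int, list[int]] = {}
        for i in range(n):
            for j in sets[i]:
                members.setdefault(j, []).append(i)
        candidates: set[tuple[int, int]] = set()
        for lst in members.values():
            for a in range(len(lst)):
                for b in range(a + 1, len(lst)):
                    candidates.add((lst[a], lst[b]))
        for i, j in candidates:
            shared = len(sets[i] & sets[j])
            if shared == 0:
                continue
            jac = shared / (2 * k - shared)
            if jac > snn_jaccard_min:
                edges.add((i, j))
    return CellGraph(n_nodes=n, edges=edges, k=k, mode=mode)
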