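"""Graph coarse-graining: partition the cell graph into metacells.

A walktrap dendrogram is computed once per connected component of the
single-cell graph; cutting it at any requested number of metacells is then
cheap, so several graining levels can be explored without recomputing the
graph or the random-walk hierarchy. The graining level gamma = N_c / N_SC
is the ratio of single cells to metacells (gamma = 1 is the identity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import CellGraph, ExpressionMatrix, build_cell_graph, embed_pca, select_variable_genes

logger = logging.getLogger(__name__)

__all__ = [
    "MergeTree",
    "MetacellPartition",
    "MetacellGraph",
    "walktrap_dendrogram",
    "cut_to_metacells",
    "louvain_partition",
    "gamma_for_sample",
    "approximate_coarse_grain",
    "split_by_annotation",
    "metacell_network",
    "make_metacells",
    "random_partition",
]


@dataclass
class MergeTree:
    """Per-component agglomerative merge sequences over cells.

    ``components`` maps component id -> sorted array of member node ids;
    ``merges`` maps component id -> list of (a, b) merges in local cluster
    indexing (igraph convention: node i is cluster i, the m-th merge
    creates cluster n_nodes + m). Merge heights are the merge ranks.
    """

    n_nodes: int
    components: dict[int, np.ndarray]
    merges: dict[int, list[tuple[int, int]]]
    component_map: np.ndarray  # node -> component id

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class MetacellPartition:
    """Cell -> metacell assignment with sizes and graining level."""

    membership: np.ndarray  # cell index -> metacell id, contiguous from 0
    gamma: float
    n_metacells: int
    sizes: np.ndarray = field(default=None)  # type: ignore[assignment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=int)
        if self.sizes is None:
            self.sizes = np.bincount(self.membership, minlength=self.n_metacells)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.membership.min(initial=0) < 0 or (
            self.membership.size and self.membership.max() >= self.n_metacells
        ):
            raise ValueError("membership ids out of range")
        if np.any(self.sizes == 0):
            raise ValueError("every metacell must be non-empty")
        if self.sizes.sum() != self.n_cells:
            raise ValueError("sizes do not sum to the number of cells")

    @property
    def n_cells(self) -> int:
        return self.membership.size

    def cells_of(self, metacell: int) -> np.ndarray:
        return np.flatnonzero(self.membership == metacell)


@dataclass
class MetacellGraph:
    """Metacell network: edge weight = number of cell-cell edges between."""

    n_metacells: int
    edges: dict[tuple[int, int], int]


def _relabel_by_first_cell(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster ids contiguously in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        out[i] = mapping[r]
    return out


def walktrap_dendrogram(graph: CellGraph, steps: int = 4) -> MergeTree:
    """Random-walk agglomerative community hierarchy, per connected component.

    Walktrap merges communities greedily by short-random-walk similarity
    (walk length ``steps``); the merge sequence is deterministic given the
    graph and can be cut at any community count afterwards.
    """
    if graph.n_nodes < 1:
        raise ValueError("graph must have at least one node")
    if steps < 1:
        raise ValueError("steps must be positive")
    g = graph.to_igraph()
    comp = g.connected_components(mode="weak")
    component_map = np.asarray(comp.membership, dtype=int)
    components: dict[int, np.ndarray] = {}
    merges: dict[int, list[tuple[int, int]]] = {}
    for cid in range(len(comp)):
        nodes = np.flatnonzero(component_map == cid)
        components[cid] = nodes
        sub = g.induced_subgraph(list(nodes))
        if len(nodes) == 1:
            merges[cid] = []
            continue
        dendro = sub.community_walktrap(steps=steps)
        merges[cid] = [(int(a), int(b)) for a, b in dendro.merges]
        if len(merges[cid]) != len(nodes) - 1:
            # walktrap stops at connected components; a connected subgraph
            # always merges down to one community
            raise RuntimeError("incomplete dendrogram for a connected component")
    return MergeTree(
        n_nodes=graph.n_nodes,
        components=components,
        merges=merges,
        component_map=component_map,
    )


def _cut_component(nodes: np.ndarray, merges: list[tuple[int, int]], n_clusters: int) -> np.ndarray:
    """Apply the first (n - n_clusters) merges; return local cluster labels."""
    n = nodes.size
    if not (1 <= n_clusters <= n):
        raise ValueError(f"cannot cut component of {n} nodes into {n_clusters} clusters")
    parent = list(range(n + len(merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (a, b) in enumerate(merges[: n - n_clusters]):
        new = n + m
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    return _relabel_by_first_cell(np.asarray(roots))


def _allocate(sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` clusters across components,
    each component getting >= 1 and <= its size; ties go to the larger
    component, then the lower component id."""
    n_comp = sizes.size
    quota = total * sizes / sizes.sum()
    alloc = np.floor(quota).astype(int)
    alloc = np.clip(alloc, 1, sizes)
    rem = quota - np.floor(quota)
    # distribute or reclaim until the budget is met
    while alloc.sum() < total:
        order = np.lexsort((np.arange(n_comp), -sizes, -rem))
        for c in order:
            if alloc[c] < sizes[c]:
                alloc[c] += 1
                rem[c] = -1.0  # consumed
                break
        else:  # pragma: no cover - guarded by caller's range check
            raise RuntimeError("allocation infeasible")
    while alloc.sum() > total:
        order = np.lexsort((np.arange(n_comp), sizes, rem))
        for c in order:
            if alloc[c] > 1:
                alloc[c] -= 1
                break
        else:  # pragma: no cover
            raise RuntimeError("allocation infeasible")
    return alloc


def _resolve_n_metacells(
    n_cells: int,
    n_components: int,
    gamma: float | None,
    n_metacells: int | None,
    clamp: bool,
) -> int:
    if (gamma is None) == (n_metacells is None):
        raise ValueError("specify exactly one of gamma or n_metacells")
    if gamma is not None:
        if gamma < 1:
            raise ValueError("gamma must be >= 1")
        n_sc = int(np.floor(n_cells / gamma + 0.5))  # round half up
        n_sc = max(n_sc, n_components) if clamp else n_sc
        n_sc = min(n_sc, n_cells)
    else:
        n_sc = int(n_metacells)
    if not (n_components <= n_sc <= n_cells):
        raise ValueError(
            f"requested {n_sc} metacells outside feasible range "
            f"[{n_components}, {n_cells}]"
        )
    return n_sc


def cut_to_metacells(
    tree: MergeTree,
    gamma: float | None = None,
    n_metacells: int | None = None,
) -> MetacellPartition:
    """Cut the walktrap dendrogram into metacells.

    N_SC = round(N_c / gamma) when gamma is given (at least one metacell
    per connected component); cuts are allocated across components
    proportionally to component size by largest-remainder rounding.
    """
    n_cells = tree.n_nodes
    n_sc = _resolve_n_metacells(
        n_cells, tree.n_components, gamma, n_metacells, clamp=gamma is not None
    )
    comp_ids = sorted(tree.components)
    comp_sizes = np.asarray([tree.components[c].size for c in comp_ids])
    alloc = _allocate(comp_sizes, n_sc)
    raw = np.full(n_cells, -1, dtype=int)
    offset = 0
    for c, n_clust in zip(comp_ids, alloc):
        nodes = tree.components[c]
        local = _cut_component(nodes, tree.merges[c], int(n_clust))
        raw[nodes] = local + offset
        offset += int(n_clust)
    membership = _relabel_by_first_cell(raw)
    return MetacellPartition(
        membership=membership,
        gamma=n_cells / n_sc,
        n_metacells=n_sc,
        metadata={"algorithm": "walktrap"},
    )


def louvain_partition(
    graph: CellGraph,
    gamma: float | None = None,
    n_metacells: int | None = None,
    steps: int = 4,
) -> MetacellPartition:
    """Louvain-based alternative backend with the community count matched
    to round(N_c / gamma).

    Louvain has no direct control over the number of communities, so
    oversized communities are recursively split (via each community's own
    walktrap dendrogram, one extra cluster at a time, always splitting the
    community with the largest cells-per-cluster ratio) and, if Louvain
    returns too many communities, the smallest are merged into their most
    connected neighbor, until exactly N_SC communities remain.
    """
    g = graph.to_igraph()
    comp = g.connected_components(mode="weak")
    n_cells = graph.n_nodes
    n_sc = _resolve_n_metacells(
        n_cells, len(comp), gamma, n_metacells, clamp=gamma is not None
    )
    clusters = [np.asarray(c, dtype=int) for c in g.community_multilevel()]
    # merge-down phase: too many communities
    while len(clusters) > n_sc:
        sizes = [c.size for c in clusters]
        smallest = int(np.lexsort((np.arange(len(clusters)), sizes))[0])
        # most-connected other cluster (ties: lower index); fall back to the
        # smallest other cluster when disconnected
        owner = np.full(n_cells, -1, dtype=int)
        for ci, c in enumerate(clusters):
            owner[c] = ci
        counts = np.zeros(len(clusters), dtype=int)
        for i, j in graph.edges:
            a, b = owner[i], owner[j]
            if a == smallest and b != smallest:
                counts[b] += 1
            elif b == smallest and a != smallest:
                counts[a] += 1
        counts[smallest] = -1
        target = int(np.argmax(counts))
        if counts[target] <= 0:
            others = [i for i in range(len(clusters)) if i != smallest]
            target = min(others, key=lambda i: (clusters[i].size, i))
        merged = np.sort(np.concatenate([clusters[smallest], clusters[target]]))
        clusters = [c for i, c in enumerate(clusters) if i not in (smallest, target)]
        clusters.append(merged)
    # split-up phase: too few communities
    while len(clusters) < n_sc:
        ratios = [(c.size, i) for i, c in enumerate(clusters)]
        size, i = max(ratios, key=lambda t: (t[0], -t[1]))
        if size < 2:
            raise RuntimeError("cannot split singleton communities further")
        sub_nodes = clusters[i]
        sub = g.induced_subgraph(list(sub_nodes))
        sub_comp = sub.connected_components(mode="weak")
        if len(sub_comp) > 1:
            parts = [sub_nodes[np.asarray(c, dtype=int)] for c in sub_comp]
        else:
            dendro = sub.community_walktrap(steps=steps)
            local = _cut_component(
                np.arange(sub_nodes.size),
                [(int(a), int(b)) for a, b in dendro.merges],
                2,
            )
            parts = [sub_nodes[local == v] for v in range(2)]
        clusters = [c for j, c in enumerate(clusters) if j != i] + parts
        if len(clusters) > n_sc:  # multi-component split overshot
            clusters.sort(key=lambda c: int(c[0]))
    raw = np.full(n_cells, -1, dtype=int)
    for ci, c in enumerate(clusters):
        raw[c] = ci
    membership = _relabel_by_first_cell(raw)
    return MetacellPartition(
        membership=membership,
        gamma=n_cells / n_sc,
        n_metacells=n_sc,
        metadata={"algorithm": "louvain"},
    )


def random_partition(
    n_cells: int,
    gamma: float | None = None,
    n_metacells: int | None = None,
    seed: int = 0,
) -> MetacellPartition:
    """Random-grouping baseline: cells shuffled and split into near-equal
    groups at the requested graining level. Used as the null comparison
    for purity, DE recovery and velocity metrics."""
    n_sc = _resolve_n_metacells(n_cells, 1, gamma, n_metacells, clamp=gamma is not None)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_cells)
    membership = np.empty(n_cells, dtype=int)
    for mc, chunk in enumerate(np.array_split(order, n_sc)):
        membership[chunk] = mc
    membership = _relabel_by_first_cell(membership)
    return MetacellPartition(
        membership=membership,
        gamma=n_cells / n_sc,
        n_metacells=n_sc,
        metadata={"algorithm": "random"},
    )


def gamma_for_sample(n: int) -> int:
    """Per-sample graining level gamma = min(floor(n / 20), 10), clamped to
    at least 1 so small samples still get a valid graining level."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    return max(1, min(n // 20, 10))


def split_by_annotation(
    partition: MetacellPartition, labels: np.ndarray
) -> MetacellPartition:
    """Split metacells so each contains cells of a single annotation.

    Every metacell holding more than one distinct label becomes one
    metacell per (metacell, label) pair; the output refines the input and
    has per-metacell label purity exactly 1.
    """
    labels = np.asarray(labels)
    if labels.size != partition.n_cells:
        raise ValueError("labels must be defined for every cell")
    if labels.dtype == object and any(l is None for l in labels):
        raise ValueError("labels must be defined for every cell")
    keys = [(int(m), str(l)) for m, l in zip(partition.membership, labels)]
    mapping: dict[tuple[int, str], int] = {}
    raw = np.empty(partition.n_cells, dtype=int)
    for i, key in enumerate(keys):
        if key not in mapping:
            mapping[key] = len(mapping)
        raw[i] = mapping[key]
    n_sc = len(mapping)
    return MetacellPartition(
        membership=raw,
        gamma=partition.n_cells / n_sc,
        n_metacells=n_sc,
        metadata={**partition.metadata, "split_by_annotation": True},
    )


def metacell_network(graph: CellGraph, partition: MetacellPartition) -> MetacellGraph:
    """Metacell network: weight(i, j) = number of cell-cell edges with one
    endpoint in metacell i and the other in metacell j."""
    if graph.n_nodes != partition.n_cells:
        raise ValueError("graph and partition cover different numbers of cells")
    weights: dict[tuple[int, int], int] = {}
    m = partition.membership
    for i, j in graph.edges:
        a, b = int(m[i]), int(m[j])
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        weights[key] = weights.get(key, 0) + 1
    return MetacellGraph(n_metacells=partition.n_metacells, edges=weights)


def make_metacells(
    expr: ExpressionMatrix,
    gamma: float,
    n_hvg: int = 1000,
    n_pcs: int = 10,
    k: int = 5,
    graph_mode: str = "knn",
    algorithm: str = "walktrap",
    steps: int = 4,
) -> tuple[MetacellPartition, "Embedding", CellGraph]:
    """Convenience pipeline: variable genes -> PCA -> kNN graph -> partition.

    Returns the partition together with the embedding and the cell graph so
    downstream steps (profiles, metacell network, velocity) can reuse them.
    """
    n_hvg = min(n_hvg, expr.n_genes)
    hvg = select_variable_genes(expr, n_hvg)
    n_pcs = min(n_pcs, min(n_hvg, expr.n_cells) - 1)
    emb = embed_pca(expr, hvg, n_components=n_pcs)
    graph = build_cell_graph(emb, k=k, mode=graph_mode)
    if algorithm == "walktrap":
        tree = walktrap_dendrogram(graph, steps=steps)
        part = cut_to_metacells(tree, gamma=gamma)
    elif algorithm == "louvain":
        part = louvain_partition(graph, gamma=gamma)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    part.metadata.update({"k": k, "n_pcs": n_pcs, "n_hvg": n_hvg, "graph_mode": graph_mode})
    return part, emb, graph


def approximate_coarse_grain(
    expr: ExpressionMatrix,
    gamma: float,
    n_subsample: int,
    seed: int,
    n_hvg: int = 1000,
    n_pcs: int = 10,
    k: int = 5,
    graph_mode: str = "knn",
    steps: int = 4,
) -> MetacellPartition:
    """Approximate coarse-graining for large datasets.

    The exact pipeline runs on a uniform random subsample of
    ``n_subsample`` cells, targeting round(N_c / gamma) metacells (gamma is
    interpreted against the full dataset); every remaining cell is then
    projected into the subsample's PCA space and assigned to the metacell
    with the nearest centroid (Euclidean distance).
    """
    n_cells = expr.n_cells
    if n_subsample > n_cells:
        raise ValueError("n_subsample cannot exceed the number of cells")
    n_target = int(np.floor(n_cells / gamma + 0.5))
    if n_subsample < n_target:
        raise ValueError(
            f"n_subsample={n_subsample} is below the requested "
            f"{n_target} metacells"
        )
    rng = np.random.default_rng(seed)
    sub_idx = np.sort(rng.choice(n_cells, size=n_subsample, replace=False))
    sub_expr = ExpressionMatrix(
        expr.dense()[:, sub_idx],
        expr.gene_ids,
        [expr.cell_ids[i] for i in sub_idx],
        is_lognorm=expr.is_lognorm,
    )
    part_sub, emb, _ = make_metacells(
        sub_expr,
        gamma=n_subsample / n_target,
        n_hvg=n_hvg,
        n_pcs=n_pcs,
        k=min(k, n_subsample - 1),
        graph_mode=graph_mode,
        steps=steps,
    )
    n_sc = part_sub.n_metacells
    centroids = np.zeros((n_sc, emb.coords.shape[1]))
    for mc in range(n_sc):
        centroids[mc] = emb.coords[part_sub.cells_of(mc)].mean(axis=0)
    membership = np.full(n_cells, -1, dtype=int)
    membership[sub_idx] = part_sub.membership
    rest = np.setdiff1d(np.arange(n_cells), sub_idx)
    if rest.size:
        coords_rest = emb.project(expr.dense()[:, rest])
        d2 = (
            np.sum(coords_rest**2, axis=1)[:, None]
            - 2.0 * coords_rest @ centroids.T
            + np.sum(centroids**2, axis=1)[None, :]
        )
        membership[rest] = np.argmin(d2, axis=1)
    return MetacellPartition(
        membership=membership,
        gamma=n_cells / n_sc,
        n_metacells=n_sc,
        metadata={"algorithm": "walktrap", "approximate": True, "seed": seed,
                  "n_subsample": n_subsample},
    )
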