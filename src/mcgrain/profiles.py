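"""Metacell-level profiles: averaged expression, layers, embeddings.

A metacell's expression profile is the arithmetic mean of the
log-normalized expression of its member cells (not the log of mean
counts); auxiliary layers such as spliced/unspliced counts and 2-D
embeddings are averaged the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .coarse import MetacellPartition
from .preprocess import ExpressionMatrix

__all__ = [
    "MetacellProfile",
    "average_expression",
    "average_layer",
    "average_embedding",
    "detection_fraction",
]


@dataclass
class MetacellProfile:
    """Metacells x genes mean expression with sizes and optional layers."""

    values: np.ndarray | sp.spmatrix
    sizes: np.ndarray
    gene_ids: list[str]
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_metacells(self) -> int:
        return self.values.shape[0]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)


def _group_indicator(partition: MetacellPartition) -> sp.csr_matrix:
    """Sparse (n_metacells x n_cells) averaging operator: row m has
    1/size(m) at the member cells of metacell m."""
    n = partition.n_cells
    data = 1.0 / partition.sizes[partition.membership]
    return sp.csr_matrix(
        (data, (partition.membership, np.arange(n))),
        shape=(partition.n_metacells, n),
    )


def average_layer(layer: np.ndarray | sp.spmatrix, partition: MetacellPartition) -> np.ndarray:
    """Per-metacell arithmetic mean of a genes x cells layer.

    Returns a metacells x genes array.
    """
    if layer.shape[1] != partition.n_cells:
        raise ValueError(
            f"layer has {layer.shape[1]} cells but partition covers "
            f"{partition.n_cells}"
        )
    op = _group_indicator(partition)
    out = op @ layer.T
    if sp.issparse(out):
        out = np.asarray(out.todense())
    return np.asarray(out)


def average_expression(
    expr: ExpressionMatrix,
    partition: MetacellPartition,
    layers: dict[str, np.ndarray] | None = None,
    sparse_threshold: float = 0.5,
) -> MetacellProfile:
    """Average expression within metacells; optional layers averaged too.

    The output matrix is stored sparse when at least ``sparse_threshold``
    of its entries are zero.
    """
    if expr.n_cells != partition.n_cells:
        raise ValueError(
            f"expression has {expr.n_cells} cells but partition covers "
            f"{partition.n_cells}"
        )
    values = average_layer(expr.values, partition)
    zero_frac = np.mean(values == 0)
    stored: np.ndarray | sp.spmatrix = values
    if zero_frac >= sparse_threshold:
        stored = sp.csr_matrix(values)
    avg_layers = {
        name: average_layer(mat, partition) for name, mat in (layers or {}).items()
    }
    return MetacellProfile(
        values=stored,
        sizes=partition.sizes.copy(),
        gene_ids=list(expr.gene_ids),
        layers=avg_layers,
    )


def average_embedding(coords: np.ndarray, partition: MetacellPartition) -> np.ndarray:
    """Per-metacell mean of a cells x d coordinate matrix (e.g. a 2-D
    layout computed at the single-cell level)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != partition.n_cells:
        raise ValueError("coordinate rows must match the number of cells")
    return np.asarray(_group_indicator(partition) @ coords)


def detection_fraction(expr: ExpressionMatrix, partition: MetacellPartition) -> np.ndarray:
    """Fraction of genes detected (mean expression > 0) in each metacell."""
    x = expr.dense()
    if np.any(x < 0):
        raise ValueError("expression must be non-negative")
    means = average_layer(x, partition)
    return np.mean(means > 0, axis=1)
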