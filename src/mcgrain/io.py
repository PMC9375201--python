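"""Readers and writers for the formats the pipeline touches.

Matrices on disk follow the 10x convention — Matrix Market (.mtx) with
genes as rows and features.tsv / barcodes.tsv sidecars — or dense CSV/TSV
with gene rows and a header of cell ids. Partitions, embeddings, labels,
GO annotations and velocity fields travel as TSV; every partition carries
a JSON sidecar recording the configuration that produced it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .coarse import MetacellGraph, MetacellPartition
from .preprocess import ExpressionMatrix
from .profiles import MetacellProfile

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_partition",
    "read_partition",
    "write_profile",
    "write_embedding",
    "read_go",
    "read_velocity",
    "write_metacell_graph",
]


@dataclass
class RunConfig:
    """Validated run configuration, serialized into every output sidecar."""

    gamma: float = 10.0
    k: int = 5
    n_pcs: int = 10
    n_hvg: int = 1000
    graph_mode: str = "knn"
    algorithm: str = "walktrap"
    steps: int = 4
    approx: bool = False
    n_subsample: int = 50_000
    seed: int = 0
    p_threshold: float = 0.05
    lfc_threshold: float = 0.5

    def validate(self) -> "RunConfig":
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if not (10 <= self.gamma <= 50):
            logger.warning(
                "gamma=%.3g is outside the recommended range [10, 50]", self.gamma
            )
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_pcs < 1 or self.n_hvg < 1 or self.steps < 1:
            raise ValueError("n_pcs, n_hvg and steps must be positive")
        if self.graph_mode not in ("knn", "snn"):
            raise ValueError(f"unknown graph_mode {self.graph_mode!r}")
        if self.algorithm not in ("walktrap", "louvain"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def _dedupe(ids: list[str], what: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for i in ids:
        if i in seen:
            seen[i] += 1
            new = f"{i}.{seen[i]}"
            logger.warning("duplicate %s id %r renamed to %r", what, i, new)
            out.append(new)
        else:
            seen[i] = 0
            out.append(i)
    return out


def read_matrix(
    path: str | Path,
    features: str | Path | None = None,
    barcodes: str | Path | None = None,
    is_lognorm: bool = False,
) -> ExpressionMatrix:
    """Read a genes x cells matrix.

    ``path`` may be a directory holding matrix.mtx + features.tsv +
    barcodes.tsv, a .mtx file (with explicit or sibling sidecars), or a
    dense CSV/TSV with gene rows and a cell-id header.
    """
    path = Path(path)
    if path.is_dir():
        return read_matrix(
            path / "matrix.mtx",
            path / "features.tsv",
            path / "barcodes.tsv",
            is_lognorm,
        )
    if path.suffix == ".mtx":
        features = Path(features) if features else path.parent / "features.tsv"
        barcodes = Path(barcodes) if barcodes else path.parent / "barcodes.tsv"
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ValueError(f"malformed Matrix Market file {path}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        gene_ids = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
        cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
        if mat.shape[0] != len(gene_ids):
            raise ValueError(
                f"{features}: {len(gene_ids)} features but matrix has "
                f"{mat.shape[0]} rows"
            )
        if mat.shape[1] != len(cell_ids):
            raise ValueError(
                f"{barcodes}: {len(cell_ids)} barcodes but matrix has "
                f"{mat.shape[1]} columns"
            )
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    gene_ids = _dedupe(gene_ids, "gene")
    cell_ids = _dedupe(cell_ids, "cell")
    return ExpressionMatrix(mat, gene_ids, cell_ids, is_lognorm=is_lognorm)


def write_matrix(expr: ExpressionMatrix, directory: str | Path) -> None:
    """Write a 10x-style bundle: matrix.mtx + features.tsv + barcodes.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = expr.values if sp.issparse(expr.values) else sp.coo_matrix(expr.values)
    scipy.io.mmwrite(directory / "matrix.mtx", mat)
    pd.Series(expr.gene_ids).to_csv(
        directory / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(expr.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_labels(path: str | Path, cell_ids: list[str] | None = None) -> np.ndarray:
    """Read per-cell labels from a 2-column TSV (cell_id, label); ordered
    to match ``cell_ids`` when given."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"], dtype=str)
    if cell_ids is None:
        return df["label"].to_numpy()
    lookup = dict(zip(df["cell_id"], df["label"]))
    missing = [c for c in cell_ids if c not in lookup]
    if missing:
        raise ValueError(f"labels missing for {len(missing)} cell(s): {missing[:5]}")
    return np.array([lookup[c] for c in cell_ids])


def write_partition(
    partition: MetacellPartition,
    cell_ids: list[str],
    path: str | Path,
    config: RunConfig | None = None,
) -> None:
    """Write cell_id/metacell_id TSV plus a JSON sidecar with the run
    parameters."""
    path = Path(path)
    pd.DataFrame({"cell_id": cell_ids, "metacell_id": partition.membership}).to_csv(
        path, sep="\t", index=False
    )
    sidecar = {
        "n_cells": int(partition.n_cells),
        "n_metacells": int(partition.n_metacells),
        "gamma": float(partition.gamma),
        **{k: v for k, v in partition.metadata.items()},
    }
    if config is not None:
        sidecar["config"] = config.to_dict()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_partition(path: str | Path, cell_ids: list[str] | None = None) -> MetacellPartition:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "metacell_id": int})
    if cell_ids is not None:
        df = df.set_index("cell_id").loc[list(cell_ids)].reset_index()
    membership = df["metacell_id"].to_numpy()
    n_sc = int(membership.max()) + 1
    meta = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return MetacellPartition(
        membership=membership,
        gamma=membership.size / n_sc,
        n_metacells=n_sc,
        metadata={k: v for k, v in meta.items() if k not in ("n_cells", "n_metacells", "gamma")},
    )


def write_profile(profile: MetacellProfile, directory: str | Path) -> None:
    """Write a metacell profile as matrix.mtx (genes x metacells, the 10x
    orientation) + features.tsv + metacell sizes.tsv, plus any layers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(directory / "matrix.mtx", sp.coo_matrix(profile.dense().T))
    pd.Series(profile.gene_ids).to_csv(
        directory / "features.tsv", sep="\t", index=False, header=False
    )
    pd.DataFrame(
        {"metacell_id": np.arange(profile.n_metacells), "size": profile.sizes}
    ).to_csv(directory / "sizes.tsv", sep="\t", index=False)
    for name, layer in profile.layers.items():
        scipy.io.mmwrite(directory / f"layer_{name}.mtx", sp.coo_matrix(np.asarray(layer).T))


def write_embedding(coords: np.ndarray, ids: list[str], path: str | Path) -> None:
    """Write an embedding as TSV: id column + one column per dimension."""
    coords = np.asarray(coords)
    df = pd.DataFrame(coords, columns=[f"PC{i+1}" for i in range(coords.shape[1])])
    df.insert(0, "cell_id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_go(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> GO annotation from a 2-column TSV (gene_id, go_id)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "go_id"], dtype=str)
    go_map: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["go_id"]):
        go_map.setdefault(gene, set()).add(term)
    return go_map


def write_go(go_map: dict[str, set[str]], path: str | Path) -> None:
    rows = [(g, t) for g in sorted(go_map) for t in sorted(go_map[g])]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_velocity(path: str | Path, cell_ids: list[str] | None = None) -> np.ndarray:
    """Read per-cell velocity vectors from TSV (cell_id + numeric columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    if cell_ids is not None:
        df = df.set_index("cell_id").loc[list(cell_ids)].reset_index()
    return df.drop(columns=["cell_id"]).to_numpy(dtype=float)


def write_velocity(v: np.ndarray, cell_ids: list[str], path: str | Path) -> None:
    v = np.asarray(v)
    df = pd.DataFrame(v, columns=[f"v{i}" for i in range(v.shape[1])])
    df.insert(0, "cell_id", cell_ids)
    df.to_csv(path, sep="\t", index=False)


def write_metacell_graph(graph: MetacellGraph, path: str | Path) -> None:
    """Write the metacell network as a weighted edge-list TSV."""
    rows = [(i, j, wt) for (i, j), wt in sorted(graph.edges.items())]
    pd.DataFrame(rows, columns=["metacell_a", "metacell_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )
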