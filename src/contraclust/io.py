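"""Reading and writing count matrices, labels, embeddings and partitions.

The canonical in-memory container is :class:`CountMatrix`: a dense
cells x genes array of raw counts plus cell/gene identifiers and optional
ground-truth cluster labels.  All readers normalise to the cells x genes
orientation regardless of how the file is laid out on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class CountMatrix:
    """Raw count matrix with ``n`` cells (rows) and ``d`` genes (columns).

    Parameters
    ----------
    counts
        Non-negative ``(n, d)`` array of raw counts (typically integers).
    cell_ids, gene_ids
        Unique identifiers for rows and columns.
    labels
        Optional per-cell ground-truth cluster labels of length ``n``.
    """

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n, d = self.counts.shape
        if n < 2 or d < 2:
            raise ValidationError(f"need at least 2 cells and 2 genes, got {n}x{d}")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(f"negative count at cell {i}, gene {j}")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite values")
        if len(self.cell_ids) != n:
            raise ValidationError("cell_ids length does not match matrix")
        if len(self.gene_ids) != d:
            raise ValidationError("gene_ids length does not match matrix")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("cell_ids are not unique")
        if len(set(self.gene_ids)) != d:
            raise ValidationError("gene_ids are not unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != n:
                raise ValidationError("labels length does not match cell count")
        if not np.allclose(self.counts, np.round(self.counts)):
            warnings.warn(
                "input matrix contains non-integer values; treating as "
                "already-normalised expression",
                stacklevel=3,
            )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "CountMatrix":
        labels = self.labels[idx] if self.labels is not None else None
        return CountMatrix(self.counts[idx], self.cell_ids[idx], self.gene_ids, labels)

    def subset_genes(self, idx: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[:, idx], self.cell_ids, self.gene_ids[idx], self.labels
        )


@dataclass
class Embedding:
    """Per-cell representation-layer output: an ``(n, e)`` real matrix."""

    z: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.z.ndim != 2:
            raise ValidationError("embedding must be 2-D")
        if not np.all(np.isfinite(self.z)):
            raise ValidationError("embedding contains non-finite values")
        if len(self.cell_ids) != self.z.shape[0]:
            raise ValidationError("cell_ids length does not match embedding")


@dataclass
class Partition:
    """Cluster assignment: per-cell integer labels in ``[0, K)``.

    Labels are re-indexed to consecutive integers ordered by cluster size
    (largest cluster is 0) so reports are stable across backends.
    """

    labels: np.ndarray
    cell_ids: np.ndarray
    method: str = "unknown"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if len(self.labels) == 0:
            raise ValidationError("partition must be non-empty")
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("cell_ids length does not match labels")
        self.labels = _relabel_by_size(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Map labels onto 0..K-1 ordered by decreasing cluster size.

    Ties are broken by original label order for determinism.
    """
    uniq, counts = np.unique(labels, return_counts=True)
    order = np.lexsort((uniq, -counts))
    mapping = {int(uniq[o]): rank for rank, o in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels], dtype=int)


# ---------------------------------------------------------------------------
# Readers


def read_counts(
    path,
    format: str = "csv",
    orientation: str = "cells_by_genes",
    labels_path=None,
) -> CountMatrix:
    """Read a count matrix in CSV/TSV, MatrixMarket MTX or H5AD form.

    ``orientation`` states how the *file* is laid out; the returned
    :class:`CountMatrix` is always cells x genes.  Missing row/column names
    are synthesised as ``cell_i`` / ``gene_j``.  For MTX, sidecar name files
    ``<stem>_rows.txt`` / ``<stem>_cols.txt`` are used when present.
    """
    path = Path(path)
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("csv", "tsv"):
        cm = _read_dense(path, sep="\t" if format == "tsv" else ",")
    elif format == "mtx":
        cm = _read_mtx(path)
    elif format == "h5ad":
        cm = _read_h5ad(path)
    else:
        raise ValidationError(f"unknown format {format!r}")
    if orientation == "genes_by_cells":
        cm = CountMatrix(cm.counts.T, cm.gene_ids, cm.cell_ids, None)
    if labels_path is not None:
        cm.labels = read_labels(labels_path, cm.cell_ids)
    return cm


def _synth_names(prefix: str, k: int) -> np.ndarray:
    return np.array([f"{prefix}_{i}" for i in range(k)], dtype=object)


def _read_dense(path: Path, sep: str) -> CountMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"failed to parse {path}: {exc}") from exc
    counts = df.to_numpy(dtype=float)
    return CountMatrix(
        counts,
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


def _read_mtx(path: Path) -> CountMatrix:
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:
        raise ValidationError(f"failed to parse {path}: {exc}") from exc
    counts = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
    )
    stem = path.with_suffix("")
    rows_f, cols_f = Path(f"{stem}_rows.txt"), Path(f"{stem}_cols.txt")
    cell_ids = (
        np.array(rows_f.read_text().split(), dtype=object)
        if rows_f.exists()
        else _synth_names("cell", counts.shape[0])
    )
    gene_ids = (
        np.array(cols_f.read_text().split(), dtype=object)
        if cols_f.exists()
        else _synth_names("gene", counts.shape[1])
    )
    return CountMatrix(counts, cell_ids, gene_ids)


def _read_h5ad(path: Path) -> CountMatrix:
    import anndata

    adata = anndata.read_h5ad(path)
    # raw counts are the declared input: prefer an explicit "counts" layer
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    if scipy.sparse.issparse(X):
        X = X.toarray()
    labels = None
    for key in ("labels", "cell_type", "group"):
        if key in adata.obs:
            labels = adata.obs[key].to_numpy(dtype=object)
            break
    return CountMatrix(
        np.asarray(X, dtype=float),
        adata.obs_names.to_numpy(dtype=object),
        adata.var_names.to_numpy(dtype=object),
        labels,
    )


def read_labels(path, cell_ids: Sequence) -> np.ndarray:
    """Read per-cell labels from a single-column CSV keyed by cell id."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] != 1:
        raise ValidationError("labels file must have exactly one value column")
    series = df.iloc[:, 0]
    missing = [c for c in cell_ids if c not in series.index]
    if missing:
        raise ValidationError(f"labels missing for cells: {missing[:5]}")
    return series.loc[list(cell_ids)].to_numpy(dtype=object)


# ---------------------------------------------------------------------------
# Writers


def write_counts(cm: CountMatrix, path, format: str = "csv") -> Path:
    """Write a CountMatrix (cells x genes) plus labels when present."""
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "\t" if format == "tsv" else ","
        pd.DataFrame(cm.counts, index=cm.cell_ids, columns=cm.gene_ids).to_csv(
            path, sep=sep
        )
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts))
        stem = path.with_suffix("")
        Path(f"{stem}_rows.txt").write_text("\n".join(map(str, cm.cell_ids)) + "\n")
        Path(f"{stem}_cols.txt").write_text("\n".join(map(str, cm.gene_ids)) + "\n")
    elif format == "h5ad":
        import anndata

        adata = anndata.AnnData(X=cm.counts)
        adata.obs_names = [str(c) for c in cm.cell_ids]
        adata.var_names = [str(g) for g in cm.gene_ids]
        if cm.labels is not None:
            adata.obs["labels"] = pd.Categorical([str(l) for l in cm.labels])
        adata.write_h5ad(path)
    else:
        raise ValidationError(f"unknown format {format!r}")
    if cm.labels is not None and format != "h5ad":
        write_labels(cm, path.with_name(path.stem + "_labels.csv"))
    return path


def write_labels(cm: CountMatrix, path) -> Path:
    if cm.labels is None:
        raise ValidationError("CountMatrix has no labels")
    pd.Series(cm.labels, index=cm.cell_ids, name="label").rename_axis(
        "cell_id"
    ).to_csv(path)
    return Path(path)


def write_partition(partition: Partition, path) -> Path:
    """Write a two-column CSV (cell_id, cluster)."""
    pd.Series(partition.labels, index=partition.cell_ids, name="cluster").rename_axis(
        "cell_id"
    ).to_csv(path)
    return Path(path)


def read_partition(path) -> Partition:
    df = pd.read_csv(path, index_col=0)
    return Partition(
        df["cluster"].to_numpy(dtype=int), df.index.to_numpy(dtype=object)
    )


def write_embedding(embedding: Embedding, path) -> Path:
    """Write an embedding as CSV with cell ids and one column per dimension."""
    df = pd.DataFrame(
        embedding.z,
        index=embedding.cell_ids,
        columns=[f"e{j}" for j in range(embedding.z.shape[1])],
    ).rename_axis("cell_id")
    df.to_csv(path, float_format="%.17g")
    return Path(path)


def read_embedding(path) -> Embedding:
    df = pd.read_csv(path, index_col=0)
    return Embedding(df.to_numpy(dtype=float), df.index.to_numpy(dtype=object))
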