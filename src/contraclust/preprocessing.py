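"""Count-matrix preprocessing: filter, normalise, log, HVG selection, scaling.

The recipe, applied in order:

1. drop genes expressed (count > 0) in fewer than ``min_cells_expressed`` cells;
2. median library-size normalisation — each cell is divided by its total
   count and multiplied by the median total, so all cells end up with the
   same library size;
3. natural-log transform ``ln(1 + x)``;
4. ranking of genes by Seurat-flavour binned normalised dispersion and
   retention of the top ``n_top_genes``;
5. per-gene standardisation to zero mean and unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CountMatrix, ValidationError

N_DISPERSION_BINS = 20


@dataclass
class PreprocessConfig:
    """Settings for the preprocessing recipe.

    ``n_top_genes`` may be the string ``"all"`` to keep every gene that
    survives filtering (still re-ordered by dispersion rank).
    """

    min_cells_expressed: int = 2
    n_top_genes: Union[int, str] = 500
    scale: bool = True
    log: bool = True

    def __post_init__(self) -> None:
        if self.n_top_genes != "all" and int(self.n_top_genes) < 2:
            raise ValidationError("n_top_genes must be >= 2 or 'all'")
        if self.min_cells_expressed < 0:
            raise ValidationError("min_cells_expressed must be >= 0")


@dataclass
class PreprocessedMatrix:
    """Output of the recipe: an ``(n, d')`` real matrix plus bookkeeping."""

    values: np.ndarray
    cell_ids: np.ndarray
    selected_genes: np.ndarray
    per_gene_mean: Optional[np.ndarray] = None
    per_gene_std: Optional[np.ndarray] = None
    size_factor_target: float = 0.0
    labels: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def filter_genes(cm: CountMatrix, min_cells_expressed: int = 2) -> CountMatrix:
    """Keep genes with nonzero counts in at least ``min_cells_expressed`` cells."""
    n_expressing = (cm.counts > 0).sum(axis=0)
    keep = n_expressing >= min_cells_expressed
    if not keep.any() or keep.sum() < 2:
        raise ValidationError(
            "gene filtering removed (almost) all genes; lower min_cells_expressed"
        )
    return cm.subset_genes(np.flatnonzero(keep))


def normalize_library_size(cm: CountMatrix) -> np.ndarray:
    """Scale each cell to the median total count.

    Every row of the result sums to the median of the original per-cell
    totals, making library sizes identical across cells.
    """
    totals = cm.counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"cell(s) with zero total count: {list(cm.cell_ids[zero[:5]])}"
        )
    median = float(np.median(totals))
    return cm.counts * (median / totals)[:, None]


def log_transform(m: np.ndarray) -> np.ndarray:
    """Entrywise natural logarithm ``ln(1 + x)``; zeros stay zero."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValidationError("log transform requires non-negative entries")
    return np.log1p(m)


def dispersion_rank(m: np.ndarray) -> np.ndarray:
    """Rank genes by normalised dispersion, most variable first.

    Seurat-flavour ranking: per-gene dispersion is variance/mean; genes are
    cut into ``N_DISPERSION_BINS`` equal-frequency bins of mean expression and
    the dispersion is z-scored within each bin, so highly-expressed genes do
    not dominate purely through their scale.  A bin holding a single gene (or
    with zero dispersion spread) keeps its raw dispersion.  Ties break by
    higher mean, then by input order.
    """
    m = np.asarray(m, dtype=float)
    mean = m.mean(axis=0)
    var = m.var(axis=0, ddof=1) if m.shape[0] > 1 else np.zeros(m.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    d = m.shape[1]
    n_bins = min(N_DISPERSION_BINS, d)
    # equal-frequency bins over the mean; searchsorted on quantile edges
    edges = np.quantile(mean, np.linspace(0, 1, n_bins + 1)[1:-1])
    bin_of = np.searchsorted(edges, mean, side="left")

    norm_disp = np.empty(d)
    for b in np.unique(bin_of):
        members = np.flatnonzero(bin_of == b)
        dvals = disp[members]
        std = dvals.std(ddof=1) if members.size > 1 else 0.0
        if std > 0:
            norm_disp[members] = (dvals - dvals.mean()) / std
        else:
            norm_disp[members] = dvals
    # sort by (-norm_disp, -mean, index): stable, deterministic
    order = np.lexsort((np.arange(d), -mean, -norm_disp))
    return order


def select_hvg(
    m: np.ndarray, gene_ids: np.ndarray, n_top: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Keep the ``n_top`` most variable genes, columns in rank order."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    if n_top > m.shape[1]:
        raise ValidationError(
            f"n_top={n_top} exceeds available genes ({m.shape[1]})"
        )
    order = dispersion_rank(m)[:n_top]
    return m[:, order], gene_ids[order]


def scale_genes(m: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardise each gene to zero mean, unit variance.

    Constant genes become all-zero columns rather than NaN.  Returns the
    scaled matrix and the (mean, std) vectors used.
    """
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValidationError("matrix must be finite before scaling")
    mean = m.mean(axis=0)
    std = m.std(axis=0, ddof=0)
    safe = np.where(std > 0, std, 1.0)
    out = (m - mean) / safe
    return out, mean, std


def preprocess(cm: CountMatrix, cfg: Optional[PreprocessConfig] = None) -> PreprocessedMatrix:
    """Run the full recipe: filter -> normalise -> log -> HVG -> scale."""
    cfg = cfg or PreprocessConfig()
    cm = filter_genes(cm, cfg.min_cells_expressed)
    values = normalize_library_size(cm)
    target = float(np.median(cm.counts.sum(axis=1)))
    if cfg.log:
        values = log_transform(values)
    n_top = cm.n_genes if cfg.n_top_genes == "all" else min(int(cfg.n_top_genes), cm.n_genes)
    values, selected = select_hvg(values, cm.gene_ids, n_top)
    mean = std = None
    if cfg.scale:
        values, mean, std = scale_genes(values)
    return PreprocessedMatrix(
        values=values,
        cell_ids=cm.cell_ids,
        selected_genes=selected,
        per_gene_mean=mean,
        per_gene_std=std,
        size_factor_target=target,
        labels=cm.labels,
    )


class CountPreprocessor(TransformerMixin, BaseEstimator):
    """Estimator wrapper over :func:`preprocess` for pipeline composition.

    ``fit`` learns the gene selection and scaling statistics from a raw
    cells x genes count array; ``transform`` returns the preprocessed matrix
    for the same data.  Because HVG selection and scaling are defined on the
    training data itself, this transformer is intended for fit_transform use
    within a single dataset, mirroring unsupervised practice.
    """

    def __init__(
        self,
        min_cells_expressed: int = 2,
        n_top_genes: Union[int, str] = 500,
        scale: bool = True,
        log: bool = True,
    ):
        self.min_cells_expressed = min_cells_expressed
        self.n_top_genes = n_top_genes
        self.scale = scale
        self.log = log

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            min_cells_expressed=self.min_cells_expressed,
            n_top_genes=self.n_top_genes,
            scale=self.scale,
            log=self.log,
        )

    def fit(self, X, y=None):
        self.fit_transform(X, y)
        return self

    def fit_transform(self, X, y=None):
        cm = _as_count_matrix(X)
        pm = preprocess(cm, self._config())
        self.selected_genes_ = pm.selected_genes
        self.per_gene_mean_ = pm.per_gene_mean
        self.per_gene_std_ = pm.per_gene_std
        self.size_factor_target_ = pm.size_factor_target
        self.result_ = pm
        return pm.values

    def transform(self, X):
        # refitting on new data would change the gene set; reuse the recipe
        # deterministically on the fitted dataset only
        if not hasattr(self, "result_"):
            raise ValidationError("CountPreprocessor is not fitted")
        return self.fit_transform(X)


def _as_count_matrix(X) -> CountMatrix:
    if isinstance(X, CountMatrix):
        return X
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    return CountMatrix(
        X,
        np.array([f"cell_{i}" for i in range(n)], dtype=object),
        np.array([f"gene_{j}" for j in range(d)], dtype=object),
    )
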