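"""Splatter-style synthetic scRNA-seq count generator.

Generates group-structured count matrices with the ingredients of the splat
"experiment" model: gamma-distributed gene base means, per-group
multiplicative differential-expression factors, lognormal library sizes,
Poisson sampling, and an expression-dependent logistic dropout step that
zeroes low-mean entries preferentially.  Two pre-configured suites mirror
the balanced (250 cells/group, 4/8/16 groups) and imbalanced (3000 cells,
group-size ratios spanning 0.6 down to 0.01) study designs, each crossed
with dropout midpoints ``mid`` in {-1, 0, 1, 1.5}.

The generator intentionally omits splatter's BCV over-dispersion layer,
batch effects and trajectory modes: only the distributional structure that
the clustering study exercises is reproduced, not splatter's RNG streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .io import CountMatrix, ValidationError

BALANCED_GROUP_COUNTS = (4, 8, 16)
DROPOUT_MIDS = (-1.0, 0.0, 1.0, 1.5)
IMBALANCED_TOTAL_CELLS = 3000
# smallest/largest group-size ratio per design, spanning the 0.6-0.01 band
_IMBALANCE_RATIO = {4: 0.6, 8: 0.077, 16: 0.01}
_MIN_GROUP_CELLS = 10


@dataclass
class SimConfig:
    """Generative parameters.

    ``dropout_mid`` shifts the logistic dropout curve along log-mean
    expression: larger values zero more entries.  ``dropout_shape`` is the
    (negative) slope, so low-expression entries drop out preferentially.
    Gamma and lognormal defaults follow splatter's published defaults.
    """

    n_genes: int = 2500
    group_sizes: Sequence[int] = field(default_factory=lambda: [250, 250, 250, 250])
    de_prob: float = 0.1
    de_fac_loc: float = 0.1
    de_fac_scale: float = 0.2
    dropout_mid: float = -1.0
    dropout_shape: float = -1.0
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if any(int(s) < 1 for s in self.group_sizes):
            raise ValidationError("all group sizes must be >= 1")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValidationError("de_prob must lie in [0, 1]")
        if min(self.de_fac_scale, self.mean_shape, self.mean_rate, self.lib_scale) <= 0:
            raise ValidationError("scale/shape parameters must be > 0")


@dataclass
class SimulatedDataset:
    """A CountMatrix with ground-truth groups and the realised dropout rate."""

    counts: CountMatrix
    true_dropout_rate: float
    config: SimConfig

    @property
    def n_groups(self) -> int:
        return len(set(self.counts.labels))


def simulate(cfg: SimConfig) -> SimulatedDataset:
    """Draw one synthetic dataset under ``cfg``.

    Steps, all under one seeded generator: gene base means from
    Gamma(shape, rate); per-group DE factors from LogNormal(0, facScale)
    applied to a random ``de_prob`` fraction of genes (half of them
    inverted, i.e. down-regulated); lognormal cell library sizes; Poisson
    counts around ``mu_gc``; and logistic dropout
    ``pi_gc = 1 / (1 + exp(-shape * (ln mu_gc - mid)))`` applied entrywise.
    ``true_dropout_rate`` records the realised fraction of expressed
    (pre-dropout nonzero) entries that the dropout step zeroed; Poisson
    zeros are not counted, which is why this rate sits below the overall
    matrix sparsity.
    """
    rng = np.random.default_rng(cfg.seed)
    n_genes = int(cfg.n_genes)
    group_sizes = [int(s) for s in cfg.group_sizes]
    n_groups = len(group_sizes)
    n_cells = sum(group_sizes)

    base_mean = rng.gamma(cfg.mean_shape, 1.0 / cfg.mean_rate, size=n_genes)

    group_means = np.tile(base_mean, (n_groups, 1))
    for g in range(n_groups):
        is_de = rng.random(n_genes) < cfg.de_prob
        factors = rng.lognormal(cfg.de_fac_loc, cfg.de_fac_scale, size=n_genes)
        down = rng.random(n_genes) < 0.5
        factors = np.where(down, 1.0 / factors, factors)
        group_means[g, is_de] *= factors[is_de]

    labels = np.repeat(np.arange(n_groups), group_sizes)
    lib_size = rng.lognormal(cfg.lib_loc, cfg.lib_scale, size=n_cells)

    # per-cell expected profile: group profile scaled to the cell's library
    props = group_means / group_means.sum(axis=1, keepdims=True)
    mu = props[labels] * lib_size[:, None]

    counts = rng.poisson(mu).astype(float)

    with np.errstate(divide="ignore"):
        log_mu = np.log(np.where(mu > 0, mu, np.finfo(float).tiny))
    pi = 1.0 / (1.0 + np.exp(-cfg.dropout_shape * (log_mu - cfg.dropout_mid)))
    dropped = rng.random(mu.shape) < pi
    expressed = counts > 0
    n_expressed = int(expressed.sum())
    realized = float((dropped & expressed).sum() / n_expressed) if n_expressed else 0.0
    counts[dropped] = 0.0

    cm = CountMatrix(
        counts,
        np.array([f"cell_{i}" for i in range(n_cells)], dtype=object),
        np.array([f"gene_{j}" for j in range(n_genes)], dtype=object),
        labels=np.array([f"group_{g}" for g in labels], dtype=object),
    )
    return SimulatedDataset(cm, realized, cfg)


def _suite_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 1000 + index) % (2**31))


def make_balanced_suite(seed: int = 0, cfg: Optional[SimConfig] = None) -> List[SimulatedDataset]:
    """The 12 balanced designs: groups in {4, 8, 16} x mid in {-1, 0, 1, 1.5}.

    250 cells per group, 2500 genes, facScale 0.2; dropout rates grow with
    ``mid`` within each group count.
    """
    base = cfg or SimConfig()
    out = []
    for i, (k, mid) in enumerate(
        (k, mid) for k in BALANCED_GROUP_COUNTS for mid in DROPOUT_MIDS
    ):
        out.append(
            simulate(
                replace(
                    base,
                    group_sizes=[250] * k,
                    dropout_mid=mid,
                    seed=_suite_seed(seed, i),
                )
            )
        )
    return out


def imbalanced_group_sizes(n_groups: int, total: int = IMBALANCED_TOTAL_CELLS) -> List[int]:
    """Geometric-decay group sizes whose min/max ratio matches the design band.

    A floor of 10 cells per group is applied so no group is degenerate; the
    remainder after rounding is assigned to the largest group.
    """
    ratio = _IMBALANCE_RATIO[n_groups]
    r = ratio ** (1.0 / (n_groups - 1))
    weights = r ** np.arange(n_groups)
    sizes = np.maximum(np.round(total * weights / weights.sum()).astype(int), _MIN_GROUP_CELLS)
    sizes[0] += total - sizes.sum()
    # integer rounding can nudge min/max above the 0.6 band edge; rebalance
    while sizes.min() / sizes.max() > 0.6 and sizes.min() > _MIN_GROUP_CELLS:
        sizes[np.argmin(sizes)] -= 1
        sizes[np.argmax(sizes)] += 1
    return [int(s) for s in sizes]


def make_imbalanced_suite(seed: int = 0, cfg: Optional[SimConfig] = None) -> List[SimulatedDataset]:
    """The 12 imbalanced designs: 3000 cells, groups in {4, 8, 16} x mid."""
    base = cfg or SimConfig()
    out = []
    for i, (k, mid) in enumerate(
        (k, mid) for k in BALANCED_GROUP_COUNTS for mid in DROPOUT_MIDS
    ):
        out.append(
            simulate(
                replace(
                    base,
                    group_sizes=imbalanced_group_sizes(k),
                    dropout_mid=mid,
                    seed=_suite_seed(seed, 100 + i),
                )
            )
        )
    return out


def stratified_downsample(cm: CountMatrix, fraction: float, seed: int = 0) -> CountMatrix:
    """Randomly keep ``fraction`` of cells within every label stratum.

    Each label's retained count is ``round(fraction * n_label)``; original
    cell order is preserved among the kept cells.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must lie in (0, 1]")
    if cm.labels is None:
        raise ValidationError("stratified downsampling requires labels")
    if fraction == 1.0:
        return cm.subset_cells(np.arange(cm.n_cells))
    rng = np.random.default_rng(seed)
    keep: List[int] = []
    for label in np.unique(cm.labels.astype(str)):
        members = np.flatnonzero(cm.labels.astype(str) == label)
        n_keep = int(round(fraction * members.size))
        if n_keep == 0:
            raise ValidationError(f"fraction {fraction} empties label {label!r}")
        keep.extend(rng.choice(members, size=n_keep, replace=False))
    return cm.subset_cells(np.sort(np.array(keep)))
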