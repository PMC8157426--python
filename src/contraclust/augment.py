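"""Gene-masking data augmentation for contrastive training.

Each training step sees two independently augmented *views* of the same
mini-batch.  The augmentation masks a random subset of gene values per cell
(input-level dropout), optionally followed by additive Gaussian noise.  With
``rescale_survivors`` on, surviving entries are multiplied by ``1/(1-p)``
(inverted-dropout semantics) so the view is unbiased: E[view] = input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .io import ValidationError


@dataclass
class AugmentConfig:
    """Masking ratio ``p``, noise level ``sigma`` and rescaling flag.

    Defaults follow the ablation findings: masking 90% of genes per view is
    the strongest-performing augmentation, and additive noise does not help,
    so ``noise_std`` defaults to 0.
    """

    mask_ratio: float = 0.9
    noise_std: float = 0.0
    rescale_survivors: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_ratio < 1.0:
            raise ValidationError("mask_ratio must lie in [0, 1)")
        if self.noise_std < 0:
            raise ValidationError("noise_std must be >= 0")


def mask_genes(batch: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Zero each entry independently with probability ``cfg.mask_ratio``.

    Every cell in every view draws its own gene mask, so successive calls
    (with an advancing generator) produce different augmented versions.
    """
    batch = np.asarray(batch, dtype=float)
    p = cfg.mask_ratio
    if p == 0.0:
        return batch.copy()
    keep = rng.random(batch.shape) >= p
    out = batch * keep
    if cfg.rescale_survivors:
        out /= 1.0 - p
    return out


def add_noise(batch: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian noise of standard deviation ``sigma``."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    batch = np.asarray(batch, dtype=float)
    if sigma == 0.0:
        return batch.copy()
    return batch + rng.normal(0.0, sigma, size=batch.shape)


def make_views(
    batch: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Create the two independently augmented views of a mini-batch."""
    batch = np.asarray(batch, dtype=float)
    if batch.shape[0] < 2:
        raise ValidationError("need at least 2 cells per batch")
    views = []
    for _ in range(2):
        v = mask_genes(batch, cfg, rng)
        if cfg.noise_std > 0:
            v = add_noise(v, cfg.noise_std, rng)
        views.append(v)
    return views[0], views[1]
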