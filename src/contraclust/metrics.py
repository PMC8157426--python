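"""Clustering evaluation battery.

External scores (need ground truth): adjusted Rand index and normalised
mutual information.  Internal scores (label-free): Silhouette and
Calinski-Harabasz.  Plus the relative cluster-count error and the
coefficient of variation used to aggregate scores over repeated runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    normalized_mutual_info_score,
    silhouette_score,
)

from .io import Embedding, ValidationError


@dataclass
class ScoreReport:
    """One evaluation row: external + internal scores for a partition."""

    ari: Optional[float] = None
    nmi: Optional[float] = None
    silhouette: Optional[float] = None
    calinski: Optional[float] = None
    k_error: Optional[float] = None
    n_clusters: Optional[int] = None
    extras: Dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        out = {
            "ari": self.ari,
            "nmi": self.nmi,
            "silhouette": self.silhouette,
            "calinski": self.calinski,
            "k_error": self.k_error,
            "n_clusters": self.n_clusters,
        }
        out.update(self.extras)
        return out


def _check_pair(truth, pred):
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValidationError("truth and pred must be 1-D and of equal length")
    if truth.size < 2:
        raise ValidationError("need at least 2 samples")
    return truth, pred


def ari(truth, pred) -> float:
    """Adjusted Rand index: pair-counting agreement, corrected for chance."""
    truth, pred = _check_pair(truth, pred)
    return float(adjusted_rand_score(truth, pred))


def nmi(truth, pred) -> float:
    """Mutual information normalised by the arithmetic mean of entropies.

    Degenerate single-cluster labelings return 0 by convention.
    """
    truth, pred = _check_pair(truth, pred)
    return float(normalized_mutual_info_score(truth, pred, average_method="arithmetic"))


def _check_internal(z: np.ndarray, pred: np.ndarray):
    z = np.asarray(z, dtype=float)
    if isinstance(pred, np.ndarray) is False:
        pred = np.asarray(pred)
    if z.ndim != 2 or z.shape[0] != pred.shape[0]:
        raise ValidationError("embedding rows must match label length")
    k = len(np.unique(pred))
    n = z.shape[0]
    if not 2 <= k <= n - 1:
        raise ValidationError(f"need 2 <= K <= n-1 clusters, got K={k}, n={n}")
    return z, pred


def silhouette(emb, pred) -> float:
    """Mean Silhouette coefficient, Euclidean distance."""
    z = emb.z if isinstance(emb, Embedding) else emb
    z, pred = _check_internal(z, np.asarray(pred))
    return float(silhouette_score(z, pred, metric="euclidean"))


def calinski_harabasz(emb, pred) -> float:
    """Between/within dispersion ratio ``[B/(K-1)] / [W/(n-K)]``."""
    z = emb.z if isinstance(emb, Embedding) else emb
    z, pred = _check_internal(z, np.asarray(pred))
    score = float(calinski_harabasz_score(z, pred))
    if not np.isfinite(score):
        raise ValidationError("degenerate partition: zero within-cluster dispersion")
    return score


def k_error(pred_k: int, true_k: int) -> float:
    """Relative cluster-count error ``(pred - true) / true``."""
    if true_k < 1:
        raise ValidationError("true_k must be >= 1")
    return (pred_k - true_k) / true_k


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation divided by the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("need at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValidationError("coefficient of variation undefined for zero mean")
    return float(values.std(ddof=1) / mean)


def score_partition(
    pred_labels,
    embedding=None,
    truth_labels=None,
    true_k: Optional[int] = None,
) -> ScoreReport:
    """Compute every applicable score for a partition in one call."""
    pred_labels = np.asarray(pred_labels)
    report = ScoreReport(n_clusters=int(len(np.unique(pred_labels))))
    if truth_labels is not None:
        report.ari = ari(truth_labels, pred_labels)
        report.nmi = nmi(truth_labels, pred_labels)
        if true_k is None:
            true_k = int(len(np.unique(np.asarray(truth_labels))))
    if true_k is not None:
        report.k_error = k_error(report.n_clusters, true_k)
    if embedding is not None and report.n_clusters >= 2:
        z = embedding.z if isinstance(embedding, Embedding) else np.asarray(embedding)
        if report.n_clusters <= z.shape[0] - 1:
            report.silhouette = silhouette(z, pred_labels)
            report.calinski = calinski_harabasz(z, pred_labels)
    return report


def aggregate_scores(reports: List[ScoreReport]) -> Dict[str, Dict[str, float]]:
    """Mean and coefficient of variation per score across repeated runs."""
    out: Dict[str, Dict[str, float]] = {}
    for key in ("ari", "nmi", "silhouette", "calinski", "k_error"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if not vals:
            continue
        entry = {"mean": float(np.mean(vals)), "values": [float(v) for v in vals]}
        if len(vals) >= 2 and np.mean(vals) != 0:
            entry["cv"] = coefficient_of_variation(vals)
        out[key] = entry
    return out
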