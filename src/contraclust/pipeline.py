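"""End-to-end runner and the experiment protocols.

``run_pipeline`` chains preprocessing, contrastive representation learning
and clustering, scoring against ground truth when labels are present.  The
sweep functions reproduce the ablation protocols: input-gene-count sweep
(chosen by the label-free Silhouette score), mask-ratio sweep, architecture
grid, and the multi-seed stability / stratified-downsampling report.  Every
experiment repeats each setting ``n_runs`` times with seeds derived as
``base_seed + run_index`` and reports per-run scores plus mean and
coefficient of variation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .augment import AugmentConfig
from .cluster import ClusterParams, cluster as run_cluster
from .encoder import EncoderConfig, TrainConfig, count_parameters, train
from .io import CountMatrix, Embedding, Partition, write_embedding, write_partition
from .metrics import ScoreReport, aggregate_scores, score_partition
from .preprocessing import PreprocessConfig, preprocess

DEFAULT_GENE_SIZES: Tuple = (500, 1000, 1500, 3000, 5000, "all")
DEFAULT_MASK_RATIOS: Tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
DOWNSAMPLE_FRACTIONS: Tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)


@dataclass
class PipelineConfig:
    """Bundle of all stage configurations plus the repetition protocol."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    layer_sizes: Sequence[int] = (200, 40, 60)
    norm_after_hidden: bool = True
    train: TrainConfig = field(default_factory=TrainConfig)
    cluster: ClusterParams = field(default_factory=lambda: ClusterParams("leiden"))
    n_runs: int = 3
    output_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(
            self,
            train=replace(self.train, seed=seed),
            cluster=replace(self.cluster, seed=seed),
        )

    def snapshot(self) -> dict:
        return {
            "preprocess": vars(self.preprocess).copy(),
            "augment": vars(self.augment).copy(),
            "layer_sizes": list(self.layer_sizes),
            "norm_after_hidden": self.norm_after_hidden,
            "train": vars(self.train).copy(),
            "cluster": self.cluster.snapshot(),
            "n_runs": self.n_runs,
        }


@dataclass
class ExperimentResult:
    """Tidy per-run score table plus per-setting aggregates."""

    rows: pd.DataFrame
    aggregates: dict
    chosen: Optional[dict] = None

    def write(self, path) -> Path:
        path = Path(path)
        self.rows.to_csv(path, index=False)
        return path


def run_pipeline(
    cm: CountMatrix, cfg: Optional[PipelineConfig] = None
) -> Tuple[Embedding, Partition, Optional[ScoreReport]]:
    """Preprocess, train the encoder, cluster, and (optionally) score.

    Scores are computed iff the input carries ground-truth labels.  When
    ``cfg.output_dir`` is set, the embedding, partition, score row and a
    config snapshot are written there.
    """
    cfg = cfg or PipelineConfig()
    pm = preprocess(cm, cfg.preprocess)
    ecfg = EncoderConfig(
        input_dim=pm.n_genes,
        layer_sizes=list(cfg.layer_sizes),
        norm_after_hidden=cfg.norm_after_hidden,
    )
    emb, history = train(pm, ecfg, cfg.train, cfg.augment)
    part = run_cluster(emb, cfg.cluster)
    report = None
    if cm.labels is not None:
        report = score_partition(part.labels, emb, truth_labels=pm.labels)
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_embedding(emb, out / "embedding.csv")
        write_partition(part, out / "partition.csv")
        payload = {"config": cfg.snapshot(), "loss_history": history}
        if report is not None:
            payload["scores"] = report.as_dict()
        (out / "run.json").write_text(json.dumps(payload, indent=2, default=str))
    return emb, part, report


def _repeat_runs(
    cm: CountMatrix, cfg: PipelineConfig, setting: dict
) -> List[dict]:
    rows = []
    for run in range(cfg.n_runs):
        seed = cfg.train.seed + run
        emb, part, report = run_pipeline(cm, cfg.with_seed(seed))
        row = dict(setting)
        row["seed"] = seed
        if report is not None:
            row.update(report.as_dict())
        else:
            row.update(
                score_partition(part.labels, emb).as_dict()
            )
        rows.append(row)
    return rows


def _result(rows: List[dict], by: str) -> ExperimentResult:
    df = pd.DataFrame(rows)
    aggregates = {}
    for value, sub in df.groupby(by, sort=False):
        reports = [
            ScoreReport(
                ari=r.get("ari"),
                nmi=r.get("nmi"),
                silhouette=r.get("silhouette"),
                calinski=r.get("calinski"),
                k_error=r.get("k_error"),
            )
            for r in sub.to_dict("records")
        ]
        aggregates[value] = aggregate_scores(reports)
    return ExperimentResult(df, aggregates)


def sweep_gene_count(
    cm: CountMatrix,
    sizes: Sequence = DEFAULT_GENE_SIZES,
    cfg: Optional[PipelineConfig] = None,
) -> ExperimentResult:
    """Run the pipeline per input-gene count; choose by mean Silhouette.

    The choice is label-free: only the internal Silhouette score of each
    setting is consulted, never ground truth.  Sizes exceeding the number
    of genes surviving the filter are skipped with a warning row.
    """
    cfg = cfg or PipelineConfig()
    rows: List[dict] = []
    for size in sizes:
        sub = replace(cfg, preprocess=replace(cfg.preprocess, n_top_genes=size))
        if size != "all" and int(size) > cm.n_genes:
            continue
        rows.extend(_repeat_runs(cm, sub, {"n_genes": size}))
    result = _result(rows, "n_genes")
    best, best_sil = None, -np.inf
    for size, agg in result.aggregates.items():
        sil = agg.get("silhouette", {}).get("mean", -np.inf)
        if sil > best_sil:
            best, best_sil = size, sil
    result.chosen = {"n_genes": best, "mean_silhouette": best_sil}
    return result


def sweep_mask_ratio(
    cm: CountMatrix,
    ratios: Sequence[float] = DEFAULT_MASK_RATIOS,
    cfg: Optional[PipelineConfig] = None,
) -> ExperimentResult:
    """Run the pipeline per gene-masking ratio and tabulate the scores."""
    cfg = cfg or PipelineConfig()
    rows: List[dict] = []
    for p in ratios:
        sub = replace(cfg, augment=replace(cfg.augment, mask_ratio=float(p)))
        rows.extend(_repeat_runs(cm, sub, {"mask_ratio": float(p)}))
    return _result(rows, "mask_ratio")


def sweep_architecture(
    cm: CountMatrix,
    grid: Sequence[Sequence[int]],
    cfg: Optional[PipelineConfig] = None,
) -> ExperimentResult:
    """Run the pipeline per encoder architecture; record parameter counts."""
    cfg = cfg or PipelineConfig()
    rows: List[dict] = []
    for arch in grid:
        sub = replace(cfg, layer_sizes=list(arch))
        n_top = cfg.preprocess.n_top_genes
        input_dim = cm.n_genes if n_top == "all" else min(int(n_top), cm.n_genes)
        try:
            n_params = count_parameters(
                EncoderConfig(
                    input_dim=input_dim,
                    layer_sizes=list(arch),
                    norm_after_hidden=cfg.norm_after_hidden,
                )
            )
        except Exception:
            continue  # invalid architecture: skipped
        setting = {"architecture": str(list(arch)), "n_parameters": n_params}
        rows.extend(_repeat_runs(cm, sub, setting))
    return _result(rows, "architecture")


def stability_report(
    cm: CountMatrix,
    cfg: Optional[PipelineConfig] = None,
    fractions: Sequence[float] = DOWNSAMPLE_FRACTIONS,
) -> ExperimentResult:
    """Multi-seed stability plus the stratified-downsampling arm.

    The full dataset is run ``n_runs`` times to report per-score
    coefficients of variation; each downsampling fraction is then run
    ``n_runs`` times on fresh stratified subsets.
    """
    from .simulate import stratified_downsample

    cfg = cfg or PipelineConfig()
    if cfg.n_runs < 2:
        raise ValueError("stability analysis needs n_runs >= 2")
    rows: List[dict] = []
    for frac in fractions:
        for run in range(cfg.n_runs):
            seed = cfg.train.seed + run
            sub_cm = (
                cm
                if frac == 1.0
                else stratified_downsample(cm, frac, seed=seed)
            )
            emb, part, report = run_pipeline(sub_cm, cfg.with_seed(seed))
            row = {"fraction": frac, "seed": seed, "n_cells": sub_cm.n_cells}
            if report is not None:
                row.update(report.as_dict())
            rows.append(row)
    return _result(rows, "fraction")
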