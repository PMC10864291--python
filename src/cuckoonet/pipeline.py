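"""End-to-end pipeline: normalize -> gene selection -> weighted CNN -> metrics.

One global seed deterministically derives independent per-stage seeds (via a
hash of seed and stage name, kept below 2**31), so any stage can be re-run in
isolation and the whole run is bit-reproducible. Fitness for the wrapper
selection is computed on an inner stratified split of the training data, so
the held-out test set never influences gene selection.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import wcnn as wcnn_mod
from .cuckoo import CSParams, SelectionResult, icso_select
from .datasets import ExpressionDataset, read_expression, stratified_kfold, stratified_split
from .errors import ValidationError
from .metrics import MetricsReport, RocCurve, aggregate_folds, roc_points
from .preprocess import zscore_fit, zscore_apply
from .wcnn import WCNNConfig, WCNNModel

__all__ = ["RunConfig", "PipelineResult", "derive_seed", "run_pipeline", "crossval_pipeline"]

log = logging.getLogger("cuckoonet")

INNER_VAL_FRACTION = 0.7  # inner train/val split for wrapper fitness


def derive_seed(master: int, label: str) -> int:
    """Stable per-stage seed: sha256 of "master:label", reduced below 2**31."""
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; mirrors the YAML/JSON config layout."""

    matrix: str | None = None
    labels: str | None = None
    orientation: str = "genes_as_rows"
    delimiter: str | None = None
    output_dir: str = "cuckoonet_out"
    train_fraction: float = 0.7
    k: int = 5
    seed: int = 0
    with_selection: bool = True
    selection: CSParams = field(default_factory=CSParams)
    wcnn: WCNNConfig = field(default_factory=WCNNConfig)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        sel = d.pop("selection", {})
        net = d.pop("wcnn", {})
        cfg = cls(**d)
        cfg.selection = sel if isinstance(sel, CSParams) else CSParams.from_dict(sel)
        cfg.wcnn = net if isinstance(net, WCNNConfig) else WCNNConfig.from_dict(net)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValidationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(payload)

    def load_dataset(self) -> ExpressionDataset:
        if self.matrix is None or self.labels is None:
            raise ValidationError("config must name matrix and labels paths")
        return read_expression(
            self.matrix, self.orientation, self.labels, self.delimiter
        )


@dataclass
class PipelineResult:
    """Everything a single train/evaluate run produces."""

    report: MetricsReport
    roc: RocCurve
    selection: SelectionResult | None
    model: WCNNModel
    n_genes_used: int

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_json(out / "report.json")
        self.roc.to_tsv(out / "roc.tsv")
        self.model.to_json(out / "model.json")
        if self.selection is not None:
            self.selection.save(out / "selected_genes.txt", out / "selection_report.json")


def _ensure_min_genes(selection: SelectionResult, n_genes: int) -> np.ndarray:
    """Top up the selected mask to the CNN's minimum gene count if needed.

    The conv/pool stack needs at least 169 genes (13x13 grid). If selection
    pruned below that, unselected genes are added back in order of the best
    nest's continuous position — the search's own per-gene confidence — which
    keeps the guard deterministic and selection-driven.
    """
    mask = selection.best_mask.astype(bool).copy()
    deficit = wcnn_mod.MIN_GENES - int(mask.sum())
    if deficit <= 0 or n_genes < wcnn_mod.MIN_GENES:
        return mask
    position = (
        selection.best_position
        if selection.best_position is not None
        else np.zeros(n_genes)
    )
    candidates = np.flatnonzero(~mask)
    order = candidates[np.argsort(-position[candidates], kind="stable")]
    mask[order[:deficit]] = True
    log.info("topped selection up to %d genes for the conv stack", int(mask.sum()))
    return mask


def _fit_and_score(
    train_ds: ExpressionDataset,
    test_ds: ExpressionDataset,
    config: RunConfig,
    stage_seed: int,
) -> PipelineResult:
    """Normalize, optionally select genes, train the CNN, score the test set."""
    stats = zscore_fit(train_ds)
    train_n = zscore_apply(train_ds, stats)
    test_n = zscore_apply(test_ds, stats)

    selection = None
    if config.with_selection:
        inner_seed = derive_seed(stage_seed, "inner-split")
        fit_ds, val_ds = stratified_split(train_n, INNER_VAL_FRACTION, inner_seed)
        params = CSParams(**{**config.selection.to_dict(), "seed": derive_seed(stage_seed, "icso")})
        selection = icso_select(fit_ds, val_ds, params)
        log.info(
            "selection: %d/%d genes, fitness %.4f",
            int(selection.best_mask.sum()), train_n.n_genes, selection.best_fitness,
        )
        mask = _ensure_min_genes(selection, train_n.n_genes)
        train_n = train_n.subset_genes(mask)
        test_n = test_n.subset_genes(mask)

    net_cfg = WCNNConfig.from_dict({**config.wcnn.to_dict(), "seed": derive_seed(stage_seed, "wcnn")})
    model = wcnn_mod.train(train_n, net_cfg)
    preds, scores = wcnn_mod.predict(model, test_n)
    report = MetricsReport.from_predictions(test_n.labels, preds)
    roc = roc_points(scores[:, 1], test_n.labels)
    log.info("evaluation: accuracy %.2f%%, AUC %.3f", report.accuracy, roc.auc)
    return PipelineResult(
        report=report, roc=roc, selection=selection, model=model,
        n_genes_used=train_n.n_genes,
    )


def run_pipeline(ds: ExpressionDataset, config: RunConfig) -> PipelineResult:
    """Single stratified train/test run (the 70/30 protocol by default)."""
    ds.validate(require_two_classes=True)
    split_seed = derive_seed(config.seed, "split")
    train_ds, test_ds = stratified_split(ds, config.train_fraction, split_seed)
    log.info(
        "split: %d train / %d test samples, %d genes",
        train_ds.n_samples, test_ds.n_samples, ds.n_genes,
    )
    return _fit_and_score(train_ds, test_ds, config, derive_seed(config.seed, "fit"))


def crossval_pipeline(
    ds: ExpressionDataset, config: RunConfig
) -> tuple[list[PipelineResult], MetricsReport]:
    """Stratified k-fold protocol; returns per-fold results and their mean report."""
    ds.validate(require_two_classes=True)
    folds = stratified_kfold(ds, config.k, derive_seed(config.seed, "kfold"))
    results = []
    for f, (train_ds, test_ds) in enumerate(folds.iter_folds(ds)):
        log.info("fold %d/%d", f + 1, config.k)
        results.append(
            _fit_and_score(train_ds, test_ds, config, derive_seed(config.seed, f"fold{f}"))
        )
    mean_report = aggregate_folds([r.report for r in results])
    return results, mean_report
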