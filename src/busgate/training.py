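"""The cross-validated training protocol.

k-fold cross-validation (default 10): the dataset is partitioned into k
folds by a seeded shuffle; each rotation trains on k-1 folds with Adam
(initial learning rate 0.001) and validates on the held-out fold; the
epoch checkpoint with the highest validation generalized DSC becomes that
fold's final model; metrics are reported as mean +/- SD across the k
rotations. Three training variants mirror the ablation design: ``full``
(two-branch gated network, all images), ``model2`` (classification branch
deleted, all images — lesion-free images still contribute a segmentation
loss against the empty mask), and ``model2_pos`` (branch deleted and
lesion-free images removed from the training side of every rotation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import FoldSplit, Manifest, make_folds, samples_to_arrays
from .estimators import GatedDenseNetSegmenter
from .metrics import (aggregate_report, area_metrics, classification_metrics)

__all__ = ["TrainConfig", "FoldResult", "TrainResult", "train_fold",
           "cross_validate", "train_variant", "VARIANTS"]

VARIANTS = ("full", "model2", "model2_pos")


@dataclass(frozen=True)
class TrainConfig:
    """Protocol hyperparameters (the architecture lives in the estimator)."""

    k_folds: int = 10
    learning_rate: float = 0.001
    epochs: int = 15
    batch_size: int = 8
    seed: int = 0
    select_metric: str = "generalized_dsc"
    grouping: str = "image"
    image_size: int = 64
    flip_probability: float = 0.5

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.select_metric != "generalized_dsc":
            raise ValueError("only generalized_dsc selection is supported")


@dataclass
class FoldResult:
    fold: int
    estimator: GatedDenseNetSegmenter
    history: list[dict]
    best_epoch: int
    best_val_dsc: float
    val_metrics: dict[str, float | None]


@dataclass
class TrainResult:
    folds: list[FoldResult]
    aggregate: pd.DataFrame    # metric -> mean, sd across folds
    split: FoldSplit | None = None

    def save(self, out_dir) -> Path:
        """JSON-lines history per fold + a CSV summary table."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fr in self.folds:
            with open(out_dir / f"fold{fr.fold}_history.jsonl", "w") as fh:
                for rec in fr.history:
                    fh.write(json.dumps(rec) + "\n")
        self.aggregate.to_csv(out_dir / "summary.csv")
        return out_dir


def _make_estimator(variant: str, config: TrainConfig, seed: int,
                    **estimator_kwargs) -> GatedDenseNetSegmenter:
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected {VARIANTS}")
    return GatedDenseNetSegmenter(
        image_size=config.image_size,
        learning_rate=config.learning_rate, epochs=config.epochs,
        batch_size=config.batch_size,
        flip_probability=config.flip_probability,
        gate=(variant == "full"),
        positives_only=(variant == "model2_pos"),
        random_state=seed, **estimator_kwargs)


def _fold_val_metrics(est: GatedDenseNetSegmenter, X_val, y_val) -> dict:
    preds = est.predict_full(X_val)
    labels = y_val.any(axis=(1, 2)).astype(int)
    per_img = [area_metrics(p.mask, t) for p, t in zip(preds, y_val)]
    out = {"dsc": float(np.mean([m.dsc for m in per_img]))}
    tprs = [m.tpr for m in per_img if m.tpr is not None]
    out["tpr"] = float(np.mean(tprs)) if tprs else None
    if est.gate and labels.min() != labels.max():
        scores = np.array([p.p_abnormal for p in preds])
        out["auc"] = classification_metrics(scores, labels).auc
    else:
        out["auc"] = None
    return out


def train_fold(train_samples, val_samples, config: TrainConfig,
               variant: str = "full",
               **estimator_kwargs) -> FoldResult:
    """Train one rotation; checkpoint = argmax of validation DSC."""
    config.validate()
    if len(val_samples) == 0 or len(train_samples) == 0:
        raise ValueError("train and validation sets must be non-empty")
    train_ids = {id(s) for s in train_samples}
    if any(id(s) in train_ids for s in val_samples):
        raise ValueError("train and validation sets must be disjoint")
    X_tr, y_tr = samples_to_arrays(train_samples, config.image_size)
    X_va, y_va = samples_to_arrays(val_samples, config.image_size)
    est = _make_estimator(variant, config, config.seed, **estimator_kwargs)
    est.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)
    return FoldResult(fold=-1, estimator=est, history=est.history_,
                      best_epoch=est.best_epoch_,
                      best_val_dsc=est.best_val_dsc_,
                      val_metrics=_fold_val_metrics(est, X_va, y_va))


def cross_validate(manifest: Manifest, config: TrainConfig,
                   variant: str = "full",
                   **estimator_kwargs) -> TrainResult:
    """Run all k rotations and aggregate fold metrics as mean +/- SD."""
    config.validate()
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected {VARIANTS}")
    if len(manifest) < config.k_folds:
        raise ValueError(
            f"manifest has {len(manifest)} records < k={config.k_folds}")
    split = make_folds(manifest, config.k_folds, config.seed,
                       grouping=config.grouping)
    folds: list[FoldResult] = []
    for fold in range(config.k_folds):
        train_idx, val_idx = split.fold_indices(fold)
        try:
            fr = train_fold([manifest.records[i] for i in train_idx],
                            [manifest.records[i] for i in val_idx],
                            config, variant, **estimator_kwargs)
        except Exception as err:
            raise RuntimeError(f"fold {fold} failed: {err}") from err
        fr.fold = fold
        folds.append(fr)
    rows = [fr.val_metrics for fr in folds]
    report = aggregate_report(rows, fold_ids=list(range(len(folds))))
    return TrainResult(folds=folds, aggregate=report.aggregate, split=split)


def train_variant(manifest: Manifest, variant: str, config: TrainConfig,
                  **estimator_kwargs) -> TrainResult:
    """Cross-validate one ablation variant.

    model2_pos filters lesion-free images out of the training side of
    each rotation (the validation fold keeps them: the generalized DSC is
    defined there and exposes false positives on normal images).
    """
    if variant == "model2_pos" and \
            not any(r.label == "abnormal" for r in manifest.records):
        raise ValueError("model2_pos requires >= 1 abnormal image")
    return cross_validate(manifest, config, variant, **estimator_kwargs)
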