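"""Desk-scale experimental designs: the ablation and the screening sweep.

The ablation trains the gated network and its two gate-free baselines on
a common training set and evaluates all three on one shared test set,
reporting the all-images generalized DSC next to positive-only metrics.
This makes the characteristic failure of tumor-only training visible by
construction: a model trained without lesion-free images keeps good
positive-image metrics but collapses on the generalized DSC of normal
images, because every spurious region drives DSC = 1/(1+|Ar|) toward 0,
while the gated model scores a perfect 1 there by predicting empty.

The screening simulation runs gated inference frame by frame over an
ordered sweep sequence (no temporal smoothing — each frame is segmented
individually) and counts false-positive frames among lesion-free frames
and detection sensitivity among lesion frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .dataio import Manifest, samples_to_arrays
from .estimators import GatedDenseNetSegmenter
from .metrics import (MetricsReport, aggregate_report, area_metrics,
                      boundary_metrics, classification_metrics)
from .model import Prediction
from .phantom import SegSample
from .training import TrainConfig, VARIANTS, _make_estimator

__all__ = ["AblationResult", "ScreeningResult", "run_ablation",
           "simulate_screening", "evaluate_on_test", "write_overlay",
           "read_overlay_masks"]


@dataclass
class AblationResult:
    reports: dict[str, MetricsReport]       # variant -> per-image metrics
    classification: dict[str, dict]         # variant -> cls metric dict
    table: pd.DataFrame                     # variant x metric summary
    strata: dict[str, int]                  # test-set composition

    def save(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / "ablation_table.csv")
        return out_dir


@dataclass
class ScreeningResult:
    predictions: list[Prediction]
    false_positive_frames: int      # lesion-free frames with nonempty mask
    n_normal_frames: int
    sensitivity_frames: float | None  # lesion frames hit (mask overlaps truth)
    n_abnormal_frames: int


def evaluate_on_test(est: GatedDenseNetSegmenter, X_test: np.ndarray,
                     y_test: np.ndarray) -> tuple[MetricsReport, dict]:
    """Per-image area+boundary metrics and image-level classification."""
    preds = est.predict_full(X_test)
    labels = y_test.any(axis=(1, 2)).astype(int)
    rows = []
    for p, t in zip(preds, y_test):
        am = area_metrics(p.mask, t)
        bm = boundary_metrics(p.mask, t)
        rows.append({**am.as_dict(), **bm.as_dict(),
                     "normal": int(not t.any())})
    report = aggregate_report(rows)
    # image-level classification from the gate probability (the baseline
    # has no classification branch: score by predicted-mask emptiness)
    if est.gate:
        scores = np.array([p.p_abnormal for p in preds])
    else:
        scores = np.array([float(p.mask.any()) for p in preds])
    cm = classification_metrics(scores, labels)
    cls = {"auc": cm.auc, "sensitivity": cm.sensitivity,
           "specificity": cm.specificity, "accuracy": cm.accuracy,
           "f1": cm.f1}
    return report, cls


def run_ablation(train_manifest: Manifest, test_manifest: Manifest,
                 config: TrainConfig, holdout_fraction: float = 0.15,
                 variants: tuple = VARIANTS,
                 **estimator_kwargs) -> AblationResult:
    """Train each variant on the same data; evaluate on the shared test set.

    A seeded holdout split of the training manifest provides the
    validation fold used for epoch selection (the protocol's best-DSC
    checkpoint rule) so that the test set is never touched in training.
    """
    test_labels = [r.label for r in test_manifest.records]
    if "abnormal" not in test_labels:
        raise ValueError("test manifest needs at least one abnormal image")
    X_test, y_test = samples_to_arrays(test_manifest.records,
                                       config.image_size)
    rng = np.random.default_rng(config.seed)
    n = len(train_manifest)
    order = rng.permutation(n)
    n_hold = max(int(round(holdout_fraction * n)), 1)
    val_idx, tr_idx = order[:n_hold], order[n_hold:]
    X_tr, y_tr = samples_to_arrays(
        [train_manifest.records[i] for i in tr_idx], config.image_size)
    X_va, y_va = samples_to_arrays(
        [train_manifest.records[i] for i in val_idx], config.image_size)

    reports: dict[str, MetricsReport] = {}
    classification: dict[str, dict] = {}
    rows = []
    for variant in variants:
        est = _make_estimator(variant, config, config.seed,
                              **estimator_kwargs)
        est.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)
        report, cls = evaluate_on_test(est, X_test, y_test)
        reports[variant] = report
        classification[variant] = cls
        per = report.per_image
        normal = per["normal"] == 1
        row = {"variant": variant,
               "dsc_all": per["dsc"].mean(),
               "dsc_normal": per.loc[normal, "dsc"].mean()
               if normal.any() else np.nan,
               "dsc_abnormal": per.loc[~normal, "dsc"].mean(),
               "tpr_abnormal": per.loc[~normal, "tpr"].mean(),
               "fpr_abnormal": per.loc[~normal, "fpr"].mean(),
               "auc": cls["auc"]}
        rows.append(row)
    table = pd.DataFrame(rows).set_index("variant")
    strata = {"n_test": len(y_test),
              "n_normal": int(sum(1 for t in y_test if not t.any())),
              "n_abnormal": int(sum(1 for t in y_test if t.any()))}
    return AblationResult(reports=reports, classification=classification,
                          table=table, strata=strata)


def simulate_screening(frames: list[SegSample],
                       est: GatedDenseNetSegmenter,
                       out_dir=None) -> ScreeningResult:
    """Gated prediction frame by frame over an ordered sweep."""
    if not frames:
        raise ValueError("frames must be non-empty")
    if not hasattr(est, "network_"):
        raise ValueError("estimator is not fitted")
    X, y = samples_to_arrays(frames, est.image_size)
    preds = est.predict_full(X)
    fp = sum(1 for p, t in zip(preds, y)
             if not t.any() and p.mask.any())
    n_normal = int(sum(1 for t in y if not t.any()))
    abnormal = [(p, t) for p, t in zip(preds, y) if t.any()]
    if abnormal:
        hits = sum(1 for p, t in abnormal if (p.mask & t).any())
        sensitivity = hits / len(abnormal)
    else:
        sensitivity = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        names = []
        for i, (frame, p, t) in enumerate(zip(frames, preds, y)):
            name = f"frame_{i:04d}.png"
            write_overlay(out_dir / name, X[i], p.mask, t)
            names.append(name)
        (out_dir / "index.txt").write_text("\n".join(names) + "\n")
    return ScreeningResult(predictions=preds, false_positive_frames=fp,
                           n_normal_frames=n_normal,
                           sensitivity_frames=sensitivity,
                           n_abnormal_frames=len(abnormal))


def run_desk_benchmark(seed: int = 0, n_train: int = 200, n_test: int = 60,
                       image_size: int = 64, epochs: int = 15,
                       variants: tuple = ("full", "model2_pos"),
                       normal_fraction: float = 0.5) -> pd.DataFrame:
    """CPU-scale ablation benchmark on phantoms.

    Generates a train/test phantom split (both half lesion-free by
    default), trains the requested variants, and returns the ablation
    summary table (one row per variant: all-image and stratified
    generalized DSC, positive-image TPR/FPR, classification AUC). The
    gate's value shows up as the normal-image DSC gap between the full
    model and the tumor-only-trained baseline, at matched abnormal-image
    TPR.
    """
    from .phantom import PhantomSpec, generate_phantom

    def manifest_of(n: int, seed_: int) -> Manifest:
        spec = PhantomSpec(image_height=image_size, image_width=image_size,
                           normal_fraction=normal_fraction, seed=seed_)
        rng = spec.rng()
        return Manifest(records=[generate_phantom(spec, rng)
                                 for _ in range(n)], root=Path("."))

    train_m = manifest_of(n_train, seed)
    test_m = manifest_of(n_test, seed + 1)
    cfg = TrainConfig(seed=seed, image_size=image_size, epochs=epochs)
    result = run_ablation(train_m, test_m, cfg, variants=variants)
    return result.table


def write_overlay(path, image: np.ndarray, pred_mask: np.ndarray,
                  true_mask: np.ndarray) -> None:
    """RGB overlay: R = image, G = truth mask, B = predicted mask.

    Masks are stored exactly (0/255) in their channels, so the predicted
    mask is recoverable bit-for-bit from the blue channel.
    """
    img8 = np.clip((np.asarray(image, dtype=np.float32) + 1.0) * 127.5,
                   0, 255).astype(np.uint8)
    rgb = np.stack([img8,
                    (np.asarray(true_mask) > 0).astype(np.uint8) * 255,
                    (np.asarray(pred_mask) > 0).astype(np.uint8) * 255],
                   axis=-1)
    iio.imwrite(path, rgb)


def read_overlay_masks(path) -> tuple[np.ndarray, np.ndarray]:
    """(true_mask, pred_mask) recovered from an overlay PNG."""
    rgb = iio.imread(path)
    return ((rgb[..., 1] > 0).astype(np.uint8),
            (rgb[..., 2] > 0).astype(np.uint8))
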