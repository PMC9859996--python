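"""Segmentation and classification evaluation metrics.

Area metrics operate on the ground-truth lesion pixel set Am and the
predicted set Ar:

    DSC = (1 + 2|Am ∩ Ar|) / (1 + |Am| + |Ar|)       (generalized Dice)
    JI  = |Am ∩ Ar| / |Am ∪ Ar|
    TPR = |Am ∩ Ar| / |Am|
    FPR = (|Am ∪ Ar| - |Am|) / |Am|
    FNR = (|Am ∪ Ar| - |Ar|) / |Am|

The +1 smoothing generalizes the Dice coefficient to mass-free images:
with Am = ∅ it reduces to 1/(1 + |Ar|), so a correctly-empty prediction
scores a perfect 1 and any spurious region is penalized. JI/TPR/FPR/FNR
are undefined when |Am| = 0 and are reported as missing-with-reason,
never silently as 0. FPR follows the set formula literally and may
exceed 1.

Boundary metrics (Hausdorff error HE, mean absolute contour error MAE)
compare the contours of the two masks: a contour pixel is a foreground
pixel with at least one background 4-neighbor, the image border counting
as background. HE is the classical symmetric Hausdorff distance; MAE
pools the directed nearest-neighbor distances of both contours and
averages them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score

__all__ = ["AreaMetrics", "BoundaryMetrics", "ClassificationMetrics",
           "area_metrics", "boundary_metrics", "classification_metrics",
           "boundary_pixels", "aggregate_report", "MetricsReport"]


@dataclass(frozen=True)
class AreaMetrics:
    dsc: float
    ji: float | None
    tpr: float | None
    fpr: float | None
    fnr: float | None
    undefined_reason: str | None = None

    def as_dict(self) -> dict:
        return {"dsc": self.dsc, "ji": self.ji, "tpr": self.tpr,
                "fpr": self.fpr, "fnr": self.fnr}


@dataclass(frozen=True)
class BoundaryMetrics:
    he: float | None
    mae: float | None
    undefined_reason: str | None = None

    def as_dict(self) -> dict:
        return {"he": self.he, "mae": self.mae}


@dataclass(frozen=True)
class ClassificationMetrics:
    auc: float | None
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    undefined_reason: str | None = None


def _validate_mask_pair(pred, true):
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    for name, m in (("pred_mask", pred), ("true_mask", true)):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary 0/1")
    return pred.astype(bool), true.astype(bool)


def area_metrics(pred_mask: np.ndarray, true_mask: np.ndarray) -> AreaMetrics:
    """Generalized DSC plus JI/TPR/FPR/FNR (the latter need |Am| > 0)."""
    ar, am = _validate_mask_pair(pred_mask, true_mask)
    n_am = int(am.sum())
    n_ar = int(ar.sum())
    inter = int((am & ar).sum())
    union = n_am + n_ar - inter
    dsc = (1.0 + 2.0 * inter) / (1.0 + n_am + n_ar)
    ji = inter / union if union > 0 else None
    if n_am == 0:
        return AreaMetrics(dsc=dsc, ji=ji, tpr=None, fpr=None, fnr=None,
                           undefined_reason="empty ground-truth mask")
    return AreaMetrics(
        dsc=dsc,
        ji=ji,
        tpr=inter / n_am,
        fpr=(union - n_am) / n_am,
        fnr=(union - n_ar) / n_am,
    )


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(row, col) coordinates of foreground pixels with a background
    4-neighbor; pixels on the image border are contour pixels."""
    m = np.asarray(mask).astype(bool)
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return np.argwhere(m & ~interior)


def boundary_metrics(pred_mask: np.ndarray, true_mask: np.ndarray,
                     pixel_spacing: float = 1.0,
                     mae_mode: str = "pooled") -> BoundaryMetrics:
    """Hausdorff error and mean absolute contour error between two masks.

    mae_mode="pooled" averages the directed nearest-neighbor distances of
    both contours together; "max_directed" takes the larger of the two
    directed means.
    """
    ar, am = _validate_mask_pair(pred_mask, true_mask)
    if not ar.any() or not am.any():
        return BoundaryMetrics(he=None, mae=None,
                               undefined_reason="empty mask")
    a = boundary_pixels(ar).astype(np.float64)
    b = boundary_pixels(am).astype(np.float64)
    d_ab = cKDTree(b).query(a)[0]   # each pred-contour pixel -> nearest truth
    d_ba = cKDTree(a).query(b)[0]
    he = max(d_ab.max(), d_ba.max())
    if mae_mode == "pooled":
        mae = np.concatenate([d_ab, d_ba]).mean()
    elif mae_mode == "max_directed":
        mae = max(d_ab.mean(), d_ba.mean())
    else:
        raise ValueError(f"unknown mae_mode {mae_mode!r}")
    return BoundaryMetrics(he=float(he) * pixel_spacing,
                           mae=float(mae) * pixel_spacing)


def classification_metrics(scores, labels, threshold: float = 0.5
                           ) -> ClassificationMetrics:
    """AUC (rank statistic) and thresholded confusion-matrix summaries.

    `labels`: 1 = abnormal (positive class), 0 = normal.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = (scores >= threshold).astype(int)
    cm = confusion_matrix(labels, pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    acc = (tp + tn) / len(labels)
    f1 = f1_score(labels, pred, zero_division=0.0)
    if labels.min() == labels.max():
        return ClassificationMetrics(
            auc=None, sensitivity=sens, specificity=spec, accuracy=acc,
            f1=float(f1), undefined_reason="single-class labels")
    auc = float(roc_auc_score(labels, scores))
    return ClassificationMetrics(auc=auc, sensitivity=float(sens),
                                 specificity=float(spec), accuracy=float(acc),
                                 f1=float(f1))


@dataclass
class MetricsReport:
    """Per-image metric table plus fold-wise mean ± SD aggregation."""

    per_image: pd.DataFrame
    aggregate: pd.DataFrame          # index: metric; columns: mean, sd
    excluded_counts: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "per_image": self.per_image.to_dict(orient="records"),
            "aggregate": {m: {"mean": float(r["mean"]), "sd": float(r["sd"])}
                          for m, r in self.aggregate.iterrows()},
            "excluded_counts": self.excluded_counts,
        }


def aggregate_report(per_image: list[dict], fold_ids=None) -> MetricsReport:
    """Fold means, then cross-fold mean and SD per metric.

    `per_image`: one dict of metric values per image (None = undefined;
    excluded from averages, with exclusion counts reported). With no
    fold_ids all images form a single fold (SD over one value is 0).
    """
    if not per_image:
        raise ValueError("no per-image metrics to aggregate")
    df = pd.DataFrame(per_image).astype(float)
    if fold_ids is None:
        fold_ids = np.zeros(len(df), dtype=int)
    df = df.assign(_fold=np.asarray(fold_ids))
    excluded = {c: int(df[c].isna().sum()) for c in df.columns
                if c != "_fold"}
    fold_means = df.groupby("_fold").mean()
    agg = pd.DataFrame({
        "mean": fold_means.mean(axis=0),
        "sd": fold_means.std(axis=0, ddof=0).fillna(0.0),
    })
    return MetricsReport(per_image=df.drop(columns="_fold"),
                         aggregate=agg, excluded_counts=excluded)
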