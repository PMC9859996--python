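"""Scikit-learn style estimator for gated lesion segmentation.

`GatedDenseNetSegmenter` wraps the two-branch dense encoder-decoder
network in the familiar fit/predict surface: `fit(X, y)` takes a stack of
preprocessed grayscale images and their binary lesion masks (the
image-level normal/abnormal label is implied by mask emptiness), trains
with Adam on the multi-task BCE + Dice loss, and — when a validation set
is supplied — retains the epoch checkpoint with the highest validation
generalized DSC. `predict` returns post-gate binary masks;
`predict_proba` returns image-level [P(normal), P(abnormal)] columns;
`score` is the mean generalized DSC, the headline metric that is defined
on lesion-free images too.

Setting ``gate=False`` yields the ablation baseline (same encoder and
decoder, classification branch deleted, never gates);
``positives_only=True`` additionally drops lesion-free images from the
training set — the common tumor-only training regime whose false-positive
behaviour on normal images the gate is designed to fix.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator

from .losses import LossConfig, total_loss
from .metrics import area_metrics
from .model import (GatedDenseUNet, NetworkConfig, Prediction, build_baseline,
                    build_network, predict as _predict)
from .nn import Adam

__all__ = ["GatedDenseNetSegmenter"]


class GatedDenseNetSegmenter(BaseEstimator):
    """Classification-gated dense U-shaped segmentation network.

    Parameters
    ----------
    image_size : int
        Side length of the (square) input images; multiple of 8.
    growth_rate, initial_channels, bottleneck_factor : int
        Width knobs of the dense blocks (channels added per conv block,
        stem output channels, 1x1 bottleneck width factor).
    encoder_block_sizes, decoder_block_sizes : tuple of int
        Conv blocks per dense block; defaults are the reference
        configuration (3, 4, 8, 12) / (8, 4, 3).
    gate : bool
        True: include the classification branch and gate predictions.
        False: gate-free segmentation baseline.
    positives_only : bool
        Drop lesion-free images from the training set (tumor-only
        training regime). Requires at least one abnormal training image.
    cls_threshold, seg_threshold : float
        Gate operating point and pixel binarization threshold.
    learning_rate, epochs, batch_size : training protocol (Adam).
    cls_weight, apply_seg_loss_to_normals : loss policy.
    flip_probability : float
        Chance of a horizontal flip per training sample per epoch.
    random_state : int
        Seeds weight init, shuffling and augmentation.

    Attributes
    ----------
    network_ : the trained network.
    history_ : list of per-epoch dicts (loss components, validation DSC).
    best_epoch_, best_val_dsc_ : checkpoint-selection outcome (when a
        validation set was given).
    classes_ : [0, 1] (normal, abnormal).
    """

    def __init__(self, image_size: int = 64, growth_rate: int = 6,
                 initial_channels: int = 12, bottleneck_factor: int = 2,
                 encoder_block_sizes: tuple = (3, 4, 8, 12),
                 decoder_block_sizes: tuple = (8, 4, 3),
                 upsample_mode: str = "bilinear", gate: bool = True,
                 positives_only: bool = False, cls_threshold: float = 0.5,
                 seg_threshold: float = 0.5, learning_rate: float = 1e-3,
                 epochs: int = 15, batch_size: int = 8,
                 cls_weight: float = 1.0,
                 apply_seg_loss_to_normals: bool = True,
                 flip_probability: float = 0.5, random_state: int = 0):
        self.image_size = image_size
        self.growth_rate = growth_rate
        self.initial_channels = initial_channels
        self.bottleneck_factor = bottleneck_factor
        self.encoder_block_sizes = encoder_block_sizes
        self.decoder_block_sizes = decoder_block_sizes
        self.upsample_mode = upsample_mode
        self.gate = gate
        self.positives_only = positives_only
        self.cls_threshold = cls_threshold
        self.seg_threshold = seg_threshold
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.cls_weight = cls_weight
        self.apply_seg_loss_to_normals = apply_seg_loss_to_normals
        self.flip_probability = flip_probability
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _network_config(self, seed: int) -> NetworkConfig:
        return NetworkConfig(
            input_size=self.image_size, growth_rate=self.growth_rate,
            initial_channels=self.initial_channels,
            bottleneck_factor=self.bottleneck_factor,
            encoder_block_sizes=tuple(self.encoder_block_sizes),
            decoder_block_sizes=tuple(self.decoder_block_sizes),
            upsample_mode=self.upsample_mode,
            cls_threshold=self.cls_threshold,
            seg_threshold=self.seg_threshold, seed=seed)

    def _loss_config(self) -> LossConfig:
        return LossConfig(
            cls_weight=self.cls_weight,
            apply_seg_loss_to_normals=self.apply_seg_loss_to_normals)

    @staticmethod
    def _validate_xy(X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(f"X must be (n, S, S); got {X.shape}")
        if y.shape != X.shape:
            raise ValueError("y must be binary masks with X's shape")
        if not np.isin(np.unique(y), (0, 1)).all():
            raise ValueError("y masks must be binary 0/1")
        return X, y.astype(np.uint8)

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on images X (n, S, S) with binary masks y (n, S, S).

        When (X_val, y_val) are given, the epoch with the highest mean
        validation generalized DSC (gated inference) is retained as the
        fitted network.
        """
        X, y = self._validate_xy(X, y)
        if X.shape[1] != self.image_size:
            raise ValueError(
                f"images are {X.shape[1]}px but image_size={self.image_size}")
        labels = y.any(axis=(1, 2)).astype(np.int64)
        if self.positives_only:
            if not labels.any():
                raise ValueError(
                    "positives_only requires at least one abnormal image")
            keep = labels.astype(bool)
            X, y, labels = X[keep], y[keep], labels[keep]
        if X_val is not None:
            X_val, y_val = self._validate_xy(X_val, y_val)
            if len(X_val) == 0:
                raise ValueError("validation set must be non-empty")

        seeds = np.random.SeedSequence(self.random_state).generate_state(3)
        net_cfg = self._network_config(int(seeds[0]) % (2 ** 31))
        loss_cfg = self._loss_config()
        net = build_network(net_cfg) if self.gate else \
            build_baseline(net_cfg)
        opt = Adam(net.parameters(), lr=self.learning_rate)
        shuffle_rng = np.random.default_rng(seeds[1])
        flip_rng = np.random.default_rng(seeds[2])

        n = len(X)
        self.history_ = []
        best_state, best_dsc, best_epoch = None, -np.inf, -1
        for epoch in range(self.epochs):
            net.train()
            order = shuffle_rng.permutation(n)
            sums: dict[str, float] = {}
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                flips = flip_rng.uniform(size=len(idx)) < \
                    self.flip_probability
                if flips.any():
                    xb = xb.copy()
                    yb = yb.copy()
                    xb[flips] = xb[flips, :, ::-1]
                    yb[flips] = yb[flips, :, ::-1]
                net.zero_grad()
                cls_logit, seg_logit = net.forward(xb)
                loss, comps = total_loss(cls_logit, seg_logit, labels[idx],
                                         yb, loss_cfg)
                loss.backward()
                opt.step()
                for k, v in comps.items():
                    sums[k] = sums.get(k, 0.0) + v
                n_batches += 1
            record = {"epoch": epoch,
                      **{k: v / n_batches for k, v in sums.items()}}
            if X_val is not None:
                val_dsc = self._mean_generalized_dsc(net, X_val, y_val)
                record["val_dsc"] = val_dsc
                if val_dsc > best_dsc:
                    best_dsc, best_epoch = val_dsc, epoch
                    best_state = copy.deepcopy(net.named_state())
            self.history_.append(record)

        if best_state is not None:
            net.load_state(best_state)
            self.best_epoch_ = best_epoch
            self.best_val_dsc_ = float(best_dsc)
        net.eval()
        self.network_ = net
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = self.image_size * self.image_size
        return self

    def _mean_generalized_dsc(self, net: GatedDenseUNet, X: np.ndarray,
                              y: np.ndarray) -> float:
        preds = self._batched_predict(net, X)
        return float(np.mean([area_metrics(p.mask, t).dsc
                              for p, t in zip(preds, y)]))

    def _batched_predict(self, net: GatedDenseUNet,
                         X: np.ndarray) -> list[Prediction]:
        out: list[Prediction] = []
        for start in range(0, len(X), max(self.batch_size, 1)):
            out.extend(_predict(net, X[start:start + self.batch_size]))
        return out

    # ------------------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise ValueError("estimator is not fitted; call fit first")

    def predict_full(self, X) -> list[Prediction]:
        """Gated per-image predictions (probability map, mask, gate flag)."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        return self._batched_predict(self.network_, X)

    def predict(self, X) -> np.ndarray:
        """Post-gate binary masks, shape (n, S, S)."""
        return np.stack([p.mask for p in self.predict_full(X)])

    def predict_proba(self, X) -> np.ndarray:
        """Image-level class probabilities [[P(normal), P(abnormal)], ...]."""
        p = np.array([pr.p_abnormal for pr in self.predict_full(X)])
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def score(self, X, y) -> float:
        """Mean generalized DSC over the given images."""
        self._check_fitted()
        X, y = self._validate_xy(X, y)
        return self._mean_generalized_dsc(self.network_, X, y)
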