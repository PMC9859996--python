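"""Two-branch dense encoder-decoder network with classification gating.

The segmentation branch is a U-shaped network with DenseNet-style blocks:
an encoder of four dense blocks separated by three transition-down stages
(1x1 compression conv + 2x2 max pooling) and a decoder of three dense
blocks, each preceded by a transition-up stage (1x1 compression + 2x
upsampling) and a concatenation with the same-scale encoder skip
features; a final 1x1 convolution emits per-pixel lesion logits at input
resolution. In the reference configuration the encoder dense blocks
contain 3, 4, 8 and 12 conv blocks and the decoder blocks 8, 4 and 3.

The classification branch shares the encoder: one conv block on the last
encoder feature map, global average pooling, and a fully connected layer
produce an image-level normal/abnormal logit. At inference the branch
acts as a gate: if the abnormality probability falls below
``cls_threshold`` the predicted mask is forced empty, which is what
suppresses false-positive segmentations on lesion-free images. (The
decoder is still executed and its output discarded — branch-free
batching; the gate is honored at the output contract.)
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import BatchNorm2d, Conv2d, ConvBlock, Linear, Module

__all__ = ["NetworkConfig", "Prediction", "GatedDenseUNet", "build_network",
           "build_baseline", "predict", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    The block counts are the reference configuration; growth_rate and
    initial_channels are width knobs (the field's convention: each conv
    block adds growth_rate channels; the stem emits initial_channels).
    cls_threshold is the gate's operating point on the abnormality
    probability; seg_threshold binarizes the per-pixel probability map.
    """

    input_size: int = 256
    encoder_block_sizes: tuple[int, ...] = (3, 4, 8, 12)
    decoder_block_sizes: tuple[int, ...] = (8, 4, 3)
    growth_rate: int = 16
    initial_channels: int = 32
    bottleneck_factor: int = 4
    upsample_mode: str = "bilinear"
    cls_threshold: float = 0.5
    seg_threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.input_size % 8 != 0 or self.input_size < 8:
            raise ValueError(
                "input_size must be a positive multiple of 8 (three 2x "
                "pooling stages)")
        if len(self.encoder_block_sizes) != 4:
            raise ValueError("encoder needs exactly 4 dense blocks")
        if len(self.decoder_block_sizes) != 3:
            raise ValueError("decoder needs exactly 3 dense blocks")
        if any(m < 1 for m in self.encoder_block_sizes +
               self.decoder_block_sizes):
            raise ValueError("dense blocks need at least one conv block")
        if self.growth_rate < 1 or self.initial_channels < 1:
            raise ValueError("growth_rate/initial_channels must be positive")
        if self.bottleneck_factor < 1:
            raise ValueError("bottleneck_factor must be positive")
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ValueError("upsample_mode must be 'bilinear' or 'nearest'")
        for name in ("cls_threshold", "seg_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["encoder_block_sizes"] = list(self.encoder_block_sizes)
        d["decoder_block_sizes"] = list(self.decoder_block_sizes)
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkConfig":
        d = yaml.safe_load(text)
        d["encoder_block_sizes"] = tuple(d["encoder_block_sizes"])
        d["decoder_block_sizes"] = tuple(d["decoder_block_sizes"])
        return cls(**d)


@dataclass
class Prediction:
    """Gated inference output for a single image."""

    p_abnormal: float
    prob_map: np.ndarray       # (H, W) per-pixel probabilities
    mask: np.ndarray           # (H, W) binary, post-gate
    gated: bool

    def __post_init__(self):
        if not 0.0 <= self.p_abnormal <= 1.0:
            raise ValueError("p_abnormal must be a probability")
        if self.gated and self.mask.any():
            raise ValueError("gated prediction must have an empty mask")


class DenseBlock(Module):
    """m densely connected conv blocks; output C_in + m * growth channels."""

    def __init__(self, in_channels: int, n_blocks: int, growth_rate: int,
                 rng: np.random.Generator, bottleneck_factor: int = 4):
        super().__init__()
        self.blocks = []
        c = in_channels
        for _ in range(n_blocks):
            self.blocks.append(
                ConvBlock(c, growth_rate, rng, bottleneck_factor))
            c += growth_rate
        self.in_channels = in_channels
        self.out_channels = c

    def __call__(self, x: Tensor) -> Tensor:
        feats = x
        for blk in self.blocks:
            new = blk(feats)
            feats = ag.concat([feats, new], axis=-1)
        return feats


class TransitionDown(Module):
    """1x1 compression convolution (factor 0.5) + 2x2 max pooling."""

    def __init__(self, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.out_channels = max(in_channels // 2, 1)
        self.bn = BatchNorm2d(in_channels)
        self.conv = Conv2d(in_channels, self.out_channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.maxpool2x2(self.conv(ag.relu(self.bn(x))))


class TransitionUp(Module):
    """1x1 compression convolution (factor 0.5) + 2x spatial upsampling."""

    def __init__(self, in_channels: int, rng: np.random.Generator,
                 mode: str = "bilinear"):
        super().__init__()
        self.out_channels = max(in_channels // 2, 1)
        self.conv = Conv2d(in_channels, self.out_channels, 1, rng)
        self.mode = mode

    def __call__(self, x: Tensor) -> Tensor:
        return ag.upsample2x(self.conv(x), self.mode)


class ClassificationHead(Module):
    """Conv block -> global average pooling -> fully connected logit."""

    def __init__(self, in_channels: int, growth_rate: int,
                 rng: np.random.Generator, bottleneck_factor: int = 4):
        super().__init__()
        self.block = ConvBlock(in_channels, growth_rate, rng,
                               bottleneck_factor)
        self.fc = Linear(growth_rate, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.block(x)
        pooled = ag.tmean(h, axis=(1, 2))      # (N, C)
        return ag.reshape(self.fc(pooled), (-1,))


class GatedDenseUNet(Module):
    """The full two-branch network (set include_classifier=False for the
    gate-free segmentation baseline)."""

    def __init__(self, config: NetworkConfig, include_classifier: bool = True):
        super().__init__()
        config.validate()
        self.config = config
        self.include_classifier = include_classifier
        rng = np.random.default_rng(config.seed)
        g = config.growth_rate
        self.stem = Conv2d(1, config.initial_channels, 3, rng)
        c = config.initial_channels

        self.encoder_blocks = []
        self.transitions_down = []
        skip_channels = []
        for i, m in enumerate(config.encoder_block_sizes):
            db = DenseBlock(c, m, g, rng, config.bottleneck_factor)
            self.encoder_blocks.append(db)
            c = db.out_channels
            if i < 3:
                skip_channels.append(c)
                td = TransitionDown(c, rng)
                self.transitions_down.append(td)
                c = td.out_channels

        if include_classifier:
            self.cls_head = ClassificationHead(c, g, rng,
                                               config.bottleneck_factor)

        self.transitions_up = []
        self.decoder_blocks = []
        for i, m in enumerate(config.decoder_block_sizes):
            tu = TransitionUp(c, rng, config.upsample_mode)
            self.transitions_up.append(tu)
            c = tu.out_channels + skip_channels[2 - i]
            db = DenseBlock(c, m, g, rng, config.bottleneck_factor)
            self.decoder_blocks.append(db)
            c = db.out_channels
        self.final_bn = BatchNorm2d(c)
        self.final_conv = Conv2d(c, 1, 1, rng)

    def forward(self, x: np.ndarray | Tensor
                ) -> tuple[Tensor | None, Tensor]:
        """Batch of (N, S, S) images -> (class logits (N,) or None,
        segmentation logits (N, S, S))."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 3 or x.shape[1] != x.shape[2] or \
                x.shape[1] != self.config.input_size:
            raise ValueError(
                f"expected (N, {self.config.input_size}, "
                f"{self.config.input_size}) input, got {x.shape}")
        h = ag.reshape(x, x.shape + (1,))
        h = self.stem(h)
        skips = []
        for i, db in enumerate(self.encoder_blocks):
            h = db(h)
            if i < 3:
                skips.append(h)
                h = self.transitions_down[i](h)
        cls_logit = self.cls_head(h) if self.include_classifier else None
        for i, (tu, db) in enumerate(zip(self.transitions_up,
                                         self.decoder_blocks)):
            h = tu(h)
            h = ag.concat([h, skips[2 - i]], axis=-1)
            h = db(h)
        seg = self.final_conv(ag.relu(self.final_bn(h)))
        seg = ag.reshape(seg, seg.shape[:3])
        return cls_logit, seg

    __call__ = forward


def build_network(config: NetworkConfig) -> GatedDenseUNet:
    """The full two-branch network of the reference configuration."""
    return GatedDenseUNet(config, include_classifier=True)


def build_baseline(config: NetworkConfig,
                   variant: str = "model2") -> GatedDenseUNet:
    """Same encoder/decoder without the classification head (never gates)."""
    if variant != "model2":
        raise ValueError(f"unknown baseline variant {variant!r}")
    return GatedDenseUNet(config, include_classifier=False)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def predict(network: GatedDenseUNet, images: np.ndarray,
            config: NetworkConfig | None = None) -> list[Prediction]:
    """Gated inference on a batch of preprocessed (N, S, S) images.

    For the full network: if sigmoid(class logit) < cls_threshold, the
    mask is forced all-zero and the prediction flagged as gated. The
    baseline network never gates.
    """
    config = config or network.config
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    network.eval()
    cls_logit, seg_logit = network.forward(images)
    prob_maps = _sigmoid(seg_logit.data)
    if cls_logit is None:
        p_abn = np.ones(len(images))
    else:
        p_abn = _sigmoid(cls_logit.data)
    out = []
    for i in range(len(images)):
        gated = bool(p_abn[i] < config.cls_threshold)
        mask = np.zeros(prob_maps[i].shape, dtype=np.uint8) if gated else (
            prob_maps[i] >= config.seg_threshold).astype(np.uint8)
        out.append(Prediction(p_abnormal=float(p_abn[i]),
                              prob_map=prob_maps[i], mask=mask, gated=gated))
    return out


def save_checkpoint(network: GatedDenseUNet, path) -> Path:
    """Single-file archive of weights, buffers and the YAML config."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    state = network.named_state()
    np.savez(path, __config__=np.frombuffer(
        network.config.to_yaml().encode(), dtype=np.uint8),
        __classifier__=np.array([network.include_classifier]),
        **state)
    return path


def load_checkpoint(path) -> GatedDenseUNet:
    with np.load(path) as data:
        cfg = NetworkConfig.from_yaml(bytes(data["__config__"]).decode())
        include_cls = bool(data["__classifier__"][0])
        net = GatedDenseUNet(cfg, include_classifier=include_cls)
        net.load_state({k: data[k] for k in data.files
                        if not k.startswith("__")})
    return net
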