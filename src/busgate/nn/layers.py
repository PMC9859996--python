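"""Neural-network modules on top of the autodiff core.

Parameters are He/Glorot-initialized from an explicit numpy Generator so a
single integer seed fixes every weight in the network; there is no global
RNG state anywhere in the backend.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, batchnorm, conv2d, matmul, relu

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "ConvBlock"]


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_state(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers."""
        state: dict[str, np.ndarray] = {}

        def visit(obj, prefix):
            for k, v in obj.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Tensor) and v.requires_grad:
                    state[name] = v.data
                elif isinstance(v, np.ndarray):
                    state[name] = v
                elif isinstance(v, Module):
                    visit(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{name}.{i}.")
        visit(self, "")
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise ValueError(f"state missing keys: {sorted(missing)[:5]}...")

        def visit(obj, prefix):
            for k, v in obj.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data = np.asarray(state[name], dtype=np.float32).copy()
                elif isinstance(v, np.ndarray):
                    v[...] = state[name]
                elif isinstance(v, Module):
                    visit(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{name}.{i}.")
        visit(self, "")

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    """Stride-1 same-padding convolution, NHWC, He fan-in init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if in_channels <= 0 or out_channels <= 0:
            raise ValueError("channel counts must be positive")
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(
            0.0, std, (kernel_size, kernel_size, in_channels, out_channels)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return batchnorm(x, self.gamma, self.beta, training=self.training,
                         running_mean=self.running_mean,
                         running_var=self.running_var,
                         momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.weight = Tensor(rng.normal(0.0, std, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class ConvBlock(Module):
    """BN -> ReLU -> 1x1 conv (bottleneck) -> BN -> ReLU -> 3x3 conv.

    The DenseNet-style composite unit: the 1x1 bottleneck maps to
    ``bottleneck_factor * growth_rate`` channels and the 3x3 convolution
    emits ``growth_rate`` channels.
    """

    def __init__(self, in_channels: int, growth_rate: int,
                 rng: np.random.Generator, bottleneck_factor: int = 4):
        super().__init__()
        if growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        mid = bottleneck_factor * growth_rate
        self.bn1 = BatchNorm2d(in_channels)
        self.conv1 = Conv2d(in_channels, mid, 1, rng)
        self.bn2 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, growth_rate, 3, rng)
        self.growth_rate = growth_rate

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(relu(self.bn1(x)))
        return self.conv2(relu(self.bn2(h)))
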