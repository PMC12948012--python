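"""Layers, parameter containers and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from speckleflow.nn import autodiff as ad
from speckleflow.nn.autodiff import Tensor


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = False

    def modules(self):
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield attr
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in [self, *self.modules()]:
            for v in vars(m).values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def train(self, mode: bool = True):
        for m in [self, *self.modules()]:
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters and running statistics."""
        out = {}
        for i, m in enumerate([self, *self.modules()]):
            for name, v in vars(m).items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out[f"m{i}.{name}"] = v.data
                elif isinstance(v, np.ndarray) and name.startswith("running_"):
                    out[f"m{i}.{name}"] = v
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, m in enumerate([self, *self.modules()]):
            for name, v in vars(m).items():
                key = f"m{i}.{name}"
                if key in arrays:
                    if isinstance(v, Tensor):
                        v.data = np.ascontiguousarray(arrays[key], dtype=np.float32)
                    else:
                        v[...] = arrays[key]


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * kernel * kernel))
        self.weight = Tensor(
            rng.standard_normal((cout, cin, kernel, kernel)) * scale, requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)

    __call__ = forward

    def set_identity(self) -> None:
        """Delta-kernel identity init (requires cin == cout)."""
        w = np.zeros_like(self.weight.data)
        k = w.shape[2] // 2
        for c in range(w.shape[0]):
            w[c, c, k, k] = 1.0
        self.weight.data = w
        self.bias.data = np.zeros_like(self.bias.data)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        return ad.batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum,
        )

    __call__ = forward


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.1):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ad.leaky_relu(x, self.slope)

    __call__ = forward


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    __call__ = forward


def conv_block(cin: int, cout: int, stride: int, rng: np.random.Generator) -> Sequential:
    """Conv3x3 -> BatchNorm -> LeakyReLU, the standard encoder/decoder block."""
    return Sequential(Conv2d(cin, cout, 3, stride=stride, rng=rng), BatchNorm2d(cout), LeakyReLU())


class UpsampleLearnable(Module):
    """Nearest-neighbour x2, replicate padding, then a 3x3 convolution.

    For flow fields the caller additionally rescales values by 2 to keep
    them in the units of the finer pixel grid.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(channels, channels, 3, pad=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(ad.pad_replicate(ad.nearest_upsample2(x), 1))

    __call__ = forward


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
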