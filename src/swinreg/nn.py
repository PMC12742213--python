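"""Neural-network layers on top of the autodiff tape.

Only the layers the registration network needs: linear maps, layer
normalisation, a GELU MLP, channels-last 3-D convolution and the batch-size-1
regime of batch normalisation.  Weight initialisation is driven exclusively by
a caller-supplied :class:`numpy.random.Generator` so whole-model construction
is reproducible from a single seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._tensor import Tensor, conv3d, no_grad


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container with recursive parameter discovery."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(full + ".")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialisation ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Module):
                yield from attr.named_buffers(full + ".")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif name.startswith("running_") and isinstance(attr, np.ndarray):
                yield full, attr

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.array(value, dtype=np.float64)
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown parameter {name!r}")


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=shape if shape is not None else (fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            self.weight = Parameter(np.zeros((in_features, out_features)))
        else:
            self.weight = Parameter(xavier(rng, in_features, out_features))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


def gelu(x: Tensor) -> Tensor:
    # tanh approximation
    return 0.5 * x * (1.0 + (0.7978845608028654 * (x + 0.044715 * x * x * x)).tanh())


class MLP(Module):
    """Two-layer feed-forward block with GELU, as used inside attention blocks."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.fc1(x)))


class Conv3d(Module):
    """Channels-last 'same' 3-D convolution with optional dilation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1):
        super().__init__()
        fan_in = in_ch * kernel ** 3
        self.weight = Parameter(xavier(rng, fan_in, out_ch,
                                       shape=(kernel, kernel, kernel, in_ch, out_ch)))
        self.bias = Parameter(np.zeros(out_ch))
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, dilation=self.dilation) + self.bias


class BatchNorm(Module):
    """Per-channel normalisation over the spatial axes (batch-size-1 regime).

    During training statistics come from the current map and running estimates
    are updated; during evaluation the running estimates are used.  With a
    batch of one this coincides with what standard batch normalisation does in
    the training configuration used here.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            with no_grad():
                m = self.momentum
                self.running_mean *= (1 - m)
                self.running_mean += m * mu.data.reshape(-1)
                self.running_var *= (1 - m)
                self.running_var += m * var.data.reshape(-1)
            return xc / (var + self.eps).sqrt() * self.gamma + self.beta
        xc = x - self.running_mean
        return xc / np.sqrt(self.running_var + self.eps) * self.gamma + self.beta


def save_weights(module: Module, path) -> None:
    """Single-file checkpoint (compressed npz of the full state dict)."""
    np.savez_compressed(path, **module.state_dict())


def load_weights(module: Module, path) -> None:
    with np.load(path) as data:
        module.load_state_dict({k: data[k] for k in data.files})
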