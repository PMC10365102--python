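"""Layer/module abstraction over the autodiff tensors.

Modules own :class:`Parameter` tensors and non-trainable buffers (batch-norm
running statistics).  ``state_dict``/``load_state_dict`` give flat
name-to-array checkpoints that serialise to ``.npz``.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "Linear", "BatchNorm2d",
           "LayerNorm", "Dropout", "trunc_normal"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) truncated at two standard deviations (resampled)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out.astype(np.float32)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        params = [v for v in vars(self).values() if isinstance(v, Parameter)]
        for _, child in self._children():
            params.extend(child.parameters())
        return params

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing -----------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                state[prefix + name] = val.data
            elif isinstance(val, np.ndarray):  # buffers (running stats)
                state[prefix + name] = val
        for name, child in self._children():
            state.update(child.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                val.data = np.asarray(state[prefix + name], dtype=np.float32).reshape(val.data.shape)
            elif isinstance(val, np.ndarray):
                val[...] = state[prefix + name]
        for name, child in self._children():
            child.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 same-padded convolution; odd square kernels only."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU stacks
        self.weight = Parameter(rng.normal(0.0, scale,
                                size=(out_channels, in_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, std: float = 0.02):
        super().__init__()
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features), std))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x):
        return T.matmul(x, self.weight) + self.bias


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 zero_init: bool = False):
        super().__init__()
        self.gamma = Parameter(np.zeros(channels) if zero_init else np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return T.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training, self.momentum, self.eps)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x):
        return T.layer_norm(x, self.gamma, self.beta, self.eps)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x):
        return T.dropout(x, self.p, self.rng, self.training)
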