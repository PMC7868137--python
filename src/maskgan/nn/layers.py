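"""Neural-network layers built on the autodiff core.

Conventions follow the DCGAN/pix2pix lineage this architecture descends
from: weights drawn from N(0, 0.02), batch-norm scale from N(1, 0.02),
(N, C, H, W) activation layout.
"""

from __future__ import annotations

from typing import Dict, Iterator, Optional

import numpy as np

from .autodiff import (DTYPE, Parameter, Tensor, conv2d, conv_transpose2d,
                       sqrt, tmean)

INIT_STD = 0.02


class Module:
    """Tiny module base: tracks parameters, buffers, submodules and mode."""

    def __init__(self):
        self._params: Dict[str, Parameter] = {}
        self._buffers: Dict[str, np.ndarray] = {}
        self._modules: Dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_module(self, name: str, module: "Module"):
        self._modules[name] = module
        object.__setattr__(self, name, module)

    def parameters(self) -> Iterator[Parameter]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # ---- (de)serialization ------------------------------------------
    def state_dict(self, prefix: str = "") -> Dict[str, np.ndarray]:
        out = {prefix + k: p.data for k, p in self._params.items()}
        out.update({prefix + k: v for k, v in self._buffers.items()})
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray], prefix: str = ""):
        for k, p in self._params.items():
            p.data = np.asarray(state[prefix + k], dtype=DTYPE)
        for k in list(self._buffers):
            self._buffers[k] = np.asarray(state[prefix + k], dtype=DTYPE)
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, dilation: int = 1,
                 rng: Optional[np.random.Generator] = None, bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.weight = Parameter(rng.normal(0.0, INIT_STD,
                                           (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 2,
                 padding: int = 1, rng: Optional[np.random.Generator] = None,
                 bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(rng.normal(0.0, INIT_STD,
                                           (in_ch, out_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias,
                                stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel standardization over (N, H, W).

    With batch size 1 the batch statistics are per-sample statistics, so
    this layer behaves like instance normalization during training.
    Evaluation mode normalizes with the current input's statistics as well
    (the pix2pix test-time convention) — still fully deterministic for a
    fixed input.  Exponential running averages are tracked and can be used
    at evaluation instead (``eval_uses_batch_stats=False``), but at a 1x1
    spatial bottleneck the batch variance is identically zero, the running
    variance collapses, and eval-time division by sqrt(eps) amplifies any
    parameter drift ~300x, so batch statistics are the default.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 rng: Optional[np.random.Generator] = None,
                 eval_uses_batch_stats: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.eps, self.momentum = eps, momentum
        self.eval_uses_batch_stats = eval_uses_batch_stats
        self.gamma = Parameter(rng.normal(1.0, INIT_STD, channels))
        self.beta = Parameter(np.zeros(channels))
        self._buffers["running_mean"] = np.zeros(channels, dtype=DTYPE)
        self._buffers["running_var"] = np.ones(channels, dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        gamma = self.gamma.reshape((1, c, 1, 1))
        beta = self.beta.reshape((1, c, 1, 1))
        if self.training or self.eval_uses_batch_stats:
            mu = tmean(x, axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = tmean(xc * xc, axis=(0, 2, 3), keepdims=True)
            if self.training:
                m = self.momentum
                self._buffers["running_mean"] = (
                    (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel())
                self._buffers["running_var"] = (
                    (1 - m) * self._buffers["running_var"] + m * var.data.ravel())
            return xc / sqrt(var + Tensor(self.eps)) * gamma + beta
        rm = Tensor(self._buffers["running_mean"].reshape(1, c, 1, 1))
        rv = Tensor(self._buffers["running_var"].reshape(1, c, 1, 1))
        denom = np.sqrt(rv.data + self.eps)
        return (x - rm) / Tensor(denom) * gamma + beta


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode.

    The mask generator is injected per call so the training loop owns all
    randomness (seed determinism).
    """

    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p

    def __call__(self, x: Tensor, rng: Optional[np.random.Generator] = None) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        rng = rng or np.random.default_rng()
        keep = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep.astype(DTYPE))


class Adam:
    """Adam optimizer (decoupled from layers; holds per-parameter moments)."""

    def __init__(self, params, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
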