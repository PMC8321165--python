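"""Layer classes with an enumerable parameter ledger.

Every layer lists its parameters as `Param` objects (value, gradient slot,
trainable flag). Non-trainable parameters exist only in batch normalization
(the moving mean/variance used at inference). Layers are callable on `Var`
nodes; `training=True` switches on dropout and batch-statistics mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from ._convops import same_pad
from .autodiff import Var


@dataclass
class Param:
    name: str
    value: np.ndarray
    trainable: bool = True
    grad: np.ndarray | None = None

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base class; subclasses fill `self.params` and implement `__call__`."""

    kind = "layer"

    def __init__(self, name: str):
        self.name = name
        self.params: list[Param] = []

    def _param(self, suffix: str, value: np.ndarray, trainable: bool = True) -> Param:
        p = Param(f"{self.name}.{suffix}", np.asarray(value), trainable)
        self.params.append(p)
        return p

    def __call__(self, x: Var, training: bool = False, rng: np.random.Generator | None = None) -> Var:
        raise NotImplementedError

    def describe(self) -> dict:
        return {
            "kind": self.kind,
            "name": self.name,
            "trainable": sum(p.size for p in self.params if p.trainable),
            "non_trainable": sum(p.size for p in self.params if not p.trainable),
        }


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            dtype=np.float32) -> np.ndarray:
    """Fan-in-scaled normal initialization."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2D(Layer):
    kind = "conv2d"

    def __init__(self, name: str, cin: int, cout: int, kh: int, kw: int,
                 rng: np.random.Generator, stride: int = 1, dilation: int = 1,
                 bias: bool = True, pad: str | tuple = "same", dtype=np.float32):
        super().__init__(name)
        self.cin, self.cout, self.kh, self.kw = cin, cout, kh, kw
        self.stride = (stride, stride)
        self.dilation = (dilation, dilation)
        if pad == "same":
            self.pad = (same_pad(kh, dilation), same_pad(kw, dilation))
        elif pad == "valid":
            self.pad = ((0, 0), (0, 0))
        else:
            self.pad = pad
        fan_in = cin * kh * kw
        self.w = self._param("w", he_init(rng, (cout, cin, kh, kw), fan_in, dtype))
        self.b = self._param("b", np.zeros(cout, dtype=dtype)) if bias else None

    def __call__(self, x, training=False, rng=None):
        b = None if self.b is None else Var(self.b.value)
        out = ad.conv2d(x, Var(self.w.value), b, self.stride, self.dilation, self.pad)
        self._wvar, self._bvar = out._parents[1], (None if self.b is None else out._parents[2])
        return out

    def collect_grads(self):
        if self._wvar.grad is not None:
            self.w.grad = self._wvar.grad if self.w.grad is None else self.w.grad + self._wvar.grad
        if self.b is not None and self._bvar.grad is not None:
            self.b.grad = self._bvar.grad if self.b.grad is None else self.b.grad + self._bvar.grad

    def describe(self):
        d = super().describe()
        d.update(kernel=(self.kh, self.kw), in_channels=self.cin, out_channels=self.cout,
                 stride=self.stride[0], dilation=self.dilation[0], has_bias=self.b is not None)
        return d


class ConvTranspose2D(Layer):
    kind = "conv2d_transpose"

    def __init__(self, name: str, cin: int, cout: int, k: int,
                 rng: np.random.Generator, stride: int = 2, bias: bool = True,
                 dtype=np.float32):
        super().__init__(name)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        # 'same' transposed conv: output = input * stride
        if k == 3 and stride == 2:
            self.pad = ((1, 1), (1, 1))
        elif k == stride:
            self.pad = ((0, 0), (0, 0))
        else:
            raise ValueError(f"unsupported transposed conv geometry k={k}, stride={stride}")
        self.w = self._param("w", he_init(rng, (cin, cout, k, k), cin * k * k, dtype))
        self.b = self._param("b", np.zeros(cout, dtype=dtype)) if bias else None

    def __call__(self, x, training=False, rng=None):
        b = None if self.b is None else Var(self.b.value)
        out = ad.conv2d_transpose(x, Var(self.w.value), b, (self.stride, self.stride), self.pad)
        self._wvar, self._bvar = out._parents[1], (None if self.b is None else out._parents[2])
        return out

    collect_grads = Conv2D.collect_grads

    def describe(self):
        d = super().describe()
        d.update(kernel=(self.k, self.k), in_channels=self.cin, out_channels=self.cout,
                 stride=self.stride, has_bias=self.b is not None)
        return d


class BatchNorm2D(Layer):
    """Per-channel batch normalization.

    gamma/beta are trainable; the moving mean/variance used at inference are
    the non-trainable parameters (their gradients are never propagated).
    """

    kind = "batchnorm2d"

    def __init__(self, name: str, channels: int, momentum: float = 0.9,
                 eps: float = 1e-3, dtype=np.float32):
        super().__init__(name)
        self.channels = channels
        self.momentum = momentum  # weight of the existing moving estimate
        self.eps = eps
        self.gamma = self._param("gamma", np.ones(channels, dtype=dtype))
        self.beta = self._param("beta", np.zeros(channels, dtype=dtype))
        self.moving_mean = self._param("moving_mean", np.zeros(channels, dtype=dtype), trainable=False)
        self.moving_var = self._param("moving_var", np.ones(channels, dtype=dtype), trainable=False)

    def __call__(self, x, training=False, rng=None):
        if training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu).pow_const(2.0)).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.moving_mean.value = m * self.moving_mean.value + (1 - m) * mu.data.ravel()
            self.moving_var.value = m * self.moving_var.value + (1 - m) * var.data.ravel()
        else:
            mu = Var(self.moving_mean.value.reshape(1, -1, 1, 1))
            var = Var(self.moving_var.value.reshape(1, -1, 1, 1))
        inv = (var + self.eps).pow_const(-0.5)
        g = Var(self.gamma.value.reshape(1, -1, 1, 1))
        b = Var(self.beta.value.reshape(1, -1, 1, 1))
        out = (x - mu) * inv * g + b
        self._gvar, self._bvar = g, b
        return out

    def collect_grads(self):
        if self._gvar.grad is not None:
            gg = self._gvar.grad.ravel()
            self.gamma.grad = gg if self.gamma.grad is None else self.gamma.grad + gg
        if self._bvar.grad is not None:
            gb = self._bvar.grad.ravel()
            self.beta.grad = gb if self.beta.grad is None else self.beta.grad + gb

    def describe(self):
        d = super().describe()
        d.update(channels=self.channels)
        return d


class PReLU(Layer):
    """Per-channel parametric ReLU (slopes shared across the plane)."""

    kind = "prelu"

    def __init__(self, name: str, channels: int, init: float = 0.25, dtype=np.float32):
        super().__init__(name)
        self.channels = channels
        self.alpha = self._param("alpha", np.full(channels, init, dtype=dtype))

    def __call__(self, x, training=False, rng=None):
        a = Var(self.alpha.value.reshape(1, -1, 1, 1))
        out = ad.relu(x) + a * ad.neg_part(x)
        self._avar = a
        return out

    def collect_grads(self):
        if self._avar.grad is not None:
            ga = self._avar.grad.ravel()
            self.alpha.grad = ga if self.alpha.grad is None else self.alpha.grad + ga

    def describe(self):
        d = super().describe()
        d.update(channels=self.channels)
        return d


class ReLU(Layer):
    kind = "relu"

    def __call__(self, x, training=False, rng=None):
        return ad.relu(x)

    def collect_grads(self):
        pass


class Dropout(Layer):
    """Inverted dropout on individual activations; identity at inference."""

    kind = "dropout"

    def __init__(self, name: str, rate: float):
        super().__init__(name)
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Var(mask)

    def collect_grads(self):
        pass

    def describe(self):
        d = super().describe()
        d.update(rate=self.rate)
        return d


class SpatialDropout2D(Dropout):
    """Dropout of whole feature maps (channels)."""

    kind = "spatial_dropout2d"

    def __call__(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        n, c = x.shape[0], x.shape[1]
        mask = (rng.random((n, c, 1, 1)) < keep).astype(x.data.dtype) / keep
        return x * Var(mask)


class MaxPool2D(Layer):
    kind = "maxpool2d"

    def __call__(self, x, training=False, rng=None):
        return ad.maxpool2x2(x)

    def collect_grads(self):
        pass


class Upsample2D(Layer):
    kind = "upsample2d"

    def __call__(self, x, training=False, rng=None):
        return ad.upsample2x(x)

    def collect_grads(self):
        pass
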