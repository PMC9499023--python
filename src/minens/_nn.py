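"""Minimal NumPy neural-network core.

Self-contained layers with explicit forward/backward passes, plus the two
optimizers the training protocols use (AdaBelief and SGD with momentum).
Everything is float64 and deterministic given a :class:`numpy.random.Generator`.

Conventions
-----------
* Activations are ``(N, C, H, W)`` inside convolutional stacks and ``(N, F)``
  after global pooling.
* A layer's ``forward(x, train)`` caches whatever ``backward(grad)`` needs;
  ``backward`` returns the gradient with respect to the layer input and
  accumulates parameter gradients in ``Parameter.grad``.
* Batch-norm layers honour ``train`` for batch statistics; running statistics
  are buffers, not parameters, so they never enter parameter counts.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ShapeError

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "SiLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "LogSoftmax",
    "SqueezeExcite",
    "MBConv",
    "SGD",
    "AdaBelief",
    "nll_loss",
    "parameter_hash",
]


class Parameter:
    """A named tensor with a gradient slot and a trainable flag."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.value.size)


class Module:
    """Base class: parameter/buffer traversal and train/eval forward."""

    def _direct_params(self) -> dict[str, Parameter]:
        return {}

    def _direct_buffers(self) -> dict[str, np.ndarray]:
        return {}

    def children(self) -> list[tuple[str, "Module"]]:
        return []

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._direct_params().items():
            yield prefix + name, p
        for cname, child in self.children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._direct_buffers().items():
            yield prefix + name, b
        for cname, child in self.children():
            yield from child.named_buffers(prefix + cname + ".")

    def set_buffer(self, name: str, value: np.ndarray) -> None:
        head, _, rest = name.partition(".")
        if rest:
            dict(self.children())[head].set_buffer(rest, value)
        else:
            buf = self._direct_buffers()[name]
            buf[...] = value

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def set_trainable(self, flag: bool) -> None:
        for p in self.parameters():
            p.trainable = flag

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


class Sequential(Module):
    def __init__(self, layers: Iterable[Module]):
        self.layers = list(layers)

    def children(self):
        return [(str(i), m) for i, m in enumerate(self.layers)]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# initializers

def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# convolution


class Conv2d(Module):
    """2-D convolution; supports standard (groups=1) and depthwise convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 groups: int = 1, bias: bool = False):
        if groups not in (1, in_channels):
            raise ValueError("only groups=1 or depthwise (groups=in_channels) supported")
        if groups == in_channels and out_channels != in_channels:
            raise ValueError("depthwise convolution requires out_channels == in_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        cin_per_group = in_channels // groups
        fan_in = cin_per_group * kernel_size * kernel_size
        self.weight = Parameter(
            kaiming_normal(rng, (out_channels, cin_per_group, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def _direct_params(self):
        d = {"weight": self.weight}
        if self.bias is not None:
            d["bias"] = self.bias
        return d

    def _pad(self, x):
        p = self.padding
        if p == 0:
            return x
        return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))

    def _out_hw(self, H, W):
        k, s, p = self.k, self.stride, self.padding
        return (H + 2 * p - k) // s + 1, (W + 2 * p - k) // s + 1

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        if C != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} input channels, got {C}")
        k, s = self.k, self.stride
        Ho, Wo = self._out_hw(H, W)
        if Ho < 1 or Wo < 1:
            raise ShapeError(f"spatial size {H}x{W} too small for kernel {k} stride {s}")
        xp = self._pad(x)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        if self.groups == 1:
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(N * Ho * Wo, C * k * k)
            wmat = self.weight.value.reshape(self.out_channels, -1)
            out = cols @ wmat.T
            if self.bias is not None:
                out += self.bias.value
            self._cache = (cols, x.shape, xp.shape, Ho, Wo)
            return out.reshape(N, Ho, Wo, self.out_channels).transpose(0, 3, 1, 2)
        # depthwise
        w = self.weight.value[:, 0]  # (C, k, k)
        out = np.einsum("nchwij,cij->nchw", win, w, optimize=True)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        self._cache = (win, x.shape, xp.shape, Ho, Wo)
        return out

    def backward(self, grad):
        k, s, p = self.k, self.stride, self.padding
        if self.groups == 1:
            cols, xshape, xpshape, Ho, Wo = self._cache
            N = xshape[0]
            g2 = grad.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, self.out_channels)
            wmat = self.weight.value.reshape(self.out_channels, -1)
            self.weight.grad += (g2.T @ cols).reshape(self.weight.value.shape)
            if self.bias is not None:
                self.bias.grad += g2.sum(axis=0)
            dcols = (g2 @ wmat).reshape(N, Ho, Wo, self.in_channels, k, k).transpose(0, 3, 1, 2, 4, 5)
        else:
            win, xshape, xpshape, Ho, Wo = self._cache
            w = self.weight.value[:, 0]
            self.weight.grad[:, 0] += np.einsum("nchwij,nchw->cij", win, grad, optimize=True)
            if self.bias is not None:
                self.bias.grad += grad.sum(axis=(0, 2, 3))
            dcols = grad[:, :, :, :, None, None] * w[None, :, None, None, :, :]
        dxp = np.zeros(xpshape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, :, :, i, j]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def _direct_params(self):
        return {"weight": self.weight, "bias": self.bias}

    def _direct_buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, train=False):
        if train:
            axes = (0, 2, 3)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mean
            unbiased = var * n / max(n - 1, 1)
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        self._cache = (xhat, ivar, train, x.shape)
        return self.weight.value[None, :, None, None] * xhat + self.bias.value[None, :, None, None]

    def backward(self, grad):
        xhat, ivar, trained, shape = self._cache
        axes = (0, 2, 3)
        self.weight.grad += (grad * xhat).sum(axis=axes)
        self.bias.grad += grad.sum(axis=axes)
        gw = self.weight.value[None, :, None, None] * ivar[None, :, None, None]
        if not trained:
            return grad * gw
        n = shape[0] * shape[2] * shape[3]
        gsum = grad.sum(axis=axes)[None, :, None, None]
        gxsum = (grad * xhat).sum(axis=axes)[None, :, None, None]
        return gw / n * (n * grad - gsum - xhat * gxsum)


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class SiLU(Module):
    """x * sigmoid(x) (a.k.a. swish), the EfficientNet activation."""

    def forward(self, x, train=False):
        sig = 1.0 / (1.0 + np.exp(-x))
        self._cache = (x, sig)
        return x * sig

    def backward(self, grad):
        x, sig = self._cache
        return grad * (sig * (1.0 + x * (1.0 - sig)))


class MaxPool2d(Module):
    """Non-overlapping max pooling (kernel == stride)."""

    def __init__(self, kernel_size: int = 2):
        self.k = kernel_size

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        k = self.k
        if H % k or W % k:
            raise ShapeError(f"spatial size {H}x{W} not divisible by pool {k}")
        Ho, Wo = H // k, W // k
        tiles = x.reshape(N, C, Ho, k, Wo, k).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, k * k)
        self._argmax = tiles.argmax(axis=-1)
        self._inshape = x.shape
        return tiles.max(axis=-1)

    def backward(self, grad):
        N, C, H, W = self._inshape
        k = self.k
        Ho, Wo = H // k, W // k
        dtiles = np.zeros((N, C, Ho, Wo, k * k))
        np.put_along_axis(dtiles, self._argmax[..., None], grad[..., None], axis=-1)
        return dtiles.reshape(N, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) mean over the spatial grid."""

    def forward(self, x, train=False):
        self._inshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        N, C, H, W = self._inshape
        return np.broadcast_to(grad[:, :, None, None], (N, C, H, W)) / (H * W)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.in_features = in_features
        self.out_features = out_features
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_features)) if bias else None

    def _direct_params(self):
        d = {"weight": self.weight}
        if self.bias is not None:
            d["bias"] = self.bias
        return d

    def forward(self, x, train=False):
        if x.ndim != 2 or x.shape[1] != self.in_features:
            raise ShapeError(f"expected (N, {self.in_features}) input, got {x.shape}")
        self._x = x
        out = x @ self.weight.value.T
        if self.bias is not None:
            out = out + self.bias.value
        return out

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class LogSoftmax(Module):
    def forward(self, x, train=False):
        m = x.max(axis=1, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        out = z - lse
        self._softmax = np.exp(out)
        return out

    def backward(self, grad):
        return grad - self._softmax * grad.sum(axis=1, keepdims=True)


class SqueezeExcite(Module):
    """Channel attention: GAP -> reduce -> SiLU -> expand -> sigmoid -> scale."""

    def __init__(self, channels: int, squeeze_channels: int, rng: np.random.Generator):
        self.fc1 = Linear(channels, squeeze_channels, rng)
        self.fc2 = Linear(squeeze_channels, channels, rng)
        self.act = SiLU()

    def children(self):
        return [("fc1", self.fc1), ("fc2", self.fc2)]

    def forward(self, x, train=False):
        s = x.mean(axis=(2, 3))
        a = self.act.forward(self.fc1.forward(s))
        z = 1.0 / (1.0 + np.exp(-self.fc2.forward(a)))
        self._cache = (x, z)
        return x * z[:, :, None, None]

    def backward(self, grad):
        x, z = self._cache
        H, W = x.shape[2], x.shape[3]
        dz = (grad * x).sum(axis=(2, 3))
        dx = grad * z[:, :, None, None]
        dpre = dz * z * (1.0 - z)
        ds = self.fc1.backward(self.act.backward(self.fc2.backward(dpre)))
        dx += ds[:, :, None, None] / (H * W)
        return dx


class MBConv(Module):
    """Inverted-bottleneck block: expand -> depthwise -> SE -> project, with skip."""

    def __init__(self, in_channels: int, out_channels: int, expand_ratio: int,
                 kernel_size: int, stride: int, squeeze_channels: int,
                 rng: np.random.Generator):
        self.use_residual = stride == 1 and in_channels == out_channels
        expanded = in_channels * expand_ratio
        stages: list[tuple[str, Module]] = []
        if expand_ratio != 1:
            stages += [("expand", Conv2d(in_channels, expanded, 1, rng)),
                       ("expand_bn", BatchNorm2d(expanded)), ("expand_act", SiLU())]
        stages += [("dw", Conv2d(expanded, expanded, kernel_size, rng, stride=stride,
                                 padding=kernel_size // 2, groups=expanded)),
                   ("dw_bn", BatchNorm2d(expanded)), ("dw_act", SiLU()),
                   ("se", SqueezeExcite(expanded, squeeze_channels, rng)),
                   ("project", Conv2d(expanded, out_channels, 1, rng)),
                   ("project_bn", BatchNorm2d(out_channels))]
        self._stages = stages

    def children(self):
        return self._stages

    def forward(self, x, train=False):
        out = x
        for _, stage in self._stages:
            out = stage.forward(out, train=train)
        if self.use_residual:
            out = out + x
        return out

    def backward(self, grad):
        g = grad
        for _, stage in reversed(self._stages):
            g = stage.backward(g)
        if self.use_residual:
            g = g + grad
        return g


# ---------------------------------------------------------------------------
# loss


def nll_loss(log_probs: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood and its gradient w.r.t. the log-probabilities."""
    n = log_probs.shape[0]
    loss = -log_probs[np.arange(n), targets].mean()
    grad = np.zeros_like(log_probs)
    grad[np.arange(n), targets] = -1.0 / n
    return float(loss), grad


# ---------------------------------------------------------------------------
# optimizers


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v


class AdaBelief:
    """AdaBelief: Adam-style steps scaled by belief in the gradient.

    The second-moment estimate tracks the variance of the gradient around its
    EMA (``(g - m)^2``) instead of the raw second moment, which yields faster
    convergence on curvatures where the gradient is predictable. Decoupled
    weight decay and no step-size rectification, matching the defaults of the
    reference implementation.
    """

    def __init__(self, params: list[Parameter], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-16,
                 weight_decay: float = 0.0, weight_decouple: bool = True,
                 rectify: bool = False):
        if rectify:
            raise NotImplementedError("rectified updates are not used here")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.weight_decouple = weight_decouple
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._s = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for p, m, s in zip(self.params, self._m, self._s):
            g = p.grad
            if self.weight_decay:
                if self.weight_decouple:
                    p.value *= 1.0 - self.lr * self.weight_decay
                else:
                    g = g + self.weight_decay * p.value
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            diff = g - m
            s *= self.beta2
            s += (1.0 - self.beta2) * diff * diff + self.eps
            p.value -= self.lr * (m / bc1) / (np.sqrt(s / bc2) + self.eps)


def parameter_hash(params: Iterable[Parameter]) -> str:
    """SHA-256 over the raw bytes of the parameter values, in iteration order."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()
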