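"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module is the numerical substrate for every trainable network in the
package: tensors carry values and gradients, operations record a backward
closure, and :meth:`Tensor.backward` runs reverse accumulation over the
recorded graph in topological order.

Only the operations the lesion-image networks actually need are provided:
2-D convolution (im2col), ReLU, 2x2 max pooling, global average/max pooling
over the spatial grid, dense affine maps, concatenation, softmax
cross-entropy and a weighted per-channel squared-error reduction used by the
feature-transfer loss.  Everything is float64 and fully deterministic.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

DTYPE = np.float64


class Tensor:
    """A node in the autodiff graph: a float64 array plus gradient state."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # break closure cycles so array memory frees by reference counting
        for node in order:
            node._backward = None
            node._parents = ()

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference mode).

    Inside the context, operations return plain value tensors without
    backward closures, so large intermediates (im2col buffers, activation
    maps) are freed as soon as they go out of scope.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _make(data: np.ndarray, parents: tuple[Tensor, ...],
          backward: Callable[[Tensor], None] | None) -> Tensor:
    out = Tensor(data)
    if not _GRAD_ENABLED:
        return out
    needs = any(p.requires_grad or p._parents for p in parents)
    if needs and backward is not None:
        out._parents = parents
        out._backward = lambda: backward(out)
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / dense ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bwd(out: Tensor) -> None:
        a._accumulate(_unbroadcast(out.grad, a.shape))
        b._accumulate(_unbroadcast(out.grad, b.shape))
    return _make(a.data + b.data, (a, b), bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    def bwd(out: Tensor) -> None:
        a._accumulate(_unbroadcast(out.grad, a.shape))
        b._accumulate(_unbroadcast(-out.grad, b.shape))
    return _make(a.data - b.data, (a, b), bwd)


def scale(a: Tensor, c: float) -> Tensor:
    def bwd(out: Tensor) -> None:
        a._accumulate(c * out.grad)
    return _make(a.data * c, (a,), bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bwd(out: Tensor) -> None:
        a._accumulate(out.grad @ b.data.T)
        b._accumulate(a.data.T @ out.grad)
    return _make(a.data @ b.data, (a, b), bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def bwd(out: Tensor) -> None:
        a._accumulate(out.grad * mask)
    return _make(a.data * mask, (a,), bwd)


def flatten(a: Tensor) -> Tensor:
    n = a.shape[0]

    def bwd(out: Tensor) -> None:
        a._accumulate(out.grad.reshape(a.shape))
    return _make(a.data.reshape(n, -1), (a,), bwd)


def concat(parts: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [p.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(out: Tensor) -> None:
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            p._accumulate(out.grad[tuple(sl)])
    return _make(np.concatenate([p.data for p in parts], axis=axis),
                 tuple(parts), bwd)


# ---------------------------------------------------------------------------
# convolution and pooling (NCHW layout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * ho:stride,
                                  j:j + stride * wo:stride]
    return cols.reshape(n, c * k * k, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dc = dcols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * ho:stride,
                j:j + stride * wo:stride] += dc[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2-D convolution; ``w`` has shape (C_out, C_in, k, k), ``b`` (C_out,)."""
    cout, cin, k, _ = w.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d channel mismatch: {x.shape[1]} vs {cin}")
    cols, ho, wo = _im2col(x.data, k, stride, pad)
    w2 = w.data.reshape(cout, cin * k * k)
    out = w2[None] @ cols
    out = out.reshape(x.shape[0], cout, ho, wo) + b.data[None, :, None, None]

    def bwd(outT: Tensor) -> None:
        d2 = outT.grad.reshape(x.shape[0], cout, ho * wo)
        w._accumulate((d2 @ cols.transpose(0, 2, 1)).sum(axis=0)
                      .reshape(w.shape))
        b._accumulate(outT.grad.sum(axis=(0, 2, 3)))
        dcols = w2.T[None] @ d2
        x._accumulate(_col2im(dcols, x.shape, k, stride, pad, ho, wo))
    return _make(out, (x, w, b), bwd)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 needs even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    xf = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = xf.argmax(axis=-1)
    out = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]

    def bwd(outT: Tensor) -> None:
        df = np.zeros_like(xf)
        np.put_along_axis(df, idx[..., None], outT.grad[..., None], axis=-1)
        dx = df.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(dx.reshape(x.shape))
    return _make(out, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape

    def bwd(out: Tensor) -> None:
        x._accumulate(np.broadcast_to(
            out.grad[:, :, None, None] / (h * w), x.shape).copy())
    return _make(x.data.mean(axis=(2, 3)), (x,), bwd)


def global_max_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=-1)

    def bwd(out: Tensor) -> None:
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], out.grad[..., None], axis=-1)
        x._accumulate(dflat.reshape(x.shape))
    return _make(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0],
                 (x,), bwd)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax of ``logits``."""
    y = np.asarray(labels, dtype=np.int64)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    eps = np.finfo(DTYPE).tiny
    loss = -np.log(probs[np.arange(n), y] + eps).mean()

    def bwd(out: Tensor) -> None:
        g = probs.copy()
        g[np.arange(n), y] -= 1.0
        logits._accumulate(out.grad * g / n)
    return _make(np.asarray(loss), (logits,), bwd)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Plain softmax on raw logit values (no graph)."""
    z = np.asarray(logits, dtype=DTYPE)
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def weighted_channel_mse(diff: Tensor, weights: np.ndarray) -> Tensor:
    """sum_c w_c * mean_n diff[n, c]^2 for a (n, C) difference matrix."""
    w = np.asarray(weights, dtype=DTYPE)
    n = diff.shape[0]
    val = float((w * (diff.data ** 2).mean(axis=0)).sum())

    def bwd(out: Tensor) -> None:
        diff._accumulate(out.grad * 2.0 * w[None, :] * diff.data / n)
    return _make(np.asarray(val), (diff,), bwd)


# ---------------------------------------------------------------------------
# parameters, layers, optimisation
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    """A leaf tensor that optimisers update."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def he_init(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    """Base class holding a flat, ordered parameter list."""

    def parameters(self) -> list[Parameter]:
        def collect(v, out):
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    collect(item, out)
            elif isinstance(v, dict):
                for key in sorted(v):
                    collect(v[key], out)

        params: list[Parameter] = []
        for v in vars(self).values():
            collect(v, params)
        return params

    def submodules(self) -> list["Module"]:
        def collect(v, out):
            if isinstance(v, Module):
                out.append(v)
                out.extend(v.submodules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    collect(item, out)
            elif isinstance(v, dict):
                for key in sorted(v):
                    collect(v[key], out)

        mods: list[Module] = []
        for v in vars(self).values():
            collect(v, mods)
        return mods

    def set_training(self, flag: bool) -> None:
        """Switch batch-normalization layers between batch and running
        statistics."""
        for m in [self] + self.submodules():
            if hasattr(m, "training"):
                m.training = bool(flag)

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: Iterable[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            if p.data.shape != s.shape:
                raise ValueError("state shape mismatch")
            p.data = np.array(s, dtype=DTYPE)

    def signature(self) -> tuple[tuple[int, ...], ...]:
        """Structural signature: ordered parameter shapes."""
        return tuple(p.data.shape for p in self.parameters())


class Conv2d(Module):
    def __init__(self, rng: np.random.Generator, cin: int, cout: int,
                 k: int, stride: int = 1, pad: int = 0):
        self.stride, self.pad = stride, pad
        self.w = Parameter(he_init(rng, (cout, cin, k, k), cin * k * k))
        self.b = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalization with learned affine and running stats.

    Running mean/variance are stored as gradient-free Parameters so they
    travel with the model state (checkpoints, parameter averaging) without
    ever receiving optimizer updates.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = Parameter(np.zeros(channels))
        self.running_var = Parameter(np.ones(channels))
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean.data = ((1 - self.momentum)
                                      * self.running_mean.data
                                      + self.momentum * mu)
            self.running_var.data = ((1 - self.momentum)
                                     * self.running_var.data
                                     + self.momentum * var)
            s = np.sqrt(var + self.eps)
            xhat = (x.data - mu[None, :, None, None]) / s[None, :, None, None]
            out = gamma.data[None, :, None, None] * xhat \
                + beta.data[None, :, None, None]
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

            def bwd(outT: Tensor) -> None:
                g = outT.grad
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
                beta._accumulate(g.sum(axis=(0, 2, 3)))
                gmean = g.mean(axis=(0, 2, 3))[None, :, None, None]
                gxmean = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                coef = (gamma.data / s)[None, :, None, None]
                x._accumulate(coef * (g - gmean - xhat * gxmean))
            return _make(out, (x, gamma, beta), bwd)
        # inference: affine map by frozen running statistics
        s = np.sqrt(self.running_var.data + self.eps)
        xhat = (x.data - self.running_mean.data[None, :, None, None]) \
            / s[None, :, None, None]
        out = gamma.data[None, :, None, None] * xhat \
            + beta.data[None, :, None, None]

        def bwd(outT: Tensor) -> None:
            g = outT.grad
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            beta._accumulate(g.sum(axis=(0, 2, 3)))
            x._accumulate(g * (gamma.data / s)[None, :, None, None])
        return _make(out, (x, gamma, beta), bwd)


class Linear(Module):
    def __init__(self, rng: np.random.Generator, nin: int, nout: int,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((nin, nout))
        else:
            w = he_init(rng, (nin, nout), nin)
        self.w = Parameter(w)
        self.b = Parameter(np.zeros(nout))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.w), self.b)


class SGD:
    """Plain stochastic gradient descent over a parameter list."""

    def __init__(self, params: Sequence[Parameter], lr: float):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad
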