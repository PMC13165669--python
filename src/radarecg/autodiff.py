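"""A small reverse-mode automatic-differentiation engine on numpy arrays.

This module provides exactly the primitives the ECG-reconstruction network
needs: broadcast-aware arithmetic, matmul, 1-D (dilated, padded) convolution,
batch/layer normalization, softmax attention pieces, real FFT with correct
adjoints (for the spectral-attention block), pooling / linear upsampling, a
``Module`` container hierarchy, and an Adam optimizer.

Gradients flow through a dynamically built tape: every op records its parent
tensors and a per-parent closure mapping the upstream gradient to that
parent's gradient contribution.  ``Tensor.backward()`` runs a topological
sort over the tape.  The FFT adjoints are the analytically derived transposes
of numpy's ``rfft``/``irfft`` (verified against finite differences in the
test suite).
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Module", "Linear", "Conv1d", "BatchNorm1d", "LayerNorm",
           "Dropout", "Sequential", "Adam", "concat", "softmax", "relu",
           "sigmoid", "maximum", "conv1d", "maxpool1d_k2", "avgpool1d",
           "upsample_linear_2x", "rfft_split", "irfft_join", "mean_all",
           "use_dtype", "default_dtype"]

_DTYPE = np.float64


def default_dtype():
    return _DTYPE


@contextlib.contextmanager
def use_dtype(dtype):
    """Temporarily set the dtype new tensors are cast to.

    float64 (the default) is used wherever exactness matters; training runs
    markedly faster under ``use_dtype(np.float32)``.  Build the model inside
    the context so its parameters share the dtype.
    """
    global _DTYPE
    old = _DTYPE
    _DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DTYPE = old


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence[tuple["Tensor", Callable]] = ()):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(data, requires_grad=True)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for p, fn in node._parents:
                if not p.requires_grad:
                    continue
                contrib = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + contrib
                else:
                    grads[id(p)] = contrib
            if node.requires_grad and node._parents:
                # interior node someone asked grad for (rare)
                pass

    # -- operators ------------------------------------------------------------
    def _binop(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)
        req = self.requires_grad or other.requires_grad
        parents = []
        if self.requires_grad:
            parents.append((self, lambda g, a=self, b=other: _unbroadcast(
                bwd_self(g, a.data, b.data), a.data.shape)))
        if other.requires_grad:
            parents.append((other, lambda g, a=self, b=other: _unbroadcast(
                bwd_other(g, a.data, b.data), b.data.shape)))
        return Tensor(out_data, req, parents)

    def __add__(self, other):
        return self._binop(other, lambda a, b: a + b,
                           lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binop(other, lambda a, b: a - b,
                           lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        return self._binop(other, lambda a, b: a * b,
                           lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binop(other, lambda a, b: a / b,
                           lambda g, a, b: g / b,
                           lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __neg__(self):
        return self * -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = Tensor(self.data ** e, self.requires_grad,
                     [(self, lambda g, a=self: g * e * a.data ** (e - 1.0))]
                     if self.requires_grad else ())
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.matmul(self.data, other.data)
        parents = []
        if self.requires_grad:
            parents.append((self, lambda g, a=self, b=other: _unbroadcast(
                np.matmul(g, np.swapaxes(b.data, -1, -2)), a.data.shape)))
        if other.requires_grad:
            parents.append((other, lambda g, a=self, b=other: _unbroadcast(
                np.matmul(np.swapaxes(a.data, -1, -2), g), b.data.shape)))
        return Tensor(out_data, self.requires_grad or other.requires_grad, parents)

    __matmul__ = matmul

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], tuple) else shape
        return Tensor(self.data.reshape(shape), self.requires_grad,
                      [(self, lambda g, s=self.data.shape: g.reshape(s))]
                      if self.requires_grad else ())

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes), self.requires_grad,
                      [(self, lambda g, inv=tuple(inv): g.transpose(inv))]
                      if self.requires_grad else ())

    def __getitem__(self, idx) -> "Tensor":
        def bwd(g, a=self, idx=idx):
            out = np.zeros_like(a.data)
            out[idx] = g
            return out
        return Tensor(self.data[idx], self.requires_grad,
                      [(self, bwd)] if self.requires_grad else ())

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                return np.broadcast_to(g, a.data.shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, a.data.shape).copy()
        return Tensor(out_data, self.requires_grad,
                      [(self, bwd)] if self.requires_grad else ())

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor(out_data, self.requires_grad,
                      [(self, lambda g, o=out_data: g * o)]
                      if self.requires_grad else ())

    def log(self) -> "Tensor":
        return Tensor(np.log(self.data), self.requires_grad,
                      [(self, lambda g, a=self: g / a.data)]
                      if self.requires_grad else ())

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)
        return Tensor(out_data, self.requires_grad,
                      [(self, lambda g, o=out_data: g * 0.5 / o)]
                      if self.requires_grad else ())


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, x.requires_grad,
                  [(x, lambda g, m=mask: g * m)] if x.requires_grad else ())


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(out_data, x.requires_grad,
                  [(x, lambda g, o=out_data: g * o * (1.0 - o))]
                  if x.requires_grad else ())


def maximum(a: Tensor, b: Tensor) -> Tensor:
    mask = a.data >= b.data
    out_data = np.where(mask, a.data, b.data)
    parents = []
    if a.requires_grad:
        parents.append((a, lambda g, m=mask, s=a.data.shape: _unbroadcast(g * m, s)))
    if b.requires_grad:
        parents.append((b, lambda g, m=mask, s=b.data.shape: _unbroadcast(g * ~m, s)))
    return Tensor(out_data, a.requires_grad or b.requires_grad, parents)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)   # constant shift, zero gradient a.e.
    e = np.exp(x.data - m)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g, o=out_data, axis=axis):
        dot = (g * o).sum(axis=axis, keepdims=True)
        return o * (g - dot)
    return Tensor(out_data, x.requires_grad,
                  [(x, bwd)] if x.requires_grad else ())


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    offset = 0
    for t in tensors:
        n = t.data.shape[axis]
        if t.requires_grad:
            sl = [slice(None)] * out_data.ndim
            sl[axis] = slice(offset, offset + n)
            parents.append((t, lambda g, sl=tuple(sl): g[sl]))
        offset += n
    return Tensor(out_data, any(t.requires_grad for t in tensors), parents)


def mean_all(x: Tensor) -> Tensor:
    return x.mean()


# ---------------------------------------------------------------------------
# Convolution and pooling
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, dilation: int, t_out: int) -> np.ndarray:
    """(B, C, Tp) -> (B, C, t_out, k) dilated sliding windows."""
    win = (k - 1) * dilation + 1
    v = np.lib.stride_tricks.sliding_window_view(xp, win, axis=-1)
    return v[..., :t_out, ::dilation]


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None,
           padding: int | tuple[int, int] = 0, dilation: int = 1) -> Tensor:
    """1-D convolution (cross-correlation): x (B,Cin,T), w (Cout,Cin,K)."""
    pl, pr = (padding, padding) if isinstance(padding, int) else padding
    B, Cin, T = x.data.shape
    Cout, _, K = w.data.shape
    ext = (K - 1) * dilation
    t_out = T + pl + pr - ext
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x.data
    cols = _im2col(xp, K, dilation, t_out)                 # (B,Cin,t_out,K)
    out_data = np.einsum("bitk,oik->bot", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None]
    parents = []
    if x.requires_grad:
        def bwd_x(g, shape=(B, Cin, T), pl=pl, pr=pr, K=K, d=dilation,
                  wd=w.data, t_out=t_out):
            gxp = np.zeros((shape[0], shape[1], shape[2] + pl + pr))
            for kk in range(K):
                # out[b,o,t] += xp[b,i,t+kk*d] * w[o,i,kk]
                gxp[:, :, kk * d: kk * d + t_out] += np.einsum(
                    "bot,oi->bit", g, wd[:, :, kk], optimize=True)
            return gxp[:, :, pl: pl + shape[2]]
        parents.append((x, bwd_x))
    if w.requires_grad:
        parents.append((w, lambda g, cols=cols: np.einsum(
            "bot,bitk->oik", g, cols, optimize=True)))
    if b is not None and b.requires_grad:
        parents.append((b, lambda g: g.sum(axis=(0, 2))))
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    return Tensor(out_data, req, parents)


def maxpool1d_k2(x: Tensor) -> Tensor:
    """Max pooling, kernel 2, stride 2 (even input length)."""
    return maximum(x[:, :, 0::2], x[:, :, 1::2])


def avgpool1d(x: Tensor, factor: int) -> Tensor:
    """Average pooling by an integer factor along the last axis."""
    B, C, T = x.data.shape
    if T % factor:
        raise ValueError("length not divisible by pooling factor")
    return x.reshape(B, C, T // factor, factor).mean(axis=3)


def upsample_linear_2x(x: Tensor) -> Tensor:
    """Length-doubling linear interpolation along the last axis.

    ``y[2i] = x[i]``, ``y[2i+1] = (x[i] + x[i+1]) / 2`` (the final odd sample
    repeats the last input sample).
    """
    B, C, T = x.data.shape
    out_data = np.empty((B, C, 2 * T))
    out_data[:, :, 0::2] = x.data
    out_data[:, :, 1:-1:2] = 0.5 * (x.data[:, :, :-1] + x.data[:, :, 1:])
    out_data[:, :, -1] = x.data[:, :, -1]

    def bwd(g, T=T):
        gx = g[:, :, 0::2].copy()
        mids = g[:, :, 1:-1:2]
        gx[:, :, :-1] += 0.5 * mids
        gx[:, :, 1:] += 0.5 * mids
        gx[:, :, -1] += g[:, :, -1]
        return gx
    return Tensor(out_data, x.requires_grad,
                  [(x, bwd)] if x.requires_grad else ())


# ---------------------------------------------------------------------------
# Real FFT with adjoints
# ---------------------------------------------------------------------------

def rfft_split(x: Tensor) -> tuple[Tensor, Tensor]:
    """Real FFT along the last axis, returned as (real, imag) tensors."""
    N = x.data.shape[-1]
    spec = np.fft.rfft(x.data, axis=-1)

    def bwd_re(g, N=N):
        h = g.copy()
        h[..., 1:] *= 0.5
        if N % 2 == 0:
            h[..., -1] *= 2.0
        return N * np.fft.irfft(h, n=N, axis=-1)

    def bwd_im(g, N=N):
        h = 0.5j * g
        h[..., 0] = 0.0
        if N % 2 == 0:
            h[..., -1] = 0.0
        return N * np.fft.irfft(h, n=N, axis=-1)

    re = Tensor(spec.real, x.requires_grad,
                [(x, bwd_re)] if x.requires_grad else ())
    im = Tensor(spec.imag, x.requires_grad,
                [(x, bwd_im)] if x.requires_grad else ())
    return re, im


def irfft_join(re: Tensor, im: Tensor, n: int) -> Tensor:
    """Inverse real FFT of a (real, imag) half-spectrum pair, output length n."""
    out_data = np.fft.irfft(re.data + 1j * im.data, n=n, axis=-1)

    def coeffs(g, n=n):
        G = np.fft.rfft(g, axis=-1)
        c = np.full(G.shape[-1], 2.0 / n)
        c[0] = 1.0 / n
        if n % 2 == 0:
            c[-1] = 1.0 / n
        return G, c

    def bwd_re(g):
        G, c = coeffs(g)
        return c * G.real

    def bwd_im(g):
        G, c = coeffs(g)
        out = c * G.imag
        out[..., 0] = 0.0
        if n % 2 == 0:
            out[..., -1] = 0.0
        return out

    parents = []
    if re.requires_grad:
        parents.append((re, bwd_re))
    if im.requires_grad:
        parents.append((im, bwd_im))
    return Tensor(out_data, re.requires_grad or im.requires_grad, parents)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Minimal parameter container with train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """All parameters plus normalization running statistics, in order."""
        arrs = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                arrs.extend([m.running_mean, m.running_var])
        return arrs

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays[:len(params)]):
            p.data = np.array(a, dtype=p.data.dtype)
        rest = list(arrays[len(params):])
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                m.running_mean = np.array(rest.pop(0), dtype=np.float64)
                m.running_var = np.array(rest.pop(0), dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / math.sqrt(n_in)
        self.w = Tensor.param(rng.uniform(-bound, bound, (n_in, n_out)))
        self.b = Tensor.param(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 padding: int | tuple[int, int] = 0, dilation: int = 1):
        super().__init__()
        bound = 1.0 / math.sqrt(c_in * k)
        self.w = Tensor.param(rng.uniform(-bound, bound, (c_out, c_in, k)))
        self.b = Tensor.param(np.zeros(c_out))
        self.padding = padding
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, padding=self.padding,
                      dilation=self.dilation)


class BatchNorm1d(Module):
    """Normalization over (batch, time) per channel for (B, C, T) inputs."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor.param(np.ones(c))
        self.beta = Tensor.param(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            diff = x - mu
            var = (diff * diff).mean(axis=(0, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            xn = diff / (var + self.eps).sqrt()
        else:
            mu = self.running_mean[None, :, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None]
            xn = (x - mu) * (1.0 / sd)
        return xn * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class LayerNorm(Module):
    """Normalization over the last axis for (B, T, C) inputs."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor.param(np.ones(d))
        self.beta = Tensor.param(np.zeros(d))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        diff = x - mu
        var = (diff * diff).mean(axis=-1, keepdims=True)
        return diff / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam optimizer with optional per-step learning-rate override."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
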