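"""Compact reverse-mode automatic differentiation and NN layers on numpy.

The model in this package (edge-aware graph-transformer encoder, attention
UNet decoder) is small enough to train on a CPU at float64 precision, so the
whole learning stack is built on a self-contained tape-based autodiff engine
over ``numpy`` arrays.  The engine supports exactly the operator set the
model needs: broadcasting arithmetic, matmul, reductions, reshapes, gather /
segment-sum (for sparse neighbourhood attention), 2-D convolution and
nearest-neighbour upsampling (for the UNet), and the usual pointwise
nonlinearities.

Gradient correctness is enforced by finite-difference checks in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "conv2d",
    "upsample_nearest2d",
    "segment_sum",
    "take",
    "softmax",
    "sigmoid",
    "swish",
    "relu",
    "Module",
    "Linear",
    "GroupNorm",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An n-d array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self)=1)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = tensor(other)
        data = self.data + other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = tensor(other)
        data = self.data * other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = tensor(other)
        data = self.data / other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        return Tensor._make(data, (self, other), bw)

    def __rtruediv__(self, other) -> "Tensor":
        return tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        data = self.data ** p

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(data, (self,), bw)

    def __matmul__(self, other) -> "Tensor":
        other = tensor(other)
        data = self.data @ other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                         self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                          other.shape))

        return Tensor._make(data, (self, other), bw)

    # -- pointwise ------------------------------------------------------------
    def exp(self) -> "Tensor":
        data = np.exp(self.data)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * data)

        return Tensor._make(data, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self) -> "Tensor":
        data = np.sqrt(self.data)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * 0.5 / data)

        return Tensor._make(data, (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape))

        return Tensor._make(data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), bw)

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def __getitem__(self, idx) -> "Tensor":
        data = self.data[idx]

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, idx, g)
                self._accum(gx)

        return Tensor._make(data, (self,), bw)


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- free functions -----------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, tensors, bw)


def take(x: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows ``x[index]`` along axis 0 (integer index array)."""
    index = np.asarray(index, dtype=np.intp)
    data = x.data[index]

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, index, g)
            x._accum(gx)

    return Tensor._make(data, (x,), bw)


def segment_sum(x: Tensor, index: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given by ``index``."""
    index = np.asarray(index, dtype=np.intp)
    data = np.zeros((n_segments,) + x.shape[1:], dtype=np.float64)
    np.add.at(data, index, x.data)

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g[index])

    return Tensor._make(data, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # constant max-shift for stability; the -60 floor keeps exp() away from
    # the subnormal range (harmless: such weights are < 1e-26 of the max)
    m = x.data.max(axis=axis, keepdims=True)
    e = clip_min(x - m, -60.0).exp()
    return e / e.sum(axis=axis, keepdims=True)


def clip_min(x: Tensor, lo: float) -> Tensor:
    mask = (x.data >= lo).astype(np.float64)

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(np.maximum(x.data, lo), (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g * data * (1.0 - data))

    return Tensor._make(data, (x,), bw)


def swish(x: Tensor) -> Tensor:
    """x * sigmoid(x) — the smooth gating activation used in the decoder."""
    return x * sigmoid(x)


def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float64)

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. ``x``: (C_in,H,W); ``w``: (C_out,C_in,kh,kw)."""
    cin, H, W = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    p, s = padding, stride
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    view = view[:, ::s, ::s]                   # (C_in, Hout, Wout, kh, kw)
    Hout, Wout = view.shape[1], view.shape[2]
    data = np.einsum("oikl,ihwkl->ohw", w.data, view, optimize=True)
    if b is not None:
        data = data + b.data[:, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bw(g: np.ndarray) -> None:
        if w.requires_grad:
            gw = np.einsum("ohw,ihwkl->oikl", g, view, optimize=True)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(1, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    contrib = np.tensordot(w.data[:, :, ki, kj], g,
                                           axes=([0], [0]))
                    gxp[:, ki:ki + Hout * s:s, kj:kj + Wout * s:s] += contrib
            x._accum(gxp[:, p:p + H, p:p + W] if p else gxp)

    return Tensor._make(data, parents, bw)


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of a (C,H,W) map by ``factor``."""
    c, H, W = x.shape
    data = np.repeat(np.repeat(x.data, factor, axis=1), factor, axis=2)

    def bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g.reshape(c, H, factor, W, factor).sum(axis=(2, 4)))

    return Tensor._make(data, (x,), bw)


# -- modules ------------------------------------------------------------------

class Module:
    """Minimal parameter container with recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            _collect_named(value, f"{prefix}{name}", out)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray],
                        prefix: str = "") -> None:
        mine = {}
        for name, value in vars(self).items():
            _collect_named_tensors(value, f"{prefix}{name}", mine)
        missing = set(mine) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for key, t in mine.items():
            arr = np.asarray(state[key], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(
                    f"shape mismatch for {key}: {arr.shape} vs {t.data.shape}")
            t.data = arr.copy()


def _collect(value) -> Iterable[Tensor]:
    if isinstance(value, Tensor):
        if value.requires_grad:
            yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _collect_named(value, name: str, out: dict[str, np.ndarray]) -> None:
    if isinstance(value, Tensor):
        if value.requires_grad:
            out[name] = value.data.copy()
    elif isinstance(value, Module):
        for k, v in value.state_dict().items():
            out[f"{name}.{k}"] = v
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _collect_named(v, f"{name}.{i}", out)


def _collect_named_tensors(value, name: str, out: dict[str, Tensor]) -> None:
    if isinstance(value, Tensor):
        if value.requires_grad:
            out[name] = value
    elif isinstance(value, Module):
        for k, v in vars(value).items():
            _collect_named_tensors(v, f"{name}.{k}", out)
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _collect_named_tensors(v, f"{name}.{i}", out)


class Linear(Module):
    """Affine map ``y = x W + b`` with Glorot-uniform initialisation."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        limit = math.sqrt(6.0 / (in_features + out_features))
        self.weight = Tensor(rng.uniform(-limit, limit,
                                         (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias \
            else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class GroupNorm(Module):
    """Group normalisation over a (C,H,W) feature map."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        if num_channels % num_groups:
            raise ValueError("channels must divide evenly into groups")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.gamma = Tensor(np.ones(num_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        c, H, W = x.shape
        g = self.num_groups
        xg = x.reshape(g, (c // g) * H * W)
        mu = xg.mean(axis=1, keepdims=True)
        var = ((xg - mu) ** 2).mean(axis=1, keepdims=True)
        y = (xg - mu) / (var + self.eps).sqrt()
        y = y.reshape(c, H, W)
        return y * self.gamma.reshape(c, 1, 1) + self.beta.reshape(c, 1, 1)


class Adam:
    """Adam optimiser over a flat list of parameters."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
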