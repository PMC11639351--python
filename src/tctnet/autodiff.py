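"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the micrograd lineage, sized for volumetric
segmentation networks: dense/batched matmul, grouped strided 3D convolution
(im2col), non-overlapping transposed convolution, layer normalisation,
softmax and GELU are first-class primitives with hand-written adjoints;
everything else is composed from elementwise ops and reductions.

All primitives report multiply-add counts (1 MAC = 2 flops) to an optional
:class:`FlopMeter`, which gives an instrumented runtime flop count that is
independent of the analytic counter in :mod:`tctnet.flops`.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Tensor",
    "FlopMeter",
    "no_grad",
    "concat",
    "conv3d",
    "conv_transpose3d",
    "gelu",
    "layer_norm",
    "log",
    "matmul",
    "maximum",
    "softmax",
]

# ---------------------------------------------------------------------------
# flop metering

_ACTIVE_METERS: list["FlopMeter"] = []


class FlopMeter:
    """Context manager accumulating runtime multiply-add flops (MAC = 2 flops).

    Only matmul/conv/transposed-conv contribute, matching the dominant-term
    convention of the analytic counter (norms, activations, softmax and bias
    additions are ignored).
    """

    def __init__(self) -> None:
        self.flops = 0

    def __enter__(self) -> "FlopMeter":
        _ACTIVE_METERS.append(self)
        return self

    def __exit__(self, *exc) -> None:
        _ACTIVE_METERS.remove(self)


def _record_flops(n: int) -> None:
    for meter in _ACTIVE_METERS:
        meter.flops += int(n)


# ---------------------------------------------------------------------------
# gradient switch

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev


# ---------------------------------------------------------------------------
# tensor core


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = _parents
        self._backward = _backward

    # -- introspection -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs exceed the recursion limit
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()
                node._backward = None

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=self.data.dtype), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other, self.dtype)
        rg = _GRAD_ENABLED and (self.requires_grad or other.requires_grad)
        out = Tensor(self.data + other.data, rg, (self, other) if rg else ())

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = bwd if rg else None
        return out

    __radd__ = __add__

    def __neg__(self):
        rg = _GRAD_ENABLED and self.requires_grad
        out = Tensor(-self.data, rg, (self,) if rg else ())
        out._backward = (lambda g: self._accumulate(-g)) if rg else None
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.dtype)
        rg = _GRAD_ENABLED and (self.requires_grad or other.requires_grad)
        out = Tensor(self.data * other.data, rg, (self, other) if rg else ())

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = bwd if rg else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.dtype)
        rg = _GRAD_ENABLED and (self.requires_grad or other.requires_grad)
        out = Tensor(self.data / other.data, rg, (self, other) if rg else ())

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / (other.data * other.data))

        out._backward = bwd if rg else None
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other, self.dtype) / self

    def __pow__(self, exponent: float):
        rg = _GRAD_ENABLED and self.requires_grad
        out = Tensor(self.data ** exponent, rg, (self,) if rg else ())
        if rg:
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1)
            )
        return out

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other, self.dtype))

    def __getitem__(self, idx):
        rg = _GRAD_ENABLED and self.requires_grad
        out = Tensor(self.data[idx], rg, (self,) if rg else ())

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bwd if rg else None
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        rg = _GRAD_ENABLED and self.requires_grad
        out = Tensor(self.data.reshape(shape), rg, (self,) if rg else ())
        out._backward = (
            (lambda g: self._accumulate(g.reshape(self.data.shape))) if rg else None
        )
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        rg = _GRAD_ENABLED and self.requires_grad
        out = Tensor(self.data.transpose(axes), rg, (self,) if rg else ())
        out._backward = (
            (lambda g: self._accumulate(g.transpose(inv))) if rg else None
        )
        return out

    # -- reductions & pointwise --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        rg = _GRAD_ENABLED and self.requires_grad
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), rg, (self,) if rg else ())

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bwd if rg else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def exp(self):
        rg = _GRAD_ENABLED and self.requires_grad
        val = np.exp(self.data)
        out = Tensor(val, rg, (self,) if rg else ())
        out._backward = (lambda g: self._accumulate(g * val)) if rg else None
        return out


def _as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype and np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    elif dtype is not None and not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    return Tensor(arr)


# ---------------------------------------------------------------------------
# functional primitives


def log(x: Tensor) -> Tensor:
    rg = _GRAD_ENABLED and x.requires_grad
    out = Tensor(np.log(x.data), rg, (x,) if rg else ())
    out._backward = (lambda g: x._accumulate(g / x.data)) if rg else None
    return out


def maximum(x: Tensor, floor: float) -> Tensor:
    """Elementwise max(x, floor); gradient passes only where x > floor."""
    rg = _GRAD_ENABLED and x.requires_grad
    mask = x.data > floor
    out = Tensor(np.maximum(x.data, floor), rg, (x,) if rg else ())
    out._backward = (lambda g: x._accumulate(g * mask)) if rg else None
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    rg = _GRAD_ENABLED and (a.requires_grad or b.requires_grad)
    val = a.data @ b.data
    _record_flops(2 * val.size * a.data.shape[-1])
    out = Tensor(val, rg, (a, b) if rg else ())

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    out._backward = bwd if rg else None
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    rg = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        rg,
        tuple(tensors) if rg else (),
    )

    def bwd(g):
        splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bwd if rg else None
    return out


_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-linear unit: x * Phi(x)."""
    rg = _GRAD_ENABLED and x.requires_grad
    phi = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out = Tensor(x.data * phi, rg, (x,) if rg else ())

    def bwd(g):
        pdf = np.exp(-0.5 * x.data * x.data) * _INV_SQRT2PI
        x._accumulate(g * (phi + x.data * pdf))

    out._backward = bwd if rg else None
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    rg = _GRAD_ENABLED and x.requires_grad
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, rg, (x,) if rg else ())

    def bwd(g):
        x._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = bwd if rg else None
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    rg = _GRAD_ENABLED and (x.requires_grad or gamma.requires_grad or beta.requires_grad)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(gamma.data * xhat + beta.data, rg, (x, gamma, beta) if rg else ())

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gh = g * gamma.data
            x._accumulate(
                inv
                * (
                    gh
                    - gh.mean(axis=-1, keepdims=True)
                    - xhat * (gh * xhat).mean(axis=-1, keepdims=True)
                )
            )

    out._backward = bwd if rg else None
    return out


# ---------------------------------------------------------------------------
# 3D convolution (im2col) and transposed convolution


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError(f"expected 3 values, got {v!r}")
        return tuple(int(i) for i in v)
    return (int(v),) * 3


def conv3d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride=1,
    padding=0,
    groups: int = 1,
) -> Tensor:
    """Grouped strided 3D cross-correlation.

    x: (Cin, H, W, D); w: (Cout, Cin//groups, k1, k2, k3); b: (Cout,).
    Output spatial size per axis: (S + 2*pad - k)//stride + 1.
    """
    s1, s2, s3 = _triple(stride)
    p1, p2, p3 = _triple(padding)
    cout, cg, k1, k2, k3 = w.shape
    cin = x.shape[0]
    if cin != cg * groups:
        raise ValueError(
            f"conv3d channel mismatch: input has {cin} channels, "
            f"weight expects {cg * groups} (groups={groups})"
        )
    xp = np.pad(x.data, ((0, 0), (p1, p1), (p2, p2), (p3, p3)))
    win = sliding_window_view(xp, (k1, k2, k3), axis=(1, 2, 3))[:, ::s1, ::s2, ::s3]
    # win: (Cin, Ho, Wo, Do, k1, k2, k3)
    _, ho, wo, do = win.shape[:4]
    kvol = k1 * k2 * k3
    npos = ho * wo * do
    cog = cout // groups
    # cols: (G, npos, Cg*kvol)
    cols = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
        npos, groups, cg * kvol
    ).transpose(1, 0, 2)
    wg = w.data.reshape(groups, cog, cg * kvol)
    y = np.matmul(cols, wg.transpose(0, 2, 1))  # (G, npos, Cog)
    _record_flops(2 * groups * npos * cog * cg * kvol)
    y = y.transpose(0, 2, 1).reshape(cout, ho, wo, do)
    if b is not None:
        y = y + b.data.reshape(cout, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    rg = _GRAD_ENABLED and any(t.requires_grad for t in parents)
    out = Tensor(y, rg, parents if rg else ())

    def bwd(g):
        gc = g.reshape(groups, cog, npos).transpose(0, 2, 1)  # (G, npos, Cog)
        if b is not None and b.requires_grad:
            b._accumulate(g.reshape(cout, npos).sum(axis=1))
        if w.requires_grad:
            dw = np.matmul(gc.transpose(0, 2, 1), cols)  # (G, Cog, Cg*kvol)
            w._accumulate(dw.reshape(cout, cg, k1, k2, k3))
        if x.requires_grad:
            dcols = np.matmul(gc, wg)  # (G, npos, Cg*kvol)
            dcols = dcols.transpose(1, 0, 2).reshape(
                ho, wo, do, cin, k1, k2, k3
            ).transpose(3, 0, 1, 2, 4, 5, 6)
            dxp = np.zeros_like(xp)
            for i in range(k1):
                for j in range(k2):
                    for l in range(k3):
                        dxp[
                            :,
                            i : i + s1 * ho : s1,
                            j : j + s2 * wo : s2,
                            l : l + s3 * do : s3,
                        ] += dcols[..., i, j, l]
            h, ww_, d = x.shape[1:]
            x._accumulate(dxp[:, p1 : p1 + h, p2 : p2 + ww_, p3 : p3 + d])

    out._backward = bwd if rg else None
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=2) -> Tensor:
    """Transposed 3D convolution with kernel size equal to stride.

    The non-overlapping case (kernel == stride) used for x2 upsampling:
    each input voxel expands into a k1 x k2 x k3 output block.
    x: (Cin, H, W, D); w: (Cin, Cout, k1, k2, k3).
    """
    k1, k2, k3 = _triple(stride)
    cin, cout = w.shape[0], w.shape[1]
    if w.shape[2:] != (k1, k2, k3):
        raise ValueError("conv_transpose3d requires kernel size == stride")
    if x.shape[0] != cin:
        raise ValueError(
            f"conv_transpose3d channel mismatch: input {x.shape[0]}, weight {cin}"
        )
    h, ww_, d = x.shape[1:]
    t = np.tensordot(x.data, w.data, axes=([0], [0]))  # (H,W,D,Cout,k1,k2,k3)
    _record_flops(2 * h * ww_ * d * cin * cout * k1 * k2 * k3)
    y = t.transpose(3, 0, 4, 1, 5, 2, 6).reshape(cout, h * k1, ww_ * k2, d * k3)
    if b is not None:
        y = y + b.data.reshape(cout, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    rg = _GRAD_ENABLED and any(t_.requires_grad for t_ in parents)
    out = Tensor(y, rg, parents if rg else ())

    def bwd(g):
        gt = g.reshape(cout, h, k1, ww_, k2, d, k3).transpose(1, 3, 5, 0, 2, 4, 6)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))
        if w.requires_grad:
            w._accumulate(np.tensordot(x.data, gt, axes=([1, 2, 3], [0, 1, 2])))
        if x.requires_grad:
            x._accumulate(
                np.tensordot(gt, w.data, axes=([3, 4, 5, 6], [1, 2, 3, 4])).transpose(
                    3, 0, 1, 2
                )
            )

    out._backward = bwd if rg else None
    return out
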