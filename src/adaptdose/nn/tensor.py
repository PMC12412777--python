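"""Autodiff tape, shape proxies, and functional ops."""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An ndarray plus the tape bookkeeping to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, iter(self._parents))]
        seen.add(id(self))
        # iterative DFS (graphs can be deep)
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen and p.requires_grad:
                    seen.add(id(p))
                    stack.append((p, iter(p._parents)))
                    advanced = True
                    break
            if not advanced:
                topo.append(node)
                stack.pop()
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures as we go

    def item(self) -> float:
        return float(self.data)


class ShapeProxy:
    """Stand-in value carrying only a shape; ops propagate it symbolically."""

    __slots__ = ("shape",)

    def __init__(self, shape):
        self.shape = tuple(int(s) for s in shape)

    def __repr__(self) -> str:
        return f"ShapeProxy{self.shape}"


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise / reduction ops


def relu(x):
    if isinstance(x, ShapeProxy):
        return ShapeProxy(x.shape)
    y = np.maximum(x.data, 0.0)

    def backward(g):
        x.accumulate(g * (y > 0))

    return _make(y, (x,), backward)


def dropout(x, p: float, rng: np.random.Generator):
    """Inverted dropout; caller decides train/eval (eval: don't call)."""
    if isinstance(x, ShapeProxy):
        return ShapeProxy(x.shape)
    if p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(np.float32) / np.float32(1.0 - p)
    y = x.data * mask

    def backward(g):
        x.accumulate(g * mask)

    return _make(y, (x,), backward)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean over voxels of squared differences."""
    t = np.asarray(target, dtype=np.float32)
    if pred.data.shape != t.shape:
        raise ValueError(f"shape mismatch {pred.data.shape} vs {t.shape}")
    diff = pred.data - t
    val = np.float32(np.mean(diff.astype(np.float64) ** 2))

    def backward(g):
        pred.accumulate((2.0 / diff.size) * diff * g)

    return _make(val, (pred,), backward)


def concat(xs, axis: int = 0):
    if isinstance(xs[0], ShapeProxy):
        shape = list(xs[0].shape)
        shape[axis] = sum(x.shape[axis] for x in xs)
        return ShapeProxy(shape)
    sizes = [x.data.shape[axis] for x in xs]
    y = np.concatenate([x.data for x in xs], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for x, a, b in zip(xs, offsets[:-1], offsets[1:]):
            if x.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                x.accumulate(g[tuple(idx)])

    return _make(y, tuple(xs), backward)


# ---------------------------------------------------------------------------
# convolution


def _im2col(vol: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Column matrix (C * k^3, N) for stride-1 'same' convolution.

    Built with one near-contiguous slice copy per kernel offset, which is far
    faster than a strided transpose of the sliding-window view.
    """
    c = vol.shape[0]
    vp = np.pad(vol, ((0, 0), (pad, pad), (pad, pad), (pad, pad))) if pad else vol
    X = vp.shape[1] - k + 1
    Y = vp.shape[2] - k + 1
    Z = vp.shape[3] - k + 1
    col = np.empty((c, k**3, X, Y, Z), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                off = (i * k + j) * k + l
                col[:, off] = vp[:, i : i + X, j : j + Y, l : l + Z]
    return col.reshape(c * k**3, X * Y * Z)


def conv3d(x, w: Tensor, b: Tensor, padding: int, stem: bool = False):
    """3D convolution, stride 1.  ``w``: (Co, Ci, k, k, k); ``x``: (Ci, X, Y, Z).

    ``stem=True`` marks a network input layer: the gradient w.r.t. the input
    is skipped (the input is a leaf) and identically-zero input channels are
    pruned from the contraction — an exact optimization for sparse channel
    stacks where most roster structures are absent.
    """
    k = w.shape[-1]
    if isinstance(x, ShapeProxy):
        if x.shape[0] != w.shape[1]:
            raise ValueError(f"expected {w.shape[1]} input channels, got {x.shape[0]}")
        return ShapeProxy((w.shape[0],) + tuple(s + 2 * padding - k + 1 for s in x.shape[1:]))

    ci, X, Y, Z = x.data.shape
    if ci != w.shape[1]:
        raise ValueError(f"expected {w.shape[1]} input channels, got {ci}")
    co = w.shape[0]

    xd = x.data
    wd = w.data
    active = None
    if stem:
        active = np.flatnonzero(xd.reshape(ci, -1).any(axis=1))
        if active.size < ci:
            xd = np.ascontiguousarray(xd[active])
            wd = np.ascontiguousarray(w.data[:, active])
        else:
            active = None
    ca = xd.shape[0]

    if k == 1:
        col = xd.reshape(ca, -1)  # (Ca, N)
    else:
        col = _im2col(xd, k, padding)  # (Ca*k^3, N)
    out = wd.reshape(co, -1) @ col
    out += b.data[:, None]
    y = out.reshape(co, X, Y, Z)

    def backward(g):
        gf = g.reshape(co, -1)
        gw = gf @ col.T  # (Co, Ca*k^3)
        if active is not None:
            gwf = np.zeros((co, ci) + w.data.shape[2:], dtype=np.float32)
            gwf[:, active] = gw.reshape((co, ca) + w.data.shape[2:])
            w.accumulate(gwf)
        else:
            w.accumulate(gw.reshape(w.data.shape))
        b.accumulate(gf.sum(axis=1))
        if x.requires_grad and not stem:
            if k == 1:
                gx = (wd.reshape(co, ca).T @ gf).reshape(ca, X, Y, Z)
            else:
                # input gradient = correlation of g with the flipped kernel
                wflip = np.ascontiguousarray(
                    wd[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                ).reshape(ca, -1)  # (Ca, Co*k^3)
                col_g = _im2col(g, k, padding)  # (Co*k^3, N)
                gx = (wflip @ col_g).reshape(ca, X, Y, Z)
            x.accumulate(gx)

    return _make(y, (x, w, b), backward)


def conv_transpose3d_2x(x, w: Tensor, b: Tensor):
    """Transposed convolution, kernel 2, stride 2.  ``w``: (Co, Ci, 2, 2, 2)."""
    if isinstance(x, ShapeProxy):
        if x.shape[0] != w.shape[1]:
            raise ValueError(f"expected {w.shape[1]} input channels, got {x.shape[0]}")
        return ShapeProxy((w.shape[0],) + tuple(2 * s for s in x.shape[1:]))
    ci, X, Y, Z = x.data.shape
    co = w.shape[0]
    t = np.tensordot(w.data, x.data, axes=([1], [0]))  # (Co,2,2,2,X,Y,Z)
    y = np.ascontiguousarray(t.transpose(0, 4, 1, 5, 2, 6, 3)).reshape(
        co, 2 * X, 2 * Y, 2 * Z
    )
    y += b.data[:, None, None, None]

    def backward(g):
        gt = g.reshape(co, X, 2, Y, 2, Z, 2).transpose(0, 2, 4, 6, 1, 3, 5)
        gw = np.tensordot(gt, x.data, axes=([4, 5, 6], [1, 2, 3]))  # (Co,2,2,2,Ci)
        w.accumulate(gw.transpose(0, 4, 1, 2, 3))
        b.accumulate(g.reshape(co, -1).sum(axis=1))
        if x.requires_grad:
            gx = np.tensordot(w.data, gt, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
            x.accumulate(gx)

    return _make(y, (x, w, b), backward)


# ---------------------------------------------------------------------------
# pooling and upsampling


def _pool_shape(shape):
    c, X, Y, Z = shape
    if X % 2 or Y % 2 or Z % 2:
        raise ValueError(f"pooling requires even spatial dims, got {shape}")
    return c, X // 2, Y // 2, Z // 2


def maxpool2(x):
    if isinstance(x, ShapeProxy):
        return ShapeProxy(_pool_shape(x.shape))
    c, X2, Y2, Z2 = _pool_shape(x.data.shape)
    xr = np.ascontiguousarray(
        x.data.reshape(c, X2, 2, Y2, 2, Z2, 2).transpose(0, 1, 3, 5, 2, 4, 6)
    ).reshape(c, X2, Y2, Z2, 8)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        g8 = np.zeros((c, X2, Y2, Z2, 8), dtype=np.float32)
        np.put_along_axis(g8, idx[..., None], g[..., None], axis=-1)
        gx = (
            g8.reshape(c, X2, Y2, Z2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(x.data.shape)
        )
        x.accumulate(gx)

    return _make(y, (x,), backward)


def avgpool2(x):
    if isinstance(x, ShapeProxy):
        return ShapeProxy(_pool_shape(x.shape))
    c, X2, Y2, Z2 = _pool_shape(x.data.shape)
    y = x.data.reshape(c, X2, 2, Y2, 2, Z2, 2).mean(axis=(2, 4, 6))

    def backward(g):
        gx = np.broadcast_to(
            g[:, :, None, :, None, :, None] * np.float32(1 / 8),
            (c, X2, 2, Y2, 2, Z2, 2),
        ).reshape(x.data.shape)
        x.accumulate(gx)

    return _make(y, (x,), backward)


def upsample_nearest2(x):
    if isinstance(x, ShapeProxy):
        return ShapeProxy((x.shape[0],) + tuple(2 * s for s in x.shape[1:]))
    y = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        c, X, Y, Z = x.data.shape
        gx = g.reshape(c, X, 2, Y, 2, Z, 2).sum(axis=(2, 4, 6))
        x.accumulate(gx)

    return _make(y, (x,), backward)


def _linear_up_axis(a: np.ndarray, axis: int) -> np.ndarray:
    """Double one axis with half-pixel-centre linear interpolation.

    out[2k] = 0.75 a[k] + 0.25 a[k-1];  out[2k+1] = 0.75 a[k] + 0.25 a[k+1]
    (edge-clamped), i.e. output samples sit at input coordinates k -/+ 0.25.
    """
    a = np.moveaxis(a, axis, -1)
    left = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
    right = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
    even = 0.75 * a + 0.25 * left
    odd = 0.75 * a + 0.25 * right
    out = np.stack([even, odd], axis=-1).reshape(a.shape[:-1] + (2 * a.shape[-1],))
    return np.moveaxis(out, -1, axis)


def _linear_up_axis_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    n2 = g.shape[-1]
    gr = g.reshape(g.shape[:-1] + (n2 // 2, 2))
    ge, go = gr[..., 0], gr[..., 1]
    ga = 0.75 * (ge + go)
    ga[..., :-1] += 0.25 * ge[..., 1:]
    ga[..., 0] += 0.25 * ge[..., 0]
    ga[..., 1:] += 0.25 * go[..., :-1]
    ga[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(ga, -1, axis)


def upsample_trilinear2(x):
    if isinstance(x, ShapeProxy):
        return ShapeProxy((x.shape[0],) + tuple(2 * s for s in x.shape[1:]))
    y = x.data
    for ax in (1, 2, 3):
        y = _linear_up_axis(y, ax)
    y = y.astype(np.float32, copy=False)

    def backward(g):
        for ax in (3, 2, 1):
            g = _linear_up_axis_adjoint(g, ax)
        x.accumulate(g.astype(np.float32, copy=False))

    return _make(y, (x,), backward)


# ---------------------------------------------------------------------------
# normalization


def groupnorm(x, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5):
    if isinstance(x, ShapeProxy):
        return ShapeProxy(x.shape)
    c = x.data.shape[0]
    if c % groups:
        raise ValueError(f"group count {groups} does not divide {c} channels")
    xg = x.data.reshape(groups, -1)
    mu = xg.mean(axis=1, keepdims=True)
    var = xg.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(x.data.shape)
    y = xhat * gamma.data[:, None, None, None] + beta.data[:, None, None, None]

    def backward(g):
        gamma.accumulate((g * xhat).reshape(c, -1).sum(axis=1))
        beta.accumulate(g.reshape(c, -1).sum(axis=1))
        if x.requires_grad:
            dxhat = (g * gamma.data[:, None, None, None]).reshape(groups, -1)
            xh = xhat.reshape(groups, -1)
            m1 = dxhat.mean(axis=1, keepdims=True)
            m2 = (dxhat * xh).mean(axis=1, keepdims=True)
            gx = (inv * (dxhat - m1 - xh * m2)).reshape(x.data.shape)
            x.accumulate(gx.astype(np.float32, copy=False))

    return _make(y, (x, gamma, beta), backward)
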