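"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the compute backend for the network modules.  It implements only the
primitives the architecture needs — channel-mixing 2-D convolution with
same-padding, a shared-filter 1-D convolution along the channel axis, batch
normalisation, batched matrix products, softmax, element-wise gates, pooling
and a fused softmax/cross-entropy loss — each with a hand-written backward
pass.  Feature maps are stored channel-first as ``(C, B, H, W)`` so that a
convolution tap reduces to one large ``(O, C) @ (C, B*H*W)`` GEMM.

Gradient correctness is enforced by finite-difference checks in the test
suite; every op is dtype-agnostic (float64 in the checks, float32 in
training).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "add",
    "mul",
    "matmul",
    "conv_mix",
    "conv1d_channel",
    "sigmoid",
    "relu",
    "mean",
    "batchnorm",
    "softmax",
    "scaled_attention",
    "reshape",
    "moveaxis",
    "concat",
    "avgpool_w2",
    "maxpool_w2",
    "cross_entropy_with_logits",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (used for evaluation passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class _Arena:
    """Step-scoped buffer recycler.

    Mini-batch training repeats an identical sequence of array shapes every
    optimisation step; allocating those multi-megabyte buffers fresh each
    time costs far more (page-zeroing faults) than the arithmetic on them.
    Inside an :func:`arena` context, ``empty``/``zeros`` hand back the buffer
    that served the same (shape, dtype) slot in the previous step.
    ``next_step`` rewinds the cursors once the previous step's graph is dead.
    """

    def __init__(self):
        self.enabled = False
        self._stacks: dict[tuple, list[np.ndarray]] = {}
        self._cursor: dict[tuple, int] = {}

    def empty(self, shape, dtype) -> np.ndarray:
        if not self.enabled:
            return np.empty(shape, dtype)
        key = (tuple(np.atleast_1d(shape)) if not isinstance(shape, tuple) else shape,
               np.dtype(dtype).str)
        stack = self._stacks.setdefault(key, [])
        i = self._cursor.get(key, 0)
        self._cursor[key] = i + 1
        if i < len(stack):
            return stack[i]
        arr = np.empty(key[0], dtype)
        stack.append(arr)
        return arr

    def zeros(self, shape, dtype) -> np.ndarray:
        arr = self.empty(shape, dtype)
        arr[...] = 0
        return arr

    def next_step(self) -> None:
        for key in self._cursor:
            self._cursor[key] = 0

    def clear(self) -> None:
        self._stacks.clear()
        self._cursor.clear()


ARENA = _Arena()


@contextlib.contextmanager
def arena():
    """Enable buffer recycling for a training/evaluation loop."""
    prev = ARENA.enabled
    ARENA.enabled = True
    try:
        yield ARENA
    finally:
        ARENA.enabled = prev
        if not prev:
            ARENA.clear()


def _empty(shape, dtype):
    return ARENA.empty(shape if isinstance(shape, tuple) else tuple(shape), dtype)


def _zeros(shape, dtype):
    return ARENA.zeros(shape if isinstance(shape, tuple) else tuple(shape), dtype)


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data: np.ndarray, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {
            id(self): np.ones_like(self.data)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                # leaf parameter
                node.grad = g if node.grad is None else node.grad + g
                continue
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if pg is None:
                    continue
                if parent._backward is None and not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves reached exactly once are handled in the loop; remaining grads
        # belong to leaf parameters encountered without further parents
        for node in topo:
            g = grads.pop(id(node), None)
            if g is not None and node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    # conveniences used by layers/tests -------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, other: "Tensor") -> "Tensor":
        return mul(self, other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def tensor(data, requires_grad: bool = False, dtype=None) -> Tensor:
    arr = np.asarray(data, dtype=dtype)
    return Tensor(arr, requires_grad=requires_grad)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(
        p.requires_grad or p._backward is not None for p in parents
    ):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _binary_out(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    shape = np.broadcast_shapes(a.shape, b.shape)
    return _empty(shape, np.result_type(a.dtype, b.dtype))


def add(a: Tensor, b: Tensor) -> Tensor:
    data = np.add(a.data, b.data, out=_binary_out(a.data, b.data))

    def backward(g):
        return (
            (a, _unbroadcast(g, a.data.shape)),
            (b, _unbroadcast(g, b.data.shape)),
        )

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = np.multiply(a.data, b.data, out=_binary_out(a.data, b.data))

    def backward(g):
        def grad_for(other, target):
            if g.shape == other.shape == target.shape:
                out = np.multiply(g, other, out=_empty(g.shape, g.dtype))
            else:
                out = g * other
            return _unbroadcast(out, target.shape)

        return ((a, grad_for(b.data, a.data)), (b, grad_for(a.data, b.data)))

    return _make(data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    data = a.data * c

    def backward(g):
        return ((a, g * c),)

    return _make(data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product; 2-D operands or identically batched 3-D operands."""
    shape = np.broadcast_shapes(a.data.shape[:-2], b.data.shape[:-2]) + (
        a.data.shape[-2],
        b.data.shape[-1],
    )
    data = np.matmul(a.data, b.data, out=_empty(shape, np.result_type(a.dtype, b.dtype)))

    def backward(g):
        bt = np.swapaxes(b.data, -1, -2)
        at = np.swapaxes(a.data, -1, -2)
        ga_shape = np.broadcast_shapes(g.shape[:-2], bt.shape[:-2]) + (g.shape[-2], bt.shape[-1])
        gb_shape = np.broadcast_shapes(at.shape[:-2], g.shape[:-2]) + (at.shape[-2], g.shape[-1])
        ga = np.matmul(g, bt, out=_empty(ga_shape, np.result_type(g.dtype, bt.dtype)))
        gb = np.matmul(at, g, out=_empty(gb_shape, np.result_type(at.dtype, g.dtype)))
        return ((a, _unbroadcast(ga, a.data.shape)), (b, _unbroadcast(gb, b.data.shape)))

    return _make(data, (a, b), backward)


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def conv_mix(x: Tensor, w: Tensor, b: Tensor | None, kh: int, kw: int) -> Tensor:
    """Channel-mixing 2-D convolution with symmetric zero same-padding.

    ``x`` is ``(C, B, H, W)``, ``w`` is ``(O, C, kh, kw)``, ``b`` is ``(O,)``
    or None.  Stride 1; output ``(O, B, H, W)``.  Dispatches to the fused
    cache-tiled kernels in :mod:`efccnet._kernels`.
    """
    from . import _kernels

    C, B, H, W = x.data.shape
    O = w.data.shape[0]
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    pointwise = kh == 1 and kw == 1
    wd = np.ascontiguousarray(w.data)

    def padded(src: np.ndarray) -> np.ndarray:
        if pointwise:
            return np.ascontiguousarray(src)
        buf = _zeros((C, B, H + kh - 1, W + kw - 1), src.dtype)
        buf[:, :, ph : ph + H, pw : pw + W] = src
        return buf

    y = _zeros((O, B, H, W), x.data.dtype)
    _kernels.conv_fwd(padded(x.data), wd, y)
    if b is not None:
        y += b.data.reshape(O, 1, 1, 1)

    x_needs_grad = x.requires_grad or x._backward is not None

    def backward(g):
        if not (g.flags.c_contiguous and g.dtype == wd.dtype):
            g = np.ascontiguousarray(g, dtype=wd.dtype)
        gw = np.zeros_like(wd)
        _kernels.conv_bwd_w(g, padded(x.data), gw)
        if x_needs_grad:
            gxp = _zeros(
                (C, B, H + kh - 1, W + kw - 1) if not pointwise else (C, B, H, W),
                g.dtype,
            )
            _kernels.conv_bwd_x(g, wd, gxp)
            gx = gxp if pointwise else gxp[:, :, ph : ph + H, pw : pw + W]
        else:
            gx = None
        out = [(x, gx), (w, gw)]
        if b is not None:
            out.append((b, g.sum(axis=(1, 2, 3))))
        return out

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, backward)


def conv1d_channel(x: Tensor, w: Tensor) -> Tensor:
    """Shared-filter 1-D convolution along the channel axis (no bias).

    ``x`` is ``(C, B)`` (pooled channel statistics per sample), ``w`` is a
    single filter ``(k,)``; zero padding ``(k-1)//2`` keeps C unchanged.
    """
    C, B = x.data.shape
    k = w.data.shape[0]
    p = (k - 1) // 2
    xp = np.pad(x.data, ((p, k - 1 - p), (0, 0)))
    y = np.zeros_like(x.data)
    for j in range(k):
        y += w.data[j] * xp[j : j + C]

    def backward(g):
        gxp = np.zeros_like(xp)
        gw = np.empty_like(w.data)
        for j in range(k):
            gw[j] = np.sum(g * xp[j : j + C])
            gxp[j : j + C] += w.data[j] * g
        return ((x, gxp[p : p + C]), (w, gw))

    return _make(y, (x, w), backward)


# ---------------------------------------------------------------------------
# element-wise and reduction ops
# ---------------------------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    s = _sigmoid_np(x.data)

    def backward(g):
        return ((x, g * s * (1.0 - s)),)

    return _make(s, (x,), backward)


def _sigmoid_np(x: np.ndarray) -> np.ndarray:
    # numerically stable two-sided form
    out = np.empty_like(x, dtype=x.dtype if x.dtype.kind == "f" else np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: Tensor) -> Tensor:
    data = np.maximum(x.data, 0, out=_empty(x.data.shape, x.data.dtype))

    def backward(g):
        out = np.multiply(g, x.data > 0, out=_empty(g.shape, g.dtype))
        return ((x, out),)

    return _make(data, (x,), backward)


def mean(x: Tensor, axes: tuple[int, ...], keepdims: bool = True) -> Tensor:
    data = x.data.mean(axis=axes, keepdims=keepdims)
    n = int(np.prod([x.data.shape[a] for a in axes]))

    def backward(g):
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axes)
        out = np.divide(
            np.broadcast_to(gg, x.data.shape), n, out=_empty(x.data.shape, g.dtype)
        )
        return ((x, out),)

    return _make(data, (x,), backward)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation for ``(C, B, H, W)`` maps.

    ``gamma``/``beta`` are ``(C, 1, 1, 1)``; running statistics are updated
    in place during training and used verbatim in evaluation.
    """
    axes = (1, 2, 3)
    if training:
        mu = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
        n = x.data.size // x.data.shape[0]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu = running_mean
        var = running_var
    inv = 1.0 / np.sqrt(var + eps)
    data = np.subtract(x.data, mu, out=_empty(x.data.shape, x.data.dtype))
    data *= inv
    data *= gamma.data
    data += beta.data
    mu = np.array(mu, copy=True)  # snapshot: running buffers mutate across batches

    def backward(g):
        # xhat recomputed to avoid retaining a second map-sized array
        xhat = np.subtract(x.data, mu, out=_empty(x.data.shape, x.data.dtype))
        xhat *= inv
        prod = np.multiply(g, xhat, out=_empty(g.shape, g.dtype))
        ggamma = prod.sum(axis=axes, keepdims=True)
        gbeta = g.sum(axis=axes, keepdims=True)
        if training:
            gxhat = np.multiply(g, gamma.data, out=prod)  # prod no longer needed
            m1 = gxhat.mean(axis=axes, keepdims=True)
            m2 = np.multiply(gxhat, xhat, out=_empty(g.shape, g.dtype)).mean(
                axis=axes, keepdims=True
            )
            xhat *= m2
            gx = gxhat
            gx -= m1
            gx -= xhat
            gx *= inv
        else:
            gx = np.multiply(g, gamma.data * inv, out=_empty(g.shape, g.dtype))
        return ((x, gx), (gamma, ggamma), (beta, gbeta))

    return _make(data, (x, gamma, beta), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return ((x, s * (g - dot)),)

    return _make(s, (x,), backward)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    data = x.data.reshape(shape)

    def backward(g):
        return ((x, g.reshape(x.data.shape)),)

    return _make(data, (x,), backward)


def moveaxis(x: Tensor, src: int, dst: int) -> Tensor:
    view = np.moveaxis(x.data, src, dst)
    data = _empty(view.shape, x.data.dtype)
    np.copyto(data, view)

    def backward(g):
        return ((x, np.moveaxis(g, dst, src)),)

    return _make(data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = list(tensors)
    shape = list(ts[0].data.shape)
    shape[axis] = sum(t.data.shape[axis] for t in ts)
    out = _empty(tuple(shape), np.result_type(*(t.dtype for t in ts)))
    data = np.concatenate([t.data for t in ts], axis=axis, out=out)
    sizes = [t.data.shape[axis] for t in ts]

    def backward(g):
        outs = []
        start = 0
        for t, s in zip(ts, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            outs.append((t, g[tuple(sl)]))
            start += s
        return outs

    return _make(data, ts, backward)


# ---------------------------------------------------------------------------
# pooling along the time (last) axis
# ---------------------------------------------------------------------------

def _trim_even(x: np.ndarray) -> np.ndarray:
    W = x.shape[-1]
    return x[..., : W - (W % 2)]


def avgpool_w2(x: Tensor) -> Tensor:
    xt = _trim_even(x.data)
    shp = xt.shape[:-1] + (xt.shape[-1] // 2, 2)
    data = xt.reshape(shp).mean(axis=-1)

    def backward(g):
        gx = _zeros(x.data.shape, g.dtype)
        n2 = g.shape[-1]
        gx[..., 0 : 2 * n2 : 2] = g
        gx[..., 1 : 2 * n2 : 2] = g
        gx[..., : 2 * n2] *= 0.5
        return ((x, gx),)

    return _make(data, (x,), backward)


def maxpool_w2(x: Tensor) -> Tensor:
    xt = _trim_even(x.data)
    shp = xt.shape[:-1] + (xt.shape[-1] // 2, 2)
    pairs = xt.reshape(shp)
    idx = pairs.argmax(axis=-1)
    data = np.take_along_axis(pairs, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gp = np.zeros(shp, dtype=g.dtype)
        np.put_along_axis(gp, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[..., : shp[-2] * 2] = gp.reshape(shp[:-2] + (shp[-2] * 2,))
        return ((x, gx),)

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------------
# fused scaled dot-product attention over channel tokens
# ---------------------------------------------------------------------------

def scaled_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(q kᵀ / sqrt(d_k)) v for batched token matrices ``(B, C, d_k)``.

    Equivalent to ``matmul``/``softmax``/``matmul`` composition but runs the
    three batched products through the fused kernels and keeps only the small
    ``(B, C, C)`` attention matrix for the backward pass.
    """
    from . import _kernels

    Bn, C, dk = q.data.shape
    if dk == 0:
        raise ValueError("d_k must be positive")
    scale = 1.0 / np.sqrt(dk)
    pre = _empty((Bn, C, C), q.data.dtype)
    _kernels.bmm_nt(q.data, k.data, pre)
    pre *= scale
    pre -= pre.max(axis=-1, keepdims=True)
    np.exp(pre, out=pre)
    pre /= pre.sum(axis=-1, keepdims=True)
    S = pre  # (B, C, C) attention weights, rows sum to 1
    z = _zeros((Bn, C, dk), q.data.dtype)
    _kernels.bmm_nn(S, v.data, z)

    def backward(g):
        if not g.flags.c_contiguous:
            g = np.ascontiguousarray(g)
        gS = np.empty((Bn, C, C), g.dtype)
        _kernels.bmm_nt(g, v.data, gS)
        gv = _zeros((Bn, C, dk), g.dtype)
        _kernels.bmm_tn(S, g, gv)
        dot = (gS * S).sum(axis=-1, keepdims=True)
        gpre = S * (gS - dot)
        gpre *= scale
        gpre = gpre.astype(q.data.dtype, copy=False)
        gq = _zeros((Bn, C, dk), q.data.dtype)
        _kernels.bmm_nn(gpre, k.data, gq)
        gk = _zeros((Bn, C, dk), q.data.dtype)
        _kernels.bmm_tn(gpre, q.data, gk)
        return ((q, gq), (k, gk), (v, gv))

    return _make(z, (q, k, v), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``logits`` is ``(B, K)``, labels int ``(B,)``."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    B = logits.data.shape[0]
    loss = -logp[np.arange(B), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(B), labels] -= 1.0
        return ((logits, g * p / B),)

    return _make(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)
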