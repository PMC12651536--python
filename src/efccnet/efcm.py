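"""EEG Feature Calculation Module (EFCM).

One EFCM block refines a deep EEG feature map ``X`` of shape ``C x H x W``
(C learned channels, H electrodes, W time samples) without changing its
shape.  It runs up to three parallel branches, each with a different strip
kernel size ``k`` (default 3, 5, 7):

* local stage — a ``1 x k`` strip convolution along time followed by a
  ``k x 1`` strip convolution across electrodes, then an efficient-channel
  attention gate (global average pool, shared 3-tap channel filter, logistic
  gate) and a spatial attention gate (channel mean, 3x3 filter, logistic
  gate), with a residual connection back to the branch input;
* global stage — three unshared point-wise (1x1) projections produce Q, K, V
  which are flattened to ``C x (H*W)`` tokens; single-head scaled dot-product
  self-attention mixes the C channel tokens; the result is reshaped back and
  added residually.

Branch outputs are concatenated along channels and fused by one point-wise
convolution back to C channels, so the block is shape-preserving end to end.

Every component (convolution / self-attention / residual, and the strip
directions) can be toggled per branch for ablation studies.  The module also
exposes small pure-numpy reference operations (full 2-D convolution, the
logistic function, scaled dot-product attention) used as test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from .layers import BatchNorm2d, ChannelConv1d, Conv2dMix, Module

__all__ = [
    "BranchSpec",
    "default_branch_specs",
    "conv2d_full",
    "sigmoid",
    "residual_add",
    "scaled_dot_attention",
    "StripConv",
    "LocalBranchConv",
    "ChannelAttention",
    "SpatialAttention",
    "GlobalBranch",
    "EFCMBranch",
    "EFCMBlock",
]

_DIRECTIONS = ("time_only", "space_only", "both")


@dataclass
class BranchSpec:
    """Configuration of one EFCM branch.

    ``directions`` selects which strip-convolution factors run: ``both``
    applies ``1 x k`` along time then ``k x 1`` across electrodes;
    ``time_only``/``space_only`` keep a single factor (direction ablation).
    ``use_conv``/``use_attention``/``use_residual`` toggle the local
    convolution stage, the global self-attention stage, and the residual
    connections (component ablation); a residual needs a partner stage.
    """

    index: int = 1
    kernel: int = 3
    directions: str = "both"
    use_conv: bool = True
    use_attention: bool = True
    use_residual: bool = True
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and positive, got {self.kernel}")
        if self.directions not in _DIRECTIONS:
            raise ValueError(f"directions must be one of {_DIRECTIONS}")
        if self.use_residual and not (self.use_conv or self.use_attention):
            raise ValueError(
                "a residual connection requires the convolution or "
                "self-attention stage to be enabled"
            )


def default_branch_specs(kernels=(3, 5, 7)) -> list[BranchSpec]:
    return [BranchSpec(index=i + 1, kernel=k) for i, k in enumerate(kernels)]


# ---------------------------------------------------------------------------
# pure-numpy reference operations
# ---------------------------------------------------------------------------

def conv2d_full(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Full 2-D convolution by the literal double sum (reference oracle).

    For ``X`` of shape ``(P, Q)`` and kernel ``Y`` of shape ``(M, N)`` the
    output ``W`` has shape ``(P+M-1, Q+N-1)`` with
    ``W(i, j) = sum_m sum_n X(m, n) * Y(i-m, j-n)``.  Deliberately naive —
    learned same-padded convolutions must match its centre crop.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.size == 0 or Y.size == 0:
        raise ValueError(
            f"conv2d_full needs non-empty 2-D inputs, got {X.shape} and {Y.shape}"
        )
    P, Q = X.shape
    M, N = Y.shape
    out = np.zeros((P + M - 1, Q + N - 1))
    for i in range(P + M - 1):
        for j in range(Q + N - 1):
            acc = 0.0
            for m in range(max(0, i - M + 1), min(P, i + 1)):
                for n in range(max(0, j - N + 1), min(Q, j + 1)):
                    acc += X[m, n] * Y[i - m, j - n]
            out[i, j] = acc
    return out


def conv2d_same_crop(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Centre crop of :func:`conv2d_full` back to the shape of ``X``."""
    full = conv2d_full(X, np.flip(Y))  # flip: correlation convention of the layers
    M, N = np.asarray(Y).shape
    return full[(M - 1) // 2 : (M - 1) // 2 + X.shape[0], (N - 1) // 2 : (N - 1) // 2 + X.shape[1]]


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x))."""
    return T._sigmoid_np(np.asarray(x, dtype=np.float64))


def residual_add(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    B = np.asarray(B)
    if A.shape != B.shape:
        raise ValueError(f"residual shapes differ: {A.shape} vs {B.shape}")
    return A + B


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray, return_weights: bool = False):
    """Single-head scaled dot-product attention over C channel tokens.

    ``Q``, ``K``, ``V`` have identical shape ``(C, d_k)``; the attention
    matrix ``softmax(Q K^T / sqrt(d_k))`` is ``C x C`` with rows summing
    to 1, and the result is its product with ``V``.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape != K.shape or Q.shape != V.shape:
        raise ValueError("Q, K, V must share one shape")
    d_k = Q.shape[-1]
    if d_k == 0:
        raise ValueError("d_k must be positive")
    A = Q @ K.T / np.sqrt(d_k)
    A -= A.max(axis=-1, keepdims=True)
    E = np.exp(A)
    S = E / E.sum(axis=-1, keepdims=True)
    Z = S @ V
    return (Z, S) if return_weights else Z


# ---------------------------------------------------------------------------
# learnable components (layout: (C, B, H, W))
# ---------------------------------------------------------------------------

class StripConv(Module):
    """Learned strip convolution: ``1 x k`` (time) or ``k x 1`` (space)."""

    def __init__(
        self,
        channels: int,
        k: int,
        direction: str,
        out_channels: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        if direction not in ("time", "space"):
            raise ValueError("direction must be 'time' or 'space'")
        if k % 2 == 0 or k < 1:
            raise ValueError(f"strip kernel must be odd and positive, got {k}")
        out_channels = channels if out_channels is None else out_channels
        kh, kw = (1, k) if direction == "time" else (k, 1)
        self.direction = direction
        self.conv = Conv2dMix(channels, out_channels, kh, kw, bias=True, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x)


class LocalBranchConv(Module):
    """Strip-convolution factors of one branch, optionally normalised.

    With ``directions='both'`` the ``1 x k`` time factor runs first, then the
    ``k x 1`` electrode factor.  ``use_norm`` inserts batch normalisation and
    a ReLU after each factor (off in strict mode).
    """

    def __init__(
        self,
        channels: int,
        k: int,
        directions: str = "both",
        use_norm: bool = True,
        rng: np.random.Generator | None = None,
    ):
        self.directions = directions
        self.use_norm = use_norm
        self.time_conv = (
            StripConv(channels, k, "time", rng=rng) if directions in ("both", "time_only") else None
        )
        self.time_norm = BatchNorm2d(channels) if (self.time_conv and use_norm) else None
        self.space_conv = (
            StripConv(channels, k, "space", rng=rng)
            if directions in ("both", "space_only")
            else None
        )
        self.space_norm = BatchNorm2d(channels) if (self.space_conv and use_norm) else None

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        if self.time_conv is not None:
            h = self.time_conv(h)
            if self.time_norm is not None:
                h = T.relu(self.time_norm(h))
        if self.space_conv is not None:
            h = self.space_conv(h)
            if self.space_norm is not None:
                h = T.relu(self.space_norm(h))
        return h


class ChannelAttention(Module):
    """Efficient channel attention: GAP -> shared 3-tap filter -> logistic gate."""

    def __init__(self, k: int = 3, rng: np.random.Generator | None = None):
        self.filter = ChannelConv1d(k, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        C, B = x.shape[0], x.shape[1]
        pooled = T.mean(x, axes=(2, 3), keepdims=False)  # (C, B)
        gate = T.sigmoid(self.filter(pooled))
        return T.mul(x, T.reshape(gate, (C, B, 1, 1)))


class SpatialAttention(Module):
    """Spatial attention: channel mean -> 3x3 filter -> logistic gate."""

    def __init__(self, rng: np.random.Generator | None = None):
        self.conv = Conv2dMix(1, 1, 3, 3, bias=True, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[2] < 3 or x.shape[3] < 3:
            raise ValueError(f"spatial attention needs H, W >= 3, got {x.shape[2:]}")
        pooled = T.mean(x, axes=(0,), keepdims=True)  # (1, B, H, W)
        gate = T.sigmoid(self.conv(pooled))
        return T.mul(x, gate)


class GlobalBranch(Module):
    """Point-wise Q/K/V projections + channel-token self-attention + residual.

    The three 1x1 projections do not share parameters.  Feature maps are
    flattened electrode-major/time-minor to ``C x (H*W)`` tokens, attended
    over the C tokens (single head, scale ``1/sqrt(H*W)``), reshaped back in
    the same order, and added to the stage input unless the residual is
    toggled off.
    """

    def __init__(self, channels: int, use_residual: bool = True, rng: np.random.Generator | None = None):
        self.use_residual = use_residual
        self.pw_q = Conv2dMix(channels, channels, 1, 1, bias=True, rng=rng)
        self.pw_k = Conv2dMix(channels, channels, 1, 1, bias=True, rng=rng)
        self.pw_v = Conv2dMix(channels, channels, 1, 1, bias=True, rng=rng)

    def project(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Unshared point-wise projections, flattened to ``(B, C, H*W)`` tokens."""
        C, B, H, W = x.shape
        d_k = H * W
        if d_k == 0:
            raise ValueError("H*W must be positive")

        def flatten(t: Tensor) -> Tensor:
            return T.reshape(T.moveaxis(t, 0, 1), (B, C, d_k))

        return (
            flatten(self.pw_q(x)),
            flatten(self.pw_k(x)),
            flatten(self.pw_v(x)),
        )

    def __call__(self, x: Tensor) -> Tensor:
        C, B, H, W = x.shape
        d_k = H * W
        q, k, v = self.project(x)
        z = T.moveaxis(T.reshape(T.scaled_attention(q, k, v), (B, C, H, W)), 1, 0)
        return T.add(x, z) if self.use_residual else z


class EFCMBranch(Module):
    """One branch: local conv stage, residual, then global attention stage."""

    def __init__(
        self,
        channels: int,
        spec: BranchSpec,
        use_norm: bool = True,
        rng: np.random.Generator | None = None,
    ):
        self.spec = spec
        self.local = (
            LocalBranchConv(channels, spec.kernel, spec.directions, use_norm, rng=rng)
            if spec.use_conv
            else None
        )
        self.channel_attn = ChannelAttention(rng=rng) if spec.use_conv else None
        self.spatial_attn = SpatialAttention(rng=rng) if spec.use_conv else None
        self.global_branch = (
            GlobalBranch(channels, use_residual=spec.use_residual, rng=rng)
            if spec.use_attention
            else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        if self.local is not None:
            h = self.spatial_attn(self.channel_attn(self.local(x)))
            if self.spec.use_residual:
                h = T.add(x, h)
        else:
            h = x
        if self.global_branch is not None:
            return self.global_branch(h)
        return h


class EFCMBlock(Module):
    """Shape-preserving multi-branch block with point-wise fusion."""

    def __init__(
        self,
        channels: int,
        branch_specs: list[BranchSpec] | None = None,
        use_norm: bool = True,
        rng: np.random.Generator | None = None,
    ):
        specs = branch_specs if branch_specs is not None else default_branch_specs()
        enabled = [s for s in specs if s.enabled]
        if not enabled:
            raise ValueError("an EFCM block needs at least one enabled branch")
        self.channels = channels
        self.branches = [EFCMBranch(channels, s, use_norm, rng=rng) for s in enabled]
        self.fuse = Conv2dMix(len(enabled) * channels, channels, 1, 1, bias=True, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        ys = [branch(x) for branch in self.branches]
        cat = ys[0] if len(ys) == 1 else T.concat(ys, axis=0)
        return self.fuse(cat)
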