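"""Spatial squeeze-and-excitation (SSE) attention — reference forward pass.

The module chains two gates over a B x C x H x W feature map X:

1. Channel squeeze-and-excitation: a global-average-pooled descriptor
   ``z`` is mapped through a two-layer bottleneck
   ``y = sigmoid(W2 @ relu(W1 @ z + b1) + b2)`` and each channel of X is
   rescaled, ``X'_{c,i,j} = y_c * X_{c,i,j}``.
2. Spatial attention, computed ON the channel-recalibrated map: per-pixel
   max and mean over channels of X' are stacked into a 2-plane descriptor,
   convolved with a single k x k kernel (k odd, zero padding (k-1)/2) and
   squashed, ``S = sigmoid(conv(concat(max_out, avg_out)) + bias)``; the
   refined output is ``O_{c,i,j} = X'_{c,i,j} * S_{i,j}``.

Every step is explicit numpy with inspectable weights; no training happens
here.  Weights are seeded deterministically for reference fixtures and can
be round-tripped through a plain ``.npz`` archive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import correlate2d

__all__ = [
    "SSEWeights",
    "AttentionOutputs",
    "validate_feature_map",
    "init_weights",
    "save_weights",
    "load_weights",
    "global_avg_pool",
    "channel_excitation",
    "channel_recalibrate",
    "spatial_attention_map",
    "sse_forward",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-sided form
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def validate_feature_map(X: np.ndarray) -> np.ndarray:
    """Check a B x C x H x W array: 4-D, all dims >= 1, all finite."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 4:
        raise ValueError(f"feature map must be 4-D (B, C, H, W), got shape {X.shape}")
    if min(X.shape) < 1:
        raise ValueError(f"all dimensions must be >= 1, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature map contains NaN or Inf")
    return X


@dataclass
class SSEWeights:
    """Explicit parameters of the SSE module.

    ``w1``: (C/r, C) squeeze projection; ``w2``: (C, C/r) excitation
    projection (biases ``b1``, ``b2``); ``spatial_kernel``: (1, 2, k, k)
    convolution over the stacked [max, avg] planes with scalar
    ``spatial_bias``.  The bottleneck width is ``max(1, C // r)``.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    spatial_kernel: np.ndarray
    spatial_bias: float
    r: int
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        self.spatial_kernel = np.asarray(self.spatial_kernel, dtype=float)
        if self.k % 2 == 0:
            raise ValueError(f"spatial kernel size must be odd, got k={self.k}")
        c_mid, c = self.w1.shape
        if self.w2.shape != (c, c_mid):
            raise ValueError(
                f"w2 shape {self.w2.shape} inconsistent with w1 {self.w1.shape}: "
                f"expected ({c}, {c_mid})")
        if self.b1.shape != (c_mid,):
            raise ValueError(f"b1 must have shape ({c_mid},), got {self.b1.shape}")
        if self.b2.shape != (c,):
            raise ValueError(f"b2 must have shape ({c},), got {self.b2.shape}")
        if self.spatial_kernel.shape != (1, 2, self.k, self.k):
            raise ValueError(
                f"spatial_kernel must have shape (1, 2, {self.k}, {self.k}), "
                f"got {self.spatial_kernel.shape}")

    @property
    def channels(self) -> int:
        return self.w1.shape[1]


@dataclass(frozen=True)
class AttentionOutputs:
    """Every intermediate of one SSE forward pass (batch-major arrays)."""

    z: np.ndarray        # (B, C) pooled channel descriptor
    y: np.ndarray        # (B, C) channel gates in (0, 1)
    x_prime: np.ndarray  # (B, C, H, W) channel-recalibrated map
    max_out: np.ndarray  # (B, H, W)
    avg_out: np.ndarray  # (B, H, W)
    s: np.ndarray        # (B, H, W) spatial gate in (0, 1)
    o: np.ndarray        # (B, C, H, W) refined output


def init_weights(channels: int, r: int = 16, k: int = 7,
                 seed: int | None = 0) -> SSEWeights:
    """Seeded uniform[-1/sqrt(fan_in), 1/sqrt(fan_in)] initialization.

    ``r`` is the bottleneck reduction ratio (bottleneck width floored at
    one channel); ``k`` the odd spatial kernel size, default 7.
    """
    if channels < 1 or r < 1:
        raise ValueError("channels and r must be positive")
    if k % 2 == 0:
        raise ValueError(f"spatial kernel size must be odd, got k={k}")
    c_mid = max(1, channels // r)
    rng = np.random.default_rng(seed)

    def u(fan_in: int, *shape: int) -> np.ndarray:
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    return SSEWeights(
        w1=u(channels, c_mid, channels),
        b1=np.zeros(c_mid),
        w2=u(c_mid, channels, c_mid),
        b2=np.zeros(channels),
        spatial_kernel=u(2 * k * k, 1, 2, k, k),
        spatial_bias=0.0,
        r=r,
        k=k,
        seed=seed,
    )


def save_weights(path: str | Path, w: SSEWeights) -> None:
    """Serialize weights with shape metadata and the originating seed."""
    np.savez(path, w1=w.w1, b1=w.b1, w2=w.w2, b2=w.b2,
             spatial_kernel=w.spatial_kernel,
             spatial_bias=np.array(w.spatial_bias),
             r=np.array(w.r), k=np.array(w.k),
             seed=np.array(-1 if w.seed is None else w.seed))


def load_weights(path: str | Path) -> SSEWeights:
    with np.load(path) as z:
        seed = int(z["seed"])
        return SSEWeights(
            w1=z["w1"], b1=z["b1"], w2=z["w2"], b2=z["b2"],
            spatial_kernel=z["spatial_kernel"],
            spatial_bias=float(z["spatial_bias"]),
            r=int(z["r"]), k=int(z["k"]),
            seed=None if seed < 0 else seed,
        )


def global_avg_pool(X: np.ndarray) -> np.ndarray:
    """Per-batch, per-channel spatial mean: (B, C, H, W) -> (B, C)."""
    X = validate_feature_map(X)
    return X.mean(axis=(2, 3))


def channel_excitation(z: np.ndarray, w1: np.ndarray, b1: np.ndarray,
                       w2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Bottleneck gate ``y = sigmoid(w2 @ relu(w1 @ z + b1) + b2)``.

    ``z`` may be (C,) or (B, C); the result matches its leading shape.
    """
    z = np.asarray(z, dtype=float)
    squeezed = z.ndim == 1
    zb = z[None, :] if squeezed else z
    c_mid, c = np.shape(w1)
    if zb.shape[1] != c:
        raise ValueError(f"descriptor length {zb.shape[1]} does not match "
                         f"w1 input dimension {c}")
    if np.shape(w2) != (c, c_mid):
        raise ValueError(f"w2 shape {np.shape(w2)} does not match w1 {np.shape(w1)}")
    hidden = np.maximum(zb @ np.asarray(w1).T + b1, 0.0)
    y = _sigmoid(hidden @ np.asarray(w2).T + b2)
    return y[0] if squeezed else y


def channel_recalibrate(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Scale each channel: ``X'_{b,c,i,j} = y_{b,c} * X_{b,c,i,j}``."""
    X = validate_feature_map(X)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = np.broadcast_to(y, (X.shape[0], y.shape[0]))
    if y.shape != X.shape[:2]:
        raise ValueError(f"gate shape {y.shape} does not match (B, C) = {X.shape[:2]}")
    return X * y[:, :, None, None]


def spatial_attention_map(x_prime: np.ndarray, kernel: np.ndarray,
                          bias: float, k: int
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Channel-pooled descriptors and the spatial gate S.

    Returns ``(max_out, avg_out, S)`` each of shape (B, H, W).  The
    convolution is cross-correlation with stride 1 and zero padding
    (k-1)/2, so S preserves the spatial size for any odd k.
    """
    if k % 2 == 0:
        raise ValueError(f"spatial kernel size must be odd, got k={k}")
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape != (1, 2, k, k):
        raise ValueError(f"kernel must have shape (1, 2, {k}, {k}), got {kernel.shape}")
    x_prime = validate_feature_map(x_prime)
    max_out = x_prime.max(axis=1)
    avg_out = x_prime.mean(axis=1)
    s = np.empty_like(max_out)
    for b in range(x_prime.shape[0]):
        pre = (correlate2d(max_out[b], kernel[0, 0], mode="same", boundary="fill")
               + correlate2d(avg_out[b], kernel[0, 1], mode="same", boundary="fill")
               + bias)
        s[b] = _sigmoid(pre)
    return max_out, avg_out, s


def sse_forward(X: np.ndarray, w: SSEWeights) -> AttentionOutputs:
    """Full SSE forward pass: channel gate first, spatial gate on X'.

    Each batch element is processed independently.  The output O has the
    input's exact shape and is an elementwise contraction of X (both gates
    are strictly inside (0, 1) for finite inputs).
    """
    X = validate_feature_map(X)
    if X.shape[1] != w.channels:
        raise ValueError(f"input has {X.shape[1]} channels but weights expect "
                         f"{w.channels}")
    z = global_avg_pool(X)
    y = channel_excitation(z, w.w1, w.b1, w.w2, w.b2)
    x_prime = channel_recalibrate(X, y)
    max_out, avg_out, s = spatial_attention_map(
        x_prime, w.spatial_kernel, w.spatial_bias, w.k)
    o = x_prime * s[:, None, :, :]
    return AttentionOutputs(z=z, y=y, x_prime=x_prime,
                            max_out=max_out, avg_out=avg_out, s=s, o=o)
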