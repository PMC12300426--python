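"""Adaptive attention fusion: controller, channel/position branches, combiner.

The Adaptive Attention Controller (AAC) pools a feature map to a small
grid (default 8×8), runs single-head scaled dot-product self-attention
over the pooled positions, averages spatially, and maps the resulting
global descriptor through a two-layer MLP to a softmax pair
``(w1, w2)`` — one convex fusion weight pair per sample.

The two attention branches follow the dual-attention formulation:
position attention (PA) reweights spatial locations by an affinity
softmax over positions, channel attention (CA) reweights channels by an
inter-channel affinity softmax. Both are residual with a learnable scale
initialised at zero, so each branch is the identity at initialisation.

``aaf_fuse`` combines the branch outputs per sample:
``X_AAF = w1·X_PA + w2·X_CA``.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .nn import Module, Parameter, Tensor

__all__ = [
    "AdaptiveAttentionController",
    "ChannelAttention",
    "PositionAttention",
    "DualAttentionBlock",
    "aaf_fuse",
    "fixed_fusion_weights",
]


class AdaptiveAttentionController(Module):
    """Emits per-sample fusion weights (w1, w2) from a feature map.

    Parameters
    ----------
    channels:
        Channel count C of the input feature map; must be ≥ 2 (the MLP
        hidden layer has floor(C/2) units, minimum 1).
    downsample:
        Side of the pooled grid H'×W' the self-attention runs on.
    """

    def __init__(self, channels: int, downsample: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels < 2:
            raise ValueError(f"AAC requires at least 2 channels, got {channels}")
        rng = rng or np.random.default_rng(0)
        C = channels
        hidden = max(C // 2, 1)
        self.channels = C
        self.downsample = int(downsample)
        self.w_q = Parameter(nn.kaiming_uniform(rng, (C, C), C))
        self.w_k = Parameter(nn.kaiming_uniform(rng, (C, C), C))
        self.w_v = Parameter(nn.kaiming_uniform(rng, (C, C), C))
        self.w1 = Parameter(nn.kaiming_uniform(rng, (C, hidden), C))
        self.b1 = Parameter(np.zeros(hidden))
        self.w2 = Parameter(nn.kaiming_uniform(rng, (hidden, 2), hidden))
        self.b2 = Parameter(np.zeros(2))

    def forward(self, features: Tensor) -> Tensor:
        if features.ndim != 4 or features.shape[1] != self.channels:
            raise ValueError(
                f"expected B×{self.channels}×H×W features, got {features.shape}")
        B, C = features.shape[0], self.channels
        hw = self.downsample
        pooled = nn.adaptive_avg_pool2d(features, (hw, hw))      # B×C×H'×W'
        n = hw * hw
        seq = pooled.reshape(B, C, n).transpose((0, 2, 1))       # B×N×C, row-major flatten
        q = seq @ self.w_q
        k = seq @ self.w_k
        v = seq @ self.w_v
        attn = nn.softmax((q @ k.transpose((0, 2, 1))) * (1.0 / math.sqrt(C)), axis=-1)
        refined = attn @ v                                        # B×N×C
        global_feat = refined.mean(axis=1)                        # B×C
        h = nn.relu(global_feat @ self.w1 + self.b1)
        z = h @ self.w2 + self.b2
        w = nn.softmax(z, axis=-1)                                # B×2 on the simplex
        row_sums = w.data.sum(axis=-1)
        assert np.all(w.data >= 0) and np.allclose(row_sums, 1.0, atol=1e-5), \
            "fusion weights left the simplex"
        return w


class ChannelAttention(Module):
    """Reweights channels by inter-channel affinity (residual, scale init 0)."""

    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        self.gamma = Parameter(np.zeros(1))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        flat = x.reshape(B, C, H * W)                             # B×C×N
        energy = flat @ flat.transpose((0, 2, 1))                 # B×C×C
        attn = nn.softmax(energy, axis=-1)
        out = (attn @ flat).reshape(B, C, H, W)
        return x + self.gamma.reshape(1, 1, 1, 1) * out


class PositionAttention(Module):
    """Reweights spatial positions by pairwise affinity (residual, scale init 0).

    Query/key/value are 1×1 convolutions (queries and keys use C/8
    channels). The affinity over all H·W positions is quadratic in the
    number of pixels, so when H·W exceeds ``max_positions`` the keys and
    values are adaptively average-pooled to a grid of at most that many
    positions; queries stay at full resolution, so the output shape is
    unchanged.
    """

    def __init__(self, channels: int, max_positions: int = 256,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        inner = max(channels // 8, 1)
        self.query = nn.Conv2d(channels, inner, kernel=1, rng=rng)
        self.key = nn.Conv2d(channels, inner, kernel=1, rng=rng)
        self.value = nn.Conv2d(channels, channels, kernel=1, rng=rng)
        self.gamma = Parameter(np.zeros(1))
        self.max_positions = int(max_positions)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        q = self.query(x).reshape(B, -1, H * W).transpose((0, 2, 1))   # B×N×C'
        k_src, v_src = x, x
        if H * W > self.max_positions:
            side = int(math.isqrt(self.max_positions))
            k_src = nn.adaptive_avg_pool2d(x, (side, side))
            v_src = k_src
        k = self.key(k_src)
        v = self.value(v_src)
        m = k.shape[-2] * k.shape[-1]
        k = k.reshape(B, -1, m)                                        # B×C'×M
        v = v.reshape(B, C, m)
        attn = nn.softmax(q @ k, axis=-1)                              # B×N×M
        out = (attn @ v.transpose((0, 2, 1))).transpose((0, 2, 1)).reshape(B, C, H, W)
        return x + self.gamma.reshape(1, 1, 1, 1) * out


def fixed_fusion_weights(batch: int, weights=(0.5, 0.5)) -> Tensor:
    """Constant per-sample fusion weights (the fixed-weight baseline)."""
    w = np.asarray(weights, dtype=np.float32)
    if w.shape != (2,) or w.min() < 0 or not np.isclose(w.sum(), 1.0):
        raise ValueError(f"fixed weights must be a non-negative pair summing to 1, got {weights}")
    return Tensor(np.tile(w, (batch, 1)))


def aaf_fuse(x_pa: Tensor, x_ca: Tensor, weights: Tensor) -> Tensor:
    """Per-sample convex combination w1·X_PA + w2·X_CA."""
    if x_pa.shape != x_ca.shape:
        raise ValueError(f"branch shape mismatch: {x_pa.shape} vs {x_ca.shape}")
    if weights.shape != (x_pa.shape[0], 2):
        raise ValueError(
            f"weights must be {x_pa.shape[0]}×2 to match the batch, got {weights.shape}")
    B = x_pa.shape[0]
    w1 = weights[:, 0:1].reshape(B, 1, 1, 1)
    w2 = weights[:, 1:2].reshape(B, 1, 1, 1)
    return w1 * x_pa + w2 * x_ca


class DualAttentionBlock(Module):
    """PA and CA branches fused by externally supplied per-sample weights."""

    def __init__(self, channels: int, max_positions: int = 256,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.pa = PositionAttention(channels, max_positions=max_positions, rng=rng)
        self.ca = ChannelAttention(channels)

    def forward(self, x: Tensor, weights: Tensor) -> Tensor:
        return aaf_fuse(self.pa(x), self.ca(x), weights)
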