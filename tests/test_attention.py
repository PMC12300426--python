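"""Attention-module tests: controller contract, branch equivariances, fusion."""

import math

import numpy as np
import pytest

from caafseg import nn
from caafseg.attention import (
    AdaptiveAttentionController,
    ChannelAttention,
    DualAttentionBlock,
    PositionAttention,
    aaf_fuse,
    fixed_fusion_weights,
)
from caafseg.nn import Tensor


def rand_features(rng, b=2, c=8, h=16, w=16):
    return Tensor(rng.standard_normal((b, c, h, w)).astype(np.float32))


# -----------------------------------------------------------------------------
# controller
# -----------------------------------------------------------------------------

def test_aac_outputs_on_simplex_for_random_inputs():
    rng = np.random.default_rng(0)
    aac = AdaptiveAttentionController(8, downsample=4, rng=rng)
    for _ in range(100):
        w = aac(rand_features(rng, b=3, c=8, h=8, w=8)).data
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)


def test_aac_zeroed_head_gives_half_half():
    rng = np.random.default_rng(1)
    aac = AdaptiveAttentionController(8, rng=rng)
    aac.w2.data[:] = 0.0
    aac.b2.data[:] = 0.0
    w = aac(rand_features(rng, c=8)).data
    np.testing.assert_allclose(w, 0.5, atol=1e-7)


def numpy_aac_reference(x, p, downsample):
    """Literal step-by-step transcription of the controller, no shared code."""
    B, C, H, W = x.shape
    hw = downsample
    assert H % hw == 0 and W % hw == 0
    # adaptive average pooling with uniform bins (sizes divide evenly)
    pooled = x.reshape(B, C, hw, H // hw, hw, W // hw).mean(axis=(3, 5))
    n = hw * hw
    seq = pooled.reshape(B, C, n).transpose(0, 2, 1)
    q = seq @ p["w_q"]
    k = seq @ p["w_k"]
    v = seq @ p["w_v"]
    scores = q @ k.transpose(0, 2, 1) / math.sqrt(C)
    e = np.exp(scores - scores.max(axis=-1, keepdims=True))
    attn = e / e.sum(axis=-1, keepdims=True)
    refined = attn @ v
    global_feat = refined.mean(axis=1)
    h = np.maximum(global_feat @ p["w1"] + p["b1"], 0.0)
    z = h @ p["w2"] + p["b2"]
    ez = np.exp(z - z.max(axis=-1, keepdims=True))
    return ez / ez.sum(axis=-1, keepdims=True)


def test_aac_matches_literal_reference_transcription():
    rng = np.random.default_rng(42)
    aac = AdaptiveAttentionController(6, downsample=4, rng=rng)
    x = rng.standard_normal((3, 6, 8, 8)).astype(np.float32)
    params = {name.replace(".", "_") if False else name: p.data.astype(np.float64)
              for name, p in aac.named_parameters()}
    expected = numpy_aac_reference(x.astype(np.float64), params, 4)
    got = aac(Tensor(x)).data
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_aac_invariant_to_average_preserving_upsampling():
    rng = np.random.default_rng(3)
    aac = AdaptiveAttentionController(4, downsample=4, rng=rng)
    x = rng.standard_normal((2, 4, 4, 4)).astype(np.float32)
    up = x.repeat(2, axis=2).repeat(2, axis=3)  # pools back to the same grid
    np.testing.assert_allclose(aac(Tensor(x)).data, aac(Tensor(up)).data, atol=1e-6)


def test_aac_rejects_single_channel():
    with pytest.raises(ValueError):
        AdaptiveAttentionController(1)


def test_aac_attention_cost_scales_quadratically_with_grid():
    """Doubling the pooled grid side quadruples N, so the N²-dominated
    attention cost grows ~16× (trend assertion on counted mat-mul FLOPs)."""
    rng = np.random.default_rng(4)
    counts = {}
    for hw in (4, 8, 16):
        aac = AdaptiveAttentionController(4, downsample=hw, rng=rng)
        x = rand_features(rng, b=1, c=4, h=32, w=32)
        with nn.count_flops() as counter:
            aac(x)
        counts[hw] = counter[0]
    # with tiny C the N² terms dominate: quadrupling N per doubling
    assert counts[8] / counts[4] > 3.0
    assert counts[16] / counts[8] > 3.5
    assert counts[16] / counts[4] > 12.0


# -----------------------------------------------------------------------------
# branches
# -----------------------------------------------------------------------------

def test_channel_attention_shape_and_permutation_equivariance():
    rng = np.random.default_rng(5)
    ca = ChannelAttention(6)
    ca.gamma.data[:] = 0.7  # make the attention path active
    x = rng.standard_normal((2, 6, 5, 5)).astype(np.float32)
    out = ca(Tensor(x)).data
    assert out.shape == x.shape
    perm = rng.permutation(6)
    out_perm = ca(Tensor(x[:, perm])).data
    np.testing.assert_allclose(out_perm, out[:, perm], atol=1e-5)


def test_channel_attention_single_channel_identity_at_init():
    x = np.random.default_rng(6).random((1, 1, 4, 4)).astype(np.float32)
    ca = ChannelAttention(1)
    np.testing.assert_array_equal(ca(Tensor(x)).data, x)


def test_position_attention_constant_input_stays_constant():
    rng = np.random.default_rng(7)
    pa = PositionAttention(4, rng=rng)
    pa.gamma.data[:] = 0.5
    x = np.ones((1, 4, 6, 6), np.float32) * np.arange(1, 5, dtype=np.float32).reshape(1, 4, 1, 1)
    out = pa(Tensor(x)).data
    assert out.shape == x.shape
    for ch in range(4):
        assert np.allclose(out[0, ch], out[0, ch, 0, 0], atol=1e-5)


def test_position_attention_torus_translation_equivariance():
    # at sizes below the key/value pooling threshold the affinity has no
    # positional dependence, so rolling the input rolls the output
    rng = np.random.default_rng(8)
    pa = PositionAttention(4, max_positions=256, rng=rng)
    pa.gamma.data[:] = 0.5
    x = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
    out = pa(Tensor(x)).data
    rolled = pa(Tensor(np.roll(x, (3, 2), axis=(2, 3)))).data
    np.testing.assert_allclose(rolled, np.roll(out, (3, 2), axis=(2, 3)), atol=1e-5)


# -----------------------------------------------------------------------------
# fusion
# -----------------------------------------------------------------------------

def test_aaf_degenerate_and_mean_weights():
    rng = np.random.default_rng(9)
    a = rand_features(rng, b=3, c=4, h=6, w=6)
    b = rand_features(rng, b=3, c=4, h=6, w=6)
    w_pa = Tensor(np.tile([1.0, 0.0], (3, 1)).astype(np.float32))
    np.testing.assert_array_equal(aaf_fuse(a, b, w_pa).data, a.data)
    w_half = fixed_fusion_weights(3)
    np.testing.assert_allclose(aaf_fuse(a, b, w_half).data,
                               0.5 * (a.data + b.data), atol=1e-7)


def test_aaf_output_in_convex_hull():
    rng = np.random.default_rng(10)
    a = rand_features(rng, b=4, c=3, h=5, w=5)
    b = rand_features(rng, b=4, c=3, h=5, w=5)
    for _ in range(20):
        w1 = rng.random(4).astype(np.float32)
        w = Tensor(np.stack([w1, 1 - w1], axis=1))
        fused = aaf_fuse(a, b, w).data
        lo = np.minimum(a.data, b.data)
        hi = np.maximum(a.data, b.data)
        assert np.all(fused >= lo - 1e-5) and np.all(fused <= hi + 1e-5)


def test_aaf_identical_inputs_fixed_point():
    rng = np.random.default_rng(11)
    x = rand_features(rng, b=2, c=3, h=4, w=4)
    w1 = rng.random(2).astype(np.float32)
    w = Tensor(np.stack([w1, 1 - w1], axis=1))
    np.testing.assert_allclose(aaf_fuse(x, x, w).data, x.data, atol=1e-6)


def test_aaf_batch_mismatch_raises():
    rng = np.random.default_rng(12)
    a = rand_features(rng, b=2)
    with pytest.raises(ValueError):
        aaf_fuse(a, a, fixed_fusion_weights(3))


def test_dual_attention_block_identity_at_init():
    # both branches are residual with zero-initialised scales, so fusing
    # them with any simplex weights reproduces the input exactly
    rng = np.random.default_rng(13)
    block = DualAttentionBlock(4, rng=rng)
    x = rand_features(rng, b=2, c=4, h=6, w=6)
    out = block(x, fixed_fusion_weights(2, (0.3, 0.7)))
    np.testing.assert_allclose(out.data, x.data, atol=1e-6)
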