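"""Loss-function unit and property tests.

Expected values for the worked examples come from independent oracles:
direct formula evaluation, scipy.ndimage convolution with matching
boundary handling, and brute-force nearest-neighbour distance
enumeration.
"""

import numpy as np
import pytest
from scipy import ndimage

from caafseg import losses
from caafseg.losses import (
    LAPLACIAN,
    SOBEL_X,
    SOBEL_Y,
    boundary_aware_loss,
    dice_loss,
    edge_hausdorff_oracle,
    edt,
    edt_hausdorff_loss,
    laplacian_boundary_loss,
    laplacian_transform,
    sobel_boundary_loss,
    sobel_magnitude,
)
from caafseg.nn import Tensor


def random_binary_mask(rng, shape=(16, 16), p=0.2, nonempty=False):
    m = (rng.random(shape) < p).astype(np.float32)
    if nonempty and not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = 1.0
    return m


def brute_force_hausdorff(p: np.ndarray, g: np.ndarray) -> float:
    """Literal mean-min pairwise-distance oracle (both directions, summed)."""
    pp = np.argwhere(p > 0).astype(float)
    gg = np.argwhere(g > 0).astype(float)
    d = np.sqrt(((pp[:, None, :] - gg[None, :, :]) ** 2).sum(-1))
    return float(d.min(axis=1).mean() + d.min(axis=0).mean())


# -----------------------------------------------------------------------------
# kernels
# -----------------------------------------------------------------------------

def test_kernel_stencils():
    assert SOBEL_X.sum() == 0 and SOBEL_Y.sum() == 0 and LAPLACIAN.sum() == 0
    np.testing.assert_array_equal(SOBEL_X, np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]]))
    np.testing.assert_array_equal(SOBEL_Y, SOBEL_X.T)
    np.testing.assert_array_equal(LAPLACIAN, np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]]))


# -----------------------------------------------------------------------------
# Dice
# -----------------------------------------------------------------------------

def test_dice_perfect_overlap_is_zero():
    rng = np.random.default_rng(0)
    for _ in range(5):
        m = random_binary_mask(rng, nonempty=True)
        assert dice_loss(m, m).item() < 1e-6


def test_dice_zero_intersection_is_one():
    t = np.zeros((8, 8), np.float32)
    t[2:5, 2:5] = 1
    p = np.zeros_like(t)
    assert dice_loss(p, t).item() == pytest.approx(1.0, abs=1e-6)


def test_dice_uniform_half_example():
    # 4×4 prediction of 0.5 everywhere against 4 foreground pixels:
    # 1 − 2·(0.5·4)/(0.5·16 + 4) = 2/3
    p = np.full((4, 4), 0.5, np.float32)
    t = np.zeros((4, 4), np.float32)
    t[1:3, 1:3] = 1
    assert dice_loss(p, t).item() == pytest.approx(2.0 / 3.0, abs=1e-6)


@pytest.mark.parametrize("bad", [
    (np.zeros((4, 4)), np.zeros((5, 5))),            # shape mismatch
    (np.zeros((4, 4)), np.full((4, 4), 0.5)),         # non-binary target
    (np.full((4, 4), 1.5), np.zeros((4, 4))),         # prediction out of range
    (np.zeros((2, 2)), np.zeros((2, 2))),             # below kernel size
])
def test_input_contract_violations_raise(bad):
    with pytest.raises(ValueError):
        dice_loss(bad[0], bad[1])


# -----------------------------------------------------------------------------
# Sobel
# -----------------------------------------------------------------------------

def test_sobel_magnitude_constant_image_zero():
    m = sobel_magnitude(np.full((6, 6), 0.7, np.float32)).data[0, 0]
    assert np.allclose(m[1:-1, 1:-1], 0.0, atol=1e-5)


def test_sobel_magnitude_vertical_step():
    # columns 0-2 are 0, columns 3-5 are 1: interior pixels adjacent to the
    # step see |I*Sx| = 4 and I*Sy = 0
    img = np.zeros((6, 6), np.float32)
    img[:, 3:] = 1
    m = sobel_magnitude(img).data[0, 0]
    assert np.allclose(m[1:-1, 2], 4.0, atol=1e-5)
    assert np.allclose(m[1:-1, 3], 4.0, atol=1e-5)
    assert np.allclose(m[1:-1, 1], 0.0, atol=1e-5)


def test_sobel_magnitude_rotation_equivariance():
    rng = np.random.default_rng(3)
    img = rng.random((9, 9)).astype(np.float32)
    m = sobel_magnitude(img).data[0, 0]
    m_rot = sobel_magnitude(np.rot90(img).copy()).data[0, 0]
    np.testing.assert_allclose(np.rot90(m)[1:-1, 1:-1], m_rot[1:-1, 1:-1],
                               rtol=1e-4, atol=1e-5)


def test_sobel_loss_identity_and_symmetry():
    rng = np.random.default_rng(1)
    a = random_binary_mask(rng, (10, 10), nonempty=True)
    b = random_binary_mask(rng, (10, 10), nonempty=True)
    assert sobel_boundary_loss(a, a).item() < 1e-6
    assert sobel_boundary_loss(a, b).item() == pytest.approx(
        sobel_boundary_loss(b, a).item(), abs=1e-6)


def test_sobel_loss_zero_pred_equals_mean_target_magnitude():
    target = np.zeros((5, 5), np.float32)
    target[:, 3:] = 1
    # independent route: scipy convolution with matching reflect boundary
    gx = ndimage.convolve(target, SOBEL_X[::-1, ::-1], mode="mirror")
    gy = ndimage.convolve(target, SOBEL_Y[::-1, ::-1], mode="mirror")
    expected = float(np.hypot(gx, gy).mean())
    got = sobel_boundary_loss(np.zeros_like(target), target).item()
    assert got == pytest.approx(expected, rel=1e-5)


# -----------------------------------------------------------------------------
# Laplacian
# -----------------------------------------------------------------------------

def test_laplacian_constant_and_ramp_are_zero_interior():
    const = laplacian_transform(np.full((7, 7), 0.3, np.float32)).data[0, 0]
    assert np.allclose(const[1:-1, 1:-1], 0.0, atol=1e-6)
    ramp = np.tile(np.arange(7, dtype=np.float32), (7, 1))
    lap = laplacian_transform(ramp).data[0, 0]
    assert np.allclose(lap[1:-1, 1:-1], 0.0, atol=1e-5)


def test_laplacian_impulse_response():
    img = np.zeros((5, 5), np.float32)
    img[2, 2] = 1
    lap = laplacian_transform(img).data[0, 0]
    assert lap[2, 2] == pytest.approx(-4.0)
    for r, c in [(1, 2), (3, 2), (2, 1), (2, 3)]:
        assert lap[r, c] == pytest.approx(1.0)
    assert lap[1, 1] == pytest.approx(0.0)


def test_laplacian_loss_identity():
    img = np.zeros((5, 5), np.float32)
    img[2, 2] = 1
    assert laplacian_boundary_loss(img, img).item() == 0.0


def test_laplacian_loss_disjoint_impulses_interior():
    # impulses at (2,2) and (6,6) on 9×9: stencil responses do not touch the
    # border, so each transform contributes |−4| + 4·|1| = 8 → (8+8)/81
    p = np.zeros((9, 9), np.float32)
    g = np.zeros((9, 9), np.float32)
    p[2, 2] = 1
    g[6, 6] = 1
    assert laplacian_boundary_loss(p, g).item() == pytest.approx(16.0 / 81.0, rel=1e-6)


def test_laplacian_loss_matches_scipy_convolution_oracle():
    # near-border impulses: expected value from an independent convolution
    # with the same reflect boundary handling
    p = np.zeros((7, 7), np.float32)
    g = np.zeros((7, 7), np.float32)
    p[1, 1] = 1
    g[3, 3] = 1
    lp = ndimage.convolve(p, LAPLACIAN, mode="mirror")
    lg = ndimage.convolve(g, LAPLACIAN, mode="mirror")
    expected = float(np.abs(lp - lg).mean())
    assert laplacian_boundary_loss(p, g).item() == pytest.approx(expected, rel=1e-6)


# -----------------------------------------------------------------------------
# EDT and Hausdorff
# -----------------------------------------------------------------------------

def test_edt_all_ones_and_corner():
    np.testing.assert_array_equal(edt(np.ones((4, 4))), np.zeros((4, 4)))
    m = np.zeros((3, 3))
    m[0, 0] = 1
    expected = np.sqrt(np.add.outer(np.arange(3) ** 2, np.arange(3) ** 2))
    np.testing.assert_allclose(edt(m), expected)


def test_edt_matches_brute_force_on_random_masks():
    rng = np.random.default_rng(11)
    for _ in range(10):
        m = random_binary_mask(rng, (12, 12), p=0.1, nonempty=True)
        fg = np.argwhere(m > 0).astype(float)
        rr, cc = np.mgrid[:12, :12]
        pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        brute = np.sqrt(((pts[:, None] - fg[None]) ** 2).sum(-1)).min(1).reshape(12, 12)
        np.testing.assert_allclose(edt(m), brute, atol=1e-9)


def test_edt_hausdorff_identity_and_single_pixel():
    rng = np.random.default_rng(2)
    m = random_binary_mask(rng, nonempty=True)
    assert edt_hausdorff_loss(m, m).item() == 0.0
    p = np.zeros((5, 5), np.float32)
    g = np.zeros((5, 5), np.float32)
    p[0, 0] = 1
    g[0, 3] = 1
    assert edt_hausdorff_loss(p, g).item() == pytest.approx(6.0, abs=1e-9)


def test_edt_hausdorff_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    for _ in range(50):
        p = random_binary_mask(rng, (16, 16), p=rng.uniform(0.05, 0.4), nonempty=True)
        g = random_binary_mask(rng, (16, 16), p=rng.uniform(0.05, 0.4), nonempty=True)
        got = edt_hausdorff_loss(p, g).item()
        assert got == pytest.approx(brute_force_hausdorff(p, g), abs=1e-6)


def test_edt_hausdorff_monotone_in_separation():
    prev = -1.0
    for k in range(1, 10):
        p = np.zeros((12, 12), np.float32)
        g = np.zeros((12, 12), np.float32)
        p[0, 0] = 1
        g[0, k] = 1
        val = edt_hausdorff_loss(p, g).item()
        assert val == pytest.approx(2.0 * k, abs=1e-9)
        assert val > prev
        prev = val


def test_edt_hausdorff_empty_mask_fallbacks():
    empty = np.zeros((6, 6), np.float32)
    assert edt_hausdorff_loss(empty, empty).item() == 0.0
    g = np.zeros((6, 6), np.float32)
    g[2, 2] = 1
    expected = 2.0 * edt(g).mean()
    assert edt_hausdorff_loss(empty, g).item() == pytest.approx(expected)
    assert edt_hausdorff_loss(g, empty).item() == pytest.approx(expected)


def test_edge_oracle_identity_and_agreement_with_edt():
    square = np.zeros((9, 9), np.float32)
    square[3:6, 3:6] = 1
    assert edge_hausdorff_oracle(square, square) == 0.0
    p = np.zeros((7, 7), np.float32)
    g = np.zeros((7, 7), np.float32)
    p[1, 1] = 1
    g[4, 5] = 1
    # single-pixel masks: edge sets equal foreground sets, so both routes
    # reduce to the same pairwise distance
    assert edge_hausdorff_oracle(p, g) == pytest.approx(
        edt_hausdorff_loss(p, g).item(), abs=1e-9)
    with pytest.raises(ValueError):
        edge_hausdorff_oracle(np.zeros((5, 5)), g)


def test_edge_oracle_offset_squares_matches_enumeration():
    a = np.zeros((12, 12), np.float32)
    b = np.zeros((12, 12), np.float32)
    a[3:7, 3:7] = 1
    b[4:8, 4:8] = 1
    # enumerate inner-boundary pixel pairs independently
    def boundary(m):
        fg = m > 0
        return np.argwhere(fg & ~ndimage.binary_erosion(fg)).astype(float)
    ea, eb = boundary(a), boundary(b)
    d = np.sqrt(((ea[:, None] - eb[None]) ** 2).sum(-1))
    expected = d.min(1).mean() + d.min(0).mean()
    assert edge_hausdorff_oracle(a, b) == pytest.approx(expected, abs=1e-9)


# -----------------------------------------------------------------------------
# composite
# -----------------------------------------------------------------------------

@pytest.mark.parametrize("variant", ["sobel", "laplacian", "hausdorff"])
def test_composite_identity(variant):
    rng = np.random.default_rng(9)
    m = random_binary_mask(rng, nonempty=True)
    assert boundary_aware_loss(m, m, variant).item() < 1e-6


def test_composite_zero_weight_equals_dice():
    rng = np.random.default_rng(10)
    p = rng.random((8, 8)).astype(np.float32)
    t = random_binary_mask(rng, (8, 8), nonempty=True)
    assert boundary_aware_loss(p, t, "sobel", boundary_weight=0).item() == \
        dice_loss(p, t).item()


def test_composite_hausdorff_single_pixel_example():
    # dice = 1 (disjoint single pixels) and hausdorff = 6 → total 7
    p = np.zeros((5, 5), np.float32)
    g = np.zeros((5, 5), np.float32)
    p[0, 0] = 1
    g[0, 3] = 1
    assert boundary_aware_loss(p, g, "hausdorff").item() == pytest.approx(7.0, abs=1e-5)


def test_composite_unknown_variant_raises():
    with pytest.raises(ValueError):
        boundary_aware_loss(np.zeros((4, 4)), np.zeros((4, 4)), "sorbet")


@pytest.mark.parametrize("variant", ["sobel", "laplacian", "hausdorff"])
def test_translation_invariance(variant):
    base_p = np.zeros((16, 16), np.float32)
    base_g = np.zeros((16, 16), np.float32)
    base_p[4:7, 4:7] = 1
    base_g[5:8, 4:8] = 1
    v0 = boundary_aware_loss(base_p, base_g, variant).item()
    shifted = boundary_aware_loss(np.roll(base_p, (3, 2), (0, 1)),
                                  np.roll(base_g, (3, 2), (0, 1)), variant).item()
    assert shifted == pytest.approx(v0, rel=1e-5)


# -----------------------------------------------------------------------------
# gradients
# -----------------------------------------------------------------------------

@pytest.mark.parametrize("loss_fn", [dice_loss, sobel_boundary_loss,
                                     laplacian_boundary_loss])
def test_finite_difference_gradients(loss_fn):
    rng = np.random.default_rng(21)
    pred_np = rng.uniform(0.1, 0.9, (1, 1, 8, 8)).astype(np.float64)
    target = random_binary_mask(rng, (8, 8), nonempty=True).astype(np.float64)
    target = target[None, None]

    pred = Tensor(pred_np.copy(), requires_grad=True)
    loss = loss_fn(pred, Tensor(target))
    loss.backward()
    analytic = pred.grad

    h = 1e-6
    coords = [(0, 0, int(r), int(c))
              for r, c in rng.integers(0, 8, size=(20, 2))]
    for idx in coords:
        plus = pred_np.copy()
        minus = pred_np.copy()
        plus[idx] += h
        minus[idx] -= h
        num = (loss_fn(Tensor(plus), Tensor(target)).item()
               - loss_fn(Tensor(minus), Tensor(target)).item()) / (2 * h)
        denom = max(abs(num), abs(analytic[idx]), 1e-8)
        assert abs(num - analytic[idx]) / denom < 1e-3, (idx, num, analytic[idx])
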