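"""Seeded generator of nodule-like image–mask fixtures.

Renders 2-D grayscale patches emulating the five challenge morphologies
of pulmonary nodules on CT:

* C1 ``clear`` — isolated smooth bright blob with a well-defined margin;
* C2 ``small`` — sub-5-pixel dot among vessel-like curvilinear
  distractors (at the fixture scale 1 px ≈ 1 mm);
* C3 ``adherent`` — blob touching a tubular bright structure of matched
  intensity (vessel/chest-wall adherence);
* C4 ``cavitary`` — bright rim around a low-density interior; the mask
  is the rim and has exactly one hole;
* C5 ``spiculated`` — star-shaped lesion with radiating spikes.

Images combine a low-frequency textured background, the nodule at a
configurable contrast, optional distractors and Gaussian noise, clipped
to [0, 1]. The mask is the exact noiseless support of the nodule
(distractors excluded). Everything is deterministic per spec + seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["Morphology", "NoduleSpec", "Fixture", "DEFAULT_DIAMETERS",
           "generate_fixture", "generate_dataset", "write_dataset"]


class Morphology(str, Enum):
    CLEAR = "clear"          # C1
    SMALL = "small"          # C2
    ADHERENT = "adherent"    # C3
    CAVITARY = "cavitary"    # C4
    SPICULATED = "spiculated"  # C5


#: representative lesion diameters (px, 1 px ≈ 1 mm at the fixture scale)
DEFAULT_DIAMETERS = {
    Morphology.CLEAR: 14.83,
    Morphology.SMALL: 4.74,
    Morphology.ADHERENT: 19.79,
    Morphology.CAVITARY: 16.45,
    Morphology.SPICULATED: 25.31,
}

#: default acquisition-like settings: lesion-to-parenchyma contrast and
#: additive Gaussian noise level on the [0, 1] intensity scale
DEFAULT_CONTRAST = 0.5
DEFAULT_NOISE_SIGMA = 0.05


@dataclass(frozen=True)
class NoduleSpec:
    morphology: Morphology
    diameter_px: float
    center: tuple  # (row, col)
    contrast: float = DEFAULT_CONTRAST
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0
    size: int = 64

    def __post_init__(self):
        if self.diameter_px < 1:
            raise ValueError("diameter_px must be >= 1")
        if self.morphology == Morphology.SMALL and self.diameter_px >= 5:
            raise ValueError("small-morphology nodules must have diameter_px < 5")
        r, c = self.center
        if not (0 <= r < self.size and 0 <= c < self.size):
            raise ValueError(f"center {self.center} outside a {self.size}×{self.size} image")


@dataclass(frozen=True)
class Fixture:
    image: np.ndarray  # 1×H×W float32 in [0, 1]
    mask: np.ndarray   # 1×H×W uint8 in {0, 1}
    spec: NoduleSpec


def _radial_support(size: int, center, radius_fn) -> np.ndarray:
    rr, cc = np.mgrid[:size, :size]
    dr = rr - center[0]
    dc = cc - center[1]
    rho = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    return rho <= radius_fn(theta)


def _smooth_blob(size, center, radius, rng, wobble=0.12) -> np.ndarray:
    k = rng.integers(2, 5)
    phase = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.5, 1.0) * wobble

    def radius_fn(theta):
        return radius * (1.0 + amp * np.cos(k * theta + phase))

    return _radial_support(size, center, radius_fn)


def _star(size, center, radius, rng) -> np.ndarray:
    spikes = int(rng.integers(6, 10))
    phase = rng.uniform(0, 2 * np.pi)
    depth = rng.uniform(0.35, 0.45)

    def radius_fn(theta):
        return radius * (1.0 - depth + depth * np.cos(spikes * theta + phase))

    return _radial_support(size, center, radius_fn)


def _tube(size, rng, through=None, thickness=None) -> np.ndarray:
    """Rasterize a bright curvilinear structure (vessel / wall segment)."""
    thickness = thickness if thickness is not None else rng.uniform(1.0, 2.0)
    rr, cc = np.mgrid[:size, :size]
    if through is None:
        through = (rng.uniform(0.2, 0.8) * size, rng.uniform(0.2, 0.8) * size)
    angle = rng.uniform(0, np.pi)
    n = np.array([np.sin(angle), -np.cos(angle)])
    dist = np.abs((rr - through[0]) * n[0] + (cc - through[1]) * n[1])
    curve = rng.uniform(-0.004, 0.004)
    along = (rr - through[0]) * np.cos(angle) + (cc - through[1]) * np.sin(angle)
    dist = np.abs(dist + curve * along ** 2)
    return dist <= thickness


def _background(size, rng) -> np.ndarray:
    coarse = rng.normal(0.0, 1.0, size=(4, 4))
    tex = ndimage.zoom(coarse, size / 4, order=3)[:size, :size]
    tex = (tex - tex.min()) / (np.ptp(tex) + 1e-9)
    return 0.12 + 0.12 * tex


def generate_fixture(spec: NoduleSpec) -> Fixture:
    """Render one image–mask pair, deterministically from spec + seed."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    radius = spec.diameter_px / 2.0
    center = spec.center
    distractors = np.zeros((size, size), dtype=bool)

    if spec.morphology == Morphology.CLEAR:
        mask = _smooth_blob(size, center, radius, rng)
    elif spec.morphology == Morphology.SMALL:
        mask = _radial_support(size, center, lambda t: radius)
        # keep the discrete footprint under the sub-5-px area bound
        # (π·(5/2)² ≈ 19.6 px); trim the farthest pixels if rasterization
        # overshoots it
        cap = int(np.pi * 2.5 ** 2)
        if mask.sum() > cap:
            rr, cc = np.nonzero(mask)
            rho = np.hypot(rr - center[0], cc - center[1])
            order = np.lexsort((cc, rr, rho))
            keep = order[:cap]
            mask = np.zeros_like(mask)
            mask[rr[keep], cc[keep]] = True
        for _ in range(int(rng.integers(2, 4))):
            distractors |= _tube(size, rng)
    elif spec.morphology == Morphology.ADHERENT:
        mask = _smooth_blob(size, center, radius, rng, wobble=0.08)
        offset = radius * rng.uniform(0.8, 1.0)
        touch = (center[0] + offset * np.sin(rng.uniform(0, 2 * np.pi)),
                 center[1] + offset * np.cos(rng.uniform(0, 2 * np.pi)))
        distractors |= _tube(size, rng, through=touch, thickness=rng.uniform(1.5, 2.5))
    elif spec.morphology == Morphology.CAVITARY:
        outer = _smooth_blob(size, center, radius, rng, wobble=0.06)
        inner = _radial_support(size, center, lambda t: 0.45 * radius)
        mask = outer & ~inner
    elif spec.morphology == Morphology.SPICULATED:
        mask = _star(size, center, radius, rng)
    else:  # pragma: no cover
        raise ValueError(f"unknown morphology {spec.morphology}")

    if not mask.any():
        raise ValueError("rendered mask is empty; check diameter/center")

    # soft-edged lesion: blur the support slightly so margins are not aliased
    soft = ndimage.gaussian_filter(mask.astype(np.float64), sigma=0.8)
    image = _background(size, rng)
    image = image + spec.contrast * soft
    if distractors.any():
        soft_d = ndimage.gaussian_filter(distractors.astype(np.float64), sigma=0.6)
        image = image + spec.contrast * rng.uniform(0.85, 1.0) * soft_d
    if spec.morphology == Morphology.CAVITARY:
        # depress the cavity below the rim intensity
        inner = _radial_support(size, center, lambda t: 0.45 * radius)
        image = image - 0.6 * spec.contrast * ndimage.gaussian_filter(
            inner.astype(np.float64), sigma=0.5)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    return Fixture(image=image[None], mask=mask[None].astype(np.uint8), spec=spec)


def _allocate(n: int, proportions: dict) -> dict:
    """Largest-remainder allocation of n items to the given class mix."""
    keys = list(proportions)
    total = sum(proportions.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"morphology proportions must sum to 1, got {total}")
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def uniform_mix() -> dict:
    return {m: 1.0 / len(Morphology) for m in Morphology}


def generate_dataset(n: int, morphology_mix: dict | None = None,
                     image_size: int = 64, seed: int = 0,
                     contrast: float = DEFAULT_CONTRAST,
                     noise_sigma: float = DEFAULT_NOISE_SIGMA) -> list:
    """Generate ``n`` fixtures with the requested class mix.

    Per-fixture seeds are derived from the master seed by counter via
    ``numpy.random.SeedSequence``, so distinct master seeds produce
    disjoint fixture streams.
    """
    mix = morphology_mix or uniform_mix()
    mix = {Morphology(k): v for k, v in mix.items()}
    counts = _allocate(n, mix)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    shuffle_rng = np.random.default_rng(children[-1])

    specs = []
    i = 0
    margin_scale = image_size / 64.0
    for morph, k in counts.items():
        base_d = DEFAULT_DIAMETERS[morph]
        for _ in range(k):
            child_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
            srng = np.random.default_rng(children[i])
            d = float(base_d * srng.uniform(0.85, 1.15))
            if morph == Morphology.SMALL:
                d = min(d, 4.99)
            margin = d / 2 + 6 * margin_scale
            margin = min(margin, image_size / 2 - 1)
            center = (float(srng.uniform(margin, image_size - margin)),
                      float(srng.uniform(margin, image_size - margin)))
            specs.append(NoduleSpec(morphology=morph, diameter_px=d, center=center,
                                    contrast=contrast, noise_sigma=noise_sigma,
                                    seed=child_seed, size=image_size))
            i += 1
    shuffle_rng.shuffle(specs)
    return [generate_fixture(s) for s in specs]


def write_dataset(fixtures, out_dir) -> Path:
    """Write paired img_%04d.png / msk_%04d.png plus a manifest.csv."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "image", "mask", "morphology", "diameter_px",
                         "center_row", "center_col", "contrast", "noise_sigma", "seed"])
        for i, fx in enumerate(fixtures):
            img_name, msk_name = f"img_{i:04d}.png", f"msk_{i:04d}.png"
            iio.imwrite(out / img_name, (fx.image[0] * 255).round().astype(np.uint8))
            iio.imwrite(out / msk_name, (fx.mask[0] * 255).astype(np.uint8))
            s = fx.spec
            writer.writerow([i, img_name, msk_name, s.morphology.value,
                             f"{s.diameter_px:.3f}", f"{s.center[0]:.2f}",
                             f"{s.center[1]:.2f}", s.contrast, s.noise_sigma, s.seed])
    return manifest
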