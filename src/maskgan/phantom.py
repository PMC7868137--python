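"""Procedural CT-like phantom slices.

Every other module in the package is trainable and testable without any
download: this module emits slices that mimic the structure of contrast
abdominal CT with liver tumors — a 12-bit-like intensity range, a smooth
elliptical "organ" carrying band-limited texture, and compact lesions with a
distinct (darker, higher-frequency) texture strictly inside the organ,
together with their binary masks.

The defaults emulate a 512x512 contrast CT slice: a liver-like organ band
around 1000-1300 raw units (liver parenchyma sits near +60..+200 HU above
water on a +1024-offset 12-bit scale) and hypodense lesions.  Desk-scale
tests pass ``size=64`` and proportionally smaller radii.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .core import CtSlice, TumorMask
from .errors import InfeasibleSpec


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one procedural phantom slice.

    ``size`` must be a power of two >= 16 so the GAN encoder's repeated
    halving terminates at a 1x1 bottleneck.
    """

    size: int = 512
    organ_intensity_band: Tuple[float, float] = (1000.0, 1300.0)
    lesion_count_range: Tuple[int, int] = (1, 3)
    lesion_radius_range: Tuple[float, float] = (8.0, 32.0)
    texture_scale: float = 8.0
    noise_std: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if not (self.size >= 16 and _is_power_of_two(self.size)):
            raise InfeasibleSpec(f"size must be a power of two >= 16, got {self.size}")
        lo, hi = self.organ_intensity_band
        if not (0 <= lo < hi <= 4096):
            raise InfeasibleSpec(f"organ band {self.organ_intensity_band} outside [0, 4096]")
        rmin, rmax = self.lesion_radius_range
        if not (0 < rmin <= rmax < self.size / 4):
            raise InfeasibleSpec(
                f"lesion radii {self.lesion_radius_range} must be positive and < size/4"
            )
        cmin, cmax = self.lesion_count_range
        if not (0 <= cmin <= cmax):
            raise InfeasibleSpec(f"bad lesion count range {self.lesion_count_range}")

    def scaled(self, size: int) -> "PhantomSpec":
        """The same stated world at another grid size (radii scale with it)."""
        factor = size / self.size
        return replace(
            self,
            size=size,
            lesion_radius_range=(
                max(1.5, self.lesion_radius_range[0] * factor),
                max(2.0, self.lesion_radius_range[1] * factor),
            ),
            texture_scale=max(1.0, self.texture_scale * factor),
        )


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Band-limited unit-variance noise (smoothed white noise)."""
    t = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma)
    std = t.std()
    if std == 0:
        return np.zeros((size, size))
    return (t - t.mean()) / std


def _ellipse_mask(size: int, center, semi_axes, angle: float = 0.0) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> Tuple[CtSlice, TumorMask]:
    """Generate one phantom slice and its lesion mask, deterministic in seed."""
    slc, mask, _ = generate_phantom_with_organ(spec)
    return slc, mask


def generate_phantom_with_organ(
    spec: PhantomSpec,
) -> Tuple[CtSlice, TumorMask, np.ndarray]:
    """Like :func:`generate_phantom`, also returning the boolean organ region
    (useful for checking lesion containment and organ statistics)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    lo, hi = spec.organ_intensity_band
    mid, half_band = (lo + hi) / 2.0, (hi - lo) / 2.0

    # Body and organ geometry: jittered axis-aligned ellipses.
    center = size / 2.0 + rng.uniform(-0.03, 0.03, 2) * size
    organ_axes = rng.uniform(0.30, 0.38, 2) * size
    organ = _ellipse_mask(size, center, organ_axes)
    body = _ellipse_mask(size, (size / 2.0, size / 2.0), (0.48 * size, 0.48 * size))

    # Background: air outside the body, soft tissue inside.
    image = np.full((size, size), 60.0)
    soft = 800.0 + 0.5 * spec.noise_std * _smooth_noise(rng, size, spec.texture_scale)
    image[body] = soft[body]

    # Organ parenchyma: band-limited texture clipped into the stated band.
    organ_tex = mid + spec.noise_std * _smooth_noise(rng, size, spec.texture_scale)
    image[organ] = np.clip(organ_tex, lo, hi)[organ]

    # Lesions: compact rotated ellipses strictly inside the organ, hypodense
    # with higher-frequency texture so the generator has a contrast to learn.
    mask = np.zeros((size, size), dtype=np.uint8)
    n_lesions = int(rng.integers(spec.lesion_count_range[0],
                                 spec.lesion_count_range[1] + 1))
    dist_inside = ndimage.distance_transform_edt(organ)
    lesion_tex = (mid - 1.2 * half_band
                  + 1.5 * spec.noise_std
                  * _smooth_noise(rng, size, max(0.5, spec.texture_scale / 4.0)))
    lesion_tex = np.clip(lesion_tex, 0.0, 4096.0)
    for _ in range(n_lesions):
        radius = rng.uniform(*spec.lesion_radius_range)
        feasible = np.argwhere(dist_inside > radius + 1.0)
        if feasible.size == 0:
            raise InfeasibleSpec(
                f"no room for a lesion of radius {radius:.1f} inside the organ"
            )
        cr, cc = feasible[rng.integers(len(feasible))]
        ratio = rng.uniform(0.6, 1.0)
        angle = rng.uniform(0.0, np.pi)
        blob = _ellipse_mask(size, (cr, cc), (radius, radius * ratio), angle)
        image[blob] = lesion_tex[blob]
        mask[blob] = 1

    image = np.clip(image, 0.0, 4096.0)
    return CtSlice(image), TumorMask(mask), organ


def _item_seed(master_seed: int, index: int) -> int:
    """Counter-based per-item seed, independent of generation order."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0])


def generate_dataset(spec: PhantomSpec, n: int, seed: int) -> List[Tuple[CtSlice, TumorMask]]:
    """Generate *n* phantoms with per-item seeds derived from a master seed."""
    if n < 1:
        raise InfeasibleSpec(f"dataset size must be >= 1, got {n}")
    return [
        generate_phantom(replace(spec, seed=_item_seed(seed, i)))
        for i in range(n)
    ]
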