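"""Tumor-patch harvesting, augmentation and mask implantation.

The augmentation workflow mirrors how a small set of labeled lesions is
expanded into a large stencil library: lesion patches are cut out of labeled
slices, multiplied by flip / rotate / scale transforms to a target count,
and later implanted as whitened regions onto healthy slices for the
generator to fill (see :func:`implant_mask`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import AttentionMapImage, CtSlice, TumorMask, make_attention_map
from .errors import EmptyInput, EmptyMask, OutOfBounds

# 8-connectivity: diagonal lesion pixels belong to the same component.
_STRUCTURE = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class TumorPatch:
    """A lesion cropped from a labeled slice.

    ``origin`` is the (row, col) of the crop's top-left corner in the source
    image, so a harvested mask can be re-implanted exactly where it came from.
    """

    pixels: np.ndarray
    mask: np.ndarray
    origin: Tuple[int, int] = (0, 0)

    def __post_init__(self):
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=np.float64))
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=np.uint8))
        if self.pixels.shape != self.mask.shape:
            raise ValueError("patch pixels and mask must share a shape")
        if self.mask.sum() < 1:
            raise EmptyMask("a tumor patch needs at least one mask pixel")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class TransformRecord:
    """Manifest entry: which source patch, transformed how."""

    source_index: int
    hflip: bool
    vflip: bool
    angle_deg: float
    scale: float

    @property
    def is_identity(self) -> bool:
        return (not self.hflip and not self.vflip
                and self.angle_deg == 0.0 and self.scale == 1.0)


def harvest_patches(slc: CtSlice, mask: TumorMask, margin: int = 2) -> List[TumorPatch]:
    """One patch per connected lesion, cropped to its bounding box + margin.

    Crops are clipped at image borders.  Raises :class:`EmptyMask` for a
    mask without positive pixels.
    """
    if mask.count == 0:
        raise EmptyMask("cannot harvest patches from an empty mask")
    labels, n = ndimage.label(mask.pixels, structure=_STRUCTURE)
    patches = []
    for comp in range(1, n + 1):
        rows, cols = np.nonzero(labels == comp)
        r0 = max(0, rows.min() - margin)
        r1 = min(slc.height, rows.max() + 1 + margin)
        c0 = max(0, cols.min() - margin)
        c1 = min(slc.width, cols.max() + 1 + margin)
        patches.append(TumorPatch(
            pixels=slc.pixels[r0:r1, c0:c1].copy(),
            mask=(labels[r0:r1, c0:c1] == comp).astype(np.uint8),
            origin=(int(r0), int(c0)),
        ))
    return patches


def apply_transform(patch: TumorPatch, hflip: bool = False, vflip: bool = False,
                    angle_deg: float = 0.0, scale: float = 1.0) -> TumorPatch:
    """Apply flip / rotation / isotropic scale to pixels and mask alike.

    Pixels are resampled bilinearly; the mask uses nearest-neighbor and is
    re-binarized at 0.5 so it stays exactly binary.  Rotations by multiples
    of 90 degrees are exact grid permutations (no interpolation).
    """
    px, mk = patch.pixels, patch.mask.astype(np.float64)
    if hflip:
        px, mk = px[:, ::-1], mk[:, ::-1]
    if vflip:
        px, mk = px[::-1, :], mk[::-1, :]
    angle = angle_deg % 360.0
    if angle != 0.0:
        if angle % 90.0 == 0.0:
            k = int(angle // 90)
            px, mk = np.rot90(px, k), np.rot90(mk, k)
        else:
            px = ndimage.rotate(px, angle, reshape=True, order=1, mode="nearest")
            mk = ndimage.rotate(mk, angle, reshape=True, order=0, mode="constant")
    if scale != 1.0:
        px = ndimage.zoom(px, scale, order=1, mode="nearest")
        mk = ndimage.zoom(mk, scale, order=0, mode="constant")
    mk = (mk > 0.5).astype(np.uint8)
    if mk.sum() == 0:  # degenerate shrink: keep at least the center pixel
        mk = np.zeros_like(mk)
        mk[mk.shape[0] // 2, mk.shape[1] // 2] = 1
    return TumorPatch(np.ascontiguousarray(px), mk, origin=patch.origin)


def augment_patches(
    patches: Sequence[TumorPatch],
    target_count: int,
    seed: int,
    scale_range: Tuple[float, float] = (0.75, 1.25),
) -> Tuple[List[TumorPatch], List[TransformRecord]]:
    """Expand a patch set to exactly *target_count* items.

    The originals are returned first (identity transforms); the remaining
    ``target_count - len(patches)`` items are drawn with replacement over
    (source patch, random transform) pairs: horizontal/vertical flips with
    probability 1/2 each, a rotation uniform in [0, 360) degrees and an
    isotropic scale uniform in *scale_range*.  Deterministic given *seed*.
    Returns the patches together with a transform manifest.
    """
    if len(patches) == 0:
        raise EmptyInput("no patches to augment")
    if target_count < len(patches):
        raise EmptyInput(
            f"target_count {target_count} below source count {len(patches)}"
        )
    rng = np.random.default_rng(seed)
    out: List[TumorPatch] = list(patches)
    manifest = [TransformRecord(i, False, False, 0.0, 1.0)
                for i in range(len(patches))]
    for _ in range(target_count - len(patches)):
        idx = int(rng.integers(len(patches)))
        rec = TransformRecord(
            source_index=idx,
            hflip=bool(rng.integers(2)),
            vflip=bool(rng.integers(2)),
            angle_deg=float(rng.uniform(0.0, 360.0)),
            scale=float(rng.uniform(*scale_range)),
        )
        out.append(apply_transform(patches[idx], rec.hflip, rec.vflip,
                                   rec.angle_deg, rec.scale))
        manifest.append(rec)
    return out, manifest


def implant_mask(
    healthy: CtSlice,
    stencil: np.ndarray,
    location: Tuple[int, int],
    existing_mask: Optional[TumorMask] = None,
) -> Tuple[AttentionMapImage, TumorMask]:
    """Whiten a stencil-shaped region of a healthy slice at *location*.

    ``location`` is the (row, col) of the stencil's top-left corner.  Pass
    the returned mask back as ``existing_mask`` to place several regions;
    the whitened area is then the union of all placements.  Raises
    :class:`OutOfBounds` if the stencil does not fit inside the image.
    """
    stencil = np.asarray(stencil)
    r, c = location
    h, w = stencil.shape
    if r < 0 or c < 0 or r + h > healthy.height or c + w > healthy.width:
        raise OutOfBounds(
            f"stencil {stencil.shape} at {location} exceeds image {healthy.shape}"
        )
    full = np.zeros(healthy.shape, dtype=np.uint8)
    if existing_mask is not None:
        full |= existing_mask.pixels
    full[r:r + h, c:c + w] |= (stencil > 0).astype(np.uint8)
    mask = TumorMask(full)
    return make_attention_map(healthy, mask), mask
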