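"""Domain types for CT slices, tumor masks and attention maps.

A CT slice is a single 2D grayscale image with raw scanner intensities in a
12-bit-like range [0, 4096].  A tumor mask is a binary map of the same shape.
The *attention map* of a (slice, mask) pair is the slice with every tumor
pixel painted with the white value 4096; it tells the generator which region
to fill with synthesized lesion texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

import numpy as np

from .errors import DegenerateImage, ShapeMismatch

#: Intensity used to whiten (mask out) tumor pixels.  The full 12-bit range
#: tops out at 4095; the whitening value 4096 is stored literally and only
#: clamped when exporting to integer containers.
WHITE_VALUE = 4096

#: Inclusive intensity range of raw slices.
INTENSITY_RANGE = (0, 4096)


def _as_2d_float(pixels) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ShapeMismatch(f"expected a 2D pixel grid, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pixel values must be finite")
    return arr


@dataclass(frozen=True)
class CtSlice:
    """One 2D grayscale CT slice with raw intensities in [0, 4096].

    Parameters
    ----------
    pixels:
        2D array of intensities (row-major, origin at the top-left).
    spacing:
        Optional (row, col) physical pixel size in millimetres.
    """

    pixels: np.ndarray
    spacing: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        object.__setattr__(self, "pixels", _as_2d_float(self.pixels))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class TumorMask:
    """Binary lesion map aligned to a :class:`CtSlice` (1 = tumor)."""

    pixels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ShapeMismatch(f"expected a 2D mask, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "pixels", arr.astype(np.uint8))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def count(self) -> int:
        """Number of tumor pixels."""
        return int(self.pixels.sum())


@dataclass(frozen=True)
class NormalizedSlice:
    """A slice standardized to zero mean / unit standard deviation.

    Stores the source statistics so the transform can be inverted exactly.
    """

    pixels: np.ndarray
    source_mean: float
    source_std: float

    def __post_init__(self):
        object.__setattr__(self, "pixels", _as_2d_float(self.pixels))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def denormalize(self) -> CtSlice:
        """Invert the standardization, recovering the source intensities."""
        return CtSlice(self.pixels * self.source_std + self.source_mean)


@dataclass(frozen=True)
class AttentionMapImage:
    """A slice whose tumor pixels have been painted white (4096).

    Invariants: pixels equal the source slice wherever the mask is 0 and
    equal :data:`WHITE_VALUE` wherever the mask is 1.
    """

    pixels: np.ndarray
    mask: TumorMask

    def __post_init__(self):
        object.__setattr__(self, "pixels", _as_2d_float(self.pixels))
        if self.pixels.shape != self.mask.shape:
            raise ShapeMismatch(
                f"attention map {self.pixels.shape} vs mask {self.mask.shape}"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


class PairingLabel(Enum):
    """Which side of the adversarial game a pairing belongs to."""

    A_REAL = "A_real"
    B_SYNTH = "B_synth"


@dataclass(frozen=True)
class Pairing:
    """An ordered (image, attention map) pair shown to the discriminator.

    Pairing A couples the real image with the attention map; pairing B
    couples the synthesized image with the same attention map.
    """

    image: CtSlice
    attention: AttentionMapImage
    label: PairingLabel = field(default=PairingLabel.A_REAL)

    def __post_init__(self):
        if self.image.shape != self.attention.shape:
            raise ShapeMismatch(
                f"image {self.image.shape} vs attention {self.attention.shape}"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.image.shape


def normalize_slice(slc: CtSlice,
                    statistics: Optional[Tuple[float, float]] = None) -> NormalizedSlice:
    """Standardize a slice: (value - mean) / std.

    Statistics are computed per slice by default (population std, divide by
    n); pass ``statistics=(mean, std)`` to standardize with global
    dataset-level values instead.  Raises :class:`DegenerateImage` for a
    constant slice (or a zero supplied std).
    """
    pixels = slc.pixels
    if pixels.size < 2:
        raise DegenerateImage("need at least 2 pixels to standardize")
    if statistics is None:
        mean = float(pixels.mean())
        std = float(pixels.std())  # population convention (ddof=0)
    else:
        mean, std = float(statistics[0]), float(statistics[1])
    if std == 0.0:
        raise DegenerateImage("constant slice has zero standard deviation")
    return NormalizedSlice((pixels - mean) / std, source_mean=mean, source_std=std)


def make_attention_map(slc: CtSlice, mask: TumorMask) -> AttentionMapImage:
    """Paint every mask==1 pixel of the slice with the white value 4096."""
    if slc.shape != mask.shape:
        raise ShapeMismatch(f"slice {slc.shape} vs mask {mask.shape}")
    pixels = slc.pixels.copy()
    pixels[mask.pixels == 1] = WHITE_VALUE
    return AttentionMapImage(pixels, mask)
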