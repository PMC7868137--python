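"""PSNR scoring and difference-map visualization.

PSNR = 10 * log10(data_range^2 / MSE) in decibels, computed on raw
(de-standardized) intensities over the whole image by default; a mask can
restrict the score to the whitened regions, which is the quantity that
actually measures inpainting quality.  The default data range is 4095, the
12-bit CT convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import CtSlice
from .errors import EmptyInput, ShapeMismatch

#: 12-bit dynamic range used when no explicit data range is given.
DEFAULT_DATA_RANGE = 4095.0


def _pixels(img) -> np.ndarray:
    if isinstance(img, CtSlice):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def psnr(real, synth, data_range: float = DEFAULT_DATA_RANGE,
         mask: Optional[np.ndarray] = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images.

    ``mask`` (optional, binary) restricts the mean squared error to the
    masked pixels.
    """
    a, b = _pixels(real), _pixels(synth)
    if a.shape != b.shape:
        raise ShapeMismatch(f"{a.shape} vs {b.shape}")
    if data_range <= 0:
        raise ValueError(f"data_range must be positive, got {data_range}")
    diff2 = (a - b) ** 2
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != a.shape:
            raise ShapeMismatch(f"mask {mask.shape} vs image {a.shape}")
        if not mask.any():
            raise EmptyInput("mask selects no pixels")
        diff2 = diff2[mask]
    mse = float(diff2.mean())
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / mse))


@dataclass(frozen=True)
class DifferenceMap:
    """Per-pixel absolute differences plus a color rendering.

    ``color`` is an (H, W, 3) uint8 RGB image; ``scale`` records the
    difference value mapped to the top of the colormap so renderings are
    comparable.
    """

    values: np.ndarray
    color: np.ndarray
    scale: float
    colormap: str

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("difference values must be non-negative")


def difference_map(real, synth, colormap: str = "jet",
                   scale: Optional[float] = None) -> DifferenceMap:
    """Absolute per-pixel difference with a fixed-colormap rendering.

    ``scale`` fixes the value rendered at the colormap top; by default the
    map's own maximum (or 1 for identical images).
    """
    a, b = _pixels(real), _pixels(synth)
    if a.shape != b.shape:
        raise ShapeMismatch(f"{a.shape} vs {b.shape}")
    values = np.abs(a - b)
    if scale is None:
        scale = float(values.max()) or 1.0
    import matplotlib

    cmap = matplotlib.colormaps[colormap]
    rgba = cmap(np.clip(values / scale, 0.0, 1.0))
    color = (rgba[..., :3] * 255).astype(np.uint8)
    return DifferenceMap(values=values, color=color, scale=scale,
                         colormap=colormap)


@dataclass(frozen=True)
class PsnrSummary:
    """Aggregate PSNR over a set of (real, synthesized) pairs.

    Infinite values (identical pairs) are excluded from the mean and
    reported separately in ``infinite_count``.
    """

    mean: float
    median: float
    min: float
    max: float
    count: int
    infinite_count: int
    per_pair: Tuple[float, ...]


def evaluate_dataset(pairs: Sequence[Tuple[CtSlice, CtSlice]],
                     data_range: float = DEFAULT_DATA_RANGE) -> PsnrSummary:
    """Per-pair PSNR with mean/median/min/max aggregation.

    The mean is taken over finite values only; if every pair is identical
    the mean is NaN and ``infinite_count`` equals the pair count.
    """
    if len(pairs) == 0:
        raise EmptyInput("no image pairs to evaluate")
    scores = [psnr(r, s, data_range=data_range) for r, s in pairs]
    arr = np.asarray(scores)
    finite = arr[np.isfinite(arr)]
    mean = float(finite.mean()) if finite.size else float("nan")
    return PsnrSummary(
        mean=mean,
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
        count=len(scores),
        infinite_count=int(np.sum(~np.isfinite(arr))),
        per_pair=tuple(scores),
    )
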