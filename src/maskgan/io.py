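"""Readers and writers for CT slices.

Supported containers: NIfTI volumes (one axial slice extracted per call),
8/16-bit PNG and 8/16-bit TIFF.  16-bit containers round-trip integer
intensities in [0, 4096] losslessly; 8-bit input is linearly rescaled to the
12-bit-like range by the factor 4096/255 (documented, not invertible).
Writing defaults to 16-bit PNG; intensities are clamped to [0, 65535] on
export, which in practice only touches the white value 4096 when a narrower
container is requested.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np

from .core import CtSlice
from .errors import CorruptFile, UnsupportedFormat

#: Factor applied to 8-bit input so 255 maps onto the top of the 12-bit range.
EIGHT_BIT_SCALE = 4096.0 / 255.0

_EXT_FORMAT = {
    ".png": "png",
    ".tif": "tiff",
    ".tiff": "tiff",
    ".nii": "nifti",
}


def _infer_format(path: str, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    base = path.lower()
    if base.endswith(".nii.gz"):
        return "nifti"
    ext = os.path.splitext(base)[1]
    if ext in _EXT_FORMAT:
        return _EXT_FORMAT[ext]
    raise UnsupportedFormat(f"cannot infer format from path {path!r}")


def read_slice(path: str, fmt: Optional[str] = None, index: int = 0) -> CtSlice:
    """Read one 2D slice from *path*.

    ``index`` selects the axial slice for NIfTI volumes and is ignored for
    single-image containers.  8-bit images are rescaled by
    :data:`EIGHT_BIT_SCALE`.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "png":
        from PIL import Image, UnidentifiedImageError

        try:
            with Image.open(path) as img:
                arr = np.asarray(img)
        except (UnidentifiedImageError, OSError, SyntaxError) as exc:
            raise CorruptFile(f"cannot decode PNG {path!r}: {exc}") from exc
        return _from_int_array(arr, path)
    if fmt == "tiff":
        import tifffile

        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # tifffile raises assorted types on damage
            raise CorruptFile(f"cannot decode TIFF {path!r}: {exc}") from exc
        return _from_int_array(np.asarray(arr), path)
    if fmt == "nifti":
        import nibabel as nib

        try:
            vol = nib.load(path)
            data = np.asanyarray(vol.dataobj)
        except Exception as exc:
            raise CorruptFile(f"cannot decode NIfTI {path!r}: {exc}") from exc
        if data.ndim == 2:
            plane = data
        elif data.ndim == 3:
            if not (0 <= index < data.shape[2]):
                raise CorruptFile(
                    f"slice index {index} out of range for volume {data.shape}"
                )
            plane = data[:, :, index]
        else:
            raise CorruptFile(f"unsupported NIfTI dimensionality {data.ndim}")
        zooms = vol.header.get_zooms()[:2]
        return CtSlice(np.asarray(plane, dtype=np.float64),
                       spacing=(float(zooms[0]), float(zooms[1])))
    raise UnsupportedFormat(f"unsupported format {fmt!r}")


def _from_int_array(arr: np.ndarray, path: str) -> CtSlice:
    if arr.ndim == 3:  # tolerate grayscale saved with a channel axis
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise CorruptFile(f"{path!r} is not grayscale (shape {arr.shape})")
    if arr.ndim != 2:
        raise CorruptFile(f"{path!r} is not a 2D image (shape {arr.shape})")
    scale = EIGHT_BIT_SCALE if arr.dtype == np.uint8 else 1.0
    return CtSlice(arr.astype(np.float64) * scale)


def read_slice_8bit(path: str) -> CtSlice:
    """Read an 8-bit image and rescale [0, 255] -> [0, 4096]."""
    from PIL import Image, UnidentifiedImageError

    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("L"), dtype=np.float64)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise CorruptFile(f"cannot decode image {path!r}: {exc}") from exc
    return CtSlice(arr * EIGHT_BIT_SCALE)


def write_slice(slc: CtSlice, path: str, fmt: Optional[str] = None) -> None:
    """Write a slice; 16-bit integer containers are lossless for [0, 4096].

    Intensities are rounded to the nearest integer and clamped to the
    container range on export.
    """
    fmt = _infer_format(path, fmt)
    data16 = np.clip(np.rint(slc.pixels), 0, 65535).astype(np.uint16)
    if fmt == "png":
        from PIL import Image

        Image.fromarray(data16).save(path)  # uint16 -> 16-bit grayscale PNG
        return
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, data16)
        return
    if fmt == "nifti":
        import nibabel as nib

        img = nib.Nifti1Image(slc.pixels.astype(np.float64)[:, :, None],
                              affine=np.eye(4))
        if slc.spacing is not None:
            img.header.set_zooms((slc.spacing[0], slc.spacing[1], 1.0))
        nib.save(img, path)
        return
    raise UnsupportedFormat(f"unsupported format {fmt!r}")
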