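"""Reading and writing images: PNG/TIFF via imageio, DICOM via pydicom."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .preprocess import RawImage

__all__ = ["read_image", "read_mask", "write_image_png16", "write_mask_png"]

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}


def read_image(path: Path | str) -> RawImage:
    """Load a 2-D radiograph; DICOM photometric interpretation is honoured."""
    path = Path(path)
    if path.suffix.lower() in _DICOM_SUFFIXES:
        import pydicom

        ds = pydicom.dcmread(path)
        photometric = ("inverted"
                       if str(getattr(ds, "PhotometricInterpretation", "")) == "MONOCHROME1"
                       else "standard")
        return RawImage(ds.pixel_array.astype(np.float64), photometric)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse RGB(A) scans to luminance
        arr = arr[..., :3].mean(axis=-1)
    return RawImage(arr.astype(np.float64))


def read_mask(path: Path | str) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def write_image_png16(path: Path | str, pixels: np.ndarray) -> None:
    """Save with a per-image linear stretch to the full 16-bit range."""
    px = np.asarray(pixels, dtype=np.float64)
    lo, hi = px.min(), px.max()
    scaled = np.zeros_like(px) if hi == lo else (px - lo) / (hi - lo)
    iio.imwrite(Path(path), (scaled * 65535).round().astype(np.uint16))


def write_mask_png(path: Path | str, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), ((np.asarray(mask) > 0) * 255).astype(np.uint8))
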