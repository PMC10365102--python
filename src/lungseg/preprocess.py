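"""Grayscale truncation and normalisation of raw radiographs.

Chest radiographs arrive on arbitrary, machine-dependent intensity scales.  To
harmonise them, the intensity window is estimated from the central quarter of
the image — rows [x/4, 3x/4) by columns [y/4, 3y/4) — where the thorax sits in
a frontal chest film.  The whole image is clipped to that [Vmin, Vmax] window,
mapped affinely to [0, 1] and resized to a square model input.  The pipeline
is invariant to any positive affine rescaling a*I + b of the input, which is
exactly the harmonisation this step exists for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["RawImage", "TruncationBounds", "NormalizedImage", "central_region",
           "truncation_bounds", "apply_truncation", "normalize_unit",
           "resize_to", "resize_mask", "preprocess"]


@dataclass(frozen=True)
class RawImage:
    """A 2-D radiograph on its native intensity scale.

    ``photometric`` is "standard" (higher value = brighter display, DICOM
    MONOCHROME2) or "inverted" (MONOCHROME1); inverted images are flipped to
    the standard polarity before any windowing.
    """

    pixels: np.ndarray
    photometric: str = "standard"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError("RawImage requires a 2-D array")
        if px.shape[0] < 4 or px.shape[1] < 4:
            raise ValueError("image too small: central quarter region is empty "
                             f"for shape {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError("RawImage intensities must be finite")
        if self.photometric not in ("standard", "inverted"):
            raise ValueError(f"unknown photometric {self.photometric!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True)
class TruncationBounds:
    """The [vmin, vmax] window taken over the central-quarter region."""

    vmin: float
    vmax: float
    region: tuple[slice, slice]

    def __post_init__(self):
        if self.vmin > self.vmax:
            raise ValueError("vmin must not exceed vmax")


@dataclass(frozen=True)
class NormalizedImage:
    """Fixed-size square image with values in [0, 1] — the model's input."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("NormalizedImage must be square")
        if px.size and (px.min() < 0 or px.max() > 1):
            raise ValueError("NormalizedImage values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def central_region(img: RawImage) -> tuple[slice, slice]:
    """Half-open row/column slices of the central quarter-area window.

    For a side of length x the rows are [floor(x/4), floor(3x/4)); odd sides
    use the floor rule, keeping the window non-empty for any x, y >= 4.
    """
    x, y = img.shape
    return (slice(x // 4, (3 * x) // 4), slice(y // 4, (3 * y) // 4))


def truncation_bounds(img: RawImage) -> TruncationBounds:
    """Min/max intensity over the central region of the (polarity-fixed) image."""
    region = central_region(img)
    centre = _oriented(img)[region]
    return TruncationBounds(float(centre.min()), float(centre.max()), region)


def _oriented(img: RawImage) -> np.ndarray:
    if img.photometric == "inverted":
        return img.pixels.max() - img.pixels
    return img.pixels


def apply_truncation(pixels: np.ndarray, b: TruncationBounds) -> np.ndarray:
    """Clip every pixel into [vmin, vmax]."""
    return np.clip(np.asarray(pixels, dtype=np.float64), b.vmin, b.vmax)


def normalize_unit(pixels: np.ndarray, b: TruncationBounds) -> np.ndarray:
    """Affine map of a truncated image onto [0, 1].

    Degenerate windows (vmax == vmin, e.g. a constant image) map to all zeros
    rather than raising, so batch pipelines stay alive.
    """
    span = b.vmax - b.vmin
    px = np.asarray(pixels, dtype=np.float64)
    if span == 0:
        return np.zeros_like(px)
    return (px - b.vmin) / span


def resize_to(pixels: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize to side x side; values stay inside the input range."""
    if side < 1:
        raise ValueError("target side must be >= 1")
    px = np.asarray(pixels, dtype=np.float64)
    if px.shape == (side, side):
        return px.copy()
    return _sk_resize(px, (side, side), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def resize_mask(mask: np.ndarray, side: int) -> np.ndarray:
    """Nearest-neighbour resize for binary masks (preserves binarity)."""
    if side < 1:
        raise ValueError("target side must be >= 1")
    m = np.asarray(mask)
    if m.shape == (side, side):
        return (m > 0).astype(np.uint8)
    out = _sk_resize(m.astype(np.float64), (side, side), order=0,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def preprocess(img: RawImage | np.ndarray, side: int = 512) -> NormalizedImage:
    """Full pipeline: window estimation -> clip -> [0,1] -> resize.

    Accepts a plain 2-D array (treated as standard photometric) or a
    :class:`RawImage`.
    """
    if not isinstance(img, RawImage):
        img = RawImage(img)
    oriented = RawImage(_oriented(img))
    b = truncation_bounds(oriented)
    px = apply_truncation(oriented.pixels, b)
    px = normalize_unit(px, b)
    px = resize_to(px, side)
    return NormalizedImage(np.clip(px, 0.0, 1.0))
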