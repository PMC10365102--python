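"""Morphological clean-up of raw network masks.

Two failure modes dominate raw predictions on chest films: spurious foreground
blobs outside the lungs (tissue with lung-like gray levels) and small
unrecognised patches inside a lung.  The clean-up addresses them in order:

1. ``binarize`` — threshold the probability map;
2. ``remove_spurious`` — keep only the largest connected components (at most
   two, the two-lung prior), dropping any component smaller than a fraction of
   the largest;
3. ``complete_regions`` — fill fully-enclosed holes, then smooth boundaries
   with a small morphological opening.

Opening alone cannot restore a missing interior patch, so hole filling runs
first; both stages are independently switchable through the config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = ["PostprocessConfig", "binarize", "remove_spurious",
           "complete_regions", "postprocess"]


@dataclass(frozen=True)
class PostprocessConfig:
    binarize_threshold: float = 0.5
    connectivity: int = 8           # pixel adjacency: 4 or 8
    max_components: int = 2         # two-lung prior
    min_area_fraction: float = 0.10  # relative to the largest component
    opening_radius: int = 3
    fill_holes: bool = True
    apply_opening: bool = True

    def __post_init__(self):
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValueError("binarize_threshold must lie in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")


def _as_binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be strictly binary (0/1)")
    return m.astype(np.uint8)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Pixel is lung iff probability >= threshold."""
    return (np.asarray(prob) >= threshold).astype(np.uint8)


def remove_spurious(mask: np.ndarray, cfg: PostprocessConfig = PostprocessConfig()) -> np.ndarray:
    """Keep at most ``max_components`` largest components above the area cut."""
    m = _as_binary(mask)
    skim_conn = 1 if cfg.connectivity == 4 else 2
    labels = measure.label(m, connectivity=skim_conn)
    if labels.max() == 0:
        return m
    areas = np.bincount(labels.ravel())[1:]
    order = np.argsort(areas)[::-1]
    largest = areas[order[0]]
    keep = [lab + 1 for lab in order[:cfg.max_components]
            if areas[lab] >= cfg.min_area_fraction * largest]
    return np.isin(labels, keep).astype(np.uint8)


def complete_regions(mask: np.ndarray, cfg: PostprocessConfig = PostprocessConfig()) -> np.ndarray:
    """Fill enclosed holes, then open with a disk to smooth boundaries."""
    m = _as_binary(mask).astype(bool)
    if cfg.fill_holes:
        m = ndimage.binary_fill_holes(m)
    if cfg.apply_opening and cfg.opening_radius > 0:
        m = morphology.opening(m, morphology.disk(cfg.opening_radius))
    return m.astype(np.uint8)


def postprocess(prob: np.ndarray, cfg: PostprocessConfig = PostprocessConfig()) -> np.ndarray:
    """binarize -> remove_spurious -> complete_regions -> component re-filter.

    Opening can split a thin component in two, so the component filter runs
    once more at the end to restore the at-most-``max_components`` guarantee.
    """
    m = binarize(prob, cfg.binarize_threshold)
    m = remove_spurious(m, cfg)
    m = complete_regions(m, cfg)
    return remove_spurious(m, cfg)
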