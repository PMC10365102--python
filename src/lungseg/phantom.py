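"""Seeded synthetic chest phantoms: (raw image, ground-truth lung mask) pairs.

Each phantom renders, on a nominal [0, 1] intensity scale, the gross structure
a frontal pediatric chest film presents to a segmentation model:

* a bright elliptical thorax on a dark background;
* two darker, slightly tilted elliptical lung fields (their union is the
  ground-truth mask);
* a bright mediastinal/spinal band between the lungs;
* bright rib-like stripes crossing the thorax, partially brightening the lung
  fields they overlap;
* optional distractor blobs *outside* the lungs whose gray level sits in the
  lungs' band — the structure a naive intensity threshold mislabels;

then applies a per-image affine intensity transform a*I + b (emulating
different acquisition machines/settings) and additive Gaussian noise.  The
mask depends on geometry only, never on the intensity transform or noise.

Everything is a pure function of (config seed, image index), so any image can
be regenerated bit-for-bit from the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import RawImage

__all__ = ["PhantomConfig", "generate_phantom", "generate_pairs",
           "generate_dataset", "corrupt_mask"]


@dataclass(frozen=True)
class PhantomConfig:
    side: int = 256
    # geometry, as fractions of the side
    thorax_axes: tuple[float, float] = (0.45, 0.40)       # (row, col) semi-axes
    lung_center_row: float = 0.48
    lung_center_col_offset: float = 0.19                  # +/- from midline
    lung_axes: tuple[float, float] = (0.26, 0.135)        # (row, col) semi-axes
    lung_axes_jitter: float = 0.02
    lung_center_jitter: float = 0.02
    lung_rotation_max: float = 0.12                       # radians, mirrored tilt
    mediastinum_halfwidth: float = 0.06
    # nominal intensity levels (pre-affine); lung < thorax < rib must hold
    background_level: float = 0.10
    lung_level: float = 0.30
    thorax_level: float = 0.75
    mediastinum_level: float = 0.88
    rib_level: float = 0.95
    rib_overlay_delta: float = 0.22                       # added to lung under a rib
    rib_count_range: tuple[int, int] = (4, 6)
    rib_halfwidth: tuple[float, float] = (0.010, 0.018)
    distractor_probability: float = 0.5
    distractor_radius: tuple[float, float] = (0.02, 0.05)
    noise_sigma: float = 0.03
    # per-image "machine" transform a*I + b (a log-uniform, b uniform)
    gain_range: tuple[float, float] = (0.5, 4000.0)
    offset_range: tuple[float, float] = (0.0, 2000.0)
    # mask-corruption fixture (speck outside + hole inside the lungs)
    speck_probability: float = 1.0
    hole_probability: float = 1.0
    speck_radius: float = 0.035
    hole_radius: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if not (self.lung_level < self.thorax_level < self.rib_level):
            raise ValueError("contrast ordering lung < thorax < rib is required")
        if self.side < 16:
            raise ValueError("side must be >= 16")


def _ellipse(side: int, cr: float, cc: float, ar: float, ac: float,
             theta: float = 0.0) -> np.ndarray:
    """Boolean ellipse; centre/axes in pixels, theta in radians."""
    rr, cc_ = np.mgrid[0:side, 0:side]
    dr, dc = rr - cr, cc_ - cc
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dr + st * dc
    v = -st * dr + ct * dc
    return (u / ar) ** 2 + (v / ac) ** 2 <= 1.0


def _rng_for(cfg: PhantomConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, index])


def generate_phantom(cfg: PhantomConfig, index: int) -> tuple[RawImage, np.ndarray]:
    """Render phantom ``index`` under ``cfg``; returns (raw image, binary mask)."""
    rng = _rng_for(cfg, index)
    s = cfg.side
    img = np.full((s, s), cfg.background_level)

    thorax = _ellipse(s, 0.5 * s, 0.5 * s, cfg.thorax_axes[0] * s,
                      cfg.thorax_axes[1] * s)
    img[thorax] = cfg.thorax_level

    lungs = np.zeros((s, s), dtype=bool)
    for sign in (-1.0, 1.0):
        cr = (cfg.lung_center_row + rng.uniform(-1, 1) * cfg.lung_center_jitter) * s
        ccol = (0.5 + sign * cfg.lung_center_col_offset
                + rng.uniform(-1, 1) * cfg.lung_center_jitter) * s
        ar = (cfg.lung_axes[0] + rng.uniform(-1, 1) * cfg.lung_axes_jitter) * s
        ac = (cfg.lung_axes[1] + rng.uniform(-1, 1) * cfg.lung_axes_jitter) * s
        theta = sign * rng.uniform(0, cfg.lung_rotation_max)
        if not (0 < cr - ar and cr + ar < s and 0 < ccol - ac and ccol + ac < s):
            raise ValueError("lung ellipse extends off canvas; tighten geometry")
        lungs |= _ellipse(s, cr, ccol, ar, ac, theta)

    cols = np.arange(s)[None, :]
    band = thorax & (np.abs(cols - 0.5 * s) <= cfg.mediastinum_halfwidth * s) & ~lungs
    img[band] = cfg.mediastinum_level
    img[lungs] = cfg.lung_level

    # rib stripes: bright where they cross the thorax, milder over the lungs
    rows = np.arange(s)[:, None]
    n_ribs = int(rng.integers(cfg.rib_count_range[0], cfg.rib_count_range[1] + 1))
    centres = np.sort(rng.uniform(0.18, 0.82, size=n_ribs)) * s
    for rc in centres:
        hw = rng.uniform(*cfg.rib_halfwidth) * s
        slope = rng.uniform(-0.08, 0.08)
        stripe = np.abs(rows - (rc + slope * (cols - 0.5 * s))) <= hw
        img[stripe & thorax & ~lungs] = cfg.rib_level
        sel = stripe & lungs
        img[sel] = cfg.lung_level + cfg.rib_overlay_delta

    # distractors: lung-level blobs outside the lung fields
    if rng.random() < cfg.distractor_probability:
        for _ in range(int(rng.integers(1, 3))):
            for _attempt in range(50):
                r = rng.uniform(*cfg.distractor_radius) * s
                cr = rng.uniform(0.1 * s, 0.9 * s)
                ccol = rng.uniform(0.1 * s, 0.9 * s)
                blob = _ellipse(s, cr, ccol, r, r)
                if not (blob & lungs).any():
                    img[blob] = cfg.lung_level
                    break

    noise = rng.normal(0.0, cfg.noise_sigma, size=(s, s))
    gain = float(np.exp(rng.uniform(np.log(cfg.gain_range[0]),
                                    np.log(cfg.gain_range[1]))))
    offset = float(rng.uniform(*cfg.offset_range))
    raw = gain * (img + noise) + offset
    return RawImage(raw), lungs.astype(np.uint8)


def generate_pairs(n: int, cfg: PhantomConfig) -> list[tuple[RawImage, np.ndarray]]:
    """The first ``n`` phantoms, in memory."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_phantom(cfg, i) for i in range(n)]


def generate_dataset(n: int, cfg: PhantomConfig, outdir: Path | str) -> dict:
    """Write ``n`` phantoms to ``outdir`` (images/, masks/, manifest.json).

    Raw intensities are stored as 16-bit PNG after a per-image linear scale to
    the full uint16 range; the scale is recorded in the manifest.  Because the
    preprocessing window is invariant to positive affine maps, this storage
    transform is harmless downstream.
    """
    from . import imgio

    if int(n) < 1:
        raise ValueError("n must be >= 1")
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(int(n)):
        raw, mask = generate_phantom(cfg, i)
        name = f"phantom_{i:04d}"
        lo, hi = float(raw.pixels.min()), float(raw.pixels.max())
        imgio.write_image_png16(outdir / "images" / f"{name}.png", raw.pixels)
        imgio.write_mask_png(outdir / "masks" / f"{name}.png", mask)
        entries.append({"id": name, "index": i, "store_min": lo, "store_max": hi})
    manifest = {"n": int(n), "config": asdict(cfg), "entries": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def regenerate_from_manifest(manifest: dict) -> list[tuple[RawImage, np.ndarray]]:
    cfgd = dict(manifest["config"])
    for key in ("thorax_axes", "lung_axes", "rib_count_range", "rib_halfwidth",
                "distractor_radius", "gain_range", "offset_range"):
        cfgd[key] = tuple(cfgd[key])
    cfg = PhantomConfig(**cfgd)
    return [generate_phantom(cfg, e["index"]) for e in manifest["entries"]]


def corrupt_mask(mask: np.ndarray, cfg: PhantomConfig, seed: int) -> np.ndarray:
    """Inject the two clean-up failure modes into a ground-truth mask.

    With the configured probabilities, adds one small foreground speck outside
    the mask and punches one fully-enclosed hole inside it.  Used as a fixture
    for the post-processing stage.
    """
    rng = np.random.default_rng([cfg.seed, 7_777_777, seed])
    m = (np.asarray(mask) > 0).copy()
    s = m.shape[0]
    if rng.random() < cfg.speck_probability:
        r = max(2, int(round(cfg.speck_radius * s)))
        dilated = ndimage.binary_dilation(m, iterations=r + 2)
        free = np.argwhere(~dilated)
        margin = (free[:, 0] > r) & (free[:, 0] < s - r - 1) \
            & (free[:, 1] > r) & (free[:, 1] < m.shape[1] - r - 1)
        free = free[margin]
        if len(free):
            cr, cc = free[rng.integers(len(free))]
            m |= _ellipse(s, cr, cc, r, r)
    if rng.random() < cfg.hole_probability:
        r = max(1, int(round(cfg.hole_radius * s)))
        interior = ndimage.binary_erosion(m, iterations=r + 2)
        inside = np.argwhere(interior)
        if len(inside):
            cr, cc = inside[rng.integers(len(inside))]
            m &= ~_ellipse(s, cr, cc, r, r)
    return m.astype(np.uint8)
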