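"""Tile extraction from whole-slide images: background and tumor filtering.

Slides are scanned with a non-overlapping sliding window of 1024 px at native
resolution (0.549 um/px by default, i.e. a 562x562 micron tissue window). A
window is kept only if

* it is not background: a patch is rejected when the per-channel medians of
  all three RGB channels exceed ``median_high`` (bright background/glass) or
  all fall below ``median_low`` (pen/scanner artifacts); and
* strictly more than ``tumor_min_fraction`` of its area lies inside the
  tumor mask (masks come from files; segmentation itself is out of scope).

Coordinates are 0-based level-0 pixels, boxes half-open, and the scan is
row-major (y outer, x inner), so the accepted tile list is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .synthetic import SUBTYPES

logger = logging.getLogger(__name__)

_VALID_SUBTYPES = SUBTYPES + ("unknown",)


@dataclass(frozen=True)
class SlideRecord:
    """One slide: identity, patient grouping, file paths, resolution, label."""

    slide_id: str
    patient_id: str
    image_path: str
    mask_path: str
    mpp: float
    subtype: str = "unknown"
    mask_downsample: int = 1

    def __post_init__(self) -> None:
        if not self.mpp > 0:
            raise ValueError(f"slide {self.slide_id}: mpp must be > 0, got {self.mpp}")
        if self.subtype not in _VALID_SUBTYPES:
            raise ValueError(
                f"slide {self.slide_id}: subtype {self.subtype!r} not in {_VALID_SUBTYPES}"
            )
        if self.mask_downsample < 1:
            raise ValueError("mask_downsample must be a positive integer")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the tile filters.

    ``reject_if_any_channel=False`` (default) rejects a patch only when ALL
    three channel medians violate the same bound, which discards uniform
    white/black artifacts without dropping eosin-dominant tissue where a
    single channel is bright; the any-channel variant is available as a
    switch. ``tumor_min_fraction`` is a strict lower bound (a tile at exactly
    50% tumor is rejected).
    """

    median_low: float = 100.0
    median_high: float = 200.0
    tumor_min_fraction: float = 0.5
    tile_px: int = 1024
    stride_px: int = 1024
    reject_if_any_channel: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.median_low < self.median_high <= 255:
            raise ValueError("need 0 <= median_low < median_high <= 255")
        if not 0.0 <= self.tumor_min_fraction <= 1.0:
            raise ValueError("tumor_min_fraction must lie in [0, 1]")
        if self.tile_px < 1 or self.stride_px < 1:
            raise ValueError("tile_px and stride_px must be positive")


@dataclass(frozen=True)
class TileCandidate:
    """An accepted tile: half-open box [x0, x0+tile_px) x [y0, y0+tile_px)."""

    slide_id: str
    x0: int
    y0: int
    tumor_fraction: float
    channel_medians: tuple[float, float, float]


@dataclass
class TileScanStats:
    """Per-slide accounting of the grid scan, for run logs."""

    slide_id: str
    n_windows: int = 0
    n_background_rejected: int = 0
    n_tumor_rejected: int = 0
    n_accepted: int = 0


def effective_mpp(native_mpp: float, source_px: float, target_px: float) -> float:
    """Physical resolution after resampling a ``source_px`` window to
    ``target_px`` pixels: the window keeps its physical extent, so
    mpp scales by source_px / target_px."""
    if native_mpp <= 0 or source_px <= 0 or target_px <= 0:
        raise ValueError("effective_mpp arguments must all be positive")
    return native_mpp * source_px / target_px


def passes_background_filter(
    patch: np.ndarray, config: FilterConfig = FilterConfig()
) -> tuple[bool, tuple[float, float, float]]:
    """Apply the median-intensity background filter to an RGB patch.

    Returns ``(accept, (median_r, median_g, median_b))``.
    """
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[-1] != 3 or patch.size == 0:
        raise ValueError(f"expected a non-empty (H, W, 3) patch, got shape {patch.shape}")
    medians = np.median(patch.reshape(-1, 3), axis=0)
    if config.reject_if_any_channel:
        reject = bool(np.any(medians > config.median_high) or np.any(medians < config.median_low))
    else:
        reject = bool(np.all(medians > config.median_high) or np.all(medians < config.median_low))
    return (not reject), (float(medians[0]), float(medians[1]), float(medians[2]))


def tumor_fraction(
    x0: int, y0: int, tile_px: int, mask: np.ndarray, downsample: int = 1
) -> float:
    """Fraction of the tile box covered by the tumor mask.

    The box (level-0 pixel coordinates) is mapped onto the mask grid by
    nearest-pixel division by ``downsample``; the fraction is the mean of the
    binarized mask over that region. No interpolation is performed.
    """
    mask = np.asarray(mask)
    if downsample < 1:
        raise ValueError("downsample must be a positive integer")
    r0, r1 = y0 // downsample, (y0 + tile_px) // downsample
    c0, c1 = x0 // downsample, (x0 + tile_px) // downsample
    if r0 < 0 or c0 < 0 or r1 > mask.shape[0] or c1 > mask.shape[1] or r1 <= r0 or c1 <= c0:
        raise ValueError(
            f"tile box [{x0},{x0 + tile_px})x[{y0},{y0 + tile_px}) maps outside the "
            f"mask extent {mask.shape} at downsample {downsample}"
        )
    region = mask[r0:r1, c0:c1]
    return float(np.count_nonzero(region)) / region.size


def load_slide_image(path: str | Path) -> np.ndarray:
    """Read a slide raster (tiled TIFF or PNG) as a (H, W, 3) uint8 array."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            img = tifffile.imread(path)
        else:
            img = np.asarray(Image.open(path).convert("RGB"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read slide image {path}: {exc}") from exc
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary tumor mask (any raster) as a (H, W) array of {0, 1}."""
    path = Path(path)
    try:
        arr = np.asarray(Image.open(path).convert("L"))
    except OSError as exc:
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    return (arr > 0).astype(np.uint8)


def scan_slide(
    slide: SlideRecord, config: FilterConfig = FilterConfig()
) -> Iterator[tuple[TileCandidate, np.ndarray]]:
    """Yield ``(candidate, pixels)`` for every accepted window of a slide.

    The background filter runs first (it is cheaper); a window must pass it
    AND have tumor_fraction strictly above ``config.tumor_min_fraction``.
    Collect the per-slide accounting afterwards from :func:`extract_tiles`.
    """
    image = load_slide_image(slide.image_path)
    mask = load_mask(slide.mask_path)
    yield from _scan_arrays(slide, image, mask, config)


def _scan_arrays(
    slide: SlideRecord,
    image: np.ndarray,
    mask: np.ndarray,
    config: FilterConfig,
    stats: TileScanStats | None = None,
) -> Iterator[tuple[TileCandidate, np.ndarray]]:
    h, w = image.shape[:2]
    t, s = config.tile_px, config.stride_px
    if h < t or w < t:
        raise ValueError(
            f"slide {slide.slide_id}: dimensions ({h}, {w}) smaller than tile_px {t}"
        )
    for y0 in range(0, h - t + 1, s):
        for x0 in range(0, w - t + 1, s):
            if stats is not None:
                stats.n_windows += 1
            patch = image[y0 : y0 + t, x0 : x0 + t]
            ok, medians = passes_background_filter(patch, config)
            if not ok:
                if stats is not None:
                    stats.n_background_rejected += 1
                continue
            frac = tumor_fraction(x0, y0, t, mask, slide.mask_downsample)
            if not frac > config.tumor_min_fraction:
                if stats is not None:
                    stats.n_tumor_rejected += 1
                continue
            if stats is not None:
                stats.n_accepted += 1
            yield TileCandidate(slide.slide_id, x0, y0, frac, medians), patch


def extract_tiles(
    slide: SlideRecord,
    config: FilterConfig = FilterConfig(),
    stats: TileScanStats | None = None,
) -> list[TileCandidate]:
    """Accepted tile candidates of one slide, in row-major scan order."""
    image = load_slide_image(slide.image_path)
    mask = load_mask(slide.mask_path)
    if stats is None:
        stats = TileScanStats(slide.slide_id)
    out = [cand for cand, _ in _scan_arrays(slide, image, mask, config, stats)]
    logger.info(
        "slide %s: %d windows, %d rejected background, %d rejected tumor-fraction, %d accepted",
        slide.slide_id,
        stats.n_windows,
        stats.n_background_rejected,
        stats.n_tumor_rejected,
        stats.n_accepted,
    )
    return out


def read_manifest(path: str | Path) -> list[SlideRecord]:
    """Load a cohort manifest CSV; relative paths resolve against its folder."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"slide_id", "patient_id", "image_path", "mask_path", "mpp", "subtype"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    base = path.parent
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SlideRecord(
                slide_id=str(row.slide_id),
                patient_id=str(row.patient_id),
                image_path=str((base / str(row.image_path)).resolve()),
                mask_path=str((base / str(row.mask_path)).resolve()),
                mpp=float(row.mpp),
                subtype=str(row.subtype),
                mask_downsample=int(getattr(row, "mask_downsample", 1)),
            )
        )
    return records


def write_tile_index(candidates: list[TileCandidate], path: str | Path) -> None:
    """Write accepted tiles to a ``slide_id,x0,y0,tumor_fraction`` CSV."""
    pd.DataFrame(
        [
            {
                "slide_id": c.slide_id,
                "x0": c.x0,
                "y0": c.y0,
                "tumor_fraction": c.tumor_fraction,
            }
            for c in candidates
        ],
        columns=["slide_id", "x0", "y0", "tumor_fraction"],
    ).to_csv(path, index=False)
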