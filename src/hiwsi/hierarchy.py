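"""Three-scale patch hierarchy: P_l / P_m / P_s views of a 1024-px tile.

Vision-transformer encoders accept a fixed 224x224 input, so each native
1024-px tumor tile is resampled into three physically nested views:

* P_l - the full 1024-px tile area-averaged to 224 px (2.51 um/px at the
  0.549 um/px native resolution): macroscopic tissue architecture.
* P_m - the exact center 512-px crop downsampled to 224 px (1.25 um/px):
  intermediate context.
* P_s - selective sampling: the center 512-px crop is split into four
  256-px quadrants, scanned top-left, top-right, bottom-left, bottom-right;
  the first quadrant passing the color (background) filter is downsampled to
  224 px (0.63 um/px). If none passes, the whole tile is discarded.

All reductions use exact area averaging (each output pixel is the mean of
its fractional source box), the standard anti-aliasing choice for such
reductions, and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .tiling import FilterConfig, TileCandidate, passes_background_filter

#: Quadrant scan order of the selective-sampling rule (row, col) offsets:
#: top-left, top-right, bottom-left, bottom-right.
BLOCK_SCAN_ORDER = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class HierarchyConfig:
    source_px: int = 1024
    mid_px: int = 512
    block_px: int = 256
    target_px: int = 224
    color_filter: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if self.mid_px * 2 != self.source_px or self.block_px * 2 != self.mid_px:
            raise ValueError("require mid_px = source_px/2 and block_px = mid_px/2")
        if not 0 < self.target_px < self.block_px:
            raise ValueError("require 0 < target_px < block_px")


@dataclass(frozen=True)
class PatchTriple:
    """The three 224-px views of one source tile, plus provenance.

    ``ps_block_index`` indexes :data:`BLOCK_SCAN_ORDER` and records which
    256-px quadrant of the center crop produced P_s.
    """

    slide_id: str
    x0: int
    y0: int
    p_l: np.ndarray
    p_m: np.ndarray
    p_s: np.ndarray
    ps_block_index: int


@lru_cache(maxsize=16)
def _box_weights(source_px: int, target_px: int) -> np.ndarray:
    """(target, source) row-stochastic matrix of fractional box overlaps.

    Output pixel i covers the source interval [i*r, (i+1)*r) with
    r = source/target; entry (i, j) is the overlap of source pixel j with
    that interval, normalized so rows sum to 1. Applying the matrix on both
    axes performs exact area-average resampling.
    """
    r = source_px / target_px
    w = np.zeros((target_px, source_px), dtype=np.float64)
    for i in range(target_px):
        lo, hi = i * r, (i + 1) * r
        j0, j1 = int(np.floor(lo)), min(int(np.ceil(hi)), source_px)
        for j in range(j0, j1):
            w[i, j] = max(0.0, min(hi, j + 1) - max(lo, j))
    return w / r


def area_resample(img: np.ndarray, target_px: int) -> np.ndarray:
    """Area-average a square (S, S, 3) image to (target_px, target_px, 3)."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[0] != img.shape[1] or img.shape[2] != 3:
        raise ValueError(f"expected a square (S, S, 3) image, got shape {img.shape}")
    w = _box_weights(img.shape[0], target_px)
    x = img.astype(np.float64)
    out = np.empty((target_px, target_px, 3), dtype=np.float64)
    for c in range(3):
        out[:, :, c] = w @ x[:, :, c] @ w.T
    return out


def _check_tile(tile: np.ndarray, source_px: int) -> np.ndarray:
    tile = np.asarray(tile)
    if tile.shape != (source_px, source_px, 3):
        raise ValueError(
            f"expected a ({source_px}, {source_px}, 3) tile, got shape {tile.shape}"
        )
    return tile


def make_p_l(tile: np.ndarray, config: HierarchyConfig = HierarchyConfig()) -> np.ndarray:
    """Large-scale view: direct downsample of the whole tile to 224 px."""
    tile = _check_tile(tile, config.source_px)
    return area_resample(tile, config.target_px)


def center_crop(tile: np.ndarray, config: HierarchyConfig = HierarchyConfig()) -> np.ndarray:
    """The exact central mid_px crop (rows/cols [256, 768) at defaults)."""
    tile = _check_tile(tile, config.source_px)
    lo = (config.source_px - config.mid_px) // 2
    return tile[lo : lo + config.mid_px, lo : lo + config.mid_px]


def make_p_m(tile: np.ndarray, config: HierarchyConfig = HierarchyConfig()) -> np.ndarray:
    """Medium-scale view: center 512-px crop downsampled to 224 px."""
    return area_resample(center_crop(tile, config), config.target_px)


def select_p_s(
    tile: np.ndarray, config: HierarchyConfig = HierarchyConfig()
) -> tuple[np.ndarray, int] | None:
    """Selective sampling of the small-scale view.

    Scans the four 256-px quadrants of the center crop in
    :data:`BLOCK_SCAN_ORDER` and returns ``(p_s, block_index)`` for the first
    quadrant passing the color filter, or ``None`` (discard the whole tile)
    if all four fail.
    """
    crop = center_crop(tile, config)
    b = config.block_px
    for idx, (r, c) in enumerate(BLOCK_SCAN_ORDER):
        quadrant = crop[r * b : (r + 1) * b, c * b : (c + 1) * b]
        ok, _ = passes_background_filter(quadrant, config.color_filter)
        if ok:
            return area_resample(quadrant, config.target_px), idx
    return None


def build_triple(
    candidate: TileCandidate,
    tile: np.ndarray,
    config: HierarchyConfig = HierarchyConfig(),
) -> PatchTriple | None:
    """Assemble the PatchTriple for an accepted tile, or ``None`` when the
    selective-sampling rule discards it (P_l and P_m are always computable,
    but the sample is dropped whole)."""
    selected = select_p_s(tile, config)
    if selected is None:
        return None
    p_s, block_index = selected
    return PatchTriple(
        slide_id=candidate.slide_id,
        x0=candidate.x0,
        y0=candidate.y0,
        p_l=make_p_l(tile, config),
        p_m=make_p_m(tile, config),
        p_s=p_s,
        ps_block_index=block_index,
    )
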