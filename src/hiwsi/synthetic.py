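"""Synthetic endometrial-cancer slide cohorts for end-to-end pipeline testing.

Real molecular-subtyping cohorts (H&E whole-slide images with NGS-derived
labels) are rarely public, so this module fabricates slides that carry the
*statistical* structure the pipeline depends on, without attempting realistic
H&E texture:

* four subtype classes (MMRd, NSMP, p53abn, POLEmut);
* multi-slide-per-patient grouping, so patient-grouped cross-validation is
  exercised;
* tumor / benign-tissue / bright-background regions with controllable tumor
  coverage, so tile filtering has something to filter;
* a class signal injected at a controlled spatial scale, so the multi-scale
  patch hierarchy is the thing that has to recover it.

Signal design
-------------
Coarse-signal classes differ by a low-spatial-frequency tone (features
>= 256 px): a +/- ``RING_AMPLITUDE`` offset on the ring of each 1024-px tile
outside its central 512x512. Only the large-scale view of a tile sees that
ring, so the signal survives the P_l resampling path and no other.

Fine-signal classes differ by high-spatial-frequency texture (features
<= 8 px): one class gets single-pixel dots of amplitude +/- ``DOT_AMPLITUDE``
at density ``DOT_DENSITY``; the other gets i.i.d. Gaussian fine noise with the
*same* per-pixel variance (sd = DOT_AMPLITUDE * sqrt(DOT_DENSITY)). Mean and
variance are matched at every scale; the two are distinguishable only by
distribution shape, which survives the near-native P_s crop but is washed out
to near-Gaussian by the ~4.57x area averaging of the P_l path.

Everything is deterministic: per-slide seeds are derived from the cohort seed
and the slide id through a stable hash, so regeneration is byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

#: The four molecular subtypes of endometrial carcinoma (TCGA classification),
#: in the canonical label order used throughout the package.
SUBTYPES = ("MMRd", "NSMP", "p53abn", "POLEmut")

MANIFEST_COLUMNS = ("slide_id", "patient_id", "image_path", "mask_path", "mpp", "subtype")

# Appearance constants (8-bit intensity units).
BACKGROUND_LEVEL = 245.0   # non-tissue background; kept strictly above 230
BACKGROUND_MIN = 231.0
TISSUE_RGB = (186.0, 148.0, 178.0)  # eosin-leaning base tone
RING_AMPLITUDE = 20.0      # coarse-pair tone offset on the tile ring
DOT_AMPLITUDE = 50.0       # fine-pair dot amplitude
DOT_DENSITY = 0.1          # fraction of tumor pixels carrying a dot
TILE_PX = 1024             # native tile size the ring geometry is aligned to
CENTER_LO, CENTER_HI = 256, 768  # central 512-px window within a tile


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    ``coarse_signal_classes`` and ``fine_signal_classes`` must partition the
    four subtypes. ``slide_px`` must be a multiple of 1024 so tiles align
    exactly with the ring geometry.
    """

    slides_per_class: int = 10
    two_slide_patient_fraction: float = 0.125
    slide_px: int = 4096
    mpp: float = 0.549
    tumor_coverage: float = 0.6
    coarse_signal_classes: tuple[str, ...] = ("MMRd", "NSMP")
    fine_signal_classes: tuple[str, ...] = ("p53abn", "POLEmut")
    noise_sd: float = 8.0
    seed: int = 0

    n_classes: int = field(default=4, init=False)

    def __post_init__(self) -> None:
        if self.slides_per_class < 1:
            raise ValueError("slides_per_class must be >= 1")
        if not 0.0 <= self.two_slide_patient_fraction <= 1.0:
            raise ValueError("two_slide_patient_fraction must lie in [0, 1]")
        if self.slide_px % TILE_PX != 0 or self.slide_px < TILE_PX:
            raise ValueError(f"slide_px must be a positive multiple of {TILE_PX}")
        if not 0.0 <= self.tumor_coverage <= 1.0:
            raise ValueError("tumor_coverage must lie in [0, 1]")
        combined = set(self.coarse_signal_classes) | set(self.fine_signal_classes)
        overlap = set(self.coarse_signal_classes) & set(self.fine_signal_classes)
        if combined != set(SUBTYPES) or overlap:
            raise ValueError(
                "coarse_signal_classes and fine_signal_classes must partition "
                f"{SUBTYPES}; got coarse={self.coarse_signal_classes}, "
                f"fine={self.fine_signal_classes}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def slide_seed(seed: int, slide_id: str) -> int:
    """Per-slide RNG seed: cohort seed XOR a stable 31-bit hash of the id.

    Uses blake2b (not Python's salted ``hash``) so the value is stable across
    processes, enabling byte-identical partial regeneration.
    """
    digest = hashlib.blake2b(slide_id.encode("utf-8"), digest_size=4).digest()
    return (int.from_bytes(digest, "big") ^ int(seed)) & 0x7FFFFFFF


def _tile_ring_mask(slide_px: int) -> np.ndarray:
    """Boolean (slide_px, slide_px) mask of pixels outside the central 512x512
    window of their 1024-px tile (the region only the P_l view observes)."""
    coord = np.arange(slide_px) % TILE_PX
    in_center = (coord >= CENTER_LO) & (coord < CENTER_HI)
    return ~(in_center[:, None] & in_center[None, :])


def _tumor_bounds(spec: SyntheticCohortSpec) -> tuple[int, int, int]:
    """Return (background_band_width, tumor_col_lo, tumor_col_hi)."""
    band = spec.slide_px // 4
    tissue_w = spec.slide_px - band
    tumor_w = int(round(spec.tumor_coverage * tissue_w))
    return band, band, band + tumor_w


def generate_slide(
    spec: SyntheticCohortSpec, subtype: str, slide_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic slide and its binary tumor mask.

    Layout: a bright background band occupies the left quarter of the slide
    (all channel values > 230, so its tiles fail the background filter);
    the rest is tissue; a full-height tumor rectangle covers
    ``tumor_coverage`` of the tissue area. The class signal is injected in
    the tumor region only.

    Returns ``(image, mask)`` with image uint8 of shape (S, S, 3) and mask
    uint8 of shape (S, S) with 1 marking tumor.
    """
    if subtype not in SUBTYPES:
        raise ValueError(f"unknown subtype {subtype!r}; expected one of {SUBTYPES}")
    s = spec.slide_px
    rng = np.random.default_rng(slide_seed)

    img = np.empty((s, s, 3), dtype=np.float32)
    img[...] = np.asarray(TISSUE_RGB, dtype=np.float32)
    if spec.noise_sd > 0:
        img += rng.standard_normal((s, s, 3), dtype=np.float32) * spec.noise_sd

    band, t_lo, t_hi = _tumor_bounds(spec)
    mask = np.zeros((s, s), dtype=np.uint8)
    mask[:, t_lo:t_hi] = 1

    signal = np.zeros((s, s), dtype=np.float32)
    if t_hi > t_lo:
        if subtype in spec.coarse_signal_classes:
            sign = 1.0 if subtype == spec.coarse_signal_classes[0] else -1.0
            ring = _tile_ring_mask(s)
            signal[ring] = sign * RING_AMPLITUDE
        else:
            fine_idx = spec.fine_signal_classes.index(subtype)
            if fine_idx == 0:
                dots = rng.random((s, s), dtype=np.float32) < DOT_DENSITY
                dot_sign = np.where(rng.random((s, s), dtype=np.float32) < 0.5, -1.0, 1.0)
                signal = np.where(dots, dot_sign * DOT_AMPLITUDE, 0.0).astype(np.float32)
            else:
                fine_sd = DOT_AMPLITUDE * float(np.sqrt(DOT_DENSITY))
                signal = rng.standard_normal((s, s), dtype=np.float32) * fine_sd
        signal[mask == 0] = 0.0
        img += signal[:, :, None]

    # Background band last so it is exactly controlled (always > 230).
    if band > 0:
        bg = np.full((s, band, 3), BACKGROUND_LEVEL, dtype=np.float32)
        if spec.noise_sd > 0:
            bg += rng.standard_normal((s, band, 3), dtype=np.float32) * spec.noise_sd
        img[:, :band] = np.clip(bg, BACKGROUND_MIN, 255.0)

    return np.clip(img, 0.0, 255.0).astype(np.uint8), mask


def plan_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Deterministic cohort plan: slide ids, patient grouping, subtypes, seeds.

    Patient assignment (per class, so both slides of a patient share a
    subtype): with n slides and two-slide fraction f, the number of two-slide
    patients is round(f * n / (1 + f)) (so that the *fraction of patients*
    with two slides is ~f); a seeded shuffle of the class's slides decides
    which slides are paired.
    """
    rows = []
    rng = np.random.default_rng(spec.seed)
    for cls in SUBTYPES:
        n = spec.slides_per_class
        f = spec.two_slide_patient_fraction
        n_two = min(int(round(f * n / (1.0 + f))), n // 2)
        order = rng.permutation(n)
        patient_of = np.empty(n, dtype=int)
        for k in range(n_two):
            patient_of[order[2 * k]] = k
            patient_of[order[2 * k + 1]] = k
        for j, slide_pos in enumerate(order[2 * n_two :]):
            patient_of[slide_pos] = n_two + j
        for i in range(n):
            sid = f"{cls}_{i:03d}"
            rows.append(
                {
                    "slide_id": sid,
                    "patient_id": f"pt_{cls}_{patient_of[i]:03d}",
                    "subtype": cls,
                    "slide_seed": slide_seed(spec.seed, sid),
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(spec: SyntheticCohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write slide TIFFs, mask PNGs and the manifest CSV under ``out_dir``.

    Returns the manifest as a DataFrame with columns
    ``slide_id,patient_id,image_path,mask_path,mpp,subtype``; paths in the
    CSV are relative to the manifest location. Regeneration with the same
    spec is byte-identical.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    plan = plan_cohort(spec)
    records = []
    for row in plan.itertuples(index=False):
        img, mask = generate_slide(spec, row.subtype, row.slide_seed)
        image_name = f"{row.slide_id}.tiff"
        mask_name = f"{row.slide_id}_mask.png"
        tifffile.imwrite(out / image_name, img, tile=(TILE_PX, TILE_PX))
        Image.fromarray(mask * 255, mode="L").save(out / mask_name)
        records.append(
            {
                "slide_id": row.slide_id,
                "patient_id": row.patient_id,
                "image_path": image_name,
                "mask_path": mask_name,
                "mpp": spec.mpp,
                "subtype": row.subtype,
            }
        )
    manifest = pd.DataFrame(records, columns=list(MANIFEST_COLUMNS))
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
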