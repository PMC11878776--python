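"""Bookkeeping for the reference endometrial-cancer cohort.

The pipeline was designed against a single-center FUSCC cohort of H&E
whole-slide images with NGS-determined molecular subtypes. The raw slides
are not public, but the cohort's published accounting (screening exclusions,
per-subtype slide and patch counts) is recorded here both as documentation
of the intended operating scale and as arithmetic the test suite can verify.
"""

from __future__ import annotations

#: Screening: slides scanned, then excluded for missing sequencing data or
#: poor slide quality, leaving the analyzed cohort.
SLIDES_SCREENED = 378
EXCLUDED_MISSING_SEQUENCING = 10
EXCLUDED_POOR_QUALITY = 4
PATIENTS_SCREENED = 333
PATIENTS_INCLUDED = 324

#: Slides per molecular subtype in the analyzed cohort.
SLIDES_PER_SUBTYPE = {"MMRd": 83, "NSMP": 161, "p53abn": 67, "POLEmut": 53}

#: Patches per subtype after tumor filtering and class balancing
#: (MMRd resampled at 70%, NSMP at 50%).
PATCHES_PER_SUBTYPE = {"MMRd": 11393, "NSMP": 15048, "p53abn": 13599, "POLEmut": 9727}


def included_slide_count(
    screened: int = SLIDES_SCREENED,
    exclusions: tuple[int, ...] = (EXCLUDED_MISSING_SEQUENCING, EXCLUDED_POOR_QUALITY),
) -> int:
    """Slides remaining after screening exclusions."""
    remaining = screened - sum(exclusions)
    if remaining < 0:
        raise ValueError("exclusions exceed the screened count")
    return remaining


def total_patch_count(per_subtype: dict[str, int] | None = None) -> int:
    """Total patch count as the sum over subtypes."""
    counts = PATCHES_PER_SUBTYPE if per_subtype is None else per_subtype
    return sum(counts.values())


def total_slide_count(per_subtype: dict[str, int] | None = None) -> int:
    """Total slide count as the sum over subtypes."""
    counts = SLIDES_PER_SUBTYPE if per_subtype is None else per_subtype
    return sum(counts.values())
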