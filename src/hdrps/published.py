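"""Published reference figures for the HDRPS material library and cohorts.

The released HDRPS instrument ships a library of 3,386 affect-labeled
photographs in five content categories, built from two rating rounds (an
expert panel followed by a larger professional panel) with 60% identity-ratio
screening and cross-round label-consistency merging.  This module records the
published descriptive statistics of that library, the published exemplar
pictures with their mean valence/arousal ratings, and the published
recruitment bookkeeping of the rating panels and validation cohorts — the
constants a user needs to cross-check a rebuilt library or to score trials
taken against the released instrument.
"""

from __future__ import annotations

import pandas as pd

from .affect_core import Category

__all__ = [
    "LIBRARY_COUNTS",
    "LIBRARY_SUMMARY",
    "EXEMPLAR_PICTURES",
    "library_summary_table",
    "exemplar_table",
    "category_shares",
    "professional_panel_size",
    "formal_cohort_size",
]

#: Per-category picture counts of the released library.
LIBRARY_COUNTS: dict[Category, int] = {
    Category.PEOPLE: 404,
    Category.ANIMALS: 585,
    Category.PLANTS: 529,
    Category.OBJECTS: 609,
    Category.SCENES: 1259,
}

#: Per-category (count, valence min/max/mean, arousal min/max/mean).
LIBRARY_SUMMARY: dict[Category, dict[str, float]] = {
    Category.PEOPLE: dict(n=404, v_min=1.00, v_max=8.97, v_mean=5.04, a_min=1.21, a_max=8.94, a_mean=5.80),
    Category.ANIMALS: dict(n=585, v_min=2.27, v_max=8.09, v_mean=5.72, a_min=2.32, a_max=8.71, a_mean=5.20),
    Category.PLANTS: dict(n=529, v_min=2.88, v_max=8.02, v_mean=5.94, a_min=2.23, a_max=7.42, a_mean=4.95),
    Category.OBJECTS: dict(n=609, v_min=1.92, v_max=8.21, v_mean=5.33, a_min=1.13, a_max=9.00, a_mean=4.63),
    Category.SCENES: dict(n=1259, v_min=2.01, v_max=7.90, v_mean=5.14, a_min=1.01, a_max=7.30, a_mean=4.43),
}

#: The twenty published exemplar pictures (one per category x valence
#: stratum) with their mean valence (V) and arousal (A) ratings.
EXEMPLAR_PICTURES: dict[str, tuple[float, float]] = {
    "people-p081": (6.65, 7.30),
    "people-hn093": (5.84, 4.96),
    "people-ln016": (4.57, 3.94),
    "people-n127": (2.67, 4.17),
    "animals-p057": (6.11, 6.14),
    "animals-hn078": (5.76, 4.98),
    "animals-ln005": (4.46, 4.03),
    "animals-n002": (3.38, 7.97),
    "plants-p264": (6.70, 6.21),
    "plants-hn170": (5.89, 5.03),
    "plants-ln003": (4.05, 3.98),
    "plants-n013": (3.47, 3.73),
    "objects-p205": (6.74, 5.08),
    "objects-hn167": (5.80, 4.98),
    "objects-ln017": (4.45, 5.23),
    "objects-n125": (2.78, 4.88),
    "scenes-p306": (6.92, 6.16),
    "scenes-hn044": (5.93, 4.83),
    "scenes-ln100": (4.69, 4.02),
    "scenes-n235": (2.98, 4.11),
}

# Professional-panel recruitment bookkeeping: recruited, then excluded for
# low professional relevance, color-vision failure, SAS above norm and SDS
# above norm, with an overlap that exceeded both SAS and SDS.
PROFESSIONAL_RECRUITED = 244
EXCLUDED_LOW_RELEVANCE = 25
EXCLUDED_COLOR_VISION = 1
EXCLUDED_SAS = 9
EXCLUDED_SDS = 3
EXCLUDED_SAS_AND_SDS_OVERLAP = 3

# Formal validation cohort: working employees who passed screening, by gender.
FORMAL_COHORT_MALES = 154
FORMAL_COHORT_FEMALES = 368


def professional_panel_size() -> int:
    """Professional rater count from recruitment minus (deduplicated) exclusions."""
    excluded = (
        EXCLUDED_LOW_RELEVANCE
        + EXCLUDED_COLOR_VISION
        + EXCLUDED_SAS
        + EXCLUDED_SDS
        - EXCLUDED_SAS_AND_SDS_OVERLAP
    )
    return PROFESSIONAL_RECRUITED - excluded


def formal_cohort_size() -> int:
    """Formal-study participant count from the published gender counts."""
    return FORMAL_COHORT_MALES + FORMAL_COHORT_FEMALES


def library_summary_table() -> pd.DataFrame:
    """The released library's descriptive statistics as a DataFrame."""
    rows = [{"category": cat.value, **stats} for cat, stats in LIBRARY_SUMMARY.items()]
    return pd.DataFrame(rows).set_index("category")


def exemplar_table() -> pd.DataFrame:
    """The exemplar pictures as (image_id, mean_valence, mean_arousal)."""
    return pd.DataFrame(
        [(name, v, a) for name, (v, a) in EXEMPLAR_PICTURES.items()],
        columns=["image_id", "mean_valence", "mean_arousal"],
    )


def category_shares(counts: dict[Category, int] | None = None, ndigits: int = 2) -> dict[Category, float]:
    """Category percentage shares of the library, rounded to ``ndigits``."""
    counts = LIBRARY_COUNTS if counts is None else counts
    total = sum(counts.values())
    return {cat: round(100.0 * n / total, ndigits) for cat, n in counts.items()}
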