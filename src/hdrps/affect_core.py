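"""Core affect types and the rating-to-label conversion rules.

Every other module operates on 9-point SAM-style ratings of two affect
dimensions — valence (negative to positive) and arousal (calm to activated)
— and on the three-way labels those ratings bin into.  The binning
convention is the standard thirds partition of the 9-point scale:

* valence 1-3 -> negative, 4-6 -> neutral, 7-9 -> positive
* arousal 1-3 -> low,      4-6 -> medium,  7-9 -> high

Neutral pictures are further split by their *mean* valence into a low
neutral stratum (4 < v <= 5) and a high neutral stratum (5 < v <= 6), the
split the four-option scale version presents as separate choices.
"""

from __future__ import annotations

import enum
import re
import warnings
from typing import Optional

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Dimension",
    "ValenceLabel",
    "ArousalLabel",
    "NeutralSubtype",
    "Category",
    "RatingRecord",
    "AffectLabel",
    "ImageAffect",
    "EligibilityGate",
    "valence_rating_to_label",
    "arousal_rating_to_label",
    "neutral_subtype",
    "eligibility_check",
    "image_name",
    "parse_image_name",
    "SAS_CUTOFF",
    "SDS_CUTOFF",
]

#: Zung anxiety / depression eligibility cutoffs (Chinese normative level).
SAS_CUTOFF = 50.0
SDS_CUTOFF = 53.0


class Dimension(str, enum.Enum):
    VALENCE = "valence"
    AROUSAL = "arousal"


class ValenceLabel(str, enum.Enum):
    NEGATIVE = "negative"
    NEUTRAL = "neutral"
    POSITIVE = "positive"


class ArousalLabel(str, enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


class NeutralSubtype(str, enum.Enum):
    LOW_NEUTRAL = "low_neutral"
    HIGH_NEUTRAL = "high_neutral"


class Category(str, enum.Enum):
    PEOPLE = "people"
    ANIMALS = "animals"
    PLANTS = "plants"
    OBJECTS = "objects"
    SCENES = "scenes"


#: Filename code for each valence stratum, used in ``<category>-<code><NNN>``.
STRATUM_CODES = {
    ValenceLabel.POSITIVE: "p",
    NeutralSubtype.HIGH_NEUTRAL: "hn",
    NeutralSubtype.LOW_NEUTRAL: "ln",
    ValenceLabel.NEGATIVE: "n",
}
_CODE_TO_STRATUM = {v: k for k, v in STRATUM_CODES.items()}
_NAME_RE = re.compile(r"^(?P<category>[a-z]+)-(?P<code>hn|ln|p|n)(?P<num>\d+)$")


class RatingRecord(BaseModel):
    """One rater's 9-point score of one image on one dimension."""

    rater_id: str
    image_id: str
    dimension: Dimension
    score: int = Field(ge=1, le=9)
    session_id: str = ""
    rater_affect_valid: bool = True


class AffectLabel(BaseModel):
    """A picture's pair of affect labels, with the optional neutral split."""

    valence_label: ValenceLabel
    arousal_label: ArousalLabel
    neutral_subtype: Optional[NeutralSubtype] = None

    @model_validator(mode="after")
    def _subtype_only_if_neutral(self) -> "AffectLabel":
        if self.neutral_subtype is not None and self.valence_label is not ValenceLabel.NEUTRAL:
            raise ValueError("neutral_subtype is only valid for neutral valence")
        return self


class ImageAffect(BaseModel):
    """A library picture: category, mean ratings, labels and agreement."""

    image_id: str
    category: Category
    mean_valence: float = Field(ge=1.0, le=9.0)
    mean_arousal: float = Field(ge=1.0, le=9.0)
    valence_label: ValenceLabel
    arousal_label: ArousalLabel
    neutral_subtype: Optional[NeutralSubtype] = None
    subtype_out_of_range: bool = False
    valence_identity_ratio: float = Field(ge=0.0, le=1.0)
    arousal_identity_ratio: float = Field(ge=0.0, le=1.0)
    n_raters: int = Field(gt=0)

    @model_validator(mode="after")
    def _subtype_only_if_neutral(self) -> "ImageAffect":
        if self.neutral_subtype is not None and self.valence_label is not ValenceLabel.NEUTRAL:
            raise ValueError("neutral_subtype is only valid for neutral valence")
        return self

    @property
    def stratum(self) -> "ValenceLabel | NeutralSubtype":
        """Valence stratum used by the four-option scale version."""
        if self.valence_label is ValenceLabel.NEUTRAL and self.neutral_subtype is not None:
            return self.neutral_subtype
        return self.valence_label


class EligibilityGate(BaseModel):
    """Rater eligibility screen: color vision plus anxiety/depression norms."""

    color_vision_pass: bool
    sas_score: float
    sds_score: float


def _check_score(score: int) -> int:
    if isinstance(score, bool) or not isinstance(score, (int,)):
        # numpy integers pass through via their __index__ below
        try:
            idx = score.__index__()
        except (AttributeError, TypeError):
            raise TypeError(f"rating must be an integer, got {score!r}") from None
        score = idx
    if not 1 <= score <= 9:
        raise ValueError(f"rating must lie in [1, 9], got {score}")
    return score


def valence_rating_to_label(score: int) -> ValenceLabel:
    """Bin a 9-point valence rating into negative / neutral / positive.

    Ratings 1-3 are negative, 4-6 neutral, 7-9 positive.  Non-integer or
    out-of-range scores are rejected rather than rounded: the partition is
    defined on the integer scale points.
    """
    score = _check_score(score)
    if score <= 3:
        return ValenceLabel.NEGATIVE
    if score <= 6:
        return ValenceLabel.NEUTRAL
    return ValenceLabel.POSITIVE


def arousal_rating_to_label(score: int) -> ArousalLabel:
    """Bin a 9-point arousal rating into low / medium / high (1-3/4-6/7-9)."""
    score = _check_score(score)
    if score <= 3:
        return ArousalLabel.LOW
    if score <= 6:
        return ArousalLabel.MEDIUM
    return ArousalLabel.HIGH


def neutral_subtype(mean_valence: float, *, warn_out_of_range: bool = True) -> NeutralSubtype:
    """Split a neutral picture's mean valence into low / high neutral.

    Mean valence in (4, 5] is low neutral, (5, 6] high neutral.  A neutral
    picture's *label* comes from rater agreement, not from its mean, so the
    mean can fall outside (4, 6]; such pictures are assigned to the nearer
    subtype and a warning is emitted.
    """
    v = float(mean_valence)
    if v <= 4.0 or v > 6.0:
        if warn_out_of_range:
            warnings.warn(
                f"mean valence {v} outside the neutral interval (4, 6]; "
                "assigning the nearer subtype",
                stacklevel=2,
            )
        return NeutralSubtype.LOW_NEUTRAL if v <= 5.0 else NeutralSubtype.HIGH_NEUTRAL
    return NeutralSubtype.LOW_NEUTRAL if v <= 5.0 else NeutralSubtype.HIGH_NEUTRAL


def is_neutral_mean_in_range(mean_valence: float) -> bool:
    """True when a neutral picture's mean valence lies in (4, 6]."""
    return 4.0 < float(mean_valence) <= 6.0


def eligibility_check(gate: EligibilityGate) -> bool:
    """Rater passes iff color vision is normal, SAS < 50 and SDS < 53."""
    return bool(gate.color_vision_pass) and gate.sas_score < SAS_CUTOFF and gate.sds_score < SDS_CUTOFF


def image_name(category: Category, stratum: "ValenceLabel | NeutralSubtype", number: int) -> str:
    """Library file-naming convention ``<category>-<p|hn|ln|n><NNN>``."""
    if stratum is ValenceLabel.NEUTRAL:
        raise ValueError("neutral pictures are named by subtype (hn/ln), not by 'neutral'")
    code = STRATUM_CODES[stratum]
    return f"{Category(category).value}-{code}{number:03d}"


def parse_image_name(name: str) -> tuple[Category, "ValenceLabel | NeutralSubtype", int]:
    """Invert :func:`image_name`; raises ``ValueError`` on malformed names."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"not a valid library image name: {name!r}")
    return (
        Category(m.group("category")),
        _CODE_TO_STRATUM[m.group("code")],
        int(m.group("num")),
    )


def stratum_to_valence_label(stratum: "ValenceLabel | NeutralSubtype") -> ValenceLabel:
    """Collapse a valence stratum to its three-way label (subtypes -> neutral)."""
    if isinstance(stratum, NeutralSubtype):
        return ValenceLabel.NEUTRAL
    return ValenceLabel(stratum)
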