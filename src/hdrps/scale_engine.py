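"""Dynamic trial generation and scoring for the picture-based scale.

A trial is five rounds, one per content category (people, animals, plants,
objects, scenes) in seeded-random order.  Each round presents one picture
per valence stratum, drawn uniformly at random from the library:

* version 1 (three options): positive, neutral, negative — the neutral
  picture is drawn from the union of both neutral subtypes;
* version 2 (four options): positive, high neutral, low neutral, negative.

The respondent picks the picture that best matches their current mood.  A
completed trial is scored as the mean library valence of the five selected
pictures (a value on the 1-9 SAM scale) and labeled with the modal valence
label of the selections, ties resolving to neutral.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .affect_core import (
    Category,
    NeutralSubtype,
    ValenceLabel,
    stratum_to_valence_label,
)
from .library_builder import LibraryManifest

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleVersion",
    "TrialItem",
    "TrialResponse",
    "TrialGenerator",
    "generate_trial",
    "score_trial",
    "duplication_rate",
    "IncompleteTrialError",
]

N_ROUNDS = 5

V2_STRATA = (
    ValenceLabel.POSITIVE,
    NeutralSubtype.HIGH_NEUTRAL,
    NeutralSubtype.LOW_NEUTRAL,
    ValenceLabel.NEGATIVE,
)
V1_STRATA = (ValenceLabel.POSITIVE, ValenceLabel.NEUTRAL, ValenceLabel.NEGATIVE)


class ScaleVersion(str, enum.Enum):
    V1_3OPT = "v1_3opt"
    V2_4OPT = "v2_4opt"

    @property
    def strata(self) -> tuple:
        return V1_STRATA if self is ScaleVersion.V1_3OPT else V2_STRATA


class IncompleteTrialError(ValueError):
    """Raised when a trial has fewer than five valid selections."""


@dataclass(frozen=True)
class TrialItem:
    """One round: a category-homogeneous picture set spanning the strata."""

    round_index: int  # 1-based
    category: Category
    pictures: dict  # stratum -> image_id
    order: tuple  # presentation order of image ids

    def __post_init__(self) -> None:
        if not 1 <= self.round_index <= N_ROUNDS:
            raise ValueError("round_index must be in 1..5")
        if sorted(self.order) != sorted(self.pictures.values()):
            raise ValueError("presentation order must permute the stratum pictures")


@dataclass(frozen=True)
class TrialResponse:
    """A participant's selections for one five-round trial."""

    participant_id: str
    timestamp: float
    items: tuple  # the five TrialItems presented
    selections: tuple  # image ids, one per round

    def __post_init__(self) -> None:
        for item, sel in zip(self.items, self.selections):
            if sel is not None and sel not in item.order:
                raise ValueError(f"selection {sel!r} was not presented in round {item.round_index}")


def _stratum_pools(library: LibraryManifest, version: ScaleVersion) -> dict:
    """Per (category, stratum) picture pools; fails naming any deficient pair."""
    by_stratum = library.by_stratum()
    pools: dict = {}
    missing = []
    for cat in Category:
        pools[cat] = {}
        for stratum in version.strata:
            if stratum is ValenceLabel.NEUTRAL:
                pool = (
                    by_stratum[cat].get(NeutralSubtype.LOW_NEUTRAL, [])
                    + by_stratum[cat].get(NeutralSubtype.HIGH_NEUTRAL, [])
                )
            else:
                pool = by_stratum[cat].get(stratum, [])
            if not pool:
                missing.append((cat.value, getattr(stratum, "value", str(stratum))))
            pools[cat][stratum] = [img.image_id for img in pool]
    if missing:
        raise ValueError(f"library lacks pictures for (category, stratum): {missing}")
    return pools


def generate_trial(
    library: LibraryManifest,
    version: ScaleVersion | str = ScaleVersion.V2_4OPT,
    rng: Optional[np.random.Generator] = None,
    *,
    seed: Optional[int] = None,
) -> list[TrialItem]:
    """Generate one five-round trial: each category once, in random order.

    Within each round one picture is drawn uniformly at random per stratum
    (without within-trial replacement by construction: strata are disjoint)
    and the presentation order of the pictures is an independent random
    permutation.  Identical (library, version, seed) yields identical
    trials.
    """
    version = ScaleVersion(version)
    if rng is None:
        rng = np.random.default_rng(seed)
    pools = _stratum_pools(library, version)
    categories = list(Category)
    cat_order = [categories[i] for i in rng.permutation(len(categories))]
    items = []
    for round_index, cat in enumerate(cat_order, start=1):
        pictures = {
            stratum: pool[int(rng.integers(len(pool)))]
            for stratum, pool in pools[cat].items()
        }
        ids = list(pictures.values())
        order = tuple(ids[i] for i in rng.permutation(len(ids)))
        items.append(TrialItem(round_index, cat, pictures, order))
    return items


def score_trial(
    selections: Sequence[Optional[str]],
    library: LibraryManifest,
) -> tuple[float, ValenceLabel]:
    """Score a completed trial from its five selected pictures.

    The numeric trial score is the mean of the selected pictures' library
    mean valence (on the 1-9 scale); the trial label is the modal valence
    label of the selections with neutral subtypes collapsed to neutral.  A
    tie for the modal label resolves to neutral, the central category.
    Incomplete trials (fewer than five selections) raise
    :class:`IncompleteTrialError`.
    """
    picks = [s for s in selections if s is not None]
    if len(picks) < N_ROUNDS:
        raise IncompleteTrialError(
            f"trial has {len(picks)} selections; {N_ROUNDS} required"
        )
    images = [library.get(s) for s in picks]
    score = float(np.mean([img.mean_valence for img in images]))
    labels = Counter(img.valence_label for img in images)
    best = labels.most_common()
    if len(best) > 1 and best[1][1] == best[0][1]:
        label = ValenceLabel.NEUTRAL
    else:
        label = best[0][0]
    return score, label


def duplication_rate(
    presentations: Sequence[Sequence[str]], window: Optional[int] = None
) -> float:
    """Fraction of repeated picture presentations across one participant's trials.

    ``presentations`` is the participant's per-trial lists of presented
    image ids, oldest first; only the most recent ``window`` trials are
    considered (all by default).  The first trial in the window establishes
    the baseline; of the presentations in the remaining trials, the rate is
    the fraction whose picture already appeared in an earlier trial of the
    window.  A single trial has no opportunity to repeat and scores 0.
    """
    trials = list(presentations)
    if window is not None:
        trials = trials[-window:]
    if len(trials) < 2:
        return 0.0
    seen = set(trials[0])
    repeats = 0
    total = 0
    for trial in trials[1:]:
        for pic in trial:
            total += 1
            if pic in seen:
                repeats += 1
        seen.update(trial)
    return repeats / total if total else 0.0


@dataclass
class TrialGenerator:
    """Seeded trial generator that tracks per-picture usage and repeats.

    Identical (library, version, seed) produce identical trial sequences.
    Usage counts and per-participant presentation histories feed the
    duplication-rate monitoring statistic.
    """

    library: LibraryManifest
    version: ScaleVersion = ScaleVersion.V2_4OPT
    seed: int = 0
    usage_counts: Counter = field(default_factory=Counter)
    history: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.version = ScaleVersion(self.version)
        self._rng = np.random.default_rng(self.seed)
        _stratum_pools(self.library, self.version)  # fail fast on deficits

    def generate(self, participant_id: str = "anon") -> list[TrialItem]:
        items = generate_trial(self.library, self.version, self._rng)
        presented = [pic for item in items for pic in item.order]
        self.usage_counts.update(presented)
        self.history.setdefault(participant_id, []).append(presented)
        return items

    def duplication_rate(self, participant_id: str = "anon", window: Optional[int] = None) -> float:
        return duplication_rate(self.history.get(participant_id, []), window)
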