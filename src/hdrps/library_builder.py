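"""Two-round screening pipeline that turns rater tables into a picture library.

The library is built in two rating rounds: a small expert panel and a larger
professional panel, each scoring every picture on valence and arousal
(9-point scale).  Per round and dimension, each picture's ratings are binned
into labels and the picture's *identity ratio* — the fraction of raters whose
label equals the modal label — is computed.  A picture survives a round iff
both dimensions reach the screening threshold (60% by default).  A picture
enters the final library iff it survives both rounds *with the same pair of
labels* (e.g. positive-positive, low-low).  Final mean ratings are taken
from the professional (larger) panel by default.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel

from .affect_core import (
    ArousalLabel,
    Category,
    Dimension,
    ImageAffect,
    NeutralSubtype,
    ValenceLabel,
    arousal_rating_to_label,
    is_neutral_mean_in_range,
    neutral_subtype,
    valence_rating_to_label,
)

logger = logging.getLogger(__name__)

__all__ = [
    "identity_ratio",
    "screen_images",
    "merge_rounds",
    "library_stats",
    "LibraryManifest",
    "load_ratings_csv",
]

RATING_COLUMNS = ["rater_id", "image_id", "dimension", "score", "session_id", "rater_affect_valid"]


def load_ratings_csv(path: str | Path) -> pd.DataFrame:
    """Read a rating table CSV, validating the required columns."""
    df = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"rating table missing columns: {missing}")
    if "rater_affect_valid" not in df.columns:
        df["rater_affect_valid"] = True
    return df


def identity_ratio(
    scores: Sequence[int], dimension: Dimension | str
) -> tuple[Optional[ValenceLabel | ArousalLabel], float]:
    """Modal affect label of a rating list and the fraction of raters agreeing.

    Converts each 9-point score to a label and returns ``(modal label,
    modal count / n raters)``.  When two labels tie for the maximal count
    there is no dominant label: the modal label is ``None`` and the ratio is
    the tied maximal fraction, so the picture cannot pass any screening
    threshold above that fraction.
    """
    if len(scores) == 0:
        raise ValueError("identity_ratio requires at least one rating")
    dim = Dimension(dimension)
    to_label = valence_rating_to_label if dim is Dimension.VALENCE else arousal_rating_to_label
    counts = Counter(to_label(int(s)) for s in scores)
    best = counts.most_common()
    top_label, top_count = best[0]
    ratio = top_count / len(scores)
    if len(best) > 1 and best[1][1] == top_count:
        return None, ratio
    return top_label, ratio


def screen_images(
    ratings: pd.DataFrame,
    threshold: float = 0.60,
    *,
    round_id: str = "round",
) -> pd.DataFrame:
    """Screen every image in a rating table by its per-dimension identity ratio.

    Rating rows recorded while the rater's own affect was abnormal
    (``rater_affect_valid == False``) are excluded before anything is
    computed.  Images that lack ratings on either dimension are reported via
    the module logger and dropped.  An image is retained iff both its
    valence and arousal modal-label ratios are >= ``threshold`` (a tied
    modal label counts as failing any threshold > its tied fraction).

    Returns one row per complete image with columns ``image_id, round_id,
    valence_label, valence_ratio, arousal_label, arousal_ratio,
    mean_valence, mean_arousal, n_raters_valence, n_raters_arousal,
    retained`` (labels are ``None`` for ties).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    df = ratings
    if "rater_affect_valid" in df.columns:
        n_bad = int((~df["rater_affect_valid"].astype(bool)).sum())
        if n_bad:
            logger.info("%s: excluding %d ratings from abnormal-affect sessions", round_id, n_bad)
        df = df[df["rater_affect_valid"].astype(bool)]

    rows = []
    incomplete: list[str] = []
    for image_id, g in df.groupby("image_id", sort=True):
        by_dim = {Dimension(d): sub["score"].to_numpy() for d, sub in g.groupby("dimension")}
        if Dimension.VALENCE not in by_dim or Dimension.AROUSAL not in by_dim:
            incomplete.append(str(image_id))
            continue
        v_scores = by_dim[Dimension.VALENCE]
        a_scores = by_dim[Dimension.AROUSAL]
        v_label, v_ratio = identity_ratio(v_scores, Dimension.VALENCE)
        a_label, a_ratio = identity_ratio(a_scores, Dimension.AROUSAL)
        retained = (
            v_label is not None
            and a_label is not None
            and v_ratio >= threshold
            and a_ratio >= threshold
        )
        rows.append(
            {
                "image_id": image_id,
                "round_id": round_id,
                "valence_label": v_label.value if v_label else None,
                "valence_ratio": v_ratio,
                "arousal_label": a_label.value if a_label else None,
                "arousal_ratio": a_ratio,
                "mean_valence": float(v_scores.mean()),
                "mean_arousal": float(a_scores.mean()),
                "n_raters_valence": len(v_scores),
                "n_raters_arousal": len(a_scores),
                "retained": retained,
            }
        )
    if incomplete:
        logger.warning(
            "%s: %d images missing a dimension were excluded: %s",
            round_id,
            len(incomplete),
            ", ".join(incomplete[:10]) + ("..." if len(incomplete) > 10 else ""),
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "image_id",
            "round_id",
            "valence_label",
            "valence_ratio",
            "arousal_label",
            "arousal_ratio",
            "mean_valence",
            "mean_arousal",
            "n_raters_valence",
            "n_raters_arousal",
            "retained",
        ],
    )
    out.attrs["threshold"] = threshold
    out.attrs["incomplete_images"] = incomplete
    return out


class LibraryManifest(BaseModel):
    """The final labeled picture library."""

    images: list[ImageAffect]

    def __len__(self) -> int:
        return len(self.images)

    def counts(self) -> dict[Category, int]:
        c: Counter = Counter(img.category for img in self.images)
        return {cat: c.get(cat, 0) for cat in Category}

    def by_stratum(self) -> dict[Category, dict[object, list[ImageAffect]]]:
        """Pictures grouped by (category, valence stratum) for trial assembly."""
        out: dict[Category, dict[object, list[ImageAffect]]] = {cat: {} for cat in Category}
        for img in self.images:
            out[img.category].setdefault(img.stratum, []).append(img)
        return out

    def get(self, image_id: str) -> ImageAffect:
        for img in self.images:
            if img.image_id == image_id:
                return img
        raise KeyError(image_id)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([img.model_dump(mode="json") for img in self.images], indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LibraryManifest":
        records = json.loads(Path(path).read_text())
        return cls(images=[ImageAffect.model_validate(r) for r in records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([img.model_dump(mode="json") for img in self.images])


def _category_for(image_id: str, category_map: Optional[Mapping[str, str]]) -> Category:
    if category_map is not None and image_id in category_map:
        return Category(category_map[image_id])
    head = image_id.split("-", 1)[0]
    try:
        return Category(head)
    except ValueError:
        raise ValueError(
            f"cannot infer category for {image_id!r}; provide category_map"
        ) from None


def merge_rounds(
    round1: pd.DataFrame,
    round2: pd.DataFrame,
    *,
    category_map: Optional[Mapping[str, str]] = None,
    means: Literal["round2", "pooled"] = "round2",
) -> LibraryManifest:
    """Merge two screening rounds into the final library by label consistency.

    A picture enters the library iff it was retained in both rounds and its
    valence and arousal labels agree across rounds.  Pictures present in
    only one round are treated as not retained.  Final mean ratings come
    from round 2 (the larger panel) by default; ``means="pooled"`` uses the
    rater-count-weighted mean of both rounds instead.  Neutral pictures get
    their subtype from the final mean valence; a mean outside (4, 6] is
    assigned the nearer subtype and flagged ``subtype_out_of_range``.
    """
    r1 = round1[round1["retained"]].set_index("image_id")
    r2 = round2[round2["retained"]].set_index("image_id")
    common = r1.index.intersection(r2.index)

    images: list[ImageAffect] = []
    for image_id in common:
        a, b = r1.loc[image_id], r2.loc[image_id]
        if a["valence_label"] != b["valence_label"] or a["arousal_label"] != b["arousal_label"]:
            continue
        if means == "round2":
            mv, ma = float(b["mean_valence"]), float(b["mean_arousal"])
            n = int(b["n_raters_valence"])
        else:
            n1, n2 = int(a["n_raters_valence"]), int(b["n_raters_valence"])
            mv = (a["mean_valence"] * n1 + b["mean_valence"] * n2) / (n1 + n2)
            m1, m2 = int(a["n_raters_arousal"]), int(b["n_raters_arousal"])
            ma = (a["mean_arousal"] * m1 + b["mean_arousal"] * m2) / (m1 + m2)
            n = n1 + n2
        v_label = ValenceLabel(b["valence_label"])
        subtype: Optional[NeutralSubtype] = None
        out_of_range = False
        if v_label is ValenceLabel.NEUTRAL:
            subtype = neutral_subtype(mv, warn_out_of_range=False)
            out_of_range = not is_neutral_mean_in_range(mv)
            if out_of_range:
                logger.warning(
                    "neutral image %s has mean valence %.2f outside (4, 6]; "
                    "assigned %s", image_id, mv, subtype.value,
                )
        images.append(
            ImageAffect(
                image_id=str(image_id),
                category=_category_for(str(image_id), category_map),
                mean_valence=mv,
                mean_arousal=ma,
                valence_label=v_label,
                arousal_label=ArousalLabel(b["arousal_label"]),
                neutral_subtype=subtype,
                subtype_out_of_range=out_of_range,
                valence_identity_ratio=float(b["valence_ratio"]),
                arousal_identity_ratio=float(b["arousal_ratio"]),
                n_raters=n,
            )
        )
    return LibraryManifest(images=images)


def library_stats(manifest: LibraryManifest) -> pd.DataFrame:
    """Per-category descriptive statistics of a library.

    Returns one row per category with picture count, min/max/mean valence
    and arousal, and the category's percentage share of the library (share =
    count / total * 100, rounded to 2 decimals).  An ``all`` row holds the
    totals.  Categories with no pictures appear with count 0.
    """
    if len(manifest) == 0:
        raise ValueError("library_stats requires a non-empty manifest")
    df = manifest.to_frame()
    total = len(df)
    rows = []
    for cat in Category:
        sub = df[df["category"] == cat.value]
        n = len(sub)
        rows.append(
            {
                "category": cat.value,
                "n": n,
                "v_min": sub["mean_valence"].min() if n else float("nan"),
                "v_max": sub["mean_valence"].max() if n else float("nan"),
                "v_mean": sub["mean_valence"].mean() if n else float("nan"),
                "a_min": sub["mean_arousal"].min() if n else float("nan"),
                "a_max": sub["mean_arousal"].max() if n else float("nan"),
                "a_mean": sub["mean_arousal"].mean() if n else float("nan"),
                "share_pct": round(100.0 * n / total, 2),
            }
        )
    rows.append(
        {
            "category": "all",
            "n": total,
            "v_min": df["mean_valence"].min(),
            "v_max": df["mean_valence"].max(),
            "v_mean": df["mean_valence"].mean(),
            "a_min": df["mean_arousal"].min(),
            "a_max": df["mean_arousal"].max(),
            "a_mean": df["mean_arousal"].mean(),
            "share_pct": 100.0,
        }
    )
    return pd.DataFrame(rows).set_index("category")
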