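"""Synthetic rater panels, picture libraries and respondent cohorts.

No real photographs are needed to exercise the pipeline: a picture is fully
described by its true valence/arousal.  The generator emulates

* two rating rounds — a small expert panel and a larger professional panel —
  where each rater's score is the picture's true value plus Gaussian noise,
  rounded and clipped to the 9-point scale; and
* respondents whose latent affect follows a bounded random walk on the 1-9
  valence scale, who pick the presented picture nearest their current affect
  (softmax with a temperature), and who fill in SAM (current state plus
  report noise) and PANAS (loading mainly on the stable trait level, weakly
  on the current state — PANAS asks about a longer time frame, which is what
  makes it the discriminant instrument).

True picture values are drawn uniformly from the *interior* of each label's
score bin (0.5 scale units away from the rounding boundaries between label
bins), so that at low rater noise the modal rated label provably recovers
the generating label.  All outputs are deterministic functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .affect_core import (
    ArousalLabel,
    Category,
    NeutralSubtype,
    ValenceLabel,
    image_name,
)
from .library_builder import LibraryManifest
from .scale_engine import ScaleVersion, TrialGenerator, score_trial

__all__ = ["SimConfig", "SimulatedRatings", "SimulatedCohort",
           "simulate_ratings", "simulate_respondents"]

# Safe sampling intervals for true values: uniform within each label's score
# bin, at least 0.5 units from the 3.5 / 6.5 rounding boundaries.  Neutral
# subintervals additionally keep clear of the 5.0 subtype edge so the
# screened mean reproduces the generating subtype.  Adjacent strata are
# placed symmetric about the 3.5 / 6.5 label boundaries (midpoint of
# neg/low-neutral and of high-neutral/positive interval centers = bin edge),
# so a respondent choosing the valence-nearest picture reproduces the binned
# SAM label away from a thin boundary layer.
_VALENCE_STRATUM_INTERVALS = {
    ValenceLabel.NEGATIVE: (1.9, 2.95),
    NeutralSubtype.LOW_NEUTRAL: (4.3, 4.85),
    NeutralSubtype.HIGH_NEUTRAL: (5.15, 5.8),
    ValenceLabel.POSITIVE: (7.05, 8.0),
}
_AROUSAL_LABEL_INTERVALS = {
    ArousalLabel.LOW: (1.8, 3.0),
    ArousalLabel.MEDIUM: (4.2, 5.8),
    ArousalLabel.HIGH: (7.0, 8.2),
}


class SimConfig(BaseModel):
    """All knobs of the synthetic study, with study-scale-like defaults."""

    seed: int = 0

    # --- picture library ---
    n_images_per_category: int = Field(default=40, gt=0)
    arousal_label_probs: tuple[float, float, float] = (0.25, 0.55, 0.20)

    # --- rating rounds ---
    expert_raters: int = Field(default=7, gt=1)
    professional_raters: int = Field(default=35, gt=1)
    rater_noise_sd: float = Field(default=1.0, ge=0.0)
    expert_abnormal_session_rate: float = Field(default=0.05, ge=0.0, le=1.0)

    # --- respondent cohort ---
    n_participants: int = Field(default=100, gt=0)
    n_trials_per_participant: int = Field(default=14, ge=1)
    scale_version: ScaleVersion = ScaleVersion.V2_4OPT
    drift: float = 0.0
    trait_sd: float = Field(default=0.6, ge=0.0)
    affect_inertia: float = Field(default=0.6, ge=0.0, le=1.0)
    base_volatility: float = Field(default=0.32, ge=0.0)
    vol_age_coef: float = -0.25
    choice_temperature: float = Field(default=0.5, gt=0.0)
    sam_noise_sd: float = Field(default=0.25, ge=0.0)

    # PANAS as an affine projection: mostly trait (participant baseline),
    # only weakly state (it asks about a longer time frame), plus noise;
    # NA mirrors PA.
    panas_trait_loading: float = 1.2
    panas_state_loading: float = 0.25
    panas_noise_sd: float = Field(default=4.0, ge=0.0)
    pa_intercept: float = 12.0
    na_intercept: float = 30.0


@dataclass
class SimulatedRatings:
    expert: pd.DataFrame
    professional: pd.DataFrame
    truth: pd.DataFrame  # image_id, category, true values and labels


@dataclass
class SimulatedCohort:
    trials: pd.DataFrame       # one row per scored trial
    calibration: pd.DataFrame  # SAM pre/post + PANAS per trial
    covariates: pd.DataFrame   # one row per participant
    truth: pd.DataFrame        # latent affect a_t per (participant, trial)
    generator: TrialGenerator


def _clip_round(values: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(values), 1, 9).astype(int)


def _simulate_round(
    rng: np.random.Generator,
    truth: pd.DataFrame,
    n_raters: int,
    noise_sd: float,
    round_name: str,
    abnormal_rate: float,
) -> pd.DataFrame:
    rows = []
    rater_ids = [f"{round_name}_r{j:03d}" for j in range(n_raters)]
    abnormal = rng.random(n_raters) < abnormal_rate
    for j, rater in enumerate(rater_ids):
        session = f"{round_name}_s{j:03d}"
        for dim, col in (("valence", "true_valence"), ("arousal", "true_arousal")):
            scores = _clip_round(truth[col].to_numpy() + rng.normal(0.0, noise_sd, len(truth)))
            for image_id, score in zip(truth["image_id"], scores):
                rows.append((rater, image_id, dim, int(score), session, not abnormal[j]))
    return pd.DataFrame(
        rows,
        columns=["rater_id", "image_id", "dimension", "score", "session_id", "rater_affect_valid"],
    )


def simulate_ratings(config: SimConfig) -> SimulatedRatings:
    """Simulate the two rating rounds over a library with known true affect.

    Each category's pictures are allocated evenly across the four valence
    strata (negative, low neutral, high neutral, positive); arousal labels
    are sampled with ``arousal_label_probs``.  A rater's score is
    round(clip(true + N(0, noise_sd), 1, 9)).  A configurable fraction of
    expert sessions is flagged as taken under abnormal affect
    (``rater_affect_valid = False``), which the screening step must drop.
    """
    rng = np.random.default_rng(config.seed)
    strata = list(_VALENCE_STRATUM_INTERVALS)
    arousal_labels = list(_AROUSAL_LABEL_INTERVALS)
    records = []
    for cat in Category:
        counters = {s: 0 for s in strata}
        for i in range(config.n_images_per_category):
            stratum = strata[i % len(strata)]
            counters[stratum] += 1
            lo, hi = _VALENCE_STRATUM_INTERVALS[stratum]
            tv = float(rng.uniform(lo, hi))
            a_label = arousal_labels[
                int(rng.choice(len(arousal_labels), p=np.asarray(config.arousal_label_probs)))
            ]
            alo, ahi = _AROUSAL_LABEL_INTERVALS[a_label]
            ta = float(rng.uniform(alo, ahi))
            v_label = (
                ValenceLabel.NEUTRAL if isinstance(stratum, NeutralSubtype) else stratum
            )
            records.append(
                {
                    "image_id": image_name(cat, stratum, counters[stratum]),
                    "category": cat.value,
                    "true_valence": tv,
                    "true_arousal": ta,
                    "true_valence_label": v_label.value,
                    "true_arousal_label": a_label.value,
                    "true_stratum": getattr(stratum, "value", str(stratum)),
                }
            )
    truth = pd.DataFrame(records)
    expert = _simulate_round(
        rng, truth, config.expert_raters, config.rater_noise_sd,
        "expert", config.expert_abnormal_session_rate,
    )
    professional = _simulate_round(
        rng, truth, config.professional_raters, config.rater_noise_sd, "prof", 0.0
    )
    return SimulatedRatings(expert=expert, professional=professional, truth=truth)


def _simulate_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Demographics shaped like a working-adult cohort (integer-coded)."""
    age_p = np.array([0.356, 0.276, 0.239, 0.128])
    age = rng.choice(4, size=n, p=age_p / age_p.sum())
    # seniority rises with age group, with noise
    seniority = np.clip(age + rng.integers(-1, 2, size=n), 0, 4)
    marital = np.where(age == 0, rng.choice([0, 1], size=n, p=[0.7, 0.3]),
                       rng.choice([0, 1, 2], size=n, p=[0.15, 0.75, 0.10]))
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:04d}" for i in range(n)],
            "gender": rng.choice(2, size=n, p=[0.3, 0.7]),
            "age_group": age,
            "management_level": rng.choice(4, size=n, p=[0.282, 0.324, 0.065, 0.329]),
            "seniority": seniority,
            "marital_status": marital,
            "education": rng.choice(3, size=n, p=np.array([0.287, 0.421, 0.291]) / 0.999),
            "sds": np.round(rng.normal(40.0, 8.0, size=n), 1),
            "sas": np.round(rng.normal(38.0, 8.0, size=n), 1),
        }
    ).set_index("participant_id")


def simulate_respondents(
    config: SimConfig,
    library: LibraryManifest,
    *,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedCohort:
    """Simulate a respondent cohort taking repeated picture-scale trials.

    Each participant carries a trait baseline b ~ N(5, trait_sd) and a
    latent affect trajectory a_t bounded on [1, 9]: a mean-reverting
    (emotional-inertia) process a_{t+1} = b + inertia * (a_t - b) + drift +
    N(0, vol), clipped to the scale (affect_inertia = 1 recovers a pure
    random walk).  Per-participant volatility is base_volatility *
    exp(vol_age_coef * age_group) — older participants are calmer, which is
    the ground truth the instability analysis should recover.  Per round
    the respondent
    selects picture p with probability proportional to
    exp(-|valence_p - a_t| / temperature).  SAM pre/post reports are
    round(clip(a_t + N(0, sam_noise_sd))) with independent noise (the trial
    itself does not move affect); PANAS PA/NA are affine in (trait, state)
    plus noise, clipped to the 10-50 instrument range.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    covariates = _simulate_covariates(rng, config.n_participants)
    generator = TrialGenerator(library, config.scale_version, seed=int(rng.integers(2**31)))

    trial_rows, calib_rows, truth_rows = [], [], []
    for pid, cov in covariates.iterrows():
        trait = float(np.clip(rng.normal(5.0, config.trait_sd), 1.5, 8.5))
        vol = config.base_volatility * float(np.exp(config.vol_age_coef * cov["age_group"]))
        a = trait
        for t in range(config.n_trials_per_participant):
            if t > 0:
                a = float(np.clip(
                    trait + config.affect_inertia * (a - trait) + config.drift
                    + rng.normal(0.0, vol),
                    1.0, 9.0,
                ))
            items = generator.generate(pid)
            selections = []
            for item in items:
                vals = np.array([library.get(p).mean_valence for p in item.order])
                logits = -np.abs(vals - a) / config.choice_temperature
                probs = np.exp(logits - logits.max())
                probs /= probs.sum()
                selections.append(item.order[int(rng.choice(len(item.order), p=probs))])
            score, label = score_trial(selections, library)
            sam_pre = int(_clip_round(np.array([a + rng.normal(0.0, config.sam_noise_sd)]))[0])
            sam_post = int(_clip_round(np.array([a + rng.normal(0.0, config.sam_noise_sd)]))[0])
            pa = float(np.clip(
                config.pa_intercept + config.panas_trait_loading * trait
                + config.panas_state_loading * a + rng.normal(0.0, config.panas_noise_sd),
                10.0, 50.0,
            ))
            na = float(np.clip(
                config.na_intercept - config.panas_trait_loading * trait
                - config.panas_state_loading * a + rng.normal(0.0, config.panas_noise_sd),
                10.0, 50.0,
            ))
            trial_rows.append(
                {
                    "participant_id": pid,
                    "timestamp": float(t),
                    "trial_index": t,
                    "selections": "|".join(selections),
                    "trial_score": score,
                    "trial_label": label.value,
                }
            )
            calib_rows.append(
                {
                    "participant_id": pid,
                    "timestamp": float(t),
                    "sam_pre": sam_pre,
                    "sam_post": sam_post,
                    "panas_pa": pa,
                    "panas_na": na,
                }
            )
            truth_rows.append(
                {"participant_id": pid, "timestamp": float(t), "latent_affect": a,
                 "trait": trait, "volatility": vol}
            )
    return SimulatedCohort(
        trials=pd.DataFrame(trial_rows),
        calibration=pd.DataFrame(calib_rows),
        covariates=covariates,
        truth=pd.DataFrame(truth_rows),
        generator=generator,
    )
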