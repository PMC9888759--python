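"""Field-validation analyses: reflection check, label accuracy and stability.

Three questions about the picture scale are answered here.  First, does
taking the scale itself shift mood?  A paired SAM test before/after the
trial should show no significant change, and the fraction of trials whose
SAM moved by less than 10 percentage points (of the 8-unit SAM span) should
be large.  Second, do the picture selections agree with a concurrent SAM
report once both are converted to valence labels (consistency accuracy)?
Third, how stable is repeated measurement: per-participant affective
instability is summarised by the root mean successive squared difference
(rMSSD) of each instrument's score series and correlated with demographic
and mental-health covariates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .affect_core import ValenceLabel, valence_rating_to_label
from .psychometrics import PairedTestResult, paired_pre_post_test

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationRecord",
    "ReflectionReport",
    "reflection_check",
    "consistency_accuracy",
    "rmssd",
    "instability_correlates",
    "panas_composite",
    "ORDINAL_CODINGS",
    "encode_covariates",
]

#: SAM span used to express a pre/post change in percentage points.
SAM_SPAN = 8.0
#: Default "affect changed" criterion, in percentage points of the SAM span.
CHANGE_THRESHOLD_PCT = 10.0


class CalibrationRecord(BaseModel):
    """Pre/post SAM and PANAS calibration responses for one trial."""

    participant_id: str
    timestamp: float
    sam_pre: int = Field(ge=1, le=9)
    sam_post: Optional[int] = Field(default=None, ge=1, le=9)
    panas_pa: float = Field(ge=10.0, le=50.0)
    panas_na: float = Field(ge=10.0, le=50.0)


@dataclass(frozen=True)
class ReflectionReport:
    paired: PairedTestResult
    fraction_below_threshold: float
    threshold_pct: float
    n: int

    @property
    def reflection_verified(self) -> bool:
        """No significant pre/post shift and most changes under threshold."""
        return self.paired.no_significant_difference and self.fraction_below_threshold > 0.5


def reflection_check(
    sam_pre: Sequence[float],
    sam_post: Sequence[Optional[float]],
    *,
    threshold_pct: float = CHANGE_THRESHOLD_PCT,
) -> ReflectionReport:
    """Picture-emotion reflection check from paired pre/post SAM reports.

    Pairs with a missing post value are dropped.  Runs the paired t-test on
    (pre, post) and computes each pair's percent change |post - pre| / 8 x
    100; the report carries the fraction of pairs changing by less than
    ``threshold_pct`` percentage points.  The fraction is antitone in the
    threshold by construction.
    """
    pre = np.asarray(sam_pre, dtype=float)
    post = np.asarray(sam_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be equal length")
    ok = ~(np.isnan(pre) | np.isnan(post))
    pre, post = pre[ok], post[ok]
    if pre.size == 0:
        raise ValueError("no complete pre/post pairs")
    paired = paired_pre_post_test(pre, post)
    pct_change = np.abs(post - pre) / SAM_SPAN * 100.0
    frac = float((pct_change < threshold_pct).mean())
    return ReflectionReport(paired, frac, threshold_pct, int(pre.size))


def consistency_accuracy(
    sam_ratings: Sequence[int], trial_labels: Sequence[ValenceLabel | str]
) -> float:
    """Fraction of trials whose SAM valence label matches the trial label.

    Each concurrent SAM rating is binned with the standard thirds rule and
    compared with the picture-scale trial label; unpaired entries (either
    side missing) are dropped with a warning.
    """
    pairs = [
        (s, lab)
        for s, lab in zip(sam_ratings, trial_labels)
        if s is not None and lab is not None and not (isinstance(s, float) and math.isnan(s))
    ]
    n_dropped = max(len(list(sam_ratings)), len(list(trial_labels))) - len(pairs)
    if n_dropped:
        logger.warning("dropped %d unpaired SAM/trial entries", n_dropped)
    if not pairs:
        raise ValueError("no paired SAM/trial records")
    hits = sum(
        valence_rating_to_label(int(s)) is ValenceLabel(lab) for s, lab in pairs
    )
    return hits / len(pairs)


def rmssd(series: Sequence[float]) -> float:
    """Root mean successive squared difference of an ordered score series.

    rMSSD = sqrt( mean_t (x_{t+1} - x_t)^2 ); higher values indicate
    greater moment-to-moment instability.  Requires length >= 2.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("rmssd requires an ordered series of length >= 2")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


#: Integer codings for the ordinal covariates, in their natural category order.
ORDINAL_CODINGS: dict[str, dict[str, int]] = {
    "gender": {"male": 0, "female": 1},
    "age_group": {"18-30": 0, "31-40": 1, "41-50": 2, "51-60": 3},
    "marital_status": {"unmarried": 0, "married": 1, "divorced": 2},
    "education": {"college_or_below": 0, "undergraduate": 1, "master_or_above": 2},
    "management_level": {
        "government_institution": 0,
        "enterprise": 1,
        "service": 2,
        "worker_freelance_other": 3,
    },
}


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Integer-code any string-valued ordinal covariates (see ORDINAL_CODINGS)."""
    out = covariates.copy()
    for col, coding in ORDINAL_CODINGS.items():
        if col in out.columns and out[col].dtype == object:
            out[col] = out[col].map(coding)
            if out[col].isna().any():
                raise ValueError(f"unknown categories in covariate {col!r}")
    return out


def panas_composite(
    pa: Sequence[float], na: Sequence[float], mode: Literal["balance", "pa", "na"] = "balance"
) -> np.ndarray:
    """Single PANAS score: PA - NA balance (default), or PA-only / NA-only."""
    pa = np.asarray(pa, dtype=float)
    na = np.asarray(na, dtype=float)
    if mode == "balance":
        return pa - na
    if mode == "pa":
        return pa
    if mode == "na":
        return na
    raise ValueError(f"unknown PANAS composite mode {mode!r}")


def participant_rmssd(
    scores: pd.DataFrame,
    instruments: Sequence[str],
    *,
    participant_col: str = "participant_id",
    time_col: str = "timestamp",
) -> pd.DataFrame:
    """Per-participant rMSSD of each instrument's time-ordered score series.

    Participants with fewer than two observations of an instrument get NaN
    for that instrument.
    """
    rows = []
    for pid, g in scores.groupby(participant_col, sort=True):
        g = g.sort_values(time_col)
        row: dict = {participant_col: pid}
        for inst in instruments:
            x = g[inst].dropna().to_numpy()
            row[f"rmssd_{inst}"] = rmssd(x) if x.size >= 2 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index(participant_col)


def _stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def instability_correlates(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    instruments: Sequence[str],
    *,
    participant_col: str = "participant_id",
    time_col: str = "timestamp",
) -> pd.DataFrame:
    """Correlate per-participant instability (rMSSD) with covariates.

    ``scores`` is long-format (participant, timestamp, one column per
    instrument); ``covariates`` is one row per participant, indexed by id,
    ordinal covariates either pre-coded or string-valued per
    ORDINAL_CODINGS.  Returns a covariate x instrument table of Pearson r
    with two-tailed significance stars (* p<0.05, ** p<0.01) in parallel
    ``<instrument>_stars`` columns.  A constant covariate yields NaN for
    that row.  Requires >= 3 participants with a valid rMSSD per
    instrument.
    """
    inst_rmssd = participant_rmssd(
        scores, instruments, participant_col=participant_col, time_col=time_col
    )
    cov = encode_covariates(covariates).astype(float)
    cov = cov.loc[cov.index.intersection(inst_rmssd.index)]
    inst_rmssd = inst_rmssd.loc[cov.index]

    out: dict[str, list] = {}
    for inst in instruments:
        y_all = inst_rmssd[f"rmssd_{inst}"]
        rs, ps = [], []
        for col in cov.columns:
            x = cov[col]
            ok = ~(x.isna() | y_all.isna())
            n = int(ok.sum())
            if n < 3:
                raise ValueError(f"need >= 3 participants with valid rMSSD for {inst}")
            xv, yv = x[ok].to_numpy(), y_all[ok].to_numpy()
            if xv.std() == 0.0 or yv.std() == 0.0:
                logger.warning("constant series for (%s, %s); correlation undefined", col, inst)
                rs.append(float("nan"))
                ps.append(float("nan"))
                continue
            r, p = stats.pearsonr(xv, yv)
            rs.append(float(r))
            ps.append(float(p))
        out[inst] = rs
        out[f"{inst}_stars"] = [_stars(p) for p in ps]
        out[f"{inst}_p"] = ps
    return pd.DataFrame(out, index=cov.columns)


def drop_abnormal_trials(
    trials: pd.DataFrame,
    *,
    participant_col: str = "participant_id",
    duration_col: str = "duration_s",
    score_col: str = "trial_score",
    min_duration_s: Optional[float] = 2.0,
) -> pd.DataFrame:
    """Drop apparently abnormal trials: implausibly fast responses and
    participants whose scores never vary across all their trials.

    Both screens are configurable; dropped counts are logged.
    """
    df = trials
    if min_duration_s is not None and duration_col in df.columns:
        fast = df[duration_col] < min_duration_s
        if fast.any():
            logger.info("dropping %d trials faster than %.1fs", int(fast.sum()), min_duration_s)
        df = df[~fast]
    if score_col in df.columns:
        flat = df.groupby(participant_col)[score_col].transform("nunique") == 1
        multi = df.groupby(participant_col)[score_col].transform("size") > 1
        bad = flat & multi
        if bad.any():
            logger.info("dropping %d trials from zero-variance participants", int(bad.sum()))
        df = df[~bad]
    return df
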