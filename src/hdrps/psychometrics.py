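"""Reliability and validity statistics with explicit pass thresholds.

Rating-panel consistency is assessed two ways: Cronbach's alpha with the
raters playing the role of scale items (floor 0.50), and the mean Pearson
correlation between each rater's ratings and the across-rater mean rating
(floor 0.50).  Instrument validity is assessed by Pearson correlation with a
calibration instrument: concurrent validity passes above 0.45 (same
construct, higher is better) and discriminant validity passes below 0.45
(different construct, lower is better).  A paired pre/post t-test checks
that administering the scale does not itself shift affect.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ReliabilityMethod",
    "ValidityKind",
    "ReliabilityResult",
    "ValidityResult",
    "PairedTestResult",
    "cronbach_alpha",
    "mean_item_total_reliability",
    "pearson_validity",
    "paired_pre_post_test",
    "RELIABILITY_FLOOR",
    "VALIDITY_CUTOFF",
]

RELIABILITY_FLOOR = 0.50
VALIDITY_CUTOFF = 0.45


class ReliabilityMethod(str, enum.Enum):
    CRONBACH_ALPHA = "cronbach_alpha"
    MEAN_ITEM_TOTAL_R = "mean_item_total_r"


class ValidityKind(str, enum.Enum):
    CONCURRENT = "concurrent"
    DISCRIMINANT = "discriminant"


@dataclass(frozen=True)
class ReliabilityResult:
    method: ReliabilityMethod
    value: float
    passed: bool
    threshold_used: float
    note: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.value) and self.passed != (self.value > self.threshold_used):
            raise ValueError("pass flag inconsistent with value/threshold")


@dataclass(frozen=True)
class ValidityResult:
    kind: ValidityKind
    pearson_r: float
    p_value: float
    passed: bool
    note: str = ""


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff: float
    sd: float
    sem: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False

    @property
    def no_significant_difference(self) -> bool:
        """True when the two-tailed p exceeds 0.05 (no pre/post shift)."""
        return self.p_value > 0.05


def _as_matrix(matrix, min_rows: int, min_cols: int, *, drop_missing_cols: bool) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("rating matrix must be 2-D (raters x items)")
    if drop_missing_cols and np.isnan(m).any():
        keep = ~np.isnan(m).any(axis=0)
        n_drop = int((~keep).sum())
        logger.warning("dropping %d items with missing ratings", n_drop)
        m = m[:, keep]
    if m.shape[0] < min_rows or m.shape[1] < min_cols:
        raise ValueError(
            f"need at least {min_rows} raters and {min_cols} items, got {m.shape}"
        )
    return m


def cronbach_alpha(
    matrix, *, threshold: float = RELIABILITY_FLOOR, raters_as_items: bool = True
) -> ReliabilityResult:
    """Cronbach's alpha of a raters-x-items rating matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of total score),
    with sample (ddof=1) variances.  By default the *raters* are treated as
    the scale items, so alpha measures panel consistency across the rated
    pictures; ``raters_as_items=False`` transposes the matrix for ordinary
    item-set reliability.  Items (columns) with missing cells are dropped
    with a warning.  A zero total-score variance leaves alpha undefined
    (NaN, not passed).
    """
    m = _as_matrix(matrix, 2, 2, drop_missing_cols=True)
    if not raters_as_items:
        m = m.T
    k = m.shape[0]
    item_vars = m.var(axis=1, ddof=1)
    total_var = m.sum(axis=0).var(ddof=1)
    if total_var == 0.0:
        return ReliabilityResult(
            ReliabilityMethod.CRONBACH_ALPHA, float("nan"), False, threshold,
            note="total-score variance is zero; alpha undefined",
        )
    alpha = (k / (k - 1)) * (1.0 - item_vars.sum() / total_var)
    return ReliabilityResult(
        ReliabilityMethod.CRONBACH_ALPHA, float(alpha), bool(alpha > threshold), threshold
    )


def mean_item_total_reliability(
    matrix, *, threshold: float = RELIABILITY_FLOOR
) -> ReliabilityResult:
    """Mean correlation between each rater's ratings and the panel mean.

    For every rater, the Pearson correlation between that rater's rating
    vector and the across-rater mean vector is computed; the statistic is
    the mean of these per-rater correlations.  Raters with constant rating
    vectors (undefined correlation) are excluded with a warning; the panel
    mean always includes every rater.
    """
    m = _as_matrix(matrix, 2, 3, drop_missing_cols=True)
    overall = m.mean(axis=0)
    if overall.std() == 0.0:
        return ReliabilityResult(
            ReliabilityMethod.MEAN_ITEM_TOTAL_R, float("nan"), False, threshold,
            note="panel mean is constant; correlations undefined",
        )
    rs = []
    n_dropped = 0
    for row in m:
        if row.std() == 0.0:
            n_dropped += 1
            continue
        rs.append(stats.pearsonr(row, overall).statistic)
    if n_dropped:
        logger.warning("excluded %d constant-rating raters from reliability", n_dropped)
    if not rs:
        return ReliabilityResult(
            ReliabilityMethod.MEAN_ITEM_TOTAL_R, float("nan"), False, threshold,
            note="all raters constant; reliability undefined",
        )
    value = float(np.mean(rs))
    return ReliabilityResult(
        ReliabilityMethod.MEAN_ITEM_TOTAL_R, value, bool(value > threshold), threshold
    )


def pearson_validity(x, y, kind: ValidityKind | str, *, cutoff: float = VALIDITY_CUTOFF) -> ValidityResult:
    """Pearson correlation between a scale and a calibration instrument.

    Concurrent validity passes iff r > cutoff (strict); discriminant
    validity passes iff r < cutoff (strict).  r exactly at the cutoff fails
    both.  Zero variance in either series leaves r undefined.
    """
    kind = ValidityKind(kind)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if x.size < 3:
        raise ValueError("validity requires at least 3 paired observations")
    if x.std() == 0.0 or y.std() == 0.0:
        return ValidityResult(kind, float("nan"), float("nan"), False,
                              note="zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    passed = r > cutoff if kind is ValidityKind.CONCURRENT else r < cutoff
    return ValidityResult(kind, float(r), float(p), bool(passed))


def paired_pre_post_test(pre, post, *, confidence: float = 0.95) -> PairedTestResult:
    """Paired-samples t-test of post minus pre, with CI of the mean difference.

    Returns the mean difference, its SD and SEM, the t-based confidence
    interval and the two-tailed p-value.  Zero-variance differences with a
    nonzero mean are degenerate (t undefined); they are reported with
    ``degenerate=True`` and p = 0 by convention, since every pair moved by
    the identical nonzero amount.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1-D series")
    n = pre.size
    if n < 2:
        raise ValueError("paired test requires at least 2 pairs")
    d = post - pre
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    sem = sd / math.sqrt(n)
    if sd == 0.0:
        # all pairs shifted identically; t is 0/0 or +-inf
        if mean == 0.0:
            return PairedTestResult(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, n, degenerate=True)
        return PairedTestResult(mean, 0.0, 0.0, mean, mean, math.copysign(math.inf, mean),
                                0.0, n, degenerate=True)
    t_stat, p = stats.ttest_rel(post, pre)
    half = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1) * sem
    return PairedTestResult(mean, sd, sem, mean - half, mean + half,
                            float(t_stat), float(p), n)
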