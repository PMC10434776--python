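"""Evaluation statistics for the eye-movement and rating comparisons.

Covers the study's inferential toolkit: Shapiro-Wilk normality checks
of the eye-movement metrics, paired t-tests of pre/post visual-search
differences with 95% confidence intervals, and the Cooper-Harper (CH)
grade-distribution comparison between the two optimized interfaces.

Note on interpretation: a Shapiro-Wilk p-value *below* the level
rejects normality.  (The source narrative reads small p as evidence of
normality; this module follows the test's standard convention.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .datasets import CHGradeTable
from .errors import DegenerateInputError, HudoptError

__all__ = ["PairedTestResult", "CHComparison", "shapiro_wilk", "paired_t", "ch_compare", "eye_movement_tests"]


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    p_value: float
    ci95: tuple[float, float]
    n: int
    mean_difference: float


@dataclass(frozen=True)
class CHComparison:
    n_first_higher: int
    n_equal: int
    n_second_higher: int

    @property
    def total(self) -> int:
        return self.n_first_higher + self.n_equal + self.n_second_higher

    @property
    def proportion_first(self) -> float:
        return self.n_first_higher / self.total


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (Royston's algorithm).

    Requires 3 <= n <= 5000 and non-constant data.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not 3 <= len(x) <= 5000:
        raise HudoptError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample: W undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def paired_t(x, y) -> PairedTestResult:
    """Two-sided paired t-test of mean(x - y) with a 95% CI.

    ``t = mean(d) / (sd(d)/sqrt(n))`` on the differences d = x - y,
    with n-1 degrees of freedom and the sample standard deviation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise HudoptError("paired samples must have equal length")
    n = len(x)
    if n < 2:
        raise HudoptError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            # identical samples: conventional null result
            return PairedTestResult(0.0, 1.0, (0.0, 0.0), n, 0.0)
        raise DegenerateInputError("zero-variance nonzero differences")
    se = sd / np.sqrt(n)
    t = d.mean() / se
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    tcrit = sps.t.ppf(0.975, n - 1)
    ci = (float(d.mean() - tcrit * se), float(d.mean() + tcrit * se))
    return PairedTestResult(float(t), float(p), ci, n, float(d.mean()))


def ch_compare(table: CHGradeTable) -> CHComparison:
    """Counts per preference category and the share preferring the first method.

    Uses the table's printed per-category sums (the authoritative
    totals).  Grade pairs read (first method's CH grade / second's);
    lower CH grade means the task felt easier.
    """
    sums = table.category_sums
    for key in ("first_higher", "equal", "second_higher"):
        if key not in sums:
            raise HudoptError(f"missing category {key!r}")
        if sums[key] < 0:
            raise HudoptError("negative count")
    return CHComparison(sums["first_higher"], sums["equal"], sums["second_higher"])


def eye_movement_tests(table, alpha: float = 0.05):
    """Shapiro-Wilk per metric column of the eye-movement table.

    Returns a dict column -> (W, p, normal-at-alpha).  The narrative's
    "four groups" are read as the four metric columns.
    """
    out = {}
    for col in ("gaze_ms", "glance_ms", "reaction_ms", "nasa_tlx"):
        w, p = shapiro_wilk(table.frame[col].to_numpy())
        out[col] = (w, p, p > alpha)
    return out
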