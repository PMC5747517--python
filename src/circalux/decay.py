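"""Cycloheximide-chase protein degradation analysis.

A chase course follows the remaining protein pool after synthesis is
blocked, sampled at a few timepoints (typically 0/3/6 h) in replicate.
Levels are normalized per replicate to the t = 0 amount, fitted with a
log-linear (first-order) decay model to yield a rate and half-life, and
compared between conditions timepoint by timepoint with Student's t-test
— the design used to show that a kinase accelerates or slows turnover of
its substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .preprocess import InvalidParameterError

__all__ = [
    "DecayCourse",
    "DecayFit",
    "normalize_to_t0",
    "fit_decay",
    "compare_courses",
]


@dataclass(frozen=True)
class DecayCourse:
    """Replicated protein levels over a chase time course.

    ``times_h`` strictly increases and starts at 0; ``levels`` has shape
    (n_replicates, n_times) with positive levels at t = 0.
    """

    times_h: np.ndarray
    levels: np.ndarray = field(repr=False)
    condition: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times_h, dtype=float)
        levels = np.atleast_2d(np.asarray(self.levels, dtype=float))
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "levels", levels)
        if times.size < 2 or times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise InvalidParameterError(
                "times_h must strictly increase from 0"
            )
        if levels.shape[1] != times.size:
            raise InvalidParameterError(
                f"levels has {levels.shape[1]} timepoints, times_h has {times.size}"
            )
        if np.any(levels[:, 0] <= 0):
            raise InvalidParameterError("levels at t = 0 must be positive")

    @property
    def n_reps(self) -> int:
        return self.levels.shape[0]


def normalize_to_t0(course: DecayCourse) -> DecayCourse:
    """Divide each replicate by its own t = 0 level (idempotent)."""
    scaled = course.levels / course.levels[:, :1]
    return DecayCourse(course.times_h, scaled, course.condition)


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit: level(t) = exp(-rate * t).

    ``half_life_h`` is ln 2 / rate, infinite when the fitted rate is
    non-positive (stable protein). ``rate_se`` is the standard error of
    the rate from the log-linear regression; ``r_squared`` its R^2.
    """

    rate_per_h: float
    half_life_h: float
    rate_se: float
    r_squared: float


def fit_decay(course: DecayCourse) -> DecayFit:
    """Log-linear least-squares fit of a normalized chase course.

    Pools all replicates and regresses ln(level) on time; rate = -slope.
    With only a handful of chase timepoints the log-linear form is far
    more stable than a nonlinear exponential fit and is exact for clean
    first-order decay. Scale-invariant after per-replicate normalization.
    """
    norm = normalize_to_t0(course)
    if norm.times_h.size < 3:
        raise InvalidParameterError("need at least 3 timepoints to fit decay")
    if np.any(norm.levels <= 0):
        raise InvalidParameterError("all levels must be positive for a log fit")
    t = np.tile(norm.times_h, norm.n_reps)
    y = np.log(norm.levels).ravel()
    res = stats.linregress(t, y)
    rate = -float(res.slope)
    half_life = np.log(2.0) / rate if rate > 0 else float("inf")
    return DecayFit(
        rate_per_h=rate,
        half_life_h=float(half_life),
        rate_se=float(res.stderr),
        r_squared=float(res.rvalue**2),
    )


def compare_courses(a: DecayCourse, b: DecayCourse) -> "pd.DataFrame":
    """Per-timepoint Student's t-test between two normalized courses.

    Tests each post-zero timepoint two-sided on the t0-normalized
    replicate levels (at t = 0 both courses are identically 1, so there
    is nothing to test). Returns a DataFrame with time_h, mean_a, mean_b,
    statistic, p_value.
    """
    import pandas as pd

    if a.times_h.size != b.times_h.size or np.any(a.times_h != b.times_h):
        raise InvalidParameterError("courses must share identical timepoints")
    if a.n_reps < 2 or b.n_reps < 2:
        raise InvalidParameterError("need >= 2 replicates per course")
    na, nb = normalize_to_t0(a), normalize_to_t0(b)
    rows = []
    for j in range(1, na.times_h.size):
        va, vb = na.levels[:, j], nb.levels[:, j]
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(va, vb, equal_var=True)
        rows.append(
            (float(na.times_h[j]), float(va.mean()), float(vb.mean()),
             float(t_stat), float(p))
        )
    return pd.DataFrame(
        rows, columns=["time_h", "mean_a", "mean_b", "statistic", "p_value"]
    )
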