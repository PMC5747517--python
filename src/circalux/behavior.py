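"""Actogram and physiological-rhythm statistics.

Quantifies locomotor activity records the way circadian behavioral
studies do: the free-running period of a constant-darkness segment by
chi-squared periodogram, per-day activity acrophases by 24-h cosinor,
activity profiles averaged over days, and the acrophase delay between
paired physiological rhythms (e.g. oxygen consumption of two genotypes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import InvalidParameterError, TimeSeries
from .rhythm_stats import (
    DEFAULT_ALPHA,
    chi_squared_periodogram,
    classify_rhythmic,
    cosinor_fit,
    wrap_phase_h,
)

__all__ = [
    "ActivityRecord",
    "free_running_period",
    "daily_acrophase",
    "mean_daily_profile",
    "metabolic_phase_delay",
]


@dataclass(frozen=True)
class ActivityRecord:
    """Binned locomotor event counts with a light-schedule annotation.

    ``counts`` holds non-negative events per bin of ``bin_min`` minutes,
    starting at clock hour ``start_clock_h`` of day 0. ``light_schedule``
    is a per-day sequence of (lights_on_h, lights_off_h) clock hours
    (cycled if shorter than the record), or None for constant darkness.
    """

    bin_min: int
    counts: np.ndarray = field(repr=False)
    start_clock_h: float = 0.0
    light_schedule: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if 1440 % self.bin_min != 0:
            raise InvalidParameterError("bin_min must divide 1440")
        if counts.ndim != 1 or counts.size == 0:
            raise InvalidParameterError("counts must be a non-empty 1-D array")
        if np.any(counts < 0):
            raise InvalidParameterError("counts must be non-negative")

    @property
    def bin_h(self) -> float:
        return self.bin_min / 60.0

    @property
    def bins_per_day(self) -> int:
        return 1440 // self.bin_min

    @property
    def n_days(self) -> float:
        return self.counts.size / self.bins_per_day

    @property
    def is_dd(self) -> bool:
        return self.light_schedule is None

    def as_timeseries(self) -> TimeSeries:
        return TimeSeries(0.0, self.bin_h, self.counts.astype(float))


def free_running_period(
    rec: ActivityRecord,
    day_range: tuple[int, int] | None = None,
    min_period_h: float = 20.0,
    max_period_h: float = 28.0,
    step_h: float = 0.01,
    alpha: float = DEFAULT_ALPHA,
) -> float | None:
    """Free-running period of a DD record by chi-squared periodogram.

    ``day_range`` selects whole days [start, stop); at least 7 days are
    required so the 20-28 h search has enough cycles. Returns the best
    significant period in hours, or None when no trial period reaches
    significance (e.g. an arrhythmic or empty record).
    """
    counts = rec.counts
    if day_range is not None:
        start, stop = day_range
        counts = counts[start * rec.bins_per_day : stop * rec.bins_per_day]
    if counts.size < 7 * rec.bins_per_day:
        raise InvalidParameterError("need at least 7 days of data")
    ts = TimeSeries(0.0, rec.bin_h, counts.astype(float))
    if np.all(counts == counts.flat[0]):
        return None
    pg = chi_squared_periodogram(
        ts, min_period_h, max_period_h, step_h, alpha=alpha
    )
    return pg.best_period_h


def daily_acrophase(rec: ActivityRecord) -> np.ndarray:
    """Acrophase of each complete 24-h day by cosinor at fixed 24-h period.

    Returned in clock hours (hours after midnight) for LD records, hours
    after record start for DD; one value per complete day, NaN for
    all-zero days. Under free run the per-day acrophase drifts by
    (tau - 24) h per day.
    """
    bpd = rec.bins_per_day
    n_days = rec.counts.size // bpd
    if n_days < 1:
        raise InvalidParameterError("need at least one complete day")
    offset = rec.start_clock_h if not rec.is_dd else 0.0
    out = np.full(n_days, np.nan)
    centers = rec.bin_h * (np.arange(bpd) + 0.5)
    for d in range(n_days):
        day = rec.counts[d * bpd : (d + 1) * bpd].astype(float)
        if np.all(day == 0):
            continue
        if np.ptp(day) == 0:
            continue
        fit = cosinor_fit(TimeSeries(centers[0], rec.bin_h, day), 24.0)
        out[d] = (fit.acrophase_h + offset) % 24.0
    return out


def mean_daily_profile(rec: ActivityRecord, n_days: int = 16) -> np.ndarray:
    """Average 24-h activity profile over the first ``n_days`` days.

    Counts are folded modulo 24 h at the record's bin width; the profile
    has ``bins_per_day`` entries whose sum times n_days equals the total
    counts used.
    """
    bpd = rec.bins_per_day
    if rec.counts.size < n_days * bpd:
        raise InvalidParameterError(
            f"record spans {rec.n_days:.1f} days, fewer than the {n_days} requested"
        )
    days = rec.counts[: n_days * bpd].reshape(n_days, bpd).astype(float)
    return days.mean(axis=0)


def metabolic_phase_delay(
    a: TimeSeries,
    b: TimeSeries,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Acrophase delay of rhythm ``b`` relative to ``a`` at 24-h period.

    Both series must cover at least 48 h (two full days of recording).
    The result is the circular cosinor acrophase difference b - a in
    (-12, +12] h; positive values mean b peaks later (a phase delay).
    When either series fails the chi-squared periodogram rhythmicity test
    a warning is emitted and the best-effort estimate returned.
    """
    for name, ts in (("a", a), ("b", b)):
        if ts.duration_h < 48.0:
            raise InvalidParameterError(f"series {name} must cover >= 48 h")
    for name, ts in (("a", a), ("b", b)):
        if np.ptp(ts.values) == 0:
            warnings.warn(f"series {name} is constant; delay is undefined", stacklevel=2)
            return float("nan")
        # a two-day record cannot hold two 28-h cycles; cap the scan so the
        # rhythmicity check stays defined on the minimum 48-h input
        max_p = min(28.0, ts.n * ts.dt_h / 2.0)
        pg = chi_squared_periodogram(ts, 20.0, max_p, 0.1, alpha=alpha)
        if not classify_rhythmic(pg, alpha):
            warnings.warn(
                f"series {name} not significantly rhythmic; "
                "phase delay is a best-effort estimate",
                stacklevel=2,
            )
    fit_a = cosinor_fit(a, 24.0)
    fit_b = cosinor_fit(b, 24.0)
    return float(wrap_phase_h(fit_b.acrophase_h - fit_a.acrophase_h, 24.0))
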