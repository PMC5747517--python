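"""Synthetic circadian recordings with known ground truth.

Every analysis stage in this package is validated by parameter recovery,
so this module generates each kind of input the pipeline consumes with
the generating parameters recorded alongside:

* single-cell luminescence traces — damped cosines with baseline trend,
  Gaussian photon noise, and a per-step Gaussian phase random walk that
  reproduces gradual desynchronization of uncoupled oscillators;
* SCN-like movies — a two-lobed tissue mask whose in-mask pixels are
  heterogeneous oscillators (period and initial phase drawn per pixel), a
  tunable fraction of arrhythmic pixels, and optional mean-field coupling
  that pulls each oscillator toward the ensemble phase;
* locomotor actograms — nocturnal Poisson activity driven by an internal
  clock with a free-running period, optionally masked by a light schedule;
* paired metabolic rhythms — two 24-h rhythms with a set acrophase delay,
  emulating hourly-averaged oxygen-consumption traces;
* protein decay courses — replicated exponential decay after a synthesis
  block, with multiplicative noise.

All randomness flows through ``numpy.random.default_rng(seed)``: the same
seed reproduces a dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .behavior import ActivityRecord
from .decay import DecayCourse
from .preprocess import InvalidParameterError, Movie, TimeSeries

__all__ = [
    "CellParams",
    "MovieParams",
    "GroundTruth",
    "ActogramTruth",
    "two_lobed_mask",
    "generate_cell_trace",
    "generate_scn_movie",
    "generate_actogram",
    "generate_metabolic_pair",
    "generate_decay_course",
]


# ---------------------------------------------------------------------------
# single-cell traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellParams:
    """Generating parameters of one cellular oscillator.

    The trace model is

        y(t) = baseline + trend_slope * t
             + amplitude * exp(-damping_rate * t)
                 * cos(2 pi (t - phase_h + D(t)) / period_h)
             + N(0, noise_sd),

    where D(t) is a cumulative Gaussian phase random walk with per-step
    SD ``phase_diffusion_sd`` (hours). ``phase_h`` is the acrophase: the
    noiseless undiffused trace peaks at t = phase_h.
    """

    period_h: float = 24.0
    phase_h: float = 0.0
    amplitude: float = 1.0
    damping_rate: float = 0.0
    baseline: float = 0.0
    trend_slope: float = 0.0
    noise_sd: float = 0.0
    phase_diffusion_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise InvalidParameterError("period_h must be positive")
        for name in ("amplitude", "damping_rate", "noise_sd", "phase_diffusion_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")


def generate_cell_trace(
    params: CellParams,
    dt_h: float,
    duration_h: float,
    seed: int | np.random.Generator = 0,
) -> TimeSeries:
    """Simulate one cellular luminescence trace (endpoint included)."""
    if dt_h <= 0 or duration_h <= 0:
        raise InvalidParameterError("dt_h and duration_h must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(np.floor(duration_h / dt_h + 1e-9)) + 1
    t = dt_h * np.arange(n)
    diffusion = np.zeros(n)
    if params.phase_diffusion_sd > 0:
        steps = rng.normal(0.0, params.phase_diffusion_sd, n - 1)
        diffusion[1:] = np.cumsum(steps)
    envelope = params.amplitude * np.exp(-params.damping_rate * t)
    phase = 2.0 * np.pi * (t - params.phase_h + diffusion) / params.period_h
    values = params.baseline + params.trend_slope * t + envelope * np.cos(phase)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, n)
    return TimeSeries(0.0, dt_h, values)


# ---------------------------------------------------------------------------
# SCN movies
# ---------------------------------------------------------------------------

def two_lobed_mask(height: int = 60, width: int = 60) -> np.ndarray:
    """Bilateral elliptical mask mimicking a coronal SCN slice outline."""
    rr, cc = np.mgrid[0:height, 0:width]
    mask = np.zeros((height, width), dtype=bool)
    for c_frac in (0.32, 0.68):
        r0, c0 = 0.5 * (height - 1), c_frac * (width - 1)
        a, b = 0.30 * height, 0.16 * width
        mask |= ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
    return mask


@dataclass(frozen=True)
class MovieParams:
    """Recording geometry and population statistics of a synthetic movie.

    Defaults match the recording design the analyses expect: a 60 x 60
    field imaged every 55 min for five days (131 frames), a two-lobed
    mask, and cellular periods drawn from N(period_mean_h, period_sd_h)
    with initial acrophases from N(0, phase_sd_h). ``arrhythmic_fraction``
    of the in-mask pixels get amplitude zero. ``coupling_strength`` > 0
    adds a mean-field Kuramoto pull (rad/h per radian of offset) toward
    the ensemble phase; 0 leaves oscillators independent so phase
    diffusion desynchronizes them.
    """

    height: int = 60
    width: int = 60
    mask: np.ndarray | None = None
    dt_h: float = 55.0 / 60.0
    duration_h: float = 120.0
    period_mean_h: float = 24.0
    period_sd_h: float = 0.2
    phase_sd_h: float = 1.0
    arrhythmic_fraction: float = 0.0
    coupling_strength: float = 0.0
    phase_diffusion_sd: float = 0.0
    amplitude: float = 100.0
    damping_rate: float = 0.005
    baseline: float = 100.0
    trend_slope: float = -0.1
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_h <= 0:
            raise InvalidParameterError("dt_h must be positive")
        if self.duration_h < 2.0 * self.period_mean_h:
            raise InvalidParameterError(
                "duration_h must cover at least two mean periods"
            )
        if not 0.0 <= self.arrhythmic_fraction <= 1.0:
            raise InvalidParameterError("arrhythmic_fraction must lie in [0, 1]")
        mask = self.mask
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.height, self.width):
                raise InvalidParameterError("mask shape must match height x width")
            if not mask.any():
                raise InvalidParameterError("mask must contain at least one pixel")
            object.__setattr__(self, "mask", mask)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h / self.dt_h))


@dataclass(frozen=True)
class GroundTruth:
    """Generator truth for one movie.

    ``period_map`` and ``acrophase_map`` are NaN outside the rhythmic
    pixels; ``rhythmic_mask`` is a subset of the region mask.
    ``phase_rad`` holds the simulated phase-angle trajectories, one row
    per rhythmic pixel (coordinates in ``rhythmic_pixels``), one column
    per frame — cos(phase_rad) is the noiseless oscillatory component, so
    desynchrony statistics can be recomputed from the truth directly.
    """

    period_map: np.ndarray = field(repr=False)
    acrophase_map: np.ndarray = field(repr=False)
    rhythmic_mask: np.ndarray = field(repr=False)
    rhythmic_pixels: np.ndarray = field(repr=False)
    phase_rad: np.ndarray = field(repr=False)


def generate_scn_movie(params: MovieParams) -> tuple[Movie, GroundTruth]:
    """Simulate a bioluminescence movie of heterogeneous coupled oscillators.

    Rhythmic pixels integrate d(theta_i)/dt = omega_i + coupling *
    sin(Theta - theta_i) plus per-step phase diffusion, with Theta the
    circular mean phase over rhythmic pixels; their signal is baseline +
    trend + damped-amplitude * cos(theta_i) + noise. Arrhythmic in-mask
    pixels carry the same baseline, trend and noise with zero amplitude;
    out-of-mask pixels are pure background noise.
    """
    rng = np.random.default_rng(params.seed)
    mask = params.mask if params.mask is not None else two_lobed_mask(
        params.height, params.width
    )
    n_frames = params.n_frames
    t = params.dt_h * np.arange(n_frames)
    in_mask = np.argwhere(mask)
    n_px = in_mask.shape[0]

    n_arrhythmic = int(round(params.arrhythmic_fraction * n_px))
    order = rng.permutation(n_px)
    arrhythmic_idx = order[:n_arrhythmic]
    rhythmic_idx = np.sort(order[n_arrhythmic:])
    rhythmic_pixels = in_mask[rhythmic_idx]
    n_rhy = rhythmic_pixels.shape[0]

    periods = rng.normal(params.period_mean_h, params.period_sd_h, n_rhy)
    periods = np.clip(periods, 1e-3, None)
    phases0_h = rng.normal(0.0, params.phase_sd_h, n_rhy)

    omega = 2.0 * np.pi / periods
    theta = np.empty((n_rhy, n_frames))
    theta[:, 0] = -omega * phases0_h
    diff_rad = 0.0
    for k in range(1, n_frames):
        th = theta[:, k - 1]
        drift = omega * params.dt_h
        if params.coupling_strength > 0 and n_rhy > 0:
            mean_angle = np.arctan2(np.sin(th).mean(), np.cos(th).mean())
            drift = drift + params.coupling_strength * params.dt_h * np.sin(
                mean_angle - th
            )
        if params.phase_diffusion_sd > 0:
            diff_rad = omega * rng.normal(0.0, params.phase_diffusion_sd, n_rhy)
        theta[:, k] = th + drift + diff_rad

    frames = rng.normal(0.0, params.noise_sd, (n_frames, params.height, params.width))
    base = params.baseline + params.trend_slope * t
    frames[:, mask] += base[:, None]
    envelope = params.amplitude * np.exp(-params.damping_rate * t)
    if n_rhy > 0:
        signal = envelope[None, :] * np.cos(theta)  # (n_rhy, n_frames)
        frames[:, rhythmic_pixels[:, 0], rhythmic_pixels[:, 1]] += signal.T

    period_map = np.full(mask.shape, np.nan)
    acrophase_map = np.full(mask.shape, np.nan)
    rhythmic_mask = np.zeros(mask.shape, dtype=bool)
    if n_rhy > 0:
        rows, cols = rhythmic_pixels[:, 0], rhythmic_pixels[:, 1]
        period_map[rows, cols] = periods
        acrophase_map[rows, cols] = phases0_h % periods
        rhythmic_mask[rows, cols] = True

    movie = Movie(dt_h=params.dt_h, frames=frames, mask=mask)
    truth = GroundTruth(
        period_map=period_map,
        acrophase_map=acrophase_map,
        rhythmic_mask=rhythmic_mask,
        rhythmic_pixels=rhythmic_pixels,
        phase_rad=theta,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# actograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActogramTruth:
    """Generating clock of a synthetic actogram.

    ``acrophase_by_day_h`` is the activity-bout center of each 24-h
    calendar day, in hours after that day's midnight; under free run it
    drifts by (tau - 24) h per day.
    """

    tau_h: float
    night_center_times_h: np.ndarray
    acrophase_by_day_h: np.ndarray


def generate_actogram(
    tau_h: float = 23.8,
    n_days: int = 14,
    bin_min: int = 10,
    light_schedule: Sequence[tuple[float, float]] | None = None,
    activity_level: float = 20.0,
    night_day_ratio: float = 5.0,
    masking: bool = True,
    seed: int | np.random.Generator = 0,
) -> tuple[ActivityRecord, ActogramTruth]:
    """Simulate nocturnal locomotor activity counts.

    An internal clock advances with period ``tau_h``; the Poisson rate is
    ``activity_level`` counts/h during subjective night (second half of
    each clock cycle) and ``activity_level / night_day_ratio`` during
    subjective day. Under a light schedule (per-day (lights_on_h,
    lights_off_h) clock hours) with ``masking``, activity during the
    light phase is suppressed to zero. Truth records the free-running
    period and the nightly activity centers.
    """
    if not 20.0 <= tau_h <= 28.0:
        raise InvalidParameterError("tau_h must lie in [20, 28] h")
    if 1440 % bin_min != 0:
        raise InvalidParameterError("bin_min must divide 1440")
    if activity_level < 0:
        raise InvalidParameterError("activity_level must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    bin_h = bin_min / 60.0
    bins_per_day = 1440 // bin_min
    n_bins = n_days * bins_per_day
    t = bin_h * (np.arange(n_bins) + 0.5)  # bin centers, hours from midnight day 0

    cycle = (t / tau_h) % 1.0
    night = cycle >= 0.5
    rate = np.where(night, activity_level, activity_level / night_day_ratio)
    if light_schedule is not None and masking:
        day_idx = (t // 24.0).astype(int)
        hour = t % 24.0
        lights_on = np.array([light_schedule[d % len(light_schedule)][0] for d in day_idx])
        lights_off = np.array([light_schedule[d % len(light_schedule)][1] for d in day_idx])
        lit = (hour >= lights_on) & (hour < lights_off)
        rate = np.where(lit, 0.0, rate)
    counts = rng.poisson(rate * bin_h)

    # subjective-night centers: cycle fraction 0.75 of each clock cycle
    k = np.arange(int(np.ceil(n_days * 24.0 / tau_h)) + 1)
    centers = (k + 0.75) * tau_h
    centers = centers[centers < n_days * 24.0]
    acro_by_day = np.full(n_days, np.nan)
    for c in centers:
        d = int(c // 24.0)
        if d < n_days:
            acro_by_day[d] = c % 24.0

    record = ActivityRecord(
        bin_min=bin_min,
        counts=counts,
        start_clock_h=0.0,
        light_schedule=tuple(tuple(x) for x in light_schedule) if light_schedule else None,
    )
    truth = ActogramTruth(
        tau_h=tau_h,
        night_center_times_h=centers,
        acrophase_by_day_h=acro_by_day,
    )
    return record, truth


# ---------------------------------------------------------------------------
# metabolic rhythm pairs
# ---------------------------------------------------------------------------

def generate_metabolic_pair(
    delay_h: float = 6.0,
    dt_h: float = 1.0,
    duration_h: float = 48.0,
    noise_sd: float = 0.0,
    mesor: float = 3000.0,
    amplitude: float = 400.0,
    acrophase_h: float = 18.0,
    seed: int | np.random.Generator = 0,
) -> tuple[TimeSeries, TimeSeries]:
    """Two 24-h metabolic rhythms, the second delayed by ``delay_h``.

    Defaults emulate hourly-averaged oxygen-consumption traces of a
    nocturnal animal over two days (mesor ~3000 mL/kg/h, peak at clock
    hour 18); noise is additive Gaussian on each sample.
    """
    if dt_h <= 0 or duration_h <= 0:
        raise InvalidParameterError("dt_h and duration_h must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(np.floor(duration_h / dt_h + 1e-9)) + 1
    t = dt_h * np.arange(n)

    def rhythm(phi: float) -> TimeSeries:
        values = mesor + amplitude * np.cos(2.0 * np.pi * (t - phi) / 24.0)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, n)
        return TimeSeries(0.0, dt_h, values)

    return rhythm(acrophase_h), rhythm(acrophase_h + delay_h)


# ---------------------------------------------------------------------------
# protein decay courses
# ---------------------------------------------------------------------------

def generate_decay_course(
    rate_per_h: float,
    times_h: Sequence[float] = (0.0, 3.0, 6.0),
    noise_sd: float = 0.0,
    n_reps: int = 3,
    condition: str = "synthetic",
    seed: int | np.random.Generator = 0,
) -> DecayCourse:
    """Replicated exponential decay course after a synthesis block.

    level(t) = exp(-rate * t) * (1 + N(0, noise_sd)) per replicate and
    timepoint, floored at a small positive value so log-linear fitting
    stays defined. Times must include 0 (the pre-chase reference point).
    """
    times = np.asarray(times_h, dtype=float)
    if rate_per_h < 0:
        raise InvalidParameterError("rate_per_h must be non-negative")
    if times.size < 2 or not np.any(times == 0.0):
        raise InvalidParameterError("times_h must include 0 and one later timepoint")
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = np.argsort(times)
    times = times[order]
    clean = np.exp(-rate_per_h * times)
    levels = np.tile(clean, (n_reps, 1))
    if noise_sd > 0:
        levels = levels * (1.0 + rng.normal(0.0, noise_sd, levels.shape))
        levels = np.clip(levels, 1e-9, None)
    return DecayCourse(times_h=times, levels=levels, condition=condition)
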