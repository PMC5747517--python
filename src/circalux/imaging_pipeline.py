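"""Pixel-wise movie analysis: period maps, acrophase maps, desynchrony.

Each in-mask pixel of a bioluminescence movie is treated as one
oscillator: its trace is detrended (optionally smoothed first), scanned
with the chi-squared periodogram, classified as oscillating when any
trial period is significant at the 10% level, and phased by cosinor.
Outputs are a period map, a map of acrophase relative to the whole-slice
mean signal, the oscillating-pixel fraction, distribution summaries for
genotype comparisons, and a sliding-window Kuramoto order parameter that
tracks how synchrony among pixels evolves.

The per-pixel statistics are computed with the same formulas as
``rhythm_stats`` but vectorized across pixels, so a five-day 60 x 60
movie analyzes in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .preprocess import (
    DegenerateInputError,
    InvalidParameterError,
    Movie,
    TimeSeries,
    _shrinking_mean,
    _window_samples,
)
from .rhythm_stats import (
    DEFAULT_ALPHA,
    _qp_matrix,
    _sidak,
    _trial_periods,
    chi_squared_periodogram,
    circular_mean_h,
    circular_sd_h,
    cosinor_fit,
    wrap_phase_h,
)

if TYPE_CHECKING:  # pragma: no cover
    from .cli_io import AnalysisConfig

__all__ = [
    "PixelMaps",
    "DistributionSummary",
    "analyze_movie",
    "oscillating_fraction",
    "distribution_stats",
    "desynchrony_course",
]


@dataclass(frozen=True)
class PixelMaps:
    """Per-pixel rhythm maps of one movie.

    ``period_map`` holds the best significant period per pixel (NaN where
    none); ``acrophase_map`` the cosinor acrophase relative to the
    whole-slice mean signal, wrapped into half a reference period either
    way (defined for every in-mask pixel, including non-significant ones,
    which are fitted at the reference period); ``rhythmic_mask`` marks
    pixels significant at ``alpha`` and is a subset of ``region_mask``.
    """

    period_map: np.ndarray = field(repr=False)
    acrophase_map: np.ndarray = field(repr=False)
    rhythmic_mask: np.ndarray = field(repr=False)
    region_mask: np.ndarray = field(repr=False)
    alpha: float
    reference_acrophase_h: float
    reference_period_h: float


@dataclass(frozen=True)
class DistributionSummary:
    """Mean/SD/histogram of a per-pixel quantity over rhythmic pixels.

    For acrophases the mean and SD are circular (phases wrap); ``n``
    counts contributing pixels.
    """

    n: int
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    which: str


def _condition(data: np.ndarray, dt_h: float, config: "AnalysisConfig") -> np.ndarray:
    """Smooth (optional) and detrend pixel traces, vectorized over rows."""
    if config.smoothing_window_h is not None:
        w = _window_samples(config.smoothing_window_h, dt_h)
        data = _shrinking_mean(data, w)
    w = _window_samples(config.detrend_window_h, dt_h)
    return data - _shrinking_mean(data, w)


def _periodogram_matrix(
    data: np.ndarray, dt_h: float, config: "AnalysisConfig"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chi-squared periodogram of every row of ``data``.

    Returns (periods_h, qp, p_adj) with qp and p_adj of shape
    (n_rows, n_periods); p-values are Sidak-adjusted for the number of
    trial periods exactly as in ``chi_squared_periodogram``.
    """
    periods = _trial_periods(
        config.min_period_h, config.max_period_h, config.step_h
    )
    qp, pval = _qp_matrix(data, dt_h, periods)
    return periods, qp, _sidak(pval, periods.size)


def _cosinor_phase_rows(
    data: np.ndarray, times: np.ndarray, period_h: float
) -> np.ndarray:
    """Cosinor acrophase (hours in [0, period)) of every row at one period."""
    w = 2.0 * np.pi / period_h
    design = np.column_stack(
        [np.ones_like(times), np.cos(w * times), np.sin(w * times)]
    )
    coef, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    return (np.arctan2(coef[2], coef[1]) / w) % period_h


def analyze_movie(movie: Movie, config: "AnalysisConfig | None" = None) -> PixelMaps:
    """Per-pixel rhythm analysis of a masked bioluminescence movie.

    Every in-mask pixel trace is conditioned (optional smoothing, then
    detrending by a one-cycle moving average), scanned with the
    chi-squared periodogram over the configured range, and classified as
    oscillating when significant at ``config.alpha``. Significant pixels
    get a cosinor acrophase at their own best period; non-significant
    pixels are fitted at the slice reference period so the acrophase map
    stays defined, but they are excluded from oscillating counts. The
    acrophase map is stored relative to the cosinor acrophase of the
    unweighted mean of all in-mask pixel traces.
    """
    from .cli_io import AnalysisConfig

    if config is None:
        config = AnalysisConfig()
    if movie.duration_h < 2.0 * config.max_period_h:
        raise InvalidParameterError(
            f"movie spans {movie.duration_h:.1f} h; need >= 2 cycles of the "
            f"{config.max_period_h} h maximum trial period"
        )
    mask = movie.mask
    if config.binning > 1:
        # superpixel analysis shares the pixel path: average blocks first
        from .preprocess import extract_pixel_series

        coords, series = zip(*extract_pixel_series(movie, config.binning))
        data = np.stack([s.values for s in series])
        px = np.asarray(coords)
    else:
        px = np.argwhere(mask)
        data = movie.frames[:, px[:, 0], px[:, 1]].T  # (n_px, n_frames)
    times = movie.dt_h * np.arange(movie.n_frames)

    cond = _condition(data, movie.dt_h, config)
    periods_h, qp, p_adj = _periodogram_matrix(cond, movie.dt_h, config)
    significant = p_adj < config.alpha
    any_sig = significant.any(axis=1)
    qp_masked = np.where(significant, qp, -np.inf)
    best_idx = np.argmax(qp_masked, axis=1)
    best_period = np.where(any_sig, periods_h[best_idx], np.nan)

    # slice reference: mean of in-mask pixel traces, conditioned identically
    ref_raw = data.mean(axis=0)
    ref_cond = _condition(ref_raw[None, :], movie.dt_h, config)[0]
    ref_ts = TimeSeries(0.0, movie.dt_h, ref_cond)
    ref_pg = chi_squared_periodogram(
        ref_ts, config.min_period_h, config.max_period_h, config.step_h,
        alpha=config.alpha,
    )
    ref_period = ref_pg.best_period_h
    if ref_period is None:
        ref_period = (
            float(np.nanmean(best_period)) if any_sig.any() else 24.0
        )
    ref_fit = cosinor_fit(ref_ts, ref_period)

    # per-pixel acrophase at own best period (reference period if none)
    acro = np.empty(data.shape[0])
    fit_period = np.where(any_sig, best_period, ref_period)
    for p in np.unique(fit_period):
        rows = fit_period == p
        acro[rows] = _cosinor_phase_rows(cond[rows], times, float(p))
    rel_acro = wrap_phase_h(acro - ref_fit.acrophase_h, ref_period)

    shape = mask.shape
    period_map = np.full(shape, np.nan)
    acro_map = np.full(shape, np.nan)
    rhythmic = np.zeros(shape, dtype=bool)
    rows, cols = px[:, 0], px[:, 1]
    period_map[rows, cols] = best_period
    acro_map[rows, cols] = rel_acro
    rhythmic[rows, cols] = any_sig
    region = np.zeros(shape, dtype=bool)
    region[rows, cols] = True
    return PixelMaps(
        period_map=period_map,
        acrophase_map=acro_map,
        rhythmic_mask=rhythmic,
        region_mask=region,
        alpha=config.alpha,
        reference_acrophase_h=float(ref_fit.acrophase_h),
        reference_period_h=float(ref_period),
    )


def oscillating_fraction(maps: PixelMaps) -> float:
    """Percentage of region pixels classified as oscillating."""
    denom = int(maps.region_mask.sum())
    if denom == 0:
        raise InvalidParameterError("region mask is empty")
    return 100.0 * float(maps.rhythmic_mask.sum()) / denom


def distribution_stats(
    maps: PixelMaps, which: str, bins: int = 20
) -> DistributionSummary:
    """Distribution of per-pixel periods or acrophases over rhythmic pixels.

    Periods use ordinary mean/SD; acrophases use circular mean/SD on the
    reference period because phases wrap. This feeds the genotype
    comparisons of rhythm dispersion (variance F-tests).
    """
    if which not in ("period", "acrophase"):
        raise InvalidParameterError("which must be 'period' or 'acrophase'")
    sel = maps.rhythmic_mask
    if int(sel.sum()) < 2:
        raise DegenerateInputError("need at least 2 rhythmic pixels")
    if which == "period":
        values = maps.period_map[sel]
        mean, sd = float(values.mean()), float(values.std(ddof=1))
    else:
        values = maps.acrophase_map[sel]
        period = maps.reference_period_h
        mean = circular_mean_h(values, period)
        mean = float(wrap_phase_h(mean, period))
        sd = circular_sd_h(values, period)
    counts, edges = np.histogram(values, bins=bins)
    return DistributionSummary(
        n=int(sel.sum()), mean=mean, sd=sd, bin_edges=edges, counts=counts,
        which=which,
    )


def desynchrony_course(
    movie: Movie,
    window_h: float = 24.0,
    stride_h: float = 6.0,
    maps: PixelMaps | None = None,
    config: "AnalysisConfig | None" = None,
) -> TimeSeries:
    """Sliding-window Kuramoto order parameter of the rhythmic pixels.

    In each window the conditioned trace of every rhythmic pixel is
    phased by cosinor at the fixed slice reference period, and

        R = | mean_j exp(2 pi i phase_j / period) |  in [0, 1]

    summarizes synchrony: R ~ 1 for phase-locked oscillators, falling
    toward the 1/sqrt(n) noise floor as phases disperse. Returned as a
    TimeSeries sampled at window centers every ``stride_h``.
    """
    from .cli_io import AnalysisConfig

    if config is None:
        config = AnalysisConfig()
    if maps is None:
        maps = analyze_movie(movie, config)
    period = maps.reference_period_h
    if window_h < period:
        raise InvalidParameterError("window_h must cover at least one period")
    sel = maps.rhythmic_mask
    if not sel.any():
        raise DegenerateInputError("no rhythmic pixels")
    px = np.argwhere(sel)
    data = movie.frames[:, px[:, 0], px[:, 1]].T
    cond = _condition(data, movie.dt_h, config)
    times = movie.dt_h * np.arange(movie.n_frames)

    w_samples = max(3, int(round(window_h / movie.dt_h)))
    stride = max(1, int(round(stride_h / movie.dt_h)))
    r_values, r_times = [], []
    for start in range(0, movie.n_frames - w_samples + 1, stride):
        sl = slice(start, start + w_samples)
        phases = _cosinor_phase_rows(cond[:, sl], times[sl], period)
        ang = 2.0 * np.pi * phases / period
        r_values.append(float(np.hypot(np.sin(ang).mean(), np.cos(ang).mean())))
        r_times.append(times[start] + 0.5 * (w_samples - 1) * movie.dt_h)
    if len(r_values) < 2:
        raise InvalidParameterError("movie too short for the requested window")
    return TimeSeries(r_times[0], stride * movie.dt_h, np.asarray(r_values))
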