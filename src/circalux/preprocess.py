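"""Signal conditioning for luminescence traces and movies.

Raw bioluminescence recordings carry slow baseline drift (substrate
depletion, focus drift) and frame-to-frame photon noise on top of the
circadian component. The operations here condition a trace before rhythm
statistics are computed: centered moving-average smoothing, baseline
removal by subtracting a one-cycle moving average, amplitude
normalization, and per-pixel series extraction from image stacks.

Edges are handled with shrinking windows throughout: near a record
boundary the window simply contains fewer samples, so no data are
fabricated by padding and the output length always equals the input
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "TimeSeries",
    "Movie",
    "InvalidParameterError",
    "DegenerateInputError",
    "moving_average",
    "detrend",
    "normalize",
    "extract_pixel_series",
    "line_profile",
]


class InvalidParameterError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ValueError):
    """The input is formally valid but carries no usable signal."""


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled signal.

    Parameters
    ----------
    t0_h : float
        Time of the first sample, in hours from the start of the recording.
    dt_h : float
        Sampling interval in hours; must be positive.
    values : numpy.ndarray
        Sample values, one per time point; at least two samples.
    """

    t0_h: float
    dt_h: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt_h <= 0:
            raise InvalidParameterError(f"dt_h must be positive, got {self.dt_h}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise InvalidParameterError(
                "values must be a 1-D array with at least 2 samples"
            )

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_h(self) -> float:
        """Time spanned between first and last sample."""
        return (self.n - 1) * self.dt_h

    @property
    def times(self) -> np.ndarray:
        """Sample times in hours from recording start."""
        return self.t0_h + self.dt_h * np.arange(self.n)

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        """Copy of this series with the same time base and new values."""
        return TimeSeries(self.t0_h, self.dt_h, values)


@dataclass(frozen=True)
class Movie:
    """Time-lapse image stack with a region-of-interest mask.

    ``frames`` has shape (n_frames, height, width); ``mask`` is a boolean
    (height, width) grid marking the tissue region (e.g. the SCN outline)
    within which pixels are analyzed.
    """

    dt_h: float
    frames: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "mask", mask)
        if self.dt_h <= 0:
            raise InvalidParameterError(f"dt_h must be positive, got {self.dt_h}")
        if frames.ndim != 3:
            raise InvalidParameterError("frames must be a (time, row, col) stack")
        if mask.shape != frames.shape[1:]:
            raise InvalidParameterError(
                f"mask shape {mask.shape} does not match frame shape {frames.shape[1:]}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_h(self) -> float:
        return self.n_frames * self.dt_h

    def pixel_series(self, row: int, col: int) -> TimeSeries:
        return TimeSeries(0.0, self.dt_h, self.frames[:, row, col])


def _window_samples(window_h: float, dt_h: float) -> int:
    """Nearest odd sample count for a window given in hours."""
    w = int(round(window_h / dt_h))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    return w


def _shrinking_mean(values: np.ndarray, w: int) -> np.ndarray:
    """Centered running mean over axis -1 with truncated edge windows."""
    if w == 1:
        return values.astype(float, copy=True)
    half = w // 2
    n = values.shape[-1]
    csum = np.cumsum(values, axis=-1, dtype=float)
    zeros = np.zeros(values.shape[:-1] + (1,))
    csum = np.concatenate([zeros, csum], axis=-1)
    idx = np.arange(n)
    hi = np.minimum(idx + half + 1, n)
    lo = np.maximum(idx - half, 0)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def moving_average(ts: TimeSeries, window_h: float) -> TimeSeries:
    """Centered moving-average smoothing.

    The window is converted to the nearest odd number of samples; edge
    windows shrink so the output has the same length as the input. A
    one-sample window is the identity.
    """
    if window_h < ts.dt_h:
        raise InvalidParameterError(
            f"window_h={window_h} is shorter than the sampling interval {ts.dt_h}"
        )
    w = _window_samples(window_h, ts.dt_h)
    return ts.with_values(_shrinking_mean(ts.values, w))


def detrend(ts: TimeSeries, baseline_window_h: float = 24.0) -> TimeSeries:
    """Remove baseline drift by subtracting a one-cycle moving average.

    Subtracting a moving average whose width matches the circadian period
    (default 24 h) cancels slow drift and the mean while passing the
    circadian component nearly unchanged in the interior of the record.
    """
    if ts.duration_h < baseline_window_h:
        raise InvalidParameterError(
            f"series spans {ts.duration_h} h, shorter than the "
            f"{baseline_window_h} h baseline window"
        )
    w = _window_samples(baseline_window_h, ts.dt_h)
    return ts.with_values(ts.values - _shrinking_mean(ts.values, w))


def normalize(ts: TimeSeries, mode: str = "zscore") -> TimeSeries:
    """Scale a trace to unit amplitude.

    mode "zscore" maps to mean 0 / SD 1; mode "range" maps the extremes
    to [0, 1]. Both are affine, so downstream period statistics are
    unchanged; normalization only equalizes display and map scales.
    """
    v = ts.values
    if mode == "zscore":
        sd = v.std()
        if sd == 0:
            raise DegenerateInputError("zero-variance series cannot be z-scored")
        return ts.with_values((v - v.mean()) / sd)
    if mode == "range":
        lo, hi = v.min(), v.max()
        if hi == lo:
            raise DegenerateInputError("constant series cannot be range-normalized")
        return ts.with_values((v - lo) / (hi - lo))
    raise InvalidParameterError(f"unknown normalization mode {mode!r}")


def extract_pixel_series(
    movie: Movie, binning: int = 1
) -> Iterator[tuple[tuple[int, int], TimeSeries]]:
    """Yield one time series per in-mask (super)pixel.

    With ``binning`` b > 1 the frames are first averaged over b x b blocks;
    a block is in-mask when any of its pixels is, and the block's series
    averages only its in-mask pixels. Coordinates are the 0-based (row,
    col) of each block's top-left pixel.
    """
    if binning < 1:
        raise InvalidParameterError("binning must be >= 1")
    h, w = movie.shape
    if binning > min(h, w):
        raise InvalidParameterError(
            f"binning {binning} exceeds frame extent {movie.shape}"
        )
    for r0 in range(0, h, binning):
        for c0 in range(0, w, binning):
            block_mask = movie.mask[r0 : r0 + binning, c0 : c0 + binning]
            if not block_mask.any():
                continue
            block = movie.frames[:, r0 : r0 + binning, c0 : c0 + binning]
            vals = block[:, block_mask].mean(axis=1)
            yield (r0, c0), TimeSeries(0.0, movie.dt_h, vals)


def line_profile(
    movie: Movie, start_px: tuple[int, int], end_px: tuple[int, int]
) -> np.ndarray:
    """Kymograph along a straight pixel segment.

    Samples the movie at nearest pixels along the discrete line from
    ``start_px`` to ``end_px`` (inclusive, (row, col) coordinates) and
    returns a (position, time) matrix, rows ordered start to end. This is
    the representation behind phase-wave displays along a cut through the
    tissue.
    """
    h, w = movie.shape
    for name, (r, c) in (("start_px", start_px), ("end_px", end_px)):
        if not (0 <= r < h and 0 <= c < w):
            raise InvalidParameterError(f"{name}={r, c} lies outside frame {h}x{w}")
    n = int(max(abs(end_px[0] - start_px[0]), abs(end_px[1] - start_px[1]))) + 1
    rows = np.rint(np.linspace(start_px[0], end_px[0], n)).astype(int)
    cols = np.rint(np.linspace(start_px[1], end_px[1], n)).astype(int)
    return movie.frames[:, rows, cols].T.copy()
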