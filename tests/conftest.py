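import numpy as np
import pytest

from circalux import CellParams, TimeSeries, generate_cell_trace


@pytest.fixture
def cosine_24h() -> TimeSeries:
    """Noiseless 24-h cosine, amplitude 1, peak at t = 0, 5 days hourly."""
    return generate_cell_trace(
        CellParams(period_h=24.0, amplitude=1.0), dt_h=1.0, duration_h=120.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


def asymmetric_wave(
    rise_h: float, fall_h: float, n_cycles: int, dt_h: float
) -> TimeSeries:
    """Closed-form sawtooth-like oscillation: slow rise, fast fall.

    Built from half-cosine segments so troughs sit at multiples of
    (rise_h + fall_h) and peaks rise_h later; used to exercise extrema
    and half-period analysis against known construction.
    """
    period = rise_h + fall_h
    t = np.arange(0.0, n_cycles * period + dt_h / 2, dt_h)
    phase = t % period
    rising = phase < rise_h
    values = np.where(
        rising,
        -np.cos(np.pi * phase / rise_h),
        np.cos(np.pi * (phase - rise_h) / fall_h),
    )
    return TimeSeries(0.0, dt_h, values)
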