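import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from circalux import (
    CellParams,
    CosinorFit,
    Extrema,
    Extremum,
    InvalidParameterError,
    TimeSeries,
    chi_squared_periodogram,
    classify_rhythmic,
    cosinor_fit,
    detect_extrema,
    detrend,
    generate_cell_trace,
    group_compare,
    half_periods,
    relative_acrophase,
    variance_f_test,
    wrap_phase_h,
)
from circalux.preprocess import DegenerateInputError

from conftest import asymmetric_wave


def series(values, dt=1.0, t0=0.0):
    return TimeSeries(t0, dt, np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# chi-squared periodogram
# ---------------------------------------------------------------------------

class TestPeriodogram:
    def test_constant_series_degenerate(self):
        pg = chi_squared_periodogram(series(np.full(240, 5.0)))
        assert np.all(pg.qp == 0)
        assert np.all(pg.p_value == 1)
        assert pg.best_period_h is None
        assert not classify_rhythmic(pg)

    def test_noiseless_cosine_finds_period(self):
        t = np.arange(240.0)
        pg = chi_squared_periodogram(
            series(np.cos(2 * np.pi * t / 24.0)), 20.0, 28.0, 1.0
        )
        assert pg.best_period_h == pytest.approx(24.0)
        assert classify_rhythmic(pg)
        assert pg.best_period_h in pg.trial_periods_h

    def test_qp_nonnegative_and_best_only_if_significant(self):
        rng = np.random.default_rng(7)
        pg = chi_squared_periodogram(series(rng.normal(size=131), dt=55 / 60))
        assert np.all(pg.qp >= 0)
        assert (pg.best_period_h is not None) == (pg.min_p < pg.alpha)

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            chi_squared_periodogram(series(np.ones(40)), 20.0, 28.0, 0.1)

    def test_affine_invariance(self, rng):
        v = np.cos(2 * np.pi * np.arange(240) / 23.5) + rng.normal(0, 0.5, 240)
        a = chi_squared_periodogram(series(v))
        b = chi_squared_periodogram(series(-3.7 * v + 11.0))
        assert np.allclose(a.qp, b.qp)
        assert a.best_period_h == b.best_period_h

    def test_noisy_period_recovery_matches_ls_oracle(self):
        """Best period within +-0.2 h of truth 23.8 h in >=95/100 seeds.

        Oracle: exhaustive least-squares sinusoid fit over the identical
        period grid (min-RSS period), computed independently of the fold.
        Ten-day records: the Qp peak needs several more cycles than the
        LS fit to discriminate 0.1-h period steps.
        """
        grid = np.arange(20.0, 28.05, 0.1)
        t = np.arange(0.0, 240.25, 0.5)
        hits_pg, hits_oracle = 0, 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            v = np.cos(2 * np.pi * t / 23.8) + rng.normal(0, 0.3, t.size)
            ts = series(v, dt=0.5)
            pg = chi_squared_periodogram(ts, 20.0, 28.0, 0.1)
            assert pg.best_period_h is not None
            hits_pg += abs(pg.best_period_h - 23.8) <= 0.2
            rss = [cosinor_fit(ts, p).rss for p in grid]
            hits_oracle += abs(grid[np.argmin(rss)] - 23.8) <= 0.2
        assert hits_oracle >= 95  # oracle sanity under the same noise
        assert hits_pg >= 95


class TestClassifyRhythmic:
    def test_false_positive_rate_below_alpha(self):
        """Rhythmic call rate on detrended white noise stays <= alpha.

        200 noise traces at the 55-min cadence through the standard
        detrend -> periodogram path; with the family-level adjustment the
        call rate must not exceed the nominal 0.10 plus binomial slack.
        """
        rng = np.random.default_rng(42)
        calls = 0
        for _ in range(200):
            ts = detrend(series(rng.normal(size=131), dt=55 / 60), 24.0)
            calls += classify_rhythmic(chi_squared_periodogram(ts))
        # binomial 95% envelope around 0.10 with n=200: up to ~0.135
        assert calls / 200 <= 0.135


# ---------------------------------------------------------------------------
# cosinor
# ---------------------------------------------------------------------------

class TestCosinor:
    def test_exact_cosine(self):
        t = np.arange(0.0, 48.5, 0.5)
        fit = cosinor_fit(series(2.0 + np.cos(2 * np.pi * t / 24.0), dt=0.5), 24.0)
        assert fit.mesor == pytest.approx(2.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-9)
        assert fit.acrophase_h == pytest.approx(0.0, abs=1e-9) or (
            fit.acrophase_h == pytest.approx(24.0, abs=1e-9)
        )
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_shifted_cosine_acrophase(self):
        t = np.arange(0.0, 48.5, 0.5)
        fit = cosinor_fit(series(np.cos(2 * np.pi * (t - 6.0) / 24.0), dt=0.5), 24.0)
        assert fit.acrophase_h == pytest.approx(6.0, abs=1e-9)

    def test_degenerate_design_rejected(self):
        with pytest.raises(InvalidParameterError):
            cosinor_fit(series([1.0, 2.0]), 24.0)
        with pytest.raises(InvalidParameterError):
            cosinor_fit(series(np.ones(10)), 24.0)  # spans 9 h < period

    def test_noisy_acrophase_matches_grid_oracle(self):
        """Mean acrophase error < 0.3 h over 100 seeds, agreeing with a
        dense (amplitude-free) grid search over the acrophase."""
        t = np.arange(0.0, 72.5, 0.5)
        phi_grid = np.arange(0.0, 24.0, 0.02)
        cos_bank = np.cos(2 * np.pi * (t[None, :] - phi_grid[:, None]) / 24.0)
        errors, agree = [], []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            true_phi = rng.uniform(0, 24)
            v = 1.0 + np.cos(2 * np.pi * (t - true_phi) / 24.0) + rng.normal(
                0, 0.3, t.size
            )
            fit = cosinor_fit(series(v, dt=0.5), 24.0)
            errors.append(abs(wrap_phase_h(fit.acrophase_h - true_phi, 24.0)))
            # oracle: per candidate phase, best 2-parameter linear fit
            # with non-negative amplitude (phi and phi+12 are otherwise
            # interchangeable with a sign flip)
            sse = []
            for c in cos_bank:
                design = np.column_stack([np.ones_like(t), c])
                coef, *_ = np.linalg.lstsq(design, v, rcond=None)
                if coef[1] < 0:
                    sse.append(np.inf)
                    continue
                resid = v - design @ coef
                sse.append(resid @ resid)
            oracle_phi = phi_grid[int(np.argmin(sse))]
            agree.append(abs(wrap_phase_h(fit.acrophase_h - oracle_phi, 24.0)))
        assert np.mean(errors) < 0.3
        assert np.mean(agree) < 0.05

    @settings(max_examples=25, deadline=None)
    @given(shift=st.floats(-30, 30))
    def test_time_shift_equivariance(self, shift):
        """Shifting the time origin by d shifts acrophase by d (mod period)."""
        t = np.arange(0.0, 72.5, 0.5)
        v = 0.5 + np.cos(2 * np.pi * (t - 3.0) / 24.0)
        a = cosinor_fit(series(v, dt=0.5, t0=0.0), 24.0)
        b = cosinor_fit(series(v, dt=0.5, t0=shift), 24.0)
        assert wrap_phase_h(b.acrophase_h - a.acrophase_h - shift, 24.0) == (
            pytest.approx(0.0, abs=1e-6)
        )


class TestRelativeAcrophase:
    def fit(self, phi, period=24.0):
        return CosinorFit(0.0, 1.0, phi, period, 0.0)

    @pytest.mark.parametrize(
        "phi_a,phi_b,expected",
        [(5.0, 5.0, 0.0), (23.0, 1.0, -2.0), (6.0, 0.0, 6.0), (0.0, 12.0, 12.0)],
    )
    def test_wrapping(self, phi_a, phi_b, expected):
        assert relative_acrophase(self.fit(phi_a), self.fit(phi_b)) == (
            pytest.approx(expected)
        )

    def test_mismatched_periods_rejected(self):
        with pytest.raises(InvalidParameterError):
            relative_acrophase(self.fit(0.0, 24.0), self.fit(0.0, 25.0))


# ---------------------------------------------------------------------------
# extrema and half-periods
# ---------------------------------------------------------------------------

class TestExtrema:
    def test_cosine_extrema_every_12h(self, cosine_24h):
        # interior extrema only: the t = 0 peak sits on the boundary
        ex = detect_extrema(cosine_24h, min_separation_h=6.0)
        times = ex.times()
        kinds = [e.kind for e in ex.events]
        assert {"peak", "trough"} == set(kinds)
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        assert np.allclose(np.diff(times), 12.0, atol=0.1)

    def test_monotone_ramp_has_no_extrema(self):
        ex = detect_extrema(series(np.arange(50.0)), 6.0)
        assert len(ex) == 0

    def test_alternation_enforced_by_construction(self):
        with pytest.raises(InvalidParameterError):
            Extrema(
                (
                    Extremum(0.0, "peak", 1.0),
                    Extremum(5.0, "peak", 2.0),
                )
            )

    def test_asymmetric_wave_count_matches_construction(self):
        """Fast-fall / slow-rise waveform: extrema count and alternation
        follow the closed-form construction (5 cycles -> 5 interior peaks
        at 16 + 24k plus 4 interior troughs at 24k)."""
        ts = asymmetric_wave(rise_h=16.0, fall_h=8.0, n_cycles=5, dt_h=0.5)
        ex = detect_extrema(ts, min_separation_h=4.0)
        kinds = [e.kind for e in ex.events]
        assert len(ex) == 9
        assert kinds.count("peak") == 5 and kinds.count("trough") == 4
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_parabolic_refinement_beats_grid(self):
        # coarse sampling of a cosine: refined peak lands near the true peak
        t = np.arange(0.0, 120.0, 2.0)
        ts = series(np.cos(2 * np.pi * (t - 1.0) / 24.0), dt=2.0)
        ex = detect_extrema(ts, 6.0)
        peaks = [e.time_h for e in ex.events if e.kind == "peak"]
        offsets = [abs(wrap_phase_h(p - 1.0, 24.0)) for p in peaks]
        assert max(offsets) < 0.5  # better than the 2-h grid


class TestHalfPeriods:
    @staticmethod
    def extrema_at(times, first="trough"):
        kinds = ["trough", "peak"] if first == "trough" else ["peak", "trough"]
        return Extrema(
            tuple(
                Extremum(t, kinds[i % 2], 1.0 if kinds[i % 2] == "peak" else -1.0)
                for i, t in enumerate(times)
            )
        )

    def test_symmetric_wave_twelves(self):
        ex = self.extrema_at([0, 12, 24, 36, 48, 60])
        hp = half_periods(ex, "trough", 5)
        assert np.allclose(hp.intervals_h, 12.0)
        assert hp.labels[0] == "trough_to_peak"
        assert not hp.truncated

    def test_asymmetric_intervals(self):
        ts = asymmetric_wave(rise_h=16.0, fall_h=8.0, n_cycles=5, dt_h=0.25)
        ex = detect_extrema(ts, min_separation_h=4.0)
        hp = half_periods(ex, "trough", 5)
        assert not hp.truncated
        assert np.allclose(hp.intervals_h, [16, 8, 16, 8, 16], atol=0.3)

    def test_slow_rise_fast_fall_asymmetry_direction(self):
        """Trough-to-peak intervals exceed peak-to-trough ones for a
        destabilized, slow-rising waveform."""
        ts = asymmetric_wave(rise_h=14.0, fall_h=9.0, n_cycles=5, dt_h=0.25)
        hp = half_periods(detect_extrema(ts, 4.0), "trough", 5)
        t2p = [v for v, l in zip(hp.intervals_h, hp.labels) if l == "trough_to_peak"]
        p2t = [v for v, l in zip(hp.intervals_h, hp.labels) if l == "peak_to_trough"]
        assert np.mean(t2p) > np.mean(p2t)

    def test_sum_conservation(self):
        times = [0.0, 11.0, 25.0, 36.5, 47.0, 61.0]
        ex = self.extrema_at(times)
        hp = half_periods(ex, "trough", 5)
        assert hp.intervals_h.sum() == pytest.approx(times[-1] - times[0])

    def test_truncation_warns(self):
        ex = self.extrema_at([0, 12, 24])
        with pytest.warns(UserWarning):
            hp = half_periods(ex, "trough", 5)
        assert hp.truncated
        assert hp.intervals_h.size == 2


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

class TestVarianceFTest:
    def test_identical_samples(self):
        f, p = variance_f_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_swap_inverts_f_keeps_p(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0, 3, 15)
        f_ab, p_ab = variance_f_test(a, b)
        f_ba, p_ba = variance_f_test(b, a)
        assert f_ab == pytest.approx(1.0 / f_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_zero_variance_denominator(self):
        with pytest.raises(DegenerateInputError):
            variance_f_test([1.0, 2.0], [3.0, 3.0])

    def test_power_at_sd_ratio_three(self):
        """Detection power at SD ratio 3, n = 15 vs 16, matches the
        closed-form power of the two-sided F-test (oracle): 0.739 at the
        0.001 level, 0.98 at the 0.05 level."""
        hits_001 = hits_05 = 0
        n_mc = 400
        for seed in range(n_mc):
            rng = np.random.default_rng(seed)
            _, p = variance_f_test(rng.normal(0, 3, 15), rng.normal(0, 1, 16))
            hits_001 += p < 0.001
            hits_05 += p < 0.05
        c_hi = stats.f.ppf(1 - 0.0005, 14, 15)
        c_lo = stats.f.ppf(0.0005, 14, 15)
        power_001 = stats.f.sf(c_hi / 9, 14, 15) + stats.f.cdf(c_lo / 9, 14, 15)
        assert abs(hits_001 / n_mc - power_001) < 3 * np.sqrt(0.25 / n_mc)
        assert hits_05 / n_mc > 0.9


class TestGroupCompare:
    def test_identical_groups_p_one(self):
        df = group_compare({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_extreme_separation_significant(self):
        df = group_compare({"a": [0.0, 0.1, -0.1], "b": [10.0, 10.1, 9.9]})
        assert df.loc[0, "p_value"] < 0.05

    def test_single_observation_rejected(self):
        with pytest.raises(InvalidParameterError):
            group_compare({"a": [1.0], "b": [1.0, 2.0]})

    def test_tukey_matches_independent_oracles(self):
        """Tukey HSD p-values recomputed two independent ways: statsmodels
        pairwise_tukeyhsd, and the textbook procedure by hand (studentized
        range of the mean difference over sqrt(MSE/n))."""
        groups = {
            "ctrl": [21.0, 23.0, 22.0, 20.0, 24.0],
            "low": [26.0, 28.0, 25.0, 27.0, 29.0],
            "high": [31.0, 33.0, 30.0, 32.0, 34.0],
        }
        df = group_compare(groups, method="tukey")

        sm = pytest.importorskip("statsmodels.stats.multicomp")
        data = np.concatenate([groups[k] for k in groups])
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        res = sm.pairwise_tukeyhsd(data, labels, alpha=0.05)
        sm_p = {
            frozenset((row[0], row[1])): p
            for row, p in zip(res._results_table.data[1:], res.pvalues)
        }
        for _, row in df.iterrows():
            key = frozenset((row.group_a, row.group_b))
            assert row.p_value == pytest.approx(sm_p[key], abs=1e-3)

        # textbook hand computation for one pair (balanced design)
        k, n = 3, 5
        arrays = [np.asarray(v, float) for v in groups.values()]
        mse = np.mean([a.var(ddof=1) for a in arrays])
        q = abs(np.mean(groups["ctrl"]) - np.mean(groups["high"])) / np.sqrt(mse / n)
        p_hand = stats.studentized_range.sf(q, k, k * (n - 1))
        row = df[(df.group_a == "ctrl") & (df.group_b == "high")].iloc[0]
        assert row.p_value == pytest.approx(p_hand, abs=1e-6)
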