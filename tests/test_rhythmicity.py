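"""Correlogram, RS statistic, period estimation and actograms."""

import numpy as np
import pytest

from circatox import dam_io, rhythmicity as rh, synthetic_data as sd
from circatox.rhythmicity import (
    Correlogram,
    actogram_matrix,
    autocorrelate,
    average_actogram,
    estimate_period,
    rhythm_statistic,
    summarise_cohort,
)

from conftest import make_series


def brute_force_correlogram(x, max_lag):
    """Direct double-loop normalised autocovariance (biased estimator)."""
    x = np.asarray(x, float)
    n = len(x)
    x = x - x.mean()
    denom = sum(xi * xi for xi in x)
    out = []
    for k in range(max_lag + 1):
        s = 0.0
        for t in range(n - k):
            s += x[t] * x[t + k]
        out.append(s / denom)
    return np.array(out)


class TestAutocorrelate:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        s = make_series(rng.poisson(6, size=100), bin_width_min=60.0)
        cg = autocorrelate(s, max_lag_h=50.0)
        oracle = brute_force_correlogram(s.counts, 50)
        np.testing.assert_allclose(cg.coeffs, oracle, atol=1e-12)

    def test_cosine_peak_near_24h(self, cosine_series):
        # the biased estimator tapers a unit cosine by (1 - k/n): at lag
        # 48 of 336 bins the peak is 6/7 ~ 0.857, and it dominates the window
        cg = autocorrelate(cosine_series(tau=24.0), max_lag_h=60.0)
        k24 = int(round(24.0 / 0.5))
        assert cg.coeffs[0] == pytest.approx(1.0)
        assert cg.coeffs[k24] == pytest.approx(1.0 - 48 / 336, abs=0.02)
        window = (cg.lags_h >= 18) & (cg.lags_h <= 30)
        assert cg.coeffs[k24] == cg.coeffs[window].max()

    def test_white_noise_stays_inside_band(self):
        # white-noise autocorrelations rarely leave the 3/sqrt(n) band:
        # across seeds and lags under 0.5% of coefficients escape it
        outside = total = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            s = make_series(rng.poisson(10, size=336))
            cg = autocorrelate(s, max_lag_h=60.0)
            outside += int(np.sum(np.abs(cg.coeffs[1:]) >= 3.0 / np.sqrt(336)))
            total += len(cg.coeffs) - 1
        assert outside / total < 0.005

    def test_constant_series_no_variance(self, dd_schedule):
        s = make_series([7] * 200, schedule=dd_schedule)
        with pytest.raises(ValueError, match="no variance"):
            autocorrelate(s, max_lag_h=30.0)

    def test_excessive_lag_rejected(self):
        s = make_series(np.arange(48) % 5)
        with pytest.raises(ValueError):
            autocorrelate(s, max_lag_h=20.0)  # > half of 24 h span

    def test_ci95_formula(self):
        rng = np.random.default_rng(1)
        s = make_series(rng.poisson(5, size=336))
        cg = autocorrelate(s, max_lag_h=60.0)
        assert cg.ci95 == pytest.approx(2.0 / np.sqrt(336))


def _correlogram_with_peak(peak, n_obs=336, peak_lag_h=24.0, bin_h=0.5):
    lags = np.arange(0, 60.0 + 1e-9, bin_h)
    coeffs = np.zeros_like(lags)
    coeffs[0] = 1.0
    k = int(round(peak_lag_h / bin_h))
    coeffs[k] = peak
    coeffs[k - 1] = coeffs[k + 1] = peak * 0.9
    return Correlogram(lags_h=lags, coeffs=coeffs, n_obs=n_obs, ci95=2 / np.sqrt(n_obs))


class TestRhythmStatistic:
    @pytest.mark.parametrize(
        "peak,rs_expected,rhythmic",
        [
            (0.31, 2.8408, True),  # 0.31 / (2/sqrt(336))
            (0.15, 1.3746, False),
        ],
    )
    def test_rs_arithmetic(self, peak, rs_expected, rhythmic):
        r = rhythm_statistic(_correlogram_with_peak(peak))
        assert r.rs == pytest.approx(rs_expected, abs=1e-3)
        assert r.rhythmic is rhythmic

    def test_threshold_is_inclusive_arrhythmic(self):
        # RS exactly 1.5 counts as arrhythmic (<=1.5 rule)
        peak = 1.5 * 2 / np.sqrt(336)
        r = rhythm_statistic(_correlogram_with_peak(peak))
        assert r.rs == pytest.approx(1.5)
        assert not r.rhythmic
        assert r.period_h is None

    def test_negative_peak_floors_rs_at_zero(self):
        cg = _correlogram_with_peak(0.2)
        coeffs = -np.abs(cg.coeffs)
        coeffs[0] = 1.0
        cg = Correlogram(cg.lags_h, coeffs, cg.n_obs, cg.ci95)
        r = rhythm_statistic(cg)
        assert r.rs == 0.0 and not r.rhythmic

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(6, size=336)
        r1 = rh.score_series(make_series(counts))
        r2 = rh.score_series(make_series(counts * 7))
        assert r1.rs == pytest.approx(r2.rs, rel=1e-12)

    def test_empty_window_rejected(self):
        cg = _correlogram_with_peak(0.3)
        with pytest.raises(ValueError):
            rhythm_statistic(cg, search_window=(100.0, 120.0))


class TestEstimatePeriod:
    @pytest.mark.parametrize("tau", [22.0, 23.0, 24.0, 25.0, 26.0])
    def test_noiseless_cosine_recovery(self, cosine_series, tau):
        cg = autocorrelate(cosine_series(tau=tau), max_lag_h=60.0)
        assert estimate_period(cg) == pytest.approx(tau, abs=0.25)

    def test_coarse_grid_sanity(self, dd_schedule):
        t = (np.arange(28) + 0.5) * 6.0
        s = make_series(
            np.round(50 * (1 + np.cos(2 * np.pi * t / 24))),
            bin_width_min=360.0,
            schedule=dd_schedule,
        )
        cg = autocorrelate(s, max_lag_h=60.0)
        assert estimate_period(cg) == pytest.approx(24.0, abs=3.0)

    def test_boundary_peak_warns(self):
        cg = _correlogram_with_peak(0.5, peak_lag_h=18.0)
        with pytest.warns(UserWarning, match="boundary"):
            assert estimate_period(cg) == 18.0

    def test_noisy_recovery_mae_below_one_hour(self):
        errs = []
        for tau in (22.0, 23.0, 24.0, 25.0, 26.0):
            cfg = sd.SimulationConfig(seed=17, n_flies=10, dd_amplitude=0.5, period_h=tau)
            for s in sd.gen_activity(cfg):
                r = rh.score_series(dam_io.slice_segment(s, "DD"))
                if r.rhythmic:
                    errs.append(abs(r.period_h - tau))
        assert np.mean(errs) < 1.0


class TestCohortSummary:
    def test_all_rhythmic(self):
        results = [
            rh.RhythmResult(str(i), rs, True, 24.0, 24.0) for i, rs in enumerate([2, 3, 4])
        ]
        s = summarise_cohort(results, "g", "2-12")
        assert s.rhythmic_percent == 100.0
        assert s.rs_mean == pytest.approx(3.0)
        assert s.period_mean_h == pytest.approx(24.0)

    def test_none_rhythmic_period_absent(self):
        results = [rh.RhythmResult(str(i), 0.5, False) for i in range(5)]
        s = summarise_cohort(results)
        assert s.rhythmic_percent == 0.0
        assert s.period_mean_h is None and s.period_median_h is None

    def test_partial_percentage(self):
        results = [rh.RhythmResult(str(i), 2.0, True, 24.0) for i in range(8)]
        results += [rh.RhythmResult(str(i + 8), 1.0, False) for i in range(2)]
        assert summarise_cohort(results).rhythmic_percent == 80.0


class TestActogram:
    def test_double_plot_structure(self, dd_schedule):
        s = make_series(np.arange(3 * 48), schedule=dd_schedule)
        m = actogram_matrix(s)
        assert m.shape == (2, 96)
        np.testing.assert_array_equal(m[0, 48:], m[1, :48])

    def test_single_plot_is_reshape(self, dd_schedule):
        counts = np.arange(2 * 48)
        s = make_series(counts, schedule=dd_schedule)
        m = actogram_matrix(s, double_plot=False)
        np.testing.assert_array_equal(m, counts.reshape(2, 48))

    def test_too_short_for_double_plot(self, dd_schedule):
        s = make_series(np.arange(48), schedule=dd_schedule)
        with pytest.raises(ValueError):
            actogram_matrix(s)

    def test_average_of_identical_flies(self, dd_schedule):
        counts = np.arange(96) % 7
        sset = dam_io.ActivitySeriesSet(
            [make_series(counts, schedule=dd_schedule, fly_id=f"f{i}") for i in range(3)]
        )
        np.testing.assert_array_equal(
            average_actogram(sset), actogram_matrix(sset[0])
        )

    def test_average_of_two_flies(self, dd_schedule):
        a = make_series(np.full(96, 2), schedule=dd_schedule, fly_id="a")
        b = make_series(np.full(96, 4), schedule=dd_schedule, fly_id="b")
        m = average_actogram(dam_io.ActivitySeriesSet([a, b]))
        assert (m == 3.0).all()

    def test_synthetic_cohort_shows_daily_peak(self):
        from scipy.signal import find_peaks

        cfg = sd.SimulationConfig(seed=8, n_flies=16, dd_amplitude=0.8, phase_h=12.0)
        sset = sd.gen_activity(cfg)
        dd = dam_io.ActivitySeriesSet(
            [dam_io.slice_segment(s, "DD") for s in sset]
        )
        m = average_actogram(dd, double_plot=False)
        # each averaged DD day shows a single dominant activity peak
        for row in m[1:-1]:
            smoothed = np.convolve(row, np.ones(5) / 5, mode="same")
            peaks, _ = find_peaks(smoothed, height=0.7 * smoothed.max(), distance=24)
            assert len(peaks) == 1
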