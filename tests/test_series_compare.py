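"""Daily means, ARIMA selection, correlation null, chi-square, verification."""

import numpy as np
import pandas as pd
import pytest

from driftdive.series_compare import (ArimaSpec, ModelSelectionError,
                                      compare_drift_counts, correlate_pair,
                                      daily_mean, difference_to_stationary,
                                      fill_short_gaps, null_correlation,
                                      select_arima, simulate_arima,
                                      simulate_verification_pair,
                                      verify_against_labels)


def series_of(times, values):
    return pd.DataFrame({"timestamp_utc": pd.to_datetime(times),
                         "drift_rate_ms": values})


class TestDailyMean:
    def test_one_observation_per_day_is_identity(self):
        s = series_of(["2009-02-01T05:00", "2009-02-02T06:00"], [-0.2, -0.3])
        assert daily_mean(s)["drift_rate_ms"].tolist() == [-0.2, -0.3]

    def test_within_day_average(self):
        s = series_of(["2009-02-01T05:00", "2009-02-01T18:00"], [-0.2, -0.4])
        assert daily_mean(s)["drift_rate_ms"].tolist() == pytest.approx([-0.3])

    def test_empty(self):
        assert daily_mean(pd.DataFrame(columns=["timestamp_utc",
                                                "drift_rate_ms"])).empty

    def test_missing_days_absent_not_zero_filled(self):
        s = series_of(["2009-02-01", "2009-02-05"], [-0.2, -0.3])
        assert len(daily_mean(s)) == 2


class TestDifferencing:
    def test_zero_steps_identity(self):
        assert np.array_equal(difference_to_stationary([1.0, 3.0, 6.0], 0),
                              [1.0, 3.0, 6.0])

    def test_single_difference(self):
        assert np.array_equal(difference_to_stationary([1.0, 3.0, 6.0], 1),
                              [2.0, 3.0])

    def test_linear_ramp_differences_to_constant(self):
        ramp = np.arange(20) * 0.5
        assert difference_to_stationary(ramp, 1) == pytest.approx(0.5)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            difference_to_stationary([1.0, 2.0], 2)


class TestGapFilling:
    def test_short_gap_interpolated(self):
        daily = daily_mean(series_of(["2009-02-01", "2009-02-02",
                                      "2009-02-05"], [-0.2, -0.2, -0.5]))
        (piece,) = fill_short_gaps(daily, max_gap_days=3)
        assert len(piece) == 5          # two missing days interpolated

    def test_long_gap_splits(self):
        daily = daily_mean(series_of(
            ["2009-02-01", "2009-02-02", "2009-02-20", "2009-02-21"],
            [-0.2, -0.2, -0.5, -0.5]))
        pieces = fill_short_gaps(daily, max_gap_days=3)
        assert [len(p) for p in pieces] == [2, 2]


class TestSelectArima:
    def test_white_noise_not_differenced_and_sd_recovered(self):
        rng = np.random.default_rng(0)
        spec = select_arima(rng.normal(0, 0.1, 200), max_p=2, max_q=2)
        assert spec.d == 0
        assert spec.innovation_sd == pytest.approx(0.1, rel=0.15)

    def test_random_walk_differenced_once(self):
        rng = np.random.default_rng(1)
        walk = np.cumsum(rng.normal(0, 1, 200))
        assert select_arima(walk, max_p=1, max_q=1).d == 1

    def test_too_short_series_raises(self):
        with pytest.raises(ModelSelectionError):
            select_arima(np.zeros(10))


class TestArimaSpec:
    def test_explosive_ar_rejected(self):
        with pytest.raises(ValueError):
            ArimaSpec(p=1, d=0, q=0, ar=(1.2,))

    def test_simulation_reproducible_and_integrated(self):
        spec = ArimaSpec(p=1, d=1, q=0, ar=(0.5,), innovation_sd=0.1)
        x = simulate_arima(spec, 50, np.random.default_rng(3))
        y = simulate_arima(spec, 50, np.random.default_rng(3))
        assert np.array_equal(x, y)
        # differencing recovers a stationary-scale series
        assert np.std(np.diff(x)) < np.std(x)


class TestCorrelatePair:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 1.5, 3.0])
        assert correlate_pair(a, a) == pytest.approx(1.0)

    def test_negated_series(self):
        a = np.array([1.0, 2.0, 1.5, 3.0])
        assert correlate_pair(a, -a) == pytest.approx(-1.0)

    def test_independent_noise_rarely_correlates(self):
        rng = np.random.default_rng(5)
        small = sum(abs(correlate_pair(rng.normal(size=100),
                                       rng.normal(size=100))) < 0.3
                    for _ in range(200))
        assert small >= 190

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            correlate_pair([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


WHITE = ArimaSpec(p=0, d=0, q=0, innovation_sd=1.0)


class TestNullCorrelation:
    def test_observed_above_all_nulls_gives_floor_p(self):
        res = null_correlation(WHITE, WHITE, n_days=30, r_observed=1.01,
                               n_sim=1000, seed=0)
        assert res.p_value == pytest.approx(1 / 1001)
        assert len(res.null_r) == 1000

    def test_zero_observed_under_white_null_gives_half(self):
        ps = [null_correlation(WHITE, WHITE, n_days=60, r_observed=0.0,
                               n_sim=400, seed=s).p_value for s in range(10)]
        assert np.mean(ps) == pytest.approx(0.5, abs=0.05)

    def test_p_invariant_to_affine_transform_of_observed_series(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=50), rng.normal(size=50)
        r1 = correlate_pair(a, b)
        r2 = correlate_pair(2.0 * a + 1.0, 2.0 * b + 1.0)
        assert r1 == pytest.approx(r2)
        p1 = null_correlation(WHITE, WHITE, 50, r1, n_sim=300, seed=1).p_value
        p2 = null_correlation(WHITE, WHITE, 50, r2, n_sim=300, seed=1).p_value
        assert p1 == p2


class TestCompareDriftCounts:
    @pytest.mark.parametrize("n1,n2,chi2,p", [
        (56, 36, 4.348, 0.037),
        (65, 39, 6.5, 0.011),
        (52, 37, 2.528, 0.112),
    ])
    def test_worked_examples(self, n1, n2, chi2, p):
        stat, df, pval = compare_drift_counts(n1, n2)
        assert stat == pytest.approx(chi2, abs=5e-4)
        assert df == 1
        assert pval == pytest.approx(p, abs=5e-4)

    def test_equal_counts(self):
        stat, _, pval = compare_drift_counts(50, 50)
        assert stat == 0.0 and pval == 1.0

    def test_matches_independent_implementation(self):
        from scipy.stats import chisquare
        rng = np.random.default_rng(11)
        for _ in range(20):
            n1, n2 = rng.integers(1, 200, size=2)
            stat, _, pval = compare_drift_counts(int(n1), int(n2))
            ref = chisquare([n1, n2])
            assert stat == pytest.approx(ref.statistic)
            assert pval == pytest.approx(ref.pvalue)

    def test_both_zero_raises(self):
        with pytest.raises(ValueError):
            compare_drift_counts(0, 0)


class TestVerification:
    labels = pd.DataFrame({
        "dive_id": [f"d{i}" for i in range(10)],
        "dive_type": ["drift"] * 6 + ["D"] * 4})

    def selected(self, ids):
        return pd.DataFrame({"dive_id": ids})

    def test_all_confirmed(self):
        s = verify_against_labels(self.selected(["d0", "d1"]), self.labels)
        assert s.confirmation_pct == 100.0 and s.n_false_positive == 0

    def test_sixty_percent_confirmed(self):
        s = verify_against_labels(
            self.selected(["d0", "d1", "d2", "d3", "d4", "d5",
                           "d6", "d7", "d8", "d9"]), self.labels)
        assert s.confirmation_pct == pytest.approx(60.0)
        assert s.n_selected == s.n_confirmed + s.n_false_positive

    def test_missed_drift_dives_counted(self):
        s = verify_against_labels(self.selected(["d0"]), self.labels)
        assert s.n_missed == 5

    def test_unknown_dive_id_raises(self):
        with pytest.raises(ValueError, match="unknown dive_id"):
            verify_against_labels(self.selected(["nope"]), self.labels)


def test_verification_pair_shares_latent_signal():
    a, b = simulate_verification_pair(100, rng=0)
    r = correlate_pair(np.diff(a), np.diff(b))
    assert r > 0.5
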