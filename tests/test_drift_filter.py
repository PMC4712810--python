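"""The seven selection criteria: boundaries, conjunctivity, reporting."""

import numpy as np
import pandas as pd
import pytest

from conftest import fragment_frame, make_fragment
from driftdive.drift_filter import (CRITERIA, DEFAULT_ORDER, FilterConfig,
                                    FilterConfigError, apply_filters,
                                    criterion_1_speed, criterion_3_length,
                                    criterion_4_pct, criterion_6_time,
                                    criterion_7_prev, extract_drift_series)

CFG = FilterConfig()


def one(fragment_kwargs):
    return pd.DataFrame([make_fragment(**fragment_kwargs)])


@pytest.mark.parametrize("v,expected", [
    (-0.17, True),       # typical observed drift rate sits inside the band
    (-0.04, False), (-0.7, False),
    (-0.05, True), (-0.6, True),      # boundaries inclusive
])
def test_speed_band(v, expected):
    assert criterion_1_speed(one(dict(vspeed_ms=v)), CFG).iloc[0] == expected


@pytest.mark.parametrize("d0,d1,expected", [
    (150, 380, True), (90, 200, False), (400, 560, False),
    (100, 550, True),                 # boundaries inclusive
])
def test_depth_range(d0, d1, expected):
    f = one(dict(depth_start_m=d0, depth_end_m=d1))
    assert CRITERIA["depth"](f, CFG).iloc[0] == expected


@pytest.mark.parametrize("dur,expected", [
    (811.8, True),       # typical retained drift-fragment duration
    (480.0, False),      # "longer than 8 min" is strict
    (300.0, False),
])
def test_minimum_length_strict(dur, expected):
    assert criterion_3_length(one(dict(duration_s=dur)), CFG).iloc[0] == expected


@pytest.mark.parametrize("pct,expected", [
    (51.6, True), (39.9, False), (40.0, True),   # equality retained
])
def test_pct_duration(pct, expected):
    assert criterion_4_pct(one(dict(pct_duration=pct)), CFG).iloc[0] == expected


@pytest.mark.parametrize("nxt,expected", [
    (0.5, True), (0.1, False), (-0.3, False), (np.nan, False),
])
def test_next_fragment_must_ascend(nxt, expected):
    f = one(dict(next_speed_ms=nxt))
    assert CRITERIA["next_ascent"](f, CFG).iloc[0] == expected


@pytest.mark.parametrize("lt,expected", [
    (5.5, True), (14.0, False),
    (19.5, True),        # window half-open: 19:30 itself passes
    (13.5, False),
])
def test_afternoon_exclusion_window(lt, expected):
    assert criterion_6_time(one(dict(start_lt=lt)), CFG).iloc[0] == expected


def test_wrapping_exclusion_window():
    cfg = FilterConfig(lt_excl_start=22.0, lt_excl_end=2.0)
    assert not criterion_6_time(one(dict(start_lt=23.0)), cfg).iloc[0]
    assert not criterion_6_time(one(dict(start_lt=1.0)), cfg).iloc[0]
    assert criterion_6_time(one(dict(start_lt=12.0)), cfg).iloc[0]


@pytest.mark.parametrize("prev,expected", [
    (-1.0, True), (-0.4, False), (-0.6, True), (np.nan, False),
])
def test_prev_fragment_must_descend_actively(prev, expected):
    f = one(dict(prev_speed_ms=prev))
    assert criterion_7_prev(f, CFG).iloc[0] == expected


VIOLATIONS = [
    dict(),                                  # compliant
    dict(vspeed_ms=-0.7),
    dict(depth_start_m=90.0),
    dict(duration_s=400.0),
    dict(pct_duration=30.0),
    dict(next_speed_ms=0.1),
    dict(start_lt=14.0, mid_lt=14.1),
    dict(prev_speed_ms=-0.4),
]


def test_single_violator_fixture_retains_exactly_the_compliant_one():
    frags = fragment_frame(VIOLATIONS)
    drift, report = apply_filters(frags)
    assert len(drift) == 1
    assert drift.iloc[0].dive_id == "d0"
    for name in DEFAULT_ORDER:
        assert report.single_criterion[name]["retained"] == 7
        assert report.single_criterion[name]["pct_of_candidates"] == \
            pytest.approx(100 * 7 / 8)


def test_removed_fragment_attributed_to_time_criterion():
    frags = fragment_frame([dict(start_lt=14.0, mid_lt=14.1)])
    drift, report = apply_filters(frags)
    assert drift.empty
    steps = dict(report.stepwise)
    assert steps["time_of_day"] == 0
    # every criterion before the time window kept the fragment
    for name in DEFAULT_ORDER[:DEFAULT_ORDER.index("time_of_day")]:
        assert steps[name] == 1


def test_stepwise_counts_monotone_non_increasing(month_pipeline):
    counts = [n for _, n in month_pipeline["report"].stepwise]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert counts[0] <= month_pipeline["report"].n_candidates


def test_retained_rates_confined_to_speed_band(month_pipeline):
    v = month_pipeline["drift"].vspeed_ms
    assert ((v >= CFG.speed_min) & (v <= CFG.speed_max)).all()


def test_no_v_or_u_dive_retained(month_pipeline):
    merged = month_pipeline["drift"].merge(
        month_pipeline["labels"][["dive_id", "dive_type"]], on="dive_id")
    assert not merged.dive_type.isin(["V", "U"]).any()


def _random_fixture(rng, n=20):
    rows = []
    for _ in range(n):
        rows.append(dict(
            vspeed_ms=rng.uniform(-0.9, 0.3),
            depth_start_m=rng.uniform(50, 650),
            depth_end_m=rng.uniform(50, 650),
            duration_s=rng.uniform(200, 1200),
            pct_duration=rng.uniform(10, 80),
            next_speed_ms=rng.uniform(-0.5, 1.0),
            prev_speed_ms=rng.uniform(-1.5, 0.0),
            start_lt=rng.uniform(0, 24),
            candidate=bool(rng.random() < 0.9),
        ))
    return fragment_frame(rows)


def test_order_invariance_on_random_fixtures():
    rng = np.random.default_rng(0)
    for _ in range(20):
        frags = _random_fixture(rng)
        reference = None
        for _ in range(10):
            order = list(DEFAULT_ORDER)
            rng.shuffle(order)
            drift, _ = apply_filters(frags, order=order)
            ids = set(zip(drift.dive_id, drift.fragment_index))
            if reference is None:
                reference = ids
            assert ids == reference


def test_unknown_criterion_name_raises():
    with pytest.raises(FilterConfigError, match="unknown"):
        apply_filters(fragment_frame([dict()]), order=["speed", "bogus"])


def test_invalid_config_rejected():
    with pytest.raises(FilterConfigError):
        FilterConfig(speed_max=0.1)
    FilterConfig(speed_max=0.1, allow_positive=True)   # widened band is fine


class TestExtractDriftSeries:
    def test_empty(self):
        assert extract_drift_series(pd.DataFrame(
            columns=["individual_id", "start_utc", "vspeed_ms", "dive_id"])).empty

    def test_output_sorted_by_time(self):
        frags = fragment_frame([dict(), dict(), dict()])
        frags["start_utc"] = pd.to_datetime(
            ["2009-02-03", "2009-02-01", "2009-02-02"])
        series = extract_drift_series(frags)
        assert series.timestamp_utc.is_monotonic_increasing
        assert series.dive_id.tolist() == ["d1", "d2", "d0"]
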