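"""Event detection, TWA formula, and burden invariants.

The independent oracle throughout is a per-sample rectangle-rule
integration written directly in the tests, kept separate from the
implementation's run-based accounting.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypoburden import (
    EventConfig,
    SyntheticCohortConfig,
    ValidationError,
    compute_twa,
    detect_events,
    patient_burden,
    simulate_cohort,
)
from hypoburden.hypotension_burden import monitoring_duration_min

from conftest import make_trace, step_trace

ALL_SCOPE = EventConfig(twa_scope="all_subthreshold_time")


def twa_oracle(trace, threshold=65.0, nominal=20.0, gap_factor=3.0):
    """Brute-force per-sample TWA: sum of depth x coverage over all
    sub-threshold samples divided by wall-clock monitoring time."""
    num_s = 0.0
    for i in range(len(trace.times)):
        if i < len(trace.times) - 1:
            dt = trace.times[i + 1] - trace.times[i]
            if dt > gap_factor * nominal:
                dt = nominal
        else:
            dt = 0.0
        num_s += max(0.0, threshold - trace.map_values[i]) * dt
    total_s = trace.times[-1] - trace.times[0]
    return (num_s / 60.0) / (total_s / 60.0)


class TestDetectEvents:
    def test_never_below_threshold(self):
        trace = step_trace(60.0, [])
        assert detect_events(trace, EventConfig()) == []

    def test_worked_example_single_event(self, square_trace):
        events = detect_events(square_trace, EventConfig())
        assert len(events) == 1
        e = events[0]
        assert e.duration_min == pytest.approx(10.0)
        assert e.nadir_mmhg == 55.0
        assert e.area_mmhg_min == pytest.approx(100.0)
        assert e.start_s == pytest.approx(30.0 * 60)
        assert e.end_s == pytest.approx(40.0 * 60)

    def test_submininal_run_does_not_qualify(self):
        # 40 s below threshold (two 20 s samples) <= 60 s minimum
        trace = step_trace(10.0, [(2.0, 2.0 + 40 / 60, 60.0)])
        assert detect_events(trace, EventConfig()) == []

    def test_exactly_one_minute_does_not_qualify(self):
        trace = step_trace(10.0, [(2.0, 3.0, 60.0)])
        assert detect_events(trace, EventConfig()) == []

    def test_threshold_is_strict(self):
        trace = make_trace([65.0] * 40)
        assert detect_events(trace, EventConfig()) == []

    def test_two_disjoint_dips(self):
        trace = step_trace(100.0, [(10.0, 15.0, 55.0), (50.0, 55.0, 55.0)])
        b = patient_burden(trace, thresholds=(65.0,))
        tb = b.at(65)
        assert tb.n_events == 2
        assert tb.mean_event_duration_min == pytest.approx(5.0)
        assert tb.total_time_below_min == pytest.approx(10.0)

    def test_events_disjoint_and_ordered(self):
        rng = np.random.default_rng(4)
        trace = make_trace(80 + 20 * np.sin(np.arange(600) / 7) + rng.normal(0, 4, 600))
        events = detect_events(trace, EventConfig())
        assert len(events) > 1
        for a, b in zip(events, events[1:]):
            assert a.end_s <= b.start_s

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValidationError):
            detect_events(make_trace([80.0]), EventConfig())


class TestComputeTwa:
    def test_worked_example(self, square_trace):
        events = detect_events(square_trace, EventConfig())
        assert compute_twa(square_trace, events, EventConfig()) == pytest.approx(1.0)

    def test_no_events_gives_zero(self):
        trace = step_trace(60.0, [])
        assert compute_twa(trace, [], EventConfig()) == 0.0

    def test_constant_55_twa_independent_of_duration(self):
        for total in (30.0, 200.0):
            trace = step_trace(total, [(0.0, total + 1, 55.0)], baseline=55.0)
            events = detect_events(trace, EventConfig())
            assert compute_twa(trace, events, EventConfig()) == pytest.approx(10.0)

    def test_scope_qualifying_is_at_most_all_subthreshold(self):
        # one qualifying dip plus one sub-minute excursion
        trace = step_trace(60.0, [(10.0, 15.0, 55.0), (30.0, 30.0 + 40 / 60, 60.0)])
        qual_cfg = EventConfig()
        events = detect_events(trace, qual_cfg)
        twa_quals = compute_twa(trace, events, qual_cfg)
        twa_all = compute_twa(trace, events, ALL_SCOPE)
        assert twa_quals < twa_all
        assert twa_all == pytest.approx(twa_oracle(trace), rel=1e-12)

    def test_zero_monitoring_duration_rejected(self):
        trace = make_trace([55.0, 55.0], times=[0.0, 1e-12])
        with pytest.raises(ValidationError):
            trace2 = make_trace([55.0], times=[0.0])
            compute_twa(trace2, [], EventConfig())
        assert compute_twa(trace, [], ALL_SCOPE) >= 0  # tiny but nonzero is fine


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_synthetic_traces_match_brute_force(self, seed):
        cfg = SyntheticCohortConfig(n_group_a=2, n_group_b=2, seed=seed)
        for trace in simulate_cohort(cfg):
            events = detect_events(trace, ALL_SCOPE)
            got = compute_twa(trace, events, ALL_SCOPE)
            want = twa_oracle(trace)
            assert got == pytest.approx(want, rel=1e-9)

    @given(
        levels=st.lists(st.floats(min_value=30, max_value=120), min_size=2, max_size=60),
        threshold=st.sampled_from([50.0, 65.0]),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_property_all_scope_equals_oracle(self, levels, threshold):
        trace = make_trace(levels)
        cfg = EventConfig(threshold_mmhg=threshold, twa_scope="all_subthreshold_time")
        events = detect_events(trace, cfg)
        assert compute_twa(trace, events, cfg) == pytest.approx(
            twa_oracle(trace, threshold), rel=1e-9, abs=1e-12
        )


class TestInvariants:
    def _random_trace(self, seed):
        rng = np.random.default_rng(seed)
        return make_trace(78 + 14 * np.sin(np.arange(400) / 11) + rng.normal(0, 5, 400))

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_monotonicity(self, seed):
        trace = self._random_trace(seed)
        b = patient_burden(trace, thresholds=(65.0, 50.0))
        assert b.at(65).twa_mmhg >= b.at(50).twa_mmhg
        assert b.at(65).total_time_below_min >= b.at(50).total_time_below_min

    @pytest.mark.parametrize("seed", range(5))
    def test_severe_events_nested_in_ordinary_events(self, seed):
        trace = self._random_trace(seed)
        ev65 = detect_events(trace, EventConfig(threshold_mmhg=65.0, min_duration_s=0.0))
        ev50 = detect_events(trace, EventConfig(threshold_mmhg=50.0, min_duration_s=0.0))
        for e50 in ev50:
            assert any(
                e65.start_s <= e50.start_s and e50.end_s <= e65.end_s for e65 in ev65
            )

    def test_appending_normotension_dilutes_twa(self, square_trace):
        extended = step_trace(150.0, [(30.0, 40.0, 55.0)])
        cfg = EventConfig()
        twa_short = compute_twa(square_trace, detect_events(square_trace, cfg), cfg)
        twa_long = compute_twa(extended, detect_events(extended, cfg), cfg)
        assert 0 < twa_long < twa_short
        assert (
            patient_burden(extended).at(65).pct_time_below
            < patient_burden(square_trace).at(65).pct_time_below
        )

    def test_time_unit_invariance(self, square_trace):
        """Scaling all timestamps (and the nominal interval and minimum
        duration with them) leaves the TWA in mmHg unchanged."""
        scale = 60.0
        scaled = dataclasses.replace(
            square_trace,
            times=square_trace.times * scale,
            nominal_interval=square_trace.nominal_interval * scale,
        )
        cfg = EventConfig()
        scaled_cfg = EventConfig(min_duration_s=cfg.min_duration_s * scale)
        twa1 = compute_twa(square_trace, detect_events(square_trace, cfg), cfg)
        twa2 = compute_twa(scaled, detect_events(scaled, scaled_cfg), scaled_cfg)
        assert twa1 == pytest.approx(twa2, rel=1e-12)

    def test_burden_bounds(self, square_trace):
        b = patient_burden(square_trace)
        for thr in (65.0, 50.0):
            tb = b.at(thr)
            assert 0 <= tb.pct_time_below <= 100
            assert tb.total_time_below_min <= b.monitoring_min
            assert (tb.twa_mmhg == 0) == (not tb.any_event)


class TestGapPolicy:
    def _gappy_trace(self):
        # 20 s sampling, MAP 55, with a 10-min hole in the middle
        times = np.concatenate([np.arange(0, 300, 20.0), np.arange(900, 1200, 20.0)])
        return make_trace(np.full(len(times), 55.0), times=times)

    def test_gap_caps_coverage_and_splits_events(self):
        trace = self._gappy_trace()
        events = detect_events(trace, EventConfig())
        assert len(events) == 2  # the gap terminates the first run
        # first run: 14 full intervals + one nominal interval at the gap
        assert events[0].duration_min == pytest.approx((14 * 20 + 20) / 60.0)

    def test_wall_clock_vs_exclude_gaps_denominator(self):
        trace = self._gappy_trace()
        wall = monitoring_duration_min(trace, EventConfig())
        strict = monitoring_duration_min(trace, EventConfig(gap_policy="exclude_gaps"))
        assert wall == pytest.approx((1180 - 0) / 60.0)
        # the 620 s inter-sample hole counts one nominal interval
        assert strict == pytest.approx(wall - (620 - 20) / 60.0)
        cfg_wall = ALL_SCOPE
        cfg_strict = EventConfig(
            twa_scope="all_subthreshold_time", gap_policy="exclude_gaps"
        )
        twa_wall = compute_twa(trace, [], cfg_wall)
        twa_strict = compute_twa(trace, [], cfg_strict)
        assert twa_strict > twa_wall  # same area over a smaller denominator
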