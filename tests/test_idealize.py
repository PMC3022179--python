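"""Half-amplitude idealization: threshold geometry, noise robustness,
round-trip recovery against simulated ground truth."""

import numpy as np
import pytest

from singlechan import (
    CurrentTrace,
    GatingModel,
    IdealizeParams,
    event_frequency,
    idealize_trace,
    simulate_event_table,
    simulate_trace,
)
from singlechan.errors import (
    FormatError,
    InvalidParameterError,
    NoUnitDetectableError,
)

from conftest import CONTROL_RATE


def _rect_trace(events, amplitude=10.0, duration=12.0, rate=1000.0, noise=0.0, seed=0):
    """Noiseless rectangular trace with given (onset, length) events."""
    n = int(duration * rate)
    current = np.zeros(n)
    for onset, length in events:
        current[int(onset * rate) : int((onset + length) * rate)] += amplitude
    if noise:
        current += np.random.default_rng(seed).normal(0, noise, n)
    return CurrentTrace(
        sample_times=np.arange(n) / rate,
        current=current,
        voltage_mV=60.0,
        sampling_rate_Hz=rate,
    )


class TestThresholdGeometry:
    def test_noiseless_rectangles_recovered_exactly(self):
        # 6 s open of 12 s: too active for a median baseline, so fix it
        trace = _rect_trace([(1.0, 1.0), (4.0, 2.0), (7.5, 3.0)])
        table = idealize_trace(trace, IdealizeParams(baseline=0.0, unit_amplitude=10.0))
        assert len(table) == 3
        np.testing.assert_allclose(
            sorted(table.events["duration_s"]), [1.0, 2.0, 3.0], atol=1.1e-3
        )
        np.testing.assert_allclose(table.events["amplitude_pA"], 10.0, atol=1e-9)

    def test_all_baseline_trace_with_fixed_unit_is_empty(self):
        trace = _rect_trace([])
        table = idealize_trace(trace, IdealizeParams(unit_amplitude=10.0))
        assert len(table) == 0

    def test_flat_trace_auto_unit_errors(self):
        trace = _rect_trace([])
        with pytest.raises(NoUnitDetectableError):
            idealize_trace(trace, IdealizeParams(unit_amplitude="auto"))

    def test_non_uniform_sampling_rejected(self):
        trace = _rect_trace([(1.0, 1.0)])
        trace.sample_times = trace.sample_times**1.01
        with pytest.raises(FormatError):
            idealize_trace(trace, IdealizeParams(unit_amplitude=10.0))

    def test_sub_dead_time_events_discarded(self):
        trace = _rect_trace([(1.0, 0.004), (3.0, 1.0)])
        table = idealize_trace(trace, IdealizeParams(unit_amplitude=10.0, dead_time=0.01))
        assert len(table) == 1
        assert (table.events["duration_s"] >= 0.01).all()

    def test_stacked_opening_decomposed_into_levels(self):
        # two overlapping unit openings: occupancy 1,2,1
        trace = _rect_trace([(1.0, 3.0), (2.0, 1.0)])
        table = idealize_trace(trace, IdealizeParams(unit_amplitude=10.0, max_levels=3))
        assert sorted(table.events["level"]) == [1, 2]
        lvl2 = table.events[table.events["level"] == 2].iloc[0]
        assert lvl2.duration_s == pytest.approx(1.0, abs=2e-3)

    @pytest.mark.parametrize("bad", [dict(threshold_fraction=0.0), dict(threshold_fraction=1.0), dict(dead_time=-1.0)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            IdealizeParams(**bad)


class TestNoiseRobustness:
    def test_event_count_stable_under_noise(self):
        """Same three events detected with noise sd = 0.1 x amplitude in
        >=99% of seeds (here: all of 100)."""
        hits = 0
        for seed in range(100):
            trace = _rect_trace(
                [(1.0, 1.0), (4.0, 2.0), (7.5, 3.0)], noise=1.0, seed=seed
            )
            table = idealize_trace(trace, IdealizeParams(baseline=0.0, unit_amplitude=10.0))
            hits += len(table) == 3
        assert hits >= 99

    def test_round_trip_recall(self, control_model):
        """idealize(simulate_trace(m)) recovers >=95% of uncensored
        ground-truth events (durations >= 5*dead_time, noise 0.1x amplitude)
        with duration error < 2*dead_time."""
        dead = 0.01
        got, total = 0, 0
        for seed in range(30):
            trace = simulate_trace(control_model, 60.0, 60.0, 1000.0, seed)
            truth = simulate_event_table(control_model, 60.0, 60.0, seed)
            try:
                found = idealize_trace(trace)
            except NoUnitDetectableError:
                found = None
            g = truth.events
            g = g[(g.duration_s >= 5 * dead) & (g.onset_s + g.duration_s <= 60.0)]
            total += len(g)
            if found is None:
                continue
            used = set()
            for _, ev in g.iterrows():
                for j, (_, det) in enumerate(found.events.iterrows()):
                    if j in used:
                        continue
                    if (
                        abs(det.onset_s - ev.onset_s) < 5 * dead
                        and abs(det.duration_s - ev.duration_s) < 2 * dead
                    ):
                        got += 1
                        used.add(j)
                        break
        assert total > 50
        assert got / total >= 0.95

    def test_output_invariants(self, control_model):
        trace = simulate_trace(control_model, 60.0, 60.0, 1000.0, seed=3)
        table = idealize_trace(trace)
        df = table.events
        assert (df["duration_s"] >= 0.01).all()
        for lvl, grp in df.groupby("level"):
            assert grp["onset_s"].is_monotonic_increasing


class TestEventFrequency:
    def test_frequency_arithmetic(self):
        # 10 events over 2 minutes -> 5.0/min
        import pandas as pd

        from singlechan import EventTable

        df = pd.DataFrame(
            {
                "onset_s": np.arange(10) * 10.0,
                "duration_s": np.ones(10),
                "amplitude_pA": np.full(10, 10.0),
                "level": np.ones(10, dtype=int),
                "in_burst": np.zeros(10, dtype=bool),
            }
        )
        assert event_frequency(EventTable(events=df, recording_s=120.0)) == 5.0

    def test_zero_events_zero_frequency(self):
        trace = _rect_trace([], duration=60.0)
        table = idealize_trace(trace, IdealizeParams(unit_amplitude=10.0))
        assert event_frequency(table) == 0.0

    def test_poisson_simulation_recovers_control_rate(self):
        """200 one-hour Poisson simulations at the no-choline rate
        7.73/min: mean frequency within 3*sqrt(rate/60) of the rate."""
        m = GatingModel(
            opening_rate=CONTROL_RATE,
            dwell_mixture=(1.0, 0.05, None),
            unit_conductance=(0.161, 0.02),
            max_stack=10,
        )
        freqs = [
            event_frequency(simulate_event_table(m, 60.0, 3600.0, seed=s))
            for s in range(200)
        ]
        assert abs(np.mean(freqs) - CONTROL_RATE) < 3 * np.sqrt(CONTROL_RATE / 60.0)

    def test_burst_exclusion_removes_flagged_windows(self):
        import pandas as pd

        from singlechan import EventTable

        df = pd.DataFrame(
            {
                "onset_s": [1.0, 30.0, 31.0, 100.0],
                "duration_s": [1.0] * 4,
                "amplitude_pA": [10.0] * 4,
                "level": [1] * 4,
                "in_burst": [False, True, True, False],
            }
        )
        table = EventTable(
            events=df, recording_s=120.0, burst_windows=[(29.0, 35.0)]
        )
        assert event_frequency(table) == pytest.approx(2.0)
        assert event_frequency(table, exclude_bursts=True) == pytest.approx(
            2 / ((120.0 - 6.0) / 60.0)
        )
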