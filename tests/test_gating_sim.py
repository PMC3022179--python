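"""Generator contracts: determinism, Poisson arrivals, mixture dwell times,
per-event Gaussian conductance."""

import numpy as np
import pytest
from scipy import stats

from singlechan import (
    BurstSpec,
    GatingModel,
    simulate_dwell_times,
    simulate_event_table,
    simulate_trace,
)
from singlechan.errors import InvalidParameterError

from conftest import CHOLINE_RATE, TAU_SINGLE_60MV


def _model(**kw):
    defaults = dict(
        opening_rate=5.0,
        dwell_mixture=(1.0, 1.0, None),
        unit_conductance=(0.161, 0.02),
    )
    defaults.update(kw)
    return GatingModel(**defaults)


class TestModelValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(dwell_mixture=(1.5, 1.0, None)),
            dict(dwell_mixture=(0.5, 2.0, 1.0)),  # tau1 > tau2
            dict(dwell_mixture=(0.5, -1.0, 2.0)),
            dict(opening_rate=-1.0),
            dict(max_stack=0),
            dict(noise_sd=-0.1),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(InvalidParameterError):
            _model(**kw)

    def test_negative_burst_rejected(self):
        with pytest.raises(InvalidParameterError):
            BurstSpec(rate_per_min=-1, duration_s=1, intensity=2)


class TestSimulateTrace:
    def test_sample_grid_arithmetic(self):
        trace = simulate_trace(_model(), 60.0, 10.0, 1000.0, seed=0)
        assert len(trace.current) == 10_000
        assert len(trace.sample_times) == 10_000
        assert trace.sample_times[1] - trace.sample_times[0] == pytest.approx(1e-3)

    def test_silent_model_gives_zero_current(self):
        trace = simulate_trace(_model(opening_rate=0.0, noise_sd=0.0), 60.0, 5.0, 1000.0, seed=1)
        assert np.all(trace.current == 0.0)

    def test_seed_determinism_bit_identical(self):
        m = _model(noise_sd=0.5)
        a = simulate_trace(m, 60.0, 5.0, 1000.0, seed=42)
        b = simulate_trace(m, 60.0, 5.0, 1000.0, seed=42)
        assert a.current.tobytes() == b.current.tobytes()
        c = simulate_trace(m, 60.0, 5.0, 1000.0, seed=43)
        assert a.current.tobytes() != c.current.tobytes()

    @pytest.mark.parametrize("bad", [dict(duration=0.0), dict(sampling_rate=10.0)])
    def test_invalid_args_rejected(self, bad):
        kw = dict(duration=5.0, sampling_rate=1000.0)
        kw.update(bad)
        with pytest.raises(InvalidParameterError):
            simulate_trace(_model(), 60.0, kw["duration"], kw["sampling_rate"], seed=0)

    def test_event_rate_matches_poisson_intensity(self):
        """Empirical events/min over replicates within 3 SE of the choline
        5e-11 M opening rate (SE = sqrt(lambda*T)/T for a Poisson count)."""
        m = _model(opening_rate=CHOLINE_RATE, dwell_mixture=(1.0, 0.05, None))
        T_min = 60.0
        counts = [
            len(simulate_event_table(m, 60.0, T_min * 60.0, seed=s)) for s in range(200)
        ]
        se = np.sqrt(CHOLINE_RATE / T_min)
        assert abs(np.mean(counts) / T_min - CHOLINE_RATE) < 3 * se

    def test_embedded_conductances_match_unit_gaussian(self):
        """amplitude/voltage of embedded events is the unit Gaussian (KS)."""
        m = _model(opening_rate=60.0, dwell_mixture=(1.0, 0.2, None), max_stack=1)
        g = np.concatenate(
            [
                simulate_event_table(m, 60.0, 600.0, seed=s).events["amplitude_pA"] / 60.0
                for s in range(3)
            ]
        )
        assert len(g) >= 1000
        p = stats.kstest(g, "norm", args=(0.161, 0.02)).pvalue
        assert p > 0.01


class TestSimulateDwellTimes:
    def test_single_exponential_mean(self):
        """Sample mean of Exponential(2.07) within 3 SE of 2.07 (60 mV
        single-component lifetime)."""
        n = 10**5
        d = simulate_dwell_times((1.0, TAU_SINGLE_60MV, None), n, seed=7)
        assert abs(d.mean() - TAU_SINGLE_60MV) < 3 * TAU_SINGLE_60MV / np.sqrt(n)

    def test_degenerate_mixture_is_single_exponential(self):
        d = simulate_dwell_times((0.5, 1.0, 1.0), 50_000, seed=3)
        assert abs(d.mean() - 1.0) < 3 / np.sqrt(50_000)
        assert stats.kstest(d, "expon", args=(0, 1.0)).pvalue > 0.01

    @pytest.mark.parametrize("w,t1,t2", [(0.8, 1.53, 8.34), (0.3, 0.5, 5.0), (1.0, 2.0, None)])
    def test_mixture_mean_property(self, w, t1, t2):
        n = 20_000
        d = simulate_dwell_times((w, t1, t2), n, seed=11)
        expected = w * t1 + (1 - w) * (t2 if t2 is not None else 0.0)
        se = d.std(ddof=1) / np.sqrt(n)
        assert abs(d.mean() - expected) < 3 * se

    @pytest.mark.parametrize("bad", [dict(n=0), dict(mixture=(1.2, 1.0, 2.0)), dict(mixture=(0.5, 0.0, 2.0))])
    def test_invalid_inputs_rejected(self, bad):
        kw = dict(mixture=(1.0, 1.0, None), n=10)
        kw.update(bad)
        with pytest.raises(InvalidParameterError):
            simulate_dwell_times(kw["mixture"], kw["n"], seed=0)


class TestSimulateEventTable:
    def test_shared_generator_contract_with_trace(self):
        """Ground-truth events are exactly the rectangles in the trace."""
        m = _model(opening_rate=10.0, noise_sd=0.0)
        table = simulate_event_table(m, 60.0, 30.0, seed=5)
        trace = simulate_trace(m, 60.0, 30.0, 1000.0, seed=5)
        for _, ev in table.events.iterrows():
            mid = ev.onset_s + ev.duration_s / 2.0
            i = int(mid * 1000)
            if ev.onset_s + ev.duration_s <= 30.0 and ev.duration_s > 2e-3:
                assert trace.current[i] == pytest.approx(ev.amplitude_pA, rel=1e-9)

    def test_expected_count_over_seeds(self):
        counts = [len(simulate_event_table(_model(), 60.0, 120.0, seed=s)) for s in range(500)]
        assert 9.0 <= np.mean(counts) <= 11.0  # rate 5/min over 2 min

    def test_inter_onset_times_are_exponential(self):
        """Without bursts, arrivals are Poisson: KS on inter-onset gaps."""
        m = _model(opening_rate=600.0, dwell_mixture=(1.0, 0.01, None), max_stack=10)
        gaps = []
        for s in range(2):
            t = simulate_event_table(m, 60.0, 600.0, seed=s)
            gaps.append(np.diff(np.sort(t.events["onset_s"].to_numpy())))
        gaps = np.concatenate(gaps)
        assert len(gaps) >= 10**4
        p = stats.kstest(gaps, "expon", args=(0, 1.0 / 10.0)).pvalue
        assert p > 0.01

    def test_max_stack_limits_overlap(self):
        m = _model(opening_rate=120.0, dwell_mixture=(1.0, 5.0, None), max_stack=3)
        t = simulate_event_table(m, 60.0, 120.0, seed=9)
        assert t.events["level"].max() <= 3

    def test_burst_windows_flagged(self):
        m = _model(
            opening_rate=10.0,
            burst=BurstSpec(rate_per_min=2.0, duration_s=5.0, intensity=20.0),
        )
        t = simulate_event_table(m, 60.0, 300.0, seed=2)
        assert len(t.burst_windows) > 0
        flagged = t.events[t.events["in_burst"]]
        for _, ev in flagged.iterrows():
            assert any(a <= ev.onset_s < b for a, b in t.burst_windows)
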