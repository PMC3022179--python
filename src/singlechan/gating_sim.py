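"""Stochastic simulation of single-channel gating in planar lipid bilayers.

The generator emulates the phenomenology of peptide channels reconstituted
into a planar membrane: discrete square openings superposed on a noisy
baseline, Poisson-distributed opening events, open lifetimes drawn from a
one- or two-component exponential mixture, optional stacked (multi-level)
openings, and optional "paroxystic" burst episodes during which the opening
rate is transiently multiplied.

Amplitude bookkeeping: a single open channel of conductance ``g`` nS under
an applied potential ``V`` mV carries ``g * V`` pA, so 0.161 nS at 60 mV
gives 9.66 pA.  Conductance is drawn per event from a Gaussian and held
constant for the event's duration (square events); stacked events sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "BurstSpec",
    "GatingModel",
    "CurrentTrace",
    "EventTable",
    "simulate_dwell_times",
    "simulate_event_table",
    "simulate_trace",
]


@dataclass(frozen=True)
class BurstSpec:
    """Paroxystic burst episodes: windows during which the opening rate is
    multiplied by ``intensity``.  Burst onsets are Poisson at ``rate_per_min``
    and each window lasts ``duration_s``."""

    rate_per_min: float
    duration_s: float
    intensity: float

    def __post_init__(self) -> None:
        if self.rate_per_min < 0 or self.duration_s < 0 or self.intensity < 0:
            raise InvalidParameterError("burst rate, duration and intensity must be >= 0")


@dataclass(frozen=True)
class GatingModel:
    """Generative model of channel gating under one experimental condition.

    Parameters
    ----------
    opening_rate : float
        Poisson intensity of opening events, events per minute.
    dwell_mixture : (w, tau1, tau2)
        Open-lifetime exponential mixture: with probability ``w`` the
        duration is Exponential(tau1), else Exponential(tau2) (seconds).
        ``tau2 is None`` (or ``w == 1``) collapses to a single exponential.
    unit_conductance : (mean_nS, sd_nS)
        Gaussian unit conductance of a single open channel.
    max_stack : int
        Maximum number of simultaneously open levels; 1 forbids overlap.
    noise_sd : float
        Baseline Gaussian noise, pA, added per sample when rasterized.
    burst : BurstSpec, optional
    """

    opening_rate: float
    dwell_mixture: tuple[float, float, Optional[float]]
    unit_conductance: tuple[float, float]
    max_stack: int = 1
    noise_sd: float = 0.0
    burst: Optional[BurstSpec] = None

    def __post_init__(self) -> None:
        w, tau1, tau2 = self.dwell_mixture
        if not (0.0 <= w <= 1.0):
            raise InvalidParameterError(f"mixture weight w={w} outside [0, 1]")
        if tau1 <= 0 or (tau2 is not None and tau2 <= 0):
            raise InvalidParameterError("dwell time constants must be > 0")
        if tau2 is not None and tau1 > tau2:
            raise InvalidParameterError("require tau1 <= tau2 (fast, slow)")
        if self.opening_rate < 0:
            raise InvalidParameterError("opening_rate must be >= 0")
        if self.unit_conductance[0] <= 0 or self.unit_conductance[1] < 0:
            raise InvalidParameterError("unit conductance mean must be > 0, sd >= 0")
        if self.max_stack < 1:
            raise InvalidParameterError("max_stack must be >= 1")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass
class CurrentTrace:
    """A sampled membrane-current recording.

    ``voltage_mV`` follows the bilayer sign convention: the sign labels the
    potential applied to the trans side (negative = trans-negative).
    """

    sample_times: np.ndarray  # s, uniform grid
    current: np.ndarray  # pA
    voltage_mV: float
    sampling_rate_Hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.sample_times.shape != self.current.shape:
            raise InvalidParameterError("times and current must have equal length")
        if not np.all(np.isfinite(self.current)):
            raise InvalidParameterError("current contains non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.current) / self.sampling_rate_Hz


@dataclass
class EventTable:
    """Idealized (or ground-truth) channel openings.

    ``events`` columns: onset_s, duration_s, amplitude_pA, level, in_burst.
    ``recording_s`` is the total recording length the events came from;
    ``burst_windows`` lists (start_s, end_s) paroxystic episodes.
    """

    events: pd.DataFrame
    recording_s: float
    voltage_mV: float = 0.0
    burst_windows: list[tuple[float, float]] = field(default_factory=list)

    COLUMNS = ("onset_s", "duration_s", "amplitude_pA", "level", "in_burst")

    def __post_init__(self) -> None:
        if self.recording_s <= 0:
            raise InvalidParameterError("recording duration must be > 0")
        missing = set(self.COLUMNS) - set(self.events.columns)
        if missing:
            raise InvalidParameterError(f"event table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.events)


def simulate_dwell_times(
    mixture: tuple[float, float, Optional[float]],
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw ``n`` i.i.d. open lifetimes from an exponential mixture.

    Component is chosen Bernoulli(w); duration ~ Exponential(tau of that
    component).  With ``w == 1`` or ``tau2 is None`` this is a single
    exponential — the generative inverse of the survival model
    N(t) = A1 e^(-t/tau1) + A2 e^(-t/tau2).
    """
    w, tau1, tau2 = mixture
    if not (0.0 <= w <= 1.0):
        raise InvalidParameterError(f"mixture weight w={w} outside [0, 1]")
    if tau1 <= 0 or (tau2 is not None and tau2 <= 0):
        raise InvalidParameterError("time constants must be > 0")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if tau2 is None or w == 1.0:
        return rng.exponential(tau1, size=n)
    fast = rng.random(n) < w
    out = np.empty(n)
    out[fast] = rng.exponential(tau1, size=int(fast.sum()))
    out[~fast] = rng.exponential(tau2, size=int((~fast).sum()))
    return out


def _burst_windows(model: GatingModel, duration: float, rng: np.random.Generator) -> list[tuple[float, float]]:
    if model.burst is None or model.burst.rate_per_min == 0:
        return []
    n = rng.poisson(model.burst.rate_per_min / 60.0 * duration)
    starts = np.sort(rng.uniform(0, duration, size=n))
    return [(float(s), float(min(s + model.burst.duration_s, duration))) for s in starts]


def _in_any_window(t: np.ndarray, windows: Sequence[tuple[float, float]]) -> np.ndarray:
    flag = np.zeros(len(t), dtype=bool)
    for a, b in windows:
        flag |= (t >= a) & (t < b)
    return flag


def _generate_events(
    model: GatingModel, voltage: float, duration: float, seed: int
) -> tuple[pd.DataFrame, list[tuple[float, float]]]:
    """Shared event generator so that trace and ground-truth table agree.

    Opening onsets are a (possibly burst-modulated) Poisson process; each
    opening gets a dwell time from the mixture and a per-event conductance
    from the unit Gaussian.  Stacking level is the number of already-open
    channels at onset + 1; onsets that would exceed max_stack are dropped
    (the membrane refuses the extra channel rather than queueing it).
    """
    rng = np.random.default_rng(seed)
    windows = _burst_windows(model, duration, rng)
    lam_base = model.opening_rate / 60.0  # events / s
    if lam_base == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            EventTable.COLUMNS, (float, float, float, int, bool))})
        return empty, windows

    # thinning-free piecewise-constant Poisson: simulate at the max rate,
    # keep baseline-rate events outside bursts with prob 1/intensity
    intensity = model.burst.intensity if model.burst is not None else 1.0
    lam_max = lam_base * max(intensity, 1.0)
    n_cand = rng.poisson(lam_max * duration)
    onsets = np.sort(rng.uniform(0, duration, size=n_cand))
    in_burst = _in_any_window(onsets, windows)
    if intensity >= 1.0:
        keep_p = np.where(in_burst, intensity / max(intensity, 1.0), 1.0 / max(intensity, 1.0))
    else:
        # burst slower than baseline: thin inside windows instead
        lam_max = lam_base
        keep_p = np.where(in_burst, intensity, 1.0)
    keep = rng.random(n_cand) < keep_p
    onsets, in_burst = onsets[keep], in_burst[keep]
    n = len(onsets)

    w, tau1, tau2 = model.dwell_mixture
    if tau2 is None or w == 1.0:
        durations = rng.exponential(tau1, size=n)
    else:
        fast = rng.random(n) < w
        durations = np.where(fast, rng.exponential(tau1, size=n), rng.exponential(tau2, size=n))
    g_mean, g_sd = model.unit_conductance
    conds = rng.normal(g_mean, g_sd, size=n)
    conds = np.clip(conds, 1e-6, None)  # conductance is physical, > 0
    amplitudes = conds * voltage  # nS * mV = pA

    # assign stacking levels; drop events that would exceed max_stack
    ends = onsets + durations
    level = np.zeros(n, dtype=int)
    keep_mask = np.ones(n, dtype=bool)
    open_ends: list[float] = []  # end times of currently open, kept events
    for i in range(n):
        open_ends = [e for e in open_ends if e > onsets[i]]
        if len(open_ends) >= model.max_stack:
            keep_mask[i] = False
            continue
        level[i] = len(open_ends) + 1
        open_ends.append(ends[i])

    df = pd.DataFrame(
        {
            "onset_s": onsets[keep_mask],
            "duration_s": durations[keep_mask],
            "amplitude_pA": amplitudes[keep_mask],
            "level": level[keep_mask],
            "in_burst": in_burst[keep_mask],
        }
    )
    return df, windows


def _validate_sim_args(duration: float, sampling_rate: Optional[float] = None) -> None:
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if sampling_rate is not None and sampling_rate < 100:
        raise InvalidParameterError("sampling_rate must be >= 100 Hz")


def simulate_event_table(
    model: GatingModel, voltage: float, duration: float, seed: int
) -> EventTable:
    """Exact generated events (noise-free ground truth), no rasterization.

    Shares its random stream with :func:`simulate_trace`: the same
    (model, voltage, duration, seed) yields the events embedded in the trace.
    """
    _validate_sim_args(duration)
    df, windows = _generate_events(model, voltage, duration, seed)
    return EventTable(events=df, recording_s=duration, voltage_mV=voltage, burst_windows=windows)


def simulate_trace(
    model: GatingModel,
    voltage: float,
    duration: float,
    sampling_rate: float,
    seed: int,
    meta: Optional[dict] = None,
) -> CurrentTrace:
    """Rasterize the gating process into a sampled current trace.

    Each open event contributes a rectangle of height conductance * voltage
    (pA) between its onset and end; overlapping events add.  Gaussian
    baseline noise of ``model.noise_sd`` pA is added per sample.  Identical
    seeds produce bit-identical traces.
    """
    _validate_sim_args(duration, sampling_rate)
    df, windows = _generate_events(model, voltage, duration, seed)
    n_samples = int(round(duration * sampling_rate))
    t = np.arange(n_samples) / sampling_rate
    current = np.zeros(n_samples)
    for onset, dur, amp in zip(df["onset_s"], df["duration_s"], df["amplitude_pA"]):
        i0 = int(np.ceil(onset * sampling_rate))
        i1 = min(int(np.ceil((onset + dur) * sampling_rate)), n_samples)
        current[i0:i1] += amp
    if model.noise_sd > 0:
        noise_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E015E]))
        current += noise_rng.normal(0.0, model.noise_sd, size=n_samples)
    md = dict(meta or {})
    md.setdefault("seed", seed)
    md["burst_windows"] = [list(w) for w in windows]
    return CurrentTrace(
        sample_times=t,
        current=current,
        voltage_mV=voltage,
        sampling_rate_Hz=sampling_rate,
        meta=md,
    )
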