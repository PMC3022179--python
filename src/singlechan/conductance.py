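"""Conductance statistics: probability histograms and Gaussian central fits.

The single-channel conductance of an event is |amplitude / voltage|
(pA / mV = nS).  The distribution over events is summarized by a probability
histogram P(Lambda) fitted with a Gaussian; the fitted center Lambda_c ± SE
characterizes the conductance state of the channel under one condition, and
two conditions are compared by a Welch-style t-test on the fitted centers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .errors import FitFailureError, InsufficientDataError, InvalidParameterError
from .gating_sim import EventTable

__all__ = [
    "ConductanceFit",
    "conductances_from_events",
    "fit_conductance_histogram",
    "fit_conductance_mle",
    "compare_central_conductance",
]

MIN_FIT_EVENTS = 30


@dataclass
class ConductanceFit:
    """Gaussian fit of a conductance probability histogram."""

    bin_edges: np.ndarray  # nS
    p_lambda: np.ndarray  # probability per bin, sums to 1
    lambda_c: float  # nS, fitted center
    lambda_c_se: float  # nS, SE of the fitted center
    sigma: float  # nS, fitted width
    r_squared: float
    n_events: int
    voltage_mV: float = float("nan")
    condition: str = ""

    def __post_init__(self) -> None:
        total = float(np.sum(self.p_lambda))
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"p_lambda sums to {total}, expected 1")


def conductances_from_events(
    events: EventTable, voltage: float, include_bursts: bool = False
) -> np.ndarray:
    """Per-event conductance magnitudes |amplitude_pA / voltage_mV| in nS.

    Burst-flagged events are excluded by default (their amplitudes are
    unreliable during paroxystic activity).
    """
    if voltage == 0:
        raise InvalidParameterError("voltage must be nonzero")
    df = events.events
    if not include_bursts and len(df):
        df = df[~df["in_burst"]]
    return np.abs(df["amplitude_pA"].to_numpy(dtype=float) / voltage)


def _gaussian(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_conductance_histogram(
    conductances: Sequence[float],
    binning: Union[str, np.ndarray] = "fd",
    voltage: float = float("nan"),
    condition: str = "",
    min_events: int = MIN_FIT_EVENTS,
) -> ConductanceFit:
    """Histogram the conductances, normalize to probabilities, and fit a
    Gaussian ``a * exp(-(x - mu)^2 / 2 sigma^2)`` to the bin heights by
    nonlinear least squares.

    Binning defaults to Freedman–Diaconis; explicit edges may be given.
    The center's SE comes from the fit covariance.  Below ``min_events``
    no fit is attempted (raw mean ± SD is the honest summary there).
    """
    x = np.asarray(conductances, dtype=float)
    if len(x) < min_events:
        raise InsufficientDataError(f"need >= {min_events} events for a histogram fit, got {len(x)}")
    if np.ptp(x) == 0:
        # degenerate: all identical; center exact, no width information
        edges = np.array([x[0] - 0.5e-3, x[0] + 0.5e-3])
        return ConductanceFit(
            bin_edges=edges,
            p_lambda=np.array([1.0]),
            lambda_c=float(x[0]),
            lambda_c_se=0.0,
            sigma=float(np.diff(edges)[0]),
            r_squared=1.0,
            n_events=len(x),
            voltage_mV=voltage,
            condition=condition,
        )

    counts, edges = np.histogram(x, bins=binning)
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    a0 = float(p.max())
    mu0 = float(centers[np.argmax(p)])
    sigma0 = float(np.std(x))
    # multinomial uncertainty per bin, sqrt(p(1-p)/n), floored so empty
    # bins still constrain the fit; absolute_sigma keeps the parameter
    # covariance on the probability scale
    n = counts.sum()
    bin_sigma = np.sqrt(np.maximum(p * (1 - p), 0.25 / n) / n)
    try:
        popt, pcov = optimize.curve_fit(
            _gaussian,
            centers,
            p,
            p0=[a0, mu0, sigma0],
            sigma=bin_sigma,
            absolute_sigma=True,
            bounds=([0.0, edges[0], 1e-12], [np.inf, edges[-1], np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
        raise FitFailureError(f"Gaussian histogram fit failed: {exc}") from exc
    resid = p - _gaussian(centers, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ConductanceFit(
        bin_edges=edges,
        p_lambda=p,
        lambda_c=float(popt[1]),
        lambda_c_se=float(np.sqrt(pcov[1, 1])),
        sigma=float(abs(popt[2])),
        r_squared=r2,
        n_events=len(x),
        voltage_mV=voltage,
        condition=condition,
    )


def fit_conductance_mle(conductances: Sequence[float]) -> tuple[float, float, float]:
    """Gaussian maximum likelihood on the raw conductances: (mu, se_mu, sigma).

    Cross-check for the histogram fit; on unimodal Gaussian data the two
    agree within a couple of SEs.
    """
    x = np.asarray(conductances, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("need >= 2 values")
    mu = float(np.mean(x))
    sigma = float(np.std(x))
    return mu, sigma / np.sqrt(len(x)), sigma


def compare_central_conductance(
    fit_a: ConductanceFit, fit_b: ConductanceFit
) -> tuple[float, float]:
    """Welch-style t-test on two fitted centers using their fit SEs.

    Returns (t, two-sided P).  Degrees of freedom by Welch–Satterthwaite on
    the SEs with each fit's event count; equal centers give t = 0, P = 1
    even when both SEs are zero (a degenerate but well-defined case).
    """
    for f in (fit_a, fit_b):
        if f.lambda_c_se is None or not np.isfinite(f.lambda_c_se):
            raise InvalidParameterError("fits must carry a finite SE")
    diff = fit_a.lambda_c - fit_b.lambda_c
    pooled = np.hypot(fit_a.lambda_c_se, fit_b.lambda_c_se)
    if pooled == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.inf) * np.sign(diff), 0.0
    t = diff / pooled
    v1, v2 = fit_a.lambda_c_se**2, fit_b.lambda_c_se**2
    df = (v1 + v2) ** 2 / (
        v1**2 / max(fit_a.n_events - 1, 1) + v2**2 / max(fit_b.n_events - 1, 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)
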