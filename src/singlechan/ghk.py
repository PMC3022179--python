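"""Goldman–Hodgkin–Katz ionic selectivity for a single-salt KCl gradient.

For a membrane separating KCl solutions of different concentration the
zero-current (reversal) potential obeys

    V_rev = (RT/F) * ln[(r [K]_trans + [Cl]_cis) / (r [K]_cis + [Cl]_trans)]

with r = P_K+ / P_Cl- the permeability ratio.  The relation inverts in
closed form:

    r = ([Cl]_cis - x [Cl]_trans) / (x [K]_cis - [K]_trans),  x = e^(VF/RT)

valid for V_rev strictly between the two Nernst limits (r -> 0 gives the
Cl- Nernst potential, r -> inf the K+ Nernst potential).  Concentrations,
not activities, are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError, InvalidParameterError

__all__ = [
    "IonConditions",
    "SelectivityResult",
    "thermal_voltage_mV",
    "ghk_reversal",
    "ghk_permeability_ratio",
    "fit_reversal_potential",
    "reversal_from_step_protocol",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol


@dataclass(frozen=True)
class IonConditions:
    """Salt concentrations per chamber (mM) and bath temperature (deg C).

    For a single-salt KCl system [K] = [Cl] on each side; the convenience
    constructor :meth:`kcl` enforces that.
    """

    K_cis: float
    K_trans: float
    Cl_cis: float
    Cl_trans: float
    temperature_C: float = 23.0

    def __post_init__(self) -> None:
        for name in ("K_cis", "K_trans", "Cl_cis", "Cl_trans"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0 mM")

    @classmethod
    def kcl(cls, cis_mM: float, trans_mM: float, temperature_C: float = 23.0) -> "IonConditions":
        return cls(cis_mM, trans_mM, cis_mM, trans_mM, temperature_C)

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15


@dataclass
class SelectivityResult:
    v_rev_mV: float
    ratio: float  # P_K+ / P_Cl-
    conditions: IonConditions
    method: str  # "step-protocol" | "iv-regression" | "given"


def thermal_voltage_mV(temperature_C: float) -> float:
    """RT/F in millivolts (25.52 mV at the 23 deg C bath temperature)."""
    return GAS_CONSTANT * (temperature_C + 273.15) / FARADAY * 1000.0


def ghk_reversal(ratio: float, cond: IonConditions) -> float:
    """Forward GHK: reversal potential (mV) for a permeability ratio."""
    if ratio < 0:
        raise InvalidParameterError("permeability ratio must be >= 0")
    rtf = thermal_voltage_mV(cond.temperature_C)
    if np.isinf(ratio):  # K+-selective Nernst limit
        return rtf * float(np.log(cond.K_trans / cond.K_cis))
    num = ratio * cond.K_trans + cond.Cl_cis
    den = ratio * cond.K_cis + cond.Cl_trans
    return rtf * float(np.log(num / den))


def ghk_permeability_ratio(v_rev_mV: float, cond: IonConditions) -> float:
    """Closed-form GHK inversion: P_K+/P_Cl- from a reversal potential.

    Raises :class:`DomainError` if ``v_rev_mV`` lies at or beyond a Nernst
    limit, where the ratio would be negative or infinite.
    """
    rtf = thermal_voltage_mV(cond.temperature_C)
    x = float(np.exp(v_rev_mV / rtf))
    num = cond.Cl_cis - x * cond.Cl_trans
    den = x * cond.K_cis - cond.K_trans
    if den <= 0 or num < 0:
        raise DomainError(
            f"reversal potential {v_rev_mV} mV is outside the Nernst limits for these conditions"
        )
    return num / den


def fit_reversal_potential(
    iv_points: Sequence[tuple[float, float]]
) -> tuple[float, float, dict]:
    """Linear I–V regression: I = g (V - V_rev).

    Ordinary least squares of current (pA) on voltage (mV); the slope is
    the chord conductance in nS and -intercept/slope the reversal
    potential.  Returns (v_rev_mV, slope_nS, diagnostics) where the
    diagnostics carry r², the intercept SE and residuals.
    """
    pts = np.asarray(iv_points, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise InsufficientDataError("need >= 3 I-V points")
    v, i = pts[:, 0], pts[:, 1]
    if v.min() > 0 or v.max() < 0:
        # still fit, but flag: extrapolated zero crossing
        pass
    res = stats.linregress(v, i)
    if res.slope == 0:
        raise InvalidParameterError("zero slope; reversal potential undefined")
    v_rev = -res.intercept / res.slope
    resid = i - (res.slope * v + res.intercept)
    # SE of v_rev by the delta method
    var = (res.intercept_stderr / res.slope) ** 2 + (
        res.intercept * res.stderr / res.slope**2
    ) ** 2
    diag = {
        "r_squared": float(res.rvalue**2),
        "residuals": resid,
        "v_rev_se": float(np.sqrt(var)),
        "intercept_pA": float(res.intercept),
    }
    return float(v_rev), float(res.slope), diag


def reversal_from_step_protocol(
    holding_potentials_mV: Sequence[float], currents_pA: Sequence[float]
) -> float:
    """Zero-crossing potential from a stepped holding-potential protocol.

    The potential is stepped (e.g. in ±4 mV increments) and the reversal
    potential is where the open-channel current changes sign; linear
    interpolation between the bracketing pair is used.  An exactly zero
    current at a sampled step returns that step's potential.
    """
    v = np.asarray(holding_potentials_mV, dtype=float)
    i = np.asarray(currents_pA, dtype=float)
    if len(v) < 2 or len(v) != len(i):
        raise InsufficientDataError("need >= 2 matched (potential, current) steps")
    order = np.argsort(v)
    v, i = v[order], i[order]
    zero = np.flatnonzero(i == 0)
    if len(zero):
        return float(v[zero[0]])
    sign_change = np.flatnonzero(np.diff(np.sign(i)) != 0)
    if not len(sign_change):
        raise DomainError("current does not change sign across the sweep")
    k = sign_change[0]
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))
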