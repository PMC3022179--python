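"""Tracer-flux permeability coefficients for a two-chamber bilayer setup.

A radiolabelled tracer is added to the donor (cis) chamber; after a fixed
interval a small sample from the receiver (trans) chamber is counted.  In
the initial-flux regime (receiver accumulation small against donor content)
the permeability coefficient is

    P = (N_trans / dt) / (A * C_cis)        [cm s^-1]

where N_trans is the tracer amount that crossed (sampled counts scaled to
the chamber volume), A the membrane area and C_cis the donor concentration.
P is invariant to the tracer's specific activity: counts appear in both
numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError

__all__ = ["FluxExperiment", "FluxResult", "permeability_coefficient", "simulate_flux_counts"]

UL_TO_CM3 = 1e-3

# chamber geometry defaults: 4000 uL chambers, 300 um aperture
DEFAULT_CHAMBER_UL = 4000.0
DEFAULT_AREA_CM2 = float(np.pi * 0.015**2)  # ~7.07e-4 cm^2


@dataclass(frozen=True)
class FluxExperiment:
    """One tracer-flux experiment (possibly replicated).

    ``counts_cis_initial`` and ``counts_trans_final`` are per sampled
    volume (``sample_volume_uL``); each may be a sequence of replicates.
    """

    counts_cis_initial: tuple[float, ...]
    counts_trans_final: tuple[float, ...]
    sample_volume_uL: float = 10.0
    chamber_volume_uL: float = DEFAULT_CHAMBER_UL
    elapsed_s: float = 30.0 * 60.0
    membrane_area_cm2: float = DEFAULT_AREA_CM2

    def __post_init__(self) -> None:
        if min(self.sample_volume_uL, self.chamber_volume_uL, self.elapsed_s, self.membrane_area_cm2) <= 0:
            raise InvalidParameterError("volumes, time and area must be > 0")
        if len(self.counts_cis_initial) != len(self.counts_trans_final):
            raise InvalidParameterError("replicate counts must be paired")
        for c, t in zip(self.counts_cis_initial, self.counts_trans_final):
            if c <= 0 or t < 0:
                raise InvalidParameterError("donor counts must be > 0, receiver counts >= 0")
            if t > c:
                raise InvalidParameterError("receiver counts exceed donor counts: inconsistent data")


@dataclass
class FluxResult:
    p_coeff_cm_s: float
    se_cm_s: float
    replicates: tuple[float, ...] = field(default_factory=tuple)


def permeability_coefficient(exp: FluxExperiment) -> FluxResult:
    """Initial-flux permeability coefficient, replicate mean ± SE."""
    ps = []
    for c_cis, c_trans in zip(exp.counts_cis_initial, exp.counts_trans_final):
        # donor concentration in counts / cm^3
        conc_cis = c_cis / (exp.sample_volume_uL * UL_TO_CM3)
        # total tracer transferred to receiver chamber
        n_trans = c_trans * (exp.chamber_volume_uL / exp.sample_volume_uL)
        flux = n_trans / exp.elapsed_s  # counts / s
        ps.append(flux / (exp.membrane_area_cm2 * conc_cis))
    ps_arr = np.asarray(ps)
    se = float(ps_arr.std(ddof=1) / np.sqrt(len(ps_arr))) if len(ps_arr) > 1 else 0.0
    return FluxResult(p_coeff_cm_s=float(ps_arr.mean()), se_cm_s=se, replicates=tuple(ps))


def simulate_flux_counts(
    p_cm_s: float,
    donor_counts_per_sample: float,
    sample_volume_uL: float = 10.0,
    chamber_volume_uL: float = DEFAULT_CHAMBER_UL,
    elapsed_s: float = 30.0 * 60.0,
    membrane_area_cm2: float = DEFAULT_AREA_CM2,
) -> float:
    """Forward two-compartment model (initial-flux regime): the receiver-side
    sampled counts produced by a membrane of permeability ``p_cm_s``.
    Used to close the forward/inverse consistency loop in tests.
    """
    conc_cis = donor_counts_per_sample / (sample_volume_uL * UL_TO_CM3)
    n_trans = p_cm_s * membrane_area_cm2 * conc_cis * elapsed_s
    return n_trans * (sample_volume_uL / chamber_volume_uL)
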