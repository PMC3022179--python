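"""End-to-end study orchestration over synthetic recordings.

``run_study`` mirrors the experimental analysis sequence: for every
(condition, voltage) cell it simulates (or loads) a recording, idealizes
it, fits the conductance histogram, measures the opening frequency, and
runs the lifetime survival analysis with F-test model selection; the
results aggregate into per-condition tables.  Everything is deterministic
given the study seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import ghk
from .conductance import (
    compare_central_conductance,
    conductances_from_events,
    fit_conductance_histogram,
)
from .errors import InvalidParameterError, SingleChanError
from .gating_sim import BurstSpec, GatingModel, simulate_trace
from .idealize import IdealizeParams, event_frequency, idealize_trace
from .io import write_events, write_trace
from .lifetime import analyze_lifetimes

__all__ = ["StudyConfig", "ConditionSpec", "run_study", "make_fixtures", "load_config"]

log = logging.getLogger("singlechan.study")


@dataclass(frozen=True)
class ConditionSpec:
    label: str
    model: GatingModel


@dataclass(frozen=True)
class StudyConfig:
    conditions: tuple[ConditionSpec, ...]
    voltages_mV: tuple[float, ...]
    recording_s: float = 300.0
    sampling_rate_Hz: float = 1000.0
    idealize: IdealizeParams = field(default_factory=IdealizeParams)
    lifetime_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if not labels:
            raise InvalidParameterError("study needs at least one condition")
        if len(set(labels)) != len(labels):
            raise InvalidParameterError("condition labels must be unique")
        if any(v == 0 for v in self.voltages_mV) or not self.voltages_mV:
            raise InvalidParameterError("voltages must be non-zero and non-empty")


def load_config(path: Union[str, Path]) -> StudyConfig:
    """Parse a flat YAML study configuration.

    Schema: ``seed``, ``recording_s``, ``sampling_rate_Hz``, ``voltages_mV``
    (list), ``lifetime_alpha``, ``idealize.*`` and ``conditions`` — a list of
    mappings with ``label``, ``opening_rate_per_min``, ``dwell_w``,
    ``dwell_tau1_s``, ``dwell_tau2_s`` (optional), ``conductance_mean_nS``,
    ``conductance_sd_nS``, ``noise_sd_pA``, optional ``burst_*`` keys.
    """
    raw = yaml.safe_load(Path(path).read_text())
    conds = []
    for c in raw["conditions"]:
        burst = None
        if c.get("burst_rate_per_min"):
            burst = BurstSpec(
                rate_per_min=c["burst_rate_per_min"],
                duration_s=c.get("burst_duration_s", 5.0),
                intensity=c.get("burst_intensity", 10.0),
            )
        conds.append(
            ConditionSpec(
                label=c["label"],
                model=GatingModel(
                    opening_rate=c["opening_rate_per_min"],
                    dwell_mixture=(
                        c.get("dwell_w", 1.0),
                        c["dwell_tau1_s"],
                        c.get("dwell_tau2_s"),
                    ),
                    unit_conductance=(c["conductance_mean_nS"], c.get("conductance_sd_nS", 0.02)),
                    max_stack=c.get("max_stack", 1),
                    noise_sd=c.get("noise_sd_pA", 0.5),
                    burst=burst,
                ),
            )
        )
    ideal = raw.get("idealize", {})
    return StudyConfig(
        conditions=tuple(conds),
        voltages_mV=tuple(raw["voltages_mV"]),
        recording_s=raw.get("recording_s", 300.0),
        sampling_rate_Hz=raw.get("sampling_rate_Hz", 1000.0),
        idealize=IdealizeParams(
            baseline=ideal.get("baseline", "median"),
            unit_amplitude=ideal.get("unit_amplitude", "auto"),
            threshold_fraction=ideal.get("threshold_fraction", 0.5),
            dead_time=ideal.get("dead_time", 0.01),
            max_levels=ideal.get("max_levels", 5),
        ),
        lifetime_alpha=raw.get("lifetime_alpha", 0.05),
        seed=raw.get("seed", 0),
    )


def _cell_seed(study_seed: int, ci: int, vi: int) -> int:
    return int(np.random.SeedSequence([study_seed, ci, vi]).generate_state(1)[0] % (2**31))


def _log_stage(stage: str, params: dict, outcome: str) -> None:
    digest = hashlib.sha1(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:10]
    log.info("stage=%s input=%s params=%s outcome=%s", stage, digest, params, outcome)


def run_study(config: StudyConfig, out_dir: Union[str, Path]) -> pd.DataFrame:
    """Run every (condition, voltage) cell and write aggregate tables.

    Returns the per-cell report DataFrame (also written as
    ``study_report.tsv``).  Stage errors are recorded per cell and the
    study continues.  Identical config + seed reruns are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    fits = {}
    for ci, cond in enumerate(config.conditions):
        for vi, v in enumerate(config.voltages_mV):
            seed = _cell_seed(config.seed, ci, vi)
            row: dict = {"condition": cond.label, "voltage_mV": v, "seed": seed, "error": ""}
            try:
                trace = simulate_trace(
                    cond.model, v, config.recording_s, config.sampling_rate_Hz, seed,
                    meta={"condition": cond.label},
                )
                _log_stage("simulate", {"condition": cond.label, "V": v, "seed": seed},
                           f"{len(trace.current)} samples")
                events = idealize_trace(trace, config.idealize)
                _log_stage("idealize", {"dead_time": config.idealize.dead_time},
                           f"{len(events)} events")
                row["n_events"] = len(events)
                row["frequency_per_min"] = event_frequency(events, exclude_bursts=True)
                lam = conductances_from_events(events, v)
                try:
                    fit = fit_conductance_histogram(lam, voltage=v, condition=cond.label)
                    row["lambda_c_nS"], row["lambda_c_se_nS"] = fit.lambda_c, fit.lambda_c_se
                    fits[(cond.label, v)] = fit
                except SingleChanError:
                    row["lambda_c_nS"] = float(np.mean(lam)) if len(lam) else np.nan
                    row["lambda_c_se_nS"] = np.nan
                durs = events.events.loc[~events.events["in_burst"], "duration_s"]
                if len(durs) >= 8:
                    fit1, fit2, sel = analyze_lifetimes(
                        durs.to_numpy(), alpha=config.lifetime_alpha, seed=seed
                    )
                    chosen = fit2 if sel.selected_order == 2 else fit1
                    row.update(
                        tau1_s=chosen.tau1,
                        tau2_s=chosen.tau2 if chosen.model_order == 2 else np.nan,
                        selected_order=sel.selected_order,
                        F=sel.F,
                        P=sel.p_value,
                    )
                _log_stage("lifetime", {"alpha": config.lifetime_alpha},
                           f"order={row.get('selected_order')}")
            except SingleChanError as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
                _log_stage("cell", {"condition": cond.label, "V": v}, row["error"])
            rows.append(row)

    report = pd.DataFrame(rows)
    report.to_csv(out / "study_report.tsv", sep="\t", index=False, float_format="%.6g")

    # pairwise conductance comparisons at matching voltages
    comp_rows = []
    labels = [c.label for c in config.conditions]
    for v in config.voltages_mV:
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                fa, fb = fits.get((labels[i], v)), fits.get((labels[j], v))
                if fa is None or fb is None:
                    continue
                t, p = compare_central_conductance(fa, fb)
                comp_rows.append(
                    {"voltage_mV": v, "condition_a": labels[i], "condition_b": labels[j],
                     "t": t, "P": p}
                )
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(
            out / "conductance_comparisons.tsv", sep="\t", index=False, float_format="%.6g"
        )
    return report


def make_fixtures(seed: int, out_dir: Union[str, Path]) -> dict:
    """Write a small synthetic fixture set with a generator-parameter manifest.

    Contents: a short noisy recording, ground-truth style event tables for
    the two central study conditions, and an I-V point set generated from
    the GHK forward model at ratio 0.46 under the 100/50 mM KCl gradient.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    trace_model = GatingModel(
        opening_rate=15.97, dwell_mixture=(0.8, 1.53, 8.34),
        unit_conductance=(0.215, 0.03), noise_sd=1.0,
    )
    trace = simulate_trace(trace_model, 60.0, 30.0, 1000.0, seed, meta={"condition": "choline-cis"})
    write_trace(trace, out / "trace_choline_cis.csv")
    manifest["files"]["trace_choline_cis.csv"] = {
        "opening_rate_per_min": 15.97, "dwell": [0.8, 1.53, 8.34],
        "conductance_nS": [0.215, 0.03], "noise_sd_pA": 1.0,
        "voltage_mV": 60.0, "duration_s": 30.0,
    }

    for label, rate, lam in [("control", 7.73, 0.161), ("choline_cis", 15.97, 0.215)]:
        model = GatingModel(opening_rate=rate, dwell_mixture=(1.0, 2.07, None),
                            unit_conductance=(lam, 0.02))
        from .gating_sim import simulate_event_table

        tbl = simulate_event_table(model, 60.0, 120.0, seed + hash(label) % 1000)
        write_events(tbl, out / f"events_{label}.tsv")
        manifest["files"][f"events_{label}.tsv"] = {
            "opening_rate_per_min": rate, "conductance_nS": lam, "voltage_mV": 60.0,
        }

    cond = ghk.IonConditions.kcl(100.0, 50.0, 23.0)
    rng = np.random.default_rng(seed)
    voltages = np.arange(-30.0, 41.0, 10.0)
    g = 0.2  # nS chord conductance
    v_rev = ghk.ghk_reversal(0.46, cond)
    currents = g * (voltages - v_rev) + rng.normal(0, 0.05, size=len(voltages))
    pd.DataFrame({"voltage_mV": voltages, "current_pA": currents}).to_csv(
        out / "iv_r046.csv", index=False, float_format="%.6g"
    )
    manifest["files"]["iv_r046.csv"] = {
        "ratio": 0.46, "v_rev_mV": v_rev, "slope_nS": g, "noise_sd_pA": 0.05,
        "kcl_mM": [100.0, 50.0], "temperature_C": 23.0,
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
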