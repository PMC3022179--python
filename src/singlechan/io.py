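"""Plain-text I/O: trace CSV + JSON sidecar, event TSV, I-V CSV, fit JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .conductance import ConductanceFit
from .errors import FormatError
from .gating_sim import CurrentTrace, EventTable

__all__ = [
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "read_iv_points",
    "write_conductance_fit",
]

PathLike = Union[str, Path]


def write_trace(trace: CurrentTrace, csv_path: PathLike) -> Path:
    """Two-column CSV (time_s, current_pA) with a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    # %.10g keeps the sample grid exact out to multi-hour recordings
    pd.DataFrame({"time_s": trace.sample_times, "current_pA": trace.current}).to_csv(
        csv_path, index=False, float_format="%.10g"
    )
    sidecar = {
        "voltage_mV": trace.voltage_mV,
        "sampling_rate_Hz": trace.sampling_rate_Hz,
        **trace.meta,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_trace(csv_path: PathLike) -> CurrentTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if list(df.columns[:2]) != ["time_s", "current_pA"]:
        raise FormatError(f"{csv_path}: expected columns time_s, current_pA")
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    voltage = meta.pop("voltage_mV")
    rate = meta.pop("sampling_rate_Hz")
    return CurrentTrace(
        sample_times=df["time_s"].to_numpy(),
        current=df["current_pA"].to_numpy(),
        voltage_mV=voltage,
        sampling_rate_Hz=rate,
        meta=meta,
    )


def write_events(events: EventTable, tsv_path: PathLike) -> Path:
    tsv_path = Path(tsv_path)
    events.events.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    sidecar = {
        "recording_s": events.recording_s,
        "voltage_mV": events.voltage_mV,
        "burst_windows": [list(w) for w in events.burst_windows],
    }
    tsv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return tsv_path


def read_events(tsv_path: PathLike) -> EventTable:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t")
    sidecar_path = tsv_path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    else:  # tolerate bare tables: infer span from the events themselves
        span = float((df["onset_s"] + df["duration_s"]).max()) if len(df) else 1.0
        meta = {"recording_s": span, "voltage_mV": 0.0, "burst_windows": []}
    if "in_burst" not in df.columns:
        df["in_burst"] = False
    if "level" not in df.columns:
        df["level"] = 1
    return EventTable(
        events=df,
        recording_s=meta["recording_s"],
        voltage_mV=meta.get("voltage_mV", 0.0),
        burst_windows=[tuple(w) for w in meta.get("burst_windows", [])],
    )


def read_iv_points(csv_path: PathLike) -> np.ndarray:
    """Two-column CSV (voltage_mV, current_pA) -> (n, 2) array."""
    df = pd.read_csv(csv_path)
    if df.shape[1] < 2:
        raise FormatError(f"{csv_path}: expected two columns (voltage_mV, current_pA)")
    return df.iloc[:, :2].to_numpy(dtype=float)


def write_conductance_fit(fit: ConductanceFit, json_path: PathLike) -> Path:
    json_path = Path(json_path)
    payload = {
        "lambda_c_nS": fit.lambda_c,
        "lambda_c_se_nS": fit.lambda_c_se,
        "sigma_nS": fit.sigma,
        "r_squared": fit.r_squared,
        "n_events": fit.n_events,
        "voltage_mV": fit.voltage_mV,
        "condition": fit.condition,
        "bin_edges_nS": [float(x) for x in fit.bin_edges],
        "p_lambda": [float(x) for x in fit.p_lambda],
    }
    json_path.write_text(json.dumps(payload, indent=1))
    return json_path
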