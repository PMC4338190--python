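"""File round-tripping: tidy CSV/TSV tables with JSON sidecars.

Trajectories and recordings are written as comma-separated tables (floats
at 9 significant digits, so identical simulations give byte-identical
files) with a JSON sidecar next to them carrying pulse times, onset/escape
metadata and the full configuration.  Marker series go to TSV with the
scalar metadata in ``#``-prefixed header lines; exponent and prediction
outputs get a TSV table plus a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .markers import MarkerSample, MarkerSeries
from .protocol import PatchProtocolConfig, Recording
from .sde import SDEConfig, Trajectory

FLOAT_FMT = "%.9g"

__all__ = [
    "write_trajectory", "read_trajectory",
    "write_recording", "read_recording",
    "write_marker_series", "read_marker_series",
    "write_scaling_results", "write_predictions",
    "load_config", "dump_config", "config_from_dict",
]


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


def _jsonable(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, float) and not math.isfinite(value):
        return None if math.isnan(value) else ("inf" if value > 0 else "-inf")
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    return value


def _dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def write_trajectory(traj: Trajectory, csv_path) -> Path:
    """CSV (time, state columns, y) plus JSON sidecar; returns the sidecar path."""
    csv_path = Path(csv_path)
    cols = {"time": traj.times}
    if traj.state.ndim == 1:
        cols["V"] = traj.state
    else:
        cols["V1"] = traj.state[:, 0]
        cols["V2"] = traj.state[:, 1]
    cols["y"] = traj.y
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    meta = {
        "kind": traj.kind,
        "detrended": traj.detrended,
        "t_c": traj.t_c,
        "escape_time": traj.escape_time,
        "pulse_times": traj.pulse_times,
        "seed": traj.config.seed,
        "config": dataclasses.asdict(traj.config),
    }
    side = _sidecar(csv_path)
    _dump_json(meta, side)
    return side


def read_trajectory(csv_path) -> Trajectory:
    csv_path = Path(csv_path)
    meta = json.loads(_sidecar(csv_path).read_text())
    frame = pd.read_csv(csv_path)
    cfg = config_from_dict(SDEConfig, meta["config"])
    state = frame["V"].to_numpy() if "V" in frame else frame[["V1", "V2"]].to_numpy()
    t_c = meta["t_c"]
    return Trajectory(
        kind=meta["kind"],
        times=frame["time"].to_numpy(),
        state=state,
        y=frame["y"].to_numpy(),
        pulse_times=np.asarray(meta["pulse_times"], dtype=float),
        t_c=math.inf if t_c == "inf" else float(t_c),
        escape_time=meta["escape_time"],
        config=cfg,
        detrended=meta.get("detrended", False),
    )


def write_recording(rec: Recording, csv_path) -> Path:
    """Single tidy CSV at the voltage rate; current only on its own grid rows."""
    csv_path = Path(csv_path)
    ratio = rec.v_sampling_hz / rec.i_sampling_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigError("v_sampling_hz must be an integer multiple of i_sampling_hz")
    ratio = int(round(ratio))
    n = len(rec.voltage_mV)
    current = np.full(n, np.nan)
    n_i = min(len(rec.current_pA), (n + ratio - 1) // ratio)
    current[: n_i * ratio: ratio] = rec.current_pA[:n_i]
    pd.DataFrame(
        {
            "time_s": np.arange(n) / rec.v_sampling_hz,
            "voltage_mV": rec.voltage_mV,
            "current_pA": current,
        }
    ).to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    meta = {
        "kind": "recording",
        "onset_time_s": rec.onset_time_s,
        "pulse_times_s": rec.pulse_times_s,
        "i_critical_nominal_pA": rec.i_critical_nominal_pA,
        "control": rec.control,
        "v_sampling_hz": rec.v_sampling_hz,
        "i_sampling_hz": rec.i_sampling_hz,
        "seed": rec.sde.seed,
        "protocol": dataclasses.asdict(rec.protocol),
        "sde": dataclasses.asdict(rec.sde),
    }
    side = _sidecar(csv_path)
    _dump_json(meta, side)
    return side


def read_recording(csv_path) -> Recording:
    csv_path = Path(csv_path)
    meta = json.loads(_sidecar(csv_path).read_text())
    frame = pd.read_csv(csv_path)
    current = frame["current_pA"].to_numpy()
    return Recording(
        voltage_mV=frame["voltage_mV"].to_numpy(),
        current_pA=current[np.isfinite(current)],
        v_sampling_hz=meta["v_sampling_hz"],
        i_sampling_hz=meta["i_sampling_hz"],
        pulse_times_s=np.asarray(meta["pulse_times_s"], dtype=float),
        onset_time_s=meta["onset_time_s"],
        i_critical_nominal_pA=meta["i_critical_nominal_pA"],
        protocol=config_from_dict(PatchProtocolConfig, meta["protocol"]),
        sde=config_from_dict(SDEConfig, meta["sde"]),
        control=meta.get("control", False),
    )


def write_marker_series(series: MarkerSeries, tsv_path) -> None:
    tsv_path = Path(tsv_path)
    header = [
        f"# kind = {series.kind}",
        f"# I_c = {series.I_c}",
        f"# V_cm = {series.V_cm}",
        f"# onset_time = {series.onset_time}",
        f"# acf_lag = {series.acf_lag}",
        f"# acf_lag_time = {series.acf_lag_time}",
    ]
    body = series.to_dataframe().to_csv(sep="\t", index=False, float_format=FLOAT_FMT)
    tsv_path.write_text("\n".join(header) + "\n" + body)


def _parse_meta_value(text: str):
    text = text.strip()
    if text in ("None", ""):
        return None
    try:
        return float(text)
    except ValueError:
        return text


def read_marker_series(tsv_path) -> MarkerSeries:
    tsv_path = Path(tsv_path)
    meta = {}
    with open(tsv_path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = _parse_meta_value(value)
    frame = pd.read_csv(tsv_path, sep="\t", comment="#")
    samples = [
        MarkerSample(
            delta_I=row.delta_I_pA,
            lam=row.lambda_per_s,
            variance=row.variance_mV2,
            acf=row.acf,
            mean_voltage=row.mean_voltage_mV,
            pulse_time=row.pulse_time_s,
        )
        for row in frame.itertuples()
    ]
    acf_lag = meta.get("acf_lag")
    return MarkerSeries(
        samples=samples,
        I_c=meta.get("I_c"),
        V_cm=meta.get("V_cm"),
        onset_time=meta.get("onset_time"),
        acf_lag=int(acf_lag) if acf_lag is not None else 0,
        acf_lag_time=meta.get("acf_lag_time") or math.nan,
        kind=meta.get("kind") or "recording",
    )


def write_scaling_results(results, tsv_path, json_path) -> None:
    """Per-cutoff fit table (TSV) and mean/sd/classification summary (JSON)."""
    results.to_frame().to_csv(tsv_path, sep="\t", index=False, float_format=FLOAT_FMT)
    summary = {
        "grid": results.grid,
        "classification": {
            "label": results.classification.label,
            "distance": results.classification.distance,
            "distances": results.classification.distances,
            "reason": results.classification.reason,
        },
        "exponents": {
            m: {
                "symbol": est.symbol,
                "mean": est.mean_exponent,
                "sd": est.sd_exponent,
                "n_accepted": est.n_accepted,
                "n_fits": len(est.per_cutoff),
            }
            for m, est in results.estimates.items()
        },
        "failures": {m: str(e) for m, e in results.failures.items()},
    }
    _dump_json(summary, json_path)


def write_predictions(results, tsv_path, json_path) -> None:
    results.to_frame().to_csv(tsv_path, sep="\t", index=False, float_format=FLOAT_FMT)
    payload = {
        "theta": results.model.theta,
        "n_exclude": results.model.n_exclude,
        "n_trials_fit": len(results.predictions),
        "n_trials_failed": len(results.failures),
    }
    if results.correlation is not None:
        c = results.correlation
        payload["regression"] = {
            "r": c.r, "p_value": c.p_value, "slope": c.slope,
            "intercept": c.intercept, "n_trials": c.n_trials,
        }
    _dump_json(payload, json_path)


def config_from_dict(cls, data: dict):
    """Build a config dataclass, naming any unknown field in the error."""
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"{cls.__name__}: unknown field(s) {sorted(unknown)}; expected {sorted(fields)}"
        )
    data = dict(data)
    for key in ("state0", "pulse_offsets_ms"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"{cls.__name__}: {exc}")


def load_config(path) -> dict:
    """YAML or JSON configuration file to a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def dump_config(data: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(_jsonable(data), sort_keys=True))
    else:
        _dump_json(data, path)
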