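"""On-disk session container.

LFP traces are raw little-endian float32 (`<region>.f32`) with a JSON
sidecar (`<region>.json`: rate_hz, region, units, t0_s, n_samples); spikes
and trials are CSV; ground truth is JSON. Everything round-trips through
:func:`save_session` / :func:`load_session`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sigproc import LfpRecording
from .spiketools import SpikeTrain

__all__ = [
    "save_lfp", "load_lfp", "save_spikes", "load_spikes",
    "save_trials", "load_trials", "save_session", "load_session",
]

TRIAL_COLUMNS = ["trial_id", "phase", "t_start_s", "t_end_s",
                 "correct", "delay_s", "light", "opsin"]


def save_lfp(directory, lfp: LfpRecording, name: str | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or lfp.region or "lfp"
    (directory / f"{name}.f32").write_bytes(
        lfp.samples.astype("<f4").tobytes())
    sidecar = {
        "rate_hz": lfp.rate, "region": lfp.region, "units": "uV",
        "t0_s": lfp.t0, "n_samples": int(lfp.samples.size),
    }
    (directory / f"{name}.json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1))
    return directory / f"{name}.f32"


def load_lfp(directory, name: str) -> LfpRecording:
    directory = Path(directory)
    meta = json.loads((directory / f"{name}.json").read_text())
    samples = np.frombuffer(
        (directory / f"{name}.f32").read_bytes(), dtype="<f4").astype(float)
    if samples.size != meta["n_samples"]:
        raise IOError(f"{name}: sample count mismatch with sidecar")
    return LfpRecording(samples=samples, rate=meta["rate_hz"],
                        region=meta["region"], t0=meta.get("t0_s", 0.0))


def save_spikes(directory, trains) -> Path:
    rows = []
    for u in trains:
        for t in u.times:
            rows.append({
                "unit_id": u.unit_id, "time_s": t, "l_ratio": u.l_ratio,
                "isolation_distance": u.isolation_distance,
                "region": u.region, "stereotrode_id": u.stereotrode_id,
            })
    path = Path(directory) / "spikes.csv"
    pd.DataFrame(rows, columns=["unit_id", "time_s", "l_ratio",
                                "isolation_distance", "region",
                                "stereotrode_id"]).to_csv(path, index=False)
    return path


def load_spikes(directory) -> list[SpikeTrain]:
    df = pd.read_csv(Path(directory) / "spikes.csv")
    trains = []
    for unit_id, g in df.groupby("unit_id", sort=True):
        first = g.iloc[0]
        trains.append(SpikeTrain(
            unit_id=str(unit_id), times=np.sort(g["time_s"].to_numpy()),
            l_ratio=float(first["l_ratio"]),
            isolation_distance=float(first["isolation_distance"]),
            region=str(first.get("region", "")),
            stereotrode_id=str(first.get("stereotrode_id", "")),
        ))
    return trains


def save_trials(directory, trials: pd.DataFrame) -> Path:
    path = Path(directory) / "trials.csv"
    trials[TRIAL_COLUMNS].to_csv(path, index=False)
    return path


def load_trials(directory) -> pd.DataFrame:
    df = pd.read_csv(Path(directory) / "trials.csv")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise IOError(f"trials.csv missing columns: {sorted(missing)}")
    return df


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_session(directory, lfps: dict, trains, trials, truth=None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, lfp in lfps.items():
        save_lfp(directory, lfp, name=name)
    save_spikes(directory, trains)
    save_trials(directory, trials)
    if truth is not None:
        payload = {
            "config": truth.config, "seed": truth.seed,
            "depth_slow": _jsonable(truth.depth_slow),
            "depth_fast": truth.depth_fast,
            "unit_psi": _jsonable(truth.unit_psi),
            "unit_kappa": _jsonable(truth.unit_kappa),
            "correct": _jsonable(truth.correct),
        }
        (directory / "ground_truth.json").write_text(
            json.dumps(_jsonable(payload), sort_keys=True, indent=1))
    return directory


def load_session(directory):
    directory = Path(directory)
    lfps = {p.stem: load_lfp(directory, p.stem)
            for p in sorted(directory.glob("*.f32"))}
    if not lfps:
        raise IOError(f"no LFP container (*.f32) found in {directory}")
    trains = load_spikes(directory)
    trials = load_trials(directory)
    truth_path = directory / "ground_truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return lfps, trains, trials, truth
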