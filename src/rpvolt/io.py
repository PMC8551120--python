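"""Shared file formats.

Everything the toolkit persists is plain text:

* ``WaveformSpec`` / ``PreprocessSpec`` — JSON;
* ``SampledWaveform`` — CSV with columns ``time_s, potential_V, step_index``;
* scan streams and calibration sets — a wide CSV (one row per scan, feature
  columns ``f0…``) plus a ``*.meta.json`` sidecar holding timestamps, kind
  labels, event markers and known concentrations;
* fitted models — a single JSON file with metadata and float arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import CalibrationSet, LatentModel
from .preprocess import FittedScaler, PreprocessSpec
from .quantify import ScanStream, TimecoursePrediction
from .waveform import SampledWaveform, WaveformSpec


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".meta.json")


def save_waveform_spec(spec: WaveformSpec, path) -> None:
    Path(path).write_text(spec.to_json())


def load_waveform_spec(path) -> WaveformSpec:
    return WaveformSpec.from_json(Path(path).read_text())


def save_sampled_waveform(sw: SampledWaveform, path) -> None:
    pd.DataFrame(
        {"time_s": sw.times, "potential_V": sw.potentials, "step_index": sw.step_index}
    ).to_csv(path, index=False)


def save_stream(stream: ScanStream, path) -> None:
    path = Path(path)
    cols = [f"f{j}" for j in range(stream.X.shape[1])]
    pd.DataFrame(stream.X, columns=cols).to_csv(path, index=False, float_format="%.8g")
    meta = {
        "times": stream.times.tolist(),
        "kinds": stream.kinds.tolist() if stream.kinds is not None else None,
        "stim_onsets": list(stream.stim_onsets),
        "drug_time": stream.drug_time,
    }
    _meta_path(path).write_text(json.dumps(meta))


def load_stream(path) -> ScanStream:
    path = Path(path)
    X = pd.read_csv(path).to_numpy(dtype=float)
    meta = json.loads(_meta_path(path).read_text())
    kinds = meta.get("kinds")
    return ScanStream(
        X,
        np.asarray(meta["times"], dtype=float),
        kinds=np.asarray(kinds) if kinds is not None else None,
        stim_onsets=tuple(meta.get("stim_onsets", ())),
        drug_time=meta.get("drug_time"),
    )


def save_calibration(cal: CalibrationSet, path) -> None:
    """Calibration CSV: concentration columns first, then feature columns."""
    path = Path(path)
    df = pd.DataFrame(cal.X, columns=[f"f{j}" for j in range(cal.p)])
    for k, name in enumerate(cal.analytes):
        df.insert(k, f"c_{name}_uM", cal.Y[:, k])
    df.to_csv(path, index=False, float_format="%.8g")
    meta = {
        "analytes": list(cal.analytes),
        "kind": cal.kind,
        "step_index": cal.step_index.tolist() if cal.step_index is not None else None,
    }
    _meta_path(path).write_text(json.dumps(meta))


def load_calibration(path) -> CalibrationSet:
    path = Path(path)
    meta = json.loads(_meta_path(path).read_text())
    analytes = tuple(meta["analytes"])
    df = pd.read_csv(path)
    Y = df[[f"c_{a}_uM" for a in analytes]].to_numpy(dtype=float)
    X = df[[c for c in df.columns if c.startswith("f")]].to_numpy(dtype=float)
    step_index = meta.get("step_index")
    return CalibrationSet(
        X,
        Y,
        analytes=analytes,
        step_index=np.asarray(step_index) if step_index is not None else None,
        kind=meta.get("kind", "pulse"),
    )


def save_model(model: LatentModel, path) -> None:
    d = {
        "algorithm": model.algorithm,
        "A": model.A,
        "analytes": list(model.analytes),
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "Q_load": model.Q_load.tolist(),
        "T": model.T.tolist(),
        "B": model.B.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean.tolist(),
        "scaler": json.loads(model.scaler.to_json()),
    }
    Path(path).write_text(json.dumps(d))


def load_model(path) -> LatentModel:
    d = json.loads(Path(path).read_text())
    arr = lambda k: np.asarray(d[k], dtype=float)
    return LatentModel(
        algorithm=d["algorithm"],
        A=int(d["A"]),
        W=arr("W"),
        P=arr("P"),
        Q_load=arr("Q_load"),
        T=arr("T"),
        B=arr("B"),
        x_mean=arr("x_mean"),
        y_mean=arr("y_mean"),
        scaler=FittedScaler.from_json(json.dumps(d["scaler"])),
        analytes=tuple(d["analytes"]),
    )


def save_preprocess_spec(spec: PreprocessSpec, path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2))


def load_preprocess_spec(path) -> PreprocessSpec:
    return PreprocessSpec.from_dict(json.loads(Path(path).read_text()))


def save_timecourse(tc: TimecoursePrediction, path) -> None:
    cols = {"time_s": tc.times}
    for k, name in enumerate(tc.analytes):
        cols[f"{name}_uM"] = tc.concentrations[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")
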