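"""Waveform × model × background-subtraction comparison harness.

Given a combined acquisition (interleaved pulse and triangle calibration
scans with shared known concentrations), the harness regenerates the full
comparison grid: {PLSR, PCR} × {pulse, triangle} × {background subtracted
yes/no} × component counts (default 2/3/5).  For each cell it demultiplexes
the relevant waveform's scans, optionally subtracts the mean blank
voltammogram, grid-searches the ℓ1/ℓ2/max normalization candidates by Q²Y,
fits the model, and records training R²Y and leave-one-out Q²Y.  Reports
embed the input hashes and seed so every table is regenerable by one
command.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import (
    DEFAULT_NORM_CANDIDATES,
    CalibrationSet,
    PreprocessSpec,
    fit,
    grid_search_preprocess,
    q2y_loo,
    r2y,
)
from .errors import InvalidSpecError

DEFAULT_COMPONENTS = (2, 3, 5)
MODELS = ("plsr", "pcr")
WAVEFORMS = ("pulse", "triangle")
BACKGROUNDS = (False, True)


@dataclass(frozen=True)
class ComboSpec:
    """One cell family of the comparison grid."""

    model: str
    waveform: str
    background_subtracted: bool
    components: tuple[int, ...] = DEFAULT_COMPONENTS

    def __post_init__(self) -> None:
        if self.model not in MODELS or self.waveform not in WAVEFORMS:
            raise InvalidSpecError("model must be plsr/pcr, waveform pulse/triangle")
        if not self.components or any(a < 1 for a in self.components):
            raise InvalidSpecError("components must be ≥ 1")


@dataclass
class ComboReport:
    """Metric rows (one per model/waveform/background/components cell) plus
    provenance: input hashes, seed and software version."""

    table: pd.DataFrame
    provenance: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"provenance": self.provenance,
             "rows": self.table.to_dict(orient="records")},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str) -> "ComboReport":
        d = json.loads(payload)
        return cls(pd.DataFrame(d["rows"]), d["provenance"])


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a, dtype=float).tobytes()).hexdigest()[:16]


def blank_background_subtract(cal: CalibrationSet) -> CalibrationSet:
    """Subtract the mean voltammogram of the blank (all-zero concentration)
    scans — the natural reference within a calibration run."""
    blanks = np.all(cal.Y == 0, axis=1)
    if not blanks.any():
        raise InvalidSpecError("calibration has no blank scans to use as background")
    X = cal.X - cal.X[blanks].mean(axis=0)
    return CalibrationSet(X, cal.Y, analytes=cal.analytes,
                          step_index=cal.step_index, kind=cal.kind)


def run_grid(
    calibrations: dict[str, CalibrationSet],
    components: Sequence[int] = DEFAULT_COMPONENTS,
    models: Sequence[str] = MODELS,
    backgrounds: Sequence[bool] = BACKGROUNDS,
    preprocess_candidates: Sequence[PreprocessSpec] = DEFAULT_NORM_CANDIDATES,
    seed: int = 0,
) -> ComboReport:
    """Fit every grid cell and collect R²Y / Q²Y.

    ``calibrations`` maps waveform kind (``'pulse'``/``'triangle'``) to its
    demultiplexed calibration set; a kind missing from the dict produces an
    explicit gap (NaN metrics) rather than a silent omission.  The default
    grid yields 2 × 2 × 2 × 3 = 24 metric rows.
    """
    rows = []
    for wf in WAVEFORMS:
        cal = calibrations.get(wf)
        for bg in backgrounds:
            cal_bg = None
            if cal is not None:
                cal_bg = blank_background_subtract(cal) if bg else cal
            for model_name in models:
                if cal_bg is None:
                    for A in components:
                        rows.append(
                            {"model": model_name, "waveform": wf,
                             "background_subtracted": bg, "components": A,
                             "preprocess_norm": None,
                             "r2y": np.nan, "q2y": np.nan}
                        )
                    continue
                for A in components:
                    best, _ = grid_search_preprocess(
                        cal_bg, A, preprocess_candidates, algorithm=model_name
                    )
                    m = fit(cal_bg, A, best, algorithm=model_name)
                    rows.append(
                        {
                            "model": model_name,
                            "waveform": wf,
                            "background_subtracted": bg,
                            "components": A,
                            "preprocess_norm": best.norm or best.scale_mode,
                            "r2y": r2y(m, cal_bg.X, cal_bg.Y),
                            "q2y": q2y_loo(cal_bg, A, best, model_name),
                        }
                    )
    table = pd.DataFrame(rows)
    provenance = {
        "seed": int(seed),
        "version": __version__,
        "inputs": {
            k: {"x_sha256": _hash_array(v.X), "y_sha256": _hash_array(v.Y),
                "n": int(v.n), "p": int(v.p)}
            for k, v in sorted(calibrations.items())
        },
        "components": [int(a) for a in components],
    }
    return ComboReport(table, provenance)


def render_report(report: ComboReport) -> str:
    """Human-readable pivot of the grid: one line per model/waveform/
    background combination, component counts as sub-columns per metric."""
    t = report.table
    lines = [
        f"comparison grid (seed={report.provenance['seed']}, "
        f"rpvolt {report.provenance['version']})",
        f"{'model':<6}{'waveform':<10}{'bg':<5}"
        + "".join(f"R2Y(A={a:d}) " for a in report.provenance["components"])
        + "".join(f"Q2Y(A={a:d}) " for a in report.provenance["components"]),
    ]
    for (model, wf, bg), grp in t.groupby(
        ["model", "waveform", "background_subtracted"], sort=True
    ):
        grp = grp.sort_values("components")
        vals = "".join(f"{v:>9.3f} " for v in grp["r2y"]) + "".join(
            f"{v:>9.3f} " for v in grp["q2y"]
        )
        lines.append(f"{model:<6}{wf:<10}{'Y' if bg else 'N':<5}{vals}")
    return "\n".join(lines)
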