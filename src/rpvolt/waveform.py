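"""Applied-potential waveforms for pulse and sweep voltammetry.

Three waveform families are supported:

* ``rpv`` — a multi-step rapid pulse train (the default is the four-step
  −0.4 → +0.2 → +0.8 → −0.1 V sequence, 2 ms per step, delivered at 10 Hz
  from a −0.4 V holding potential);
* ``fscv`` — a triangular fast-scan sweep (default −0.4 → +1.2 → −0.4 V at
  400 V/s, 10 Hz);
* ``combined`` — the two delivered in strict alternation, each at 5 Hz, so
  that a single acquisition interleaves pulse and triangle scans.

A waveform is digitized over its *active* window only: the quiet holding
interval between repetitions is not sampled, so at the default 125 kHz
digitization the four-step pulse yields exactly 1000 current features per
scan with step boundaries at sample indices 250/500/750.  All index ranges
in this package are 0-based and half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidSpecError

DEFAULT_SAMPLE_RATE = 125_000.0
"""Digitization rate (Hz) reproducing 1000 features over an 8-ms window."""

MAX_POTENTIAL = 2.0
"""Hardware-plausible bound on applied potentials, volts."""

RPV_STEP_POTENTIALS = (-0.4, 0.2, 0.8, -0.1)
RPV_STEP_DURATION = 0.002
RPV_HOLDING = -0.4
FSCV_START = -0.4
FSCV_APEX = 1.2
FSCV_SCAN_RATE = 400.0
REPETITION_RATE = 10.0
ALTERNATION_RATE = 5.0


@dataclass(frozen=True)
class PulseStep:
    """One constant-potential segment of a pulse waveform."""

    potential: float
    duration: float
    max_potential: float = MAX_POTENTIAL

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise InvalidSpecError(f"step duration must be > 0, got {self.duration}")
        if abs(self.potential) > self.max_potential:
            raise InvalidSpecError(
                f"|potential| = {abs(self.potential)} V exceeds bound "
                f"{self.max_potential} V"
            )


@dataclass(frozen=True)
class Sweep:
    """Linear up/down potential sweep (triangle) at a fixed scan rate."""

    start: float
    apex: float
    end: float
    scan_rate: float

    def __post_init__(self) -> None:
        if self.scan_rate <= 0:
            raise InvalidSpecError(f"scan_rate must be > 0, got {self.scan_rate}")
        if self.apex == self.start:
            raise InvalidSpecError("sweep apex must differ from start")
        for v in (self.start, self.apex, self.end):
            if abs(v) > MAX_POTENTIAL:
                raise InvalidSpecError(f"|{v}| V exceeds bound {MAX_POTENTIAL} V")

    @property
    def duration(self) -> float:
        return (abs(self.apex - self.start) + abs(self.apex - self.end)) / self.scan_rate


@dataclass
class WaveformSpec:
    """Full description of an applied waveform and its delivery schedule."""

    kind: str  # 'rpv' | 'fscv' | 'combined'
    steps: tuple[PulseStep, ...] = ()
    sweep: Sweep | None = None
    holding_potential: float = RPV_HOLDING
    repetition_rate: float = REPETITION_RATE
    sample_rate: float = DEFAULT_SAMPLE_RATE
    rpv: "WaveformSpec | None" = None
    fscv: "WaveformSpec | None" = None
    alternation_rate: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.kind not in ("rpv", "fscv", "combined"):
            raise InvalidSpecError(f"unknown waveform kind {self.kind!r}")
        if self.kind == "rpv":
            if not self.steps:
                raise InvalidSpecError("rpv waveform requires at least one step")
            if self.active_duration > 1.0 / self.repetition_rate + 1e-12:
                raise InvalidSpecError(
                    f"active duration {self.active_duration * 1e3:.3f} ms exceeds "
                    f"repetition period {1e3 / self.repetition_rate:.3f} ms"
                )
        elif self.kind == "fscv":
            if self.sweep is None:
                raise InvalidSpecError("fscv waveform requires a sweep")
            if self.sweep.duration > 1.0 / self.repetition_rate + 1e-12:
                raise InvalidSpecError(
                    f"sweep duration {self.sweep.duration:.4g} s exceeds "
                    f"repetition period {1.0 / self.repetition_rate:.4g} s"
                )
        else:  # combined
            if self.rpv is None or self.fscv is None:
                raise InvalidSpecError("combined waveform requires rpv and fscv parts")
            if self.alternation_rate is None or self.alternation_rate <= 0:
                raise InvalidSpecError("combined waveform requires alternation_rate > 0")
            slot = 1.0 / (2.0 * self.alternation_rate)
            for part in (self.rpv, self.fscv):
                if part.active_duration > slot + 1e-12:
                    raise InvalidSpecError(
                        f"{part.kind} active duration {part.active_duration:.4g} s "
                        f"exceeds alternation slot {slot:.4g} s"
                    )

    @property
    def active_duration(self) -> float:
        """Duration (s) of the digitized window of one scan."""
        if self.kind == "rpv":
            return float(sum(s.duration for s in self.steps))
        if self.kind == "fscv":
            assert self.sweep is not None
            return self.sweep.duration
        assert self.rpv is not None and self.fscv is not None
        return max(self.rpv.active_duration, self.fscv.active_duration)

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "kind": self.kind,
            "holding_potential": self.holding_potential,
            "repetition_rate": self.repetition_rate,
            "sample_rate": self.sample_rate,
        }
        if self.kind == "rpv":
            d["steps"] = [
                {"potential": s.potential, "duration": s.duration} for s in self.steps
            ]
        elif self.kind == "fscv":
            assert self.sweep is not None
            d["sweep"] = {
                "start": self.sweep.start,
                "apex": self.sweep.apex,
                "end": self.sweep.end,
                "scan_rate": self.sweep.scan_rate,
            }
        else:
            assert self.rpv is not None and self.fscv is not None
            d["rpv"] = self.rpv.to_dict()
            d["fscv"] = self.fscv.to_dict()
            d["alternation_rate"] = self.alternation_rate
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WaveformSpec":
        kind = d["kind"]
        kwargs: dict = {
            "kind": kind,
            "holding_potential": d.get("holding_potential", RPV_HOLDING),
            "repetition_rate": d.get("repetition_rate", REPETITION_RATE),
            "sample_rate": d.get("sample_rate", DEFAULT_SAMPLE_RATE),
        }
        if kind == "rpv":
            kwargs["steps"] = tuple(
                PulseStep(s["potential"], s["duration"]) for s in d["steps"]
            )
        elif kind == "fscv":
            sw = d["sweep"]
            kwargs["sweep"] = Sweep(sw["start"], sw["apex"], sw["end"], sw["scan_rate"])
        else:
            kwargs["rpv"] = cls.from_dict(d["rpv"])
            kwargs["fscv"] = cls.from_dict(d["fscv"])
            kwargs["alternation_rate"] = d["alternation_rate"]
        return cls(**kwargs)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=kw.pop("indent", 2), **kw)

    @classmethod
    def from_json(cls, s: str) -> "WaveformSpec":
        return cls.from_dict(json.loads(s))


@dataclass
class SampledWaveform:
    """A digitized waveform: per-sample time, potential and step membership.

    ``step_index`` assigns each sample to its pulse step (or, for a triangle
    sweep, to the rising leg 0 or falling leg 1); ``feature_count`` is the
    number of current samples one scan produces.
    """

    times: np.ndarray
    potentials: np.ndarray
    step_index: np.ndarray
    feature_count: int
    kind: str = "rpv"
    sample_rate: float = DEFAULT_SAMPLE_RATE
    holding_potential: float = RPV_HOLDING

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.step_index = np.asarray(self.step_index, dtype=int)
        n = self.feature_count
        if not (len(self.times) == len(self.potentials) == len(self.step_index) == n):
            raise InvalidSpecError("sampled waveform arrays must share feature_count")
        if np.any(np.diff(self.step_index) < 0):
            raise InvalidSpecError("step_index must be non-decreasing")


def build_rpv(
    step_potentials: Sequence[float] = RPV_STEP_POTENTIALS,
    step_duration: float = RPV_STEP_DURATION,
    repetition_rate: float = REPETITION_RATE,
    holding: float = RPV_HOLDING,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> WaveformSpec:
    """Build a rapid-pulse waveform spec (defaults: the four-step pulse)."""
    if len(step_potentials) < 1:
        raise InvalidSpecError("need at least one step potential")
    steps = tuple(PulseStep(float(p), float(step_duration)) for p in step_potentials)
    return WaveformSpec(
        kind="rpv",
        steps=steps,
        holding_potential=holding,
        repetition_rate=repetition_rate,
        sample_rate=sample_rate,
    )


def build_fscv(
    start: float = FSCV_START,
    apex: float = FSCV_APEX,
    scan_rate: float = FSCV_SCAN_RATE,
    repetition_rate: float = REPETITION_RATE,
    end: float | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> WaveformSpec:
    """Build a triangular sweep spec (defaults: −0.4 → +1.2 → −0.4 V, 400 V/s)."""
    sweep = Sweep(start, apex, start if end is None else end, scan_rate)
    return WaveformSpec(
        kind="fscv",
        sweep=sweep,
        holding_potential=start,
        repetition_rate=repetition_rate,
        sample_rate=sample_rate,
    )


def build_combined(
    rpv: WaveformSpec | None = None,
    fscv: WaveformSpec | None = None,
    alternation_rate: float = ALTERNATION_RATE,
) -> WaveformSpec:
    """Interleave a pulse and a triangle waveform, each delivered at
    ``alternation_rate`` scans per second (default 5 Hz, i.e. 10 scans/s
    total alternating pulse/triangle)."""
    rpv = build_rpv() if rpv is None else rpv
    fscv = build_fscv() if fscv is None else fscv
    return WaveformSpec(
        kind="combined",
        rpv=rpv,
        fscv=fscv,
        alternation_rate=alternation_rate,
        repetition_rate=2.0 * alternation_rate,
        holding_potential=rpv.holding_potential,
    )


def _integral_samples(duration: float, sample_rate: float, what: str) -> int:
    n = duration * sample_rate
    n_round = round(n)
    if abs(n - n_round) > 1e-6 * max(1.0, abs(n)) or n_round < 1:
        raise InvalidSpecError(
            f"{what}: {duration} s × {sample_rate} Hz = {n} is not a whole "
            "number of samples"
        )
    return int(n_round)


def sample(spec: WaveformSpec, sample_rate: float | None = None) -> SampledWaveform:
    """Digitize the active window of a waveform.

    Returns one sample per ADC period; the holding interval between
    repetitions is not digitized.  For a combined waveform sample its
    ``.rpv`` / ``.fscv`` parts individually.
    """
    if spec.kind == "combined":
        raise InvalidSpecError(
            "sample the .rpv and .fscv parts of a combined waveform individually"
        )
    fs = spec.sample_rate if sample_rate is None else float(sample_rate)
    dt = 1.0 / fs
    if spec.kind == "rpv":
        pots, idx = [], []
        for i, st in enumerate(spec.steps):
            n_i = _integral_samples(st.duration, fs, f"step {i}")
            pots.append(np.full(n_i, st.potential))
            idx.append(np.full(n_i, i, dtype=int))
        potentials = np.concatenate(pots)
        step_index = np.concatenate(idx)
    else:
        sw = spec.sweep
        assert sw is not None
        n_up = _integral_samples(abs(sw.apex - sw.start) / sw.scan_rate, fs, "up leg")
        n_down = _integral_samples(abs(sw.apex - sw.end) / sw.scan_rate, fs, "down leg")
        sgn_up = 1.0 if sw.apex > sw.start else -1.0
        sgn_down = 1.0 if sw.end > sw.apex else -1.0
        up = sw.start + sgn_up * sw.scan_rate * dt * np.arange(n_up)
        down = sw.apex + sgn_down * sw.scan_rate * dt * np.arange(n_down)
        potentials = np.concatenate([up, down])
        step_index = np.concatenate(
            [np.zeros(n_up, dtype=int), np.ones(n_down, dtype=int)]
        )
    n = len(potentials)
    return SampledWaveform(
        times=np.arange(n) * dt,
        potentials=potentials,
        step_index=step_index,
        feature_count=n,
        kind="pulse" if spec.kind == "rpv" else "triangle",
        sample_rate=fs,
        holding_potential=spec.holding_potential,
    )


def step_windows(sw: SampledWaveform) -> list[tuple[int, int]]:
    """Half-open [start, end) feature ranges, one per pulse step (or sweep leg).

    The ranges partition ``[0, feature_count)``; the conventional 1-based
    inclusive description "points 251–500" of the second pulse step maps to
    ``(250, 500)`` here.
    """
    idx = sw.step_index
    boundaries = np.flatnonzero(np.diff(idx)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [sw.feature_count]])
    return [(int(a), int(b)) for a, b in zip(starts, ends)]


def combined_schedule(
    spec: WaveformSpec, duration_s: float = 1.0
) -> list[tuple[float, str]]:
    """Per-scan (start time, kind) schedule of a combined acquisition.

    Scans strictly alternate pulse/triangle at ``2 × alternation_rate``
    scans per second, starting with a pulse scan at t = 0.
    """
    if spec.kind != "combined":
        raise InvalidSpecError("schedule is defined for combined waveforms")
    assert spec.alternation_rate is not None
    period = 1.0 / (2.0 * spec.alternation_rate)
    n = int(round(duration_s / period))
    return [(k * period, "pulse" if k % 2 == 0 else "triangle") for k in range(n)]
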