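"""Synthetic voltammogram generator with known ground truth.

Real pulse-voltammetry recordings superimpose several current sources; the
simulator reproduces each with a deliberately minimal, parametric model so
that every downstream stage (preprocessing, PLSR/PCR calibration, VIP
diagnostics, time-course quantification, the comparison harness) can be
exercised against known concentrations:

* **Faradaic current** — per analyte, a sigmoidal activation above the
  oxidation potential (mirrored reduction term below the reduction
  potential), multiplied by a Cottrell-like ``t^(−1/2)`` decay within each
  potential step and an adsorption-limited onset, strictly linear in
  concentration.
* **Capacitive (double-layer) current** — an RC charging transient
  ``(ΔE/R)·exp(−t/RC)`` at every potential transition, superposed
  recursively so triangle sweeps produce the familiar steady ``C·dE/dt``
  envelope.  The effective capacitance grows weakly with total analyte
  concentration, so *non-faradaic* regions of the scan carry analyte
  information — the premise a non-background-subtracted model exploits.
* **Drift** — a deterministic linear ramp plus a seeded random walk per
  scan, added as an offset, so models that skip background subtraction must
  learn around slow baseline movement.
* **White noise** — i.i.d. Gaussian current noise per sample.

All randomness flows from explicit integer seeds; identical seeds give
identical recordings on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chemometrics import CalibrationSet
from .errors import InvalidSpecError
from .waveform import SampledWaveform, step_windows

COTTRELL_EPS = 8e-6
"""Regularization of the Cottrell decay, fixed at one 125-kHz sample period (s)."""


@dataclass(frozen=True)
class AnalyteParams:
    """Electrochemical response of one analyte.

    ``e_ox``/``e_red`` are the half-activation potentials of the sigmoidal
    oxidation/reduction terms (V); ``slope`` their width (V); ``gain`` the
    faradaic sensitivity (nA·μM⁻¹); ``tau_ads`` the adsorption onset time
    constant (s); ``decay_exponent`` the Cottrell-like decay power.
    """

    name: str
    e_ox: float
    e_red: float
    slope: float = 0.05
    gain: float = 20.0
    tau_ads: float = 5e-4
    decay_exponent: float = 0.5

    def __post_init__(self) -> None:
        if self.gain < 0 or self.slope <= 0 or self.tau_ads <= 0:
            raise InvalidSpecError("require gain ≥ 0, slope > 0, tau_ads > 0")


def default_analytes() -> tuple[AnalyteParams, AnalyteParams]:
    """Dopamine and serotonin parameter sets.

    The oxidation potentials (+0.2 V DA, +0.35 V 5-HT vs Ag/AgCl) and gains
    are modeling choices giving overlapping but distinguishable responses on
    the four-step pulse.  Serotonin adsorbs far more strongly than dopamine,
    so it gets a slower adsorption onset and a shallower within-step decay —
    the temporal contrast a pulse waveform is designed to exploit.
    """
    return (
        AnalyteParams("DA", e_ox=0.20, e_red=-0.20, gain=60.0,
                      tau_ads=1.0e-3, decay_exponent=0.5),
        AnalyteParams("5-HT", e_ox=0.35, e_red=0.00, gain=48.0,
                      tau_ads=3.0e-3, decay_exponent=0.3),
    )


@dataclass(frozen=True)
class ElectrodeParams:
    """Interface / circuit parameters of the working electrode.

    ``r_solution`` (Ω) and ``c_dl`` (F) set the capacitive charging time
    constant (defaults give RC = 100 μs, i.e. the step transient decays
    within the first ~12 % of a 2-ms step).  ``c_dl_conc_coupling``
    (F·μM⁻¹) makes the double layer weakly concentration dependent — a
    scalar couples to the total concentration, a per-analyte sequence
    weights each analyte separately (adsorption-prone serotonin perturbs
    the double layer more than dopamine, so the default couples 5-HT four
    times as strongly; this is what makes non-faradaic scan regions carry
    analyte-specific information).  ``drift_rate`` (nA·s⁻¹) and
    ``drift_walk_sd`` (nA per √scan) shape the slow baseline drift.
    """

    r_solution: float = 1.0e5
    c_dl: float = 1.0e-9
    c_dl_conc_coupling: float | tuple[float, ...] = (2.5e-13, 1.0e-12)
    drift_rate: float = 2.0e-4
    drift_walk_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.r_solution <= 0 or self.c_dl <= 0:
            raise InvalidSpecError("require r_solution > 0 and c_dl > 0")

    def c_eff(self, concentrations: Sequence[float] = ()) -> float:
        c = np.asarray(concentrations, dtype=float)
        k = self.c_dl_conc_coupling
        if np.isscalar(k) or isinstance(k, float):
            return self.c_dl + float(k) * float(c.sum())
        k = np.asarray(k, dtype=float)
        if c.size == 0:
            return self.c_dl
        if c.size != k.size:
            raise InvalidSpecError(
                "per-analyte capacitance coupling needs one weight per analyte"
            )
        return self.c_dl + float(k @ c)


@dataclass(frozen=True)
class NoiseParams:
    white_sd: float = 1.0  # nA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd < 0:
            raise InvalidSpecError("white_sd must be ≥ 0")


@dataclass(frozen=True)
class SessionSpec:
    """A recording session: basal levels plus stimulation-evoked transients.

    ``stim_amplitudes`` holds one (DA, 5-HT) amplitude pair (μM) per onset;
    a single pair is broadcast to all onsets.  Transients rise with
    ``rise_tau`` and clear with ``clearance_tau`` (s) as a peak-normalized
    difference of exponentials; overlapping transients superpose.
    """

    n_scans: int
    scan_rate: float = 5.0
    basal: tuple[float, float] = (0.5, 0.25)
    stim_onsets: tuple[int, ...] = ()
    stim_amplitudes: tuple[tuple[float, float], ...] = ()
    rise_tau: float = 2.0
    clearance_tau: float = 15.0

    def __post_init__(self) -> None:
        if self.n_scans < 1 or self.scan_rate <= 0:
            raise InvalidSpecError("need n_scans ≥ 1 and scan_rate > 0")
        if not self.rise_tau < self.clearance_tau:
            raise InvalidSpecError("require rise_tau < clearance_tau")
        for o in self.stim_onsets:
            if not 0 <= o < self.n_scans:
                raise InvalidSpecError(f"stimulation onset {o} outside [0, n_scans)")
        if self.stim_onsets:
            amps = self.stim_amplitudes
            if len(amps) not in (1, len(self.stim_onsets)):
                raise InvalidSpecError(
                    "stim_amplitudes must hold one pair or one per onset"
                )

    def amplitudes(self) -> tuple[tuple[float, float], ...]:
        if not self.stim_onsets:
            return ()
        if len(self.stim_amplitudes) == 1:
            return self.stim_amplitudes * len(self.stim_onsets)
        return self.stim_amplitudes


@dataclass(frozen=True)
class CalibrationDesign:
    """Known (DA, 5-HT) standards, replicated and presented in seeded
    pseudo-random order."""

    pairs: tuple[tuple[float, float], ...]
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise InvalidSpecError("design needs at least one concentration pair")
        if self.replicates < 1:
            raise InvalidSpecError("replicates must be ≥ 1")
        for da, ht in self.pairs:
            if da < 0 or ht < 0:
                raise InvalidSpecError("concentrations must be ≥ 0")


# Post-calibration standards: per subject, a blank before each of the three
# standards (pure DA, pure 5-HT, mixture), six scans per subject.
TABLE1_DESIGNS: dict[str, tuple[tuple[float, float], ...]] = {
    "mouse1": ((0.0, 0.0), (5.0, 0.0), (0.0, 0.0), (0.0, 4.0), (0.0, 0.0), (2.0, 2.0)),
    "mouse2": ((0.0, 0.0), (4.0, 0.0), (0.0, 0.0), (0.0, 3.0), (0.0, 0.0), (1.5, 1.5)),
    "mouse3": ((0.0, 0.0), (5.0, 0.0), (0.0, 0.0), (0.0, 5.0), (0.0, 0.0), (2.0, 2.0)),
}


def table1_design(subject: str, replicates: int = 1, seed: int = 0) -> CalibrationDesign:
    """One subject's built-in post-calibration design."""
    if subject not in TABLE1_DESIGNS:
        raise InvalidSpecError(f"unknown subject {subject!r}; have {list(TABLE1_DESIGNS)}")
    return CalibrationDesign(TABLE1_DESIGNS[subject], replicates, seed)


def table1_combined_design(seed: int = 0) -> CalibrationDesign:
    """All three subjects' designs concatenated (18 standards)."""
    pairs = sum((TABLE1_DESIGNS[k] for k in sorted(TABLE1_DESIGNS)), ())
    return CalibrationDesign(pairs, replicates=1, seed=seed)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def capacitive_current(
    delta_e: float,
    electrode: ElectrodeParams,
    t,
    concentrations: Sequence[float] = (),
):
    """Double-layer charging current (nA) ``(ΔE/R)·exp(−t/(R·C_eff))`` at
    time ``t`` (s) after a potential step of ``ΔE`` volts.

    ``C_eff = c_dl + c_dl_conc_coupling · Σc``; ΔE = 0 gives 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidSpecError("t must be ≥ 0")
    rc = electrode.r_solution * electrode.c_eff(concentrations)
    # ΔE/R in volts/ohm = amps; express in nA
    return (delta_e / electrode.r_solution) * 1e9 * np.exp(-t / rc)


def faradaic_current(
    potential,
    analyte: AnalyteParams,
    c: float,
    t_in_step,
    eps: float = COTTRELL_EPS,
):
    """Faradaic current (nA) of one analyte at a given potential and time
    since the enclosing potential step began.

    ``gain·c·[σ((E−e_ox)/slope) − σ((e_red−E)/slope)] · shape(t)`` with
    ``shape(t) = ((t+ε)/ε)^(−d) · (1 − exp(−t/tau_ads))`` — a Cottrell-like
    decay, ε-regularized so the decay factor is 1 at step onset, gated by an
    adsorption-limited onset.  Strictly linear in ``c``.
    """
    if c < 0:
        raise InvalidSpecError("concentration must be ≥ 0")
    E = np.asarray(potential, dtype=float)
    t = np.asarray(t_in_step, dtype=float)
    if np.any(t < 0):
        raise InvalidSpecError("t_in_step must be ≥ 0")
    ox = _sigmoid((E - analyte.e_ox) / analyte.slope)
    red = _sigmoid((analyte.e_red - E) / analyte.slope)
    shape = ((t + eps) / eps) ** (-analyte.decay_exponent) * (
        1.0 - np.exp(-t / analyte.tau_ads)
    )
    return analyte.gain * c * (ox - red) * shape


def _step_start_times(sw: SampledWaveform) -> np.ndarray:
    """Per-sample time since the enclosing step (or sweep leg) began."""
    t0 = np.empty(sw.feature_count)
    for a, b in step_windows(sw):
        t0[a:b] = sw.times[a:b] - sw.times[a]
    return t0


def simulate_voltammogram(
    sw: SampledWaveform,
    concentrations: Sequence[float],
    electrode: ElectrodeParams | None = None,
    noise: NoiseParams | None = None,
    scan_index: int = 0,
    analytes: Sequence[AnalyteParams] | None = None,
    dt_scan: float = 0.1,
    drift_offset: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One scan's current vector (nA, length ``feature_count``).

    Sums per-analyte faradaic currents, capacitive transients from every
    potential transition (starting from the holding potential), a drift
    offset ``drift_rate·scan_index·dt_scan + drift_offset``, and white
    noise.  Deterministic given the noise seed and ``scan_index``.
    """
    electrode = electrode if electrode is not None else ElectrodeParams()
    noise = noise if noise is not None else NoiseParams()
    analytes = tuple(analytes) if analytes is not None else default_analytes()
    conc = np.asarray(concentrations, dtype=float)
    if len(conc) != len(analytes):
        raise InvalidSpecError("one concentration per analyte required")

    dt = 1.0 / sw.sample_rate
    rc = electrode.r_solution * electrode.c_eff(conc)
    # capacitive superposition: i[k] = α·i[k−1] + ΔE_k/R  (recursive RC filter)
    delta_e = np.diff(sw.potentials, prepend=sw.holding_potential)
    alpha = np.exp(-dt / rc)
    from scipy.signal import lfilter

    i_cap = lfilter([1.0], [1.0, -alpha], delta_e / electrode.r_solution * 1e9)

    t_in_step = _step_start_times(sw)
    i_far = np.zeros(sw.feature_count)
    for an, c in zip(analytes, conc):
        if c > 0:
            i_far += faradaic_current(sw.potentials, an, float(c), t_in_step)

    drift = electrode.drift_rate * scan_index * dt_scan + drift_offset
    out = i_cap + i_far + drift
    if noise.white_sd > 0:
        if rng is None:
            rng = np.random.default_rng((int(noise.seed), int(scan_index)))
        out = out + rng.normal(0.0, noise.white_sd, sw.feature_count)
    return out


def simulate_calibration(
    design: CalibrationDesign,
    sw: SampledWaveform,
    electrode: ElectrodeParams | None = None,
    noise: NoiseParams | None = None,
    analytes: Sequence[AnalyteParams] | None = None,
    interval_s: float = 60.0,
) -> CalibrationSet:
    """Simulate a calibration run: one scan per (standard × replicate),
    presented in seeded pseudo-random order with drift accumulating across
    the session."""
    electrode = electrode if electrode is not None else ElectrodeParams()
    noise = noise if noise is not None else NoiseParams()
    analytes = tuple(analytes) if analytes is not None else default_analytes()
    rng = np.random.default_rng(design.seed)
    rows = [pair for pair in design.pairs for _ in range(design.replicates)]
    order = rng.permutation(len(rows))
    Y = np.asarray([rows[i] for i in order], dtype=float)
    X = np.empty((len(rows), sw.feature_count))
    walk = 0.0
    for i in range(len(rows)):
        walk += rng.normal(0.0, electrode.drift_walk_sd)
        X[i] = simulate_voltammogram(
            sw,
            Y[i],
            electrode,
            noise,
            scan_index=i,
            analytes=analytes,
            dt_scan=interval_s,
            drift_offset=walk,
            rng=rng,
        )
    return CalibrationSet(
        X, Y, analytes=tuple(a.name for a in analytes), step_index=sw.step_index,
        kind=sw.kind,
    )


def simulate_calibration_split(
    train_design: CalibrationDesign,
    heldout_pairs: Sequence[tuple[float, float]],
    sw: SampledWaveform,
    electrode: ElectrodeParams | None = None,
    noise: NoiseParams | None = None,
    analytes: Sequence[AnalyteParams] | None = None,
    interval_s: float = 60.0,
) -> tuple[CalibrationSet, CalibrationSet]:
    """One calibration session containing training standards plus held-out
    mixtures, interleaved in the seeded pseudo-random injection order, then
    split back into (train, heldout) calibration sets.

    Interleaving mirrors how a post-calibration actually runs — every
    standard is injected in one sitting — so held-out scans share the same
    slow-drift regime as the training scans instead of extrapolating it.
    """
    heldout_pairs = tuple(tuple(p) for p in heldout_pairs)
    if not heldout_pairs:
        raise InvalidSpecError("need at least one held-out pair")
    all_pairs = train_design.pairs + heldout_pairs
    n_train = len(train_design.pairs) * train_design.replicates
    full = CalibrationDesign(all_pairs, train_design.replicates, train_design.seed)
    cal = simulate_calibration(full, sw, electrode, noise, analytes, interval_s)
    # recover the seeded injection order to tell train rows from held-out rows
    order = np.random.default_rng(full.seed).permutation(
        len(all_pairs) * full.replicates
    )
    held = order >= n_train
    mk = lambda m: CalibrationSet(
        cal.X[m], cal.Y[m], analytes=cal.analytes, step_index=cal.step_index,
        kind=cal.kind,
    )
    return mk(~held), mk(held)


def transient_shape(dt, rise_tau: float, clearance_tau: float):
    """Peak-normalized release transient: difference of exponentials,
    zero before onset, maximum 1 at
    ``t* = ln(τ_c/τ_r)·τ_rτ_c/(τ_c−τ_r)`` after onset."""
    dt = np.asarray(dt, dtype=float)
    raw = np.where(
        dt >= 0,
        np.exp(-np.maximum(dt, 0) / clearance_tau)
        - np.exp(-np.maximum(dt, 0) / rise_tau),
        0.0,
    )
    t_peak = (
        np.log(clearance_tau / rise_tau)
        * rise_tau
        * clearance_tau
        / (clearance_tau - rise_tau)
    )
    peak = np.exp(-t_peak / clearance_tau) - np.exp(-t_peak / rise_tau)
    return raw / peak


@dataclass
class SessionResult:
    """Simulated recording: voltammogram matrix plus the ground-truth
    concentration traces that generated it (never inferred)."""

    X: np.ndarray  # (n_scans, p)
    times: np.ndarray  # (n_scans,) seconds
    truth: np.ndarray  # (n_scans, n_analytes) μM
    analytes: tuple[str, ...]
    spec: SessionSpec


def session_truth(spec: SessionSpec, n_analytes: int = 2) -> np.ndarray:
    """Ground-truth concentration traces (n_scans × analytes, μM)."""
    t = np.arange(spec.n_scans) / spec.scan_rate
    traces = np.tile(np.asarray(spec.basal, dtype=float), (spec.n_scans, 1))
    for onset, amp in zip(spec.stim_onsets, spec.amplitudes()):
        shape = transient_shape(t - onset / spec.scan_rate, spec.rise_tau,
                                spec.clearance_tau)
        traces += np.outer(shape, np.asarray(amp, dtype=float))
    return traces


def simulate_session(
    spec: SessionSpec,
    sw: SampledWaveform,
    electrode: ElectrodeParams | None = None,
    noise: NoiseParams | None = None,
    analytes: Sequence[AnalyteParams] | None = None,
) -> SessionResult:
    """Simulate a full recording session scan by scan, with cumulative
    drift, returning the matrix together with its ground-truth traces."""
    electrode = electrode if electrode is not None else ElectrodeParams()
    noise = noise if noise is not None else NoiseParams()
    analytes = tuple(analytes) if analytes is not None else default_analytes()
    truth = session_truth(spec, len(analytes))
    rng = np.random.default_rng(noise.seed)
    dt_scan = 1.0 / spec.scan_rate
    X = np.empty((spec.n_scans, sw.feature_count))
    walk = 0.0
    for i in range(spec.n_scans):
        walk += rng.normal(0.0, electrode.drift_walk_sd)
        X[i] = simulate_voltammogram(
            sw,
            truth[i],
            electrode,
            noise,
            scan_index=i,
            analytes=analytes,
            dt_scan=dt_scan,
            drift_offset=walk,
            rng=rng,
        )
    return SessionResult(
        X=X,
        times=np.arange(spec.n_scans) * dt_scan,
        truth=truth,
        analytes=tuple(a.name for a in analytes),
        spec=spec,
    )


def feature_regions(
    sw: SampledWaveform,
    analytes: Sequence[AnalyteParams] | None = None,
    electrode: ElectrodeParams | None = None,
    transient_rc_factor: float = 5.0,
    activation_threshold: float = 0.5,
) -> dict[str, np.ndarray]:
    """Boolean masks splitting features into capacitive-transient-dominated
    samples (within ``transient_rc_factor × RC`` of a potential transition)
    and faradaic windows (past the transient, at potentials where some
    analyte's oxidation activation is ≥ ``activation_threshold``)."""
    analytes = tuple(analytes) if analytes is not None else default_analytes()
    electrode = electrode if electrode is not None else ElectrodeParams()
    rc = electrode.r_solution * electrode.c_dl
    horizon = transient_rc_factor * rc
    capacitive = np.zeros(sw.feature_count, dtype=bool)
    prev = sw.holding_potential
    for a, b in step_windows(sw):
        if sw.potentials[a] != prev:
            in_window = sw.times[a:b] - sw.times[a] <= horizon
            capacitive[a:b] = in_window
        prev = sw.potentials[b - 1]
    activation = np.max(
        [_sigmoid((sw.potentials - an.e_ox) / an.slope) for an in analytes], axis=0
    )
    faradaic = (~capacitive) & (activation >= activation_threshold)
    return {"capacitive": capacitive, "faradaic": faradaic,
            "other": ~(capacitive | faradaic)}
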