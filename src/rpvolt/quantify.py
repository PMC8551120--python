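"""Time-course quantification of dopamine and serotonin.

Turns a trained calibration model plus a stream of scans into per-scan
concentration traces and the summary statistics reported for stimulation
experiments: 300-scan peri-stimulation windows (150 scans either side of
onset), 100-scan basal averages, baseline-subtracted 52-point stimulation
AUCs, and two-tailed t-tests between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, stats

from .chemometrics import LatentModel, predict
from .errors import InvalidSpecError, StreamError
from .preprocess import moving_average

WINDOW_PRE_SCANS = 150
WINDOW_POST_SCANS = 150
BASAL_SCANS = 100
AUC_POINTS = 52


@dataclass
class ScanStream:
    """A sequence of scans with timestamps, waveform-kind labels and event
    markers (stimulation onsets as scan indices, optional drug time in s)."""

    X: np.ndarray
    times: np.ndarray
    kinds: np.ndarray | None = None  # 'pulse' / 'triangle' per scan
    stim_onsets: tuple[int, ...] = ()
    drug_time: float | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.X.ndim != 2 or len(self.times) != self.X.shape[0]:
            raise InvalidSpecError("X must be (scans × features) aligned with times")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidSpecError("timestamps must be strictly increasing")
        if self.kinds is not None:
            self.kinds = np.asarray(self.kinds)
            if len(self.kinds) != self.X.shape[0]:
                raise InvalidSpecError("one kind label per scan required")

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]


@dataclass
class TimecoursePrediction:
    """Per-scan predicted concentrations (μM), optionally smoothed."""

    times: np.ndarray
    concentrations: np.ndarray  # (n_scans, m)
    analytes: tuple[str, ...]
    smoothing_window: int = 1
    stim_onsets: tuple[int, ...] = ()

    @property
    def n_scans(self) -> int:
        return self.concentrations.shape[0]


@dataclass
class StimSummary:
    """Basal levels and per-stimulation AUCs for one time course."""

    analytes: tuple[str, ...]
    basal: np.ndarray  # (m,) μM
    auc: np.ndarray  # (n_stims, m) μM·s
    basal_scans: int
    auc_points: int
    onsets: tuple[int, ...]


def demultiplex(stream: ScanStream, kind: str) -> ScanStream:
    """Extract the sub-stream of one waveform kind, timestamps preserved.

    Stimulation-onset indices are re-expressed in the sub-stream (the first
    retained scan at or after each original onset)."""
    if stream.kinds is None:
        raise StreamError("stream carries no kind labels to demultiplex")
    mask = stream.kinds == kind
    if not mask.any():
        raise StreamError(f"stream contains no scans of kind {kind!r}")
    keep = np.flatnonzero(mask)
    onsets = tuple(int(np.searchsorted(keep, o)) for o in stream.stim_onsets)
    return ScanStream(
        stream.X[mask],
        stream.times[mask],
        kinds=stream.kinds[mask],
        stim_onsets=onsets,
        drug_time=stream.drug_time,
    )


def extract_window(
    stream: ScanStream,
    stim_onset_scan: int,
    pre: int = WINDOW_PRE_SCANS,
    post: int = WINDOW_POST_SCANS,
) -> ScanStream:
    """Extract the peri-stimulation window: ``pre`` scans before onset and
    ``post`` scans from onset, so the default yields exactly 300 scans with
    the onset at index 150 (120 s at 5 scans/s)."""
    o = int(stim_onset_scan)
    margin_before = o
    margin_after = stream.n_scans - o
    if margin_before < pre or margin_after < post:
        raise StreamError(
            f"onset {o} needs {pre} scans before and {post} from onset; "
            f"available margins are {margin_before} and {margin_after}"
        )
    sl = slice(o - pre, o + post)
    return ScanStream(
        stream.X[sl],
        stream.times[sl],
        kinds=None if stream.kinds is None else stream.kinds[sl],
        stim_onsets=(pre,),
        drug_time=stream.drug_time,
    )


def predict_timecourse(
    model: LatentModel,
    stream: ScanStream,
    smoothing_window: int = 5,
    clip_negative: bool = False,
) -> TimecoursePrediction:
    """Predict per-scan concentrations and smooth them with a centered
    moving average (window 1 = raw predictions)."""
    if stream.kinds is not None and len(np.unique(stream.kinds)) > 1:
        raise StreamError("stream mixes waveform kinds; demultiplex first")
    Y_hat = predict(model, stream.X, clip_negative=clip_negative)
    smoothed = moving_average(Y_hat, smoothing_window)
    return TimecoursePrediction(
        times=stream.times.copy(),
        concentrations=smoothed,
        analytes=model.analytes,
        smoothing_window=smoothing_window,
        stim_onsets=stream.stim_onsets,
    )


def basal_estimate(tc: TimecoursePrediction, n_scans: int = BASAL_SCANS) -> np.ndarray:
    """Basal concentration per analyte: mean of the first ``n_scans`` scans
    (the pre-stimulation baseline)."""
    if tc.n_scans < n_scans:
        raise StreamError(f"trace has {tc.n_scans} scans; need ≥ {n_scans} for basal")
    seg = tc.concentrations[:n_scans]
    mean = seg.mean(axis=0)
    # the mean of identical values is that value; keep it exact so a flat
    # trace's baseline-subtracted AUC is exactly zero
    return np.where(np.ptp(seg, axis=0) == 0, seg[0], mean)


def stim_auc(
    tc: TimecoursePrediction,
    onset_index: int,
    n_points: int = AUC_POINTS,
    basal: np.ndarray | None = None,
) -> np.ndarray:
    """Stimulation AUC per analyte (μM·s): trapezoidal integral of the
    baseline-subtracted trace over ``n_points`` scans from onset.

    The baseline defaults to :func:`basal_estimate` of the same trace, so a
    flat trace integrates to exactly zero.
    """
    o = int(onset_index)
    if o < 0 or tc.n_scans - o < n_points:
        raise StreamError(
            f"need {n_points} scans from onset {o}; trace has {tc.n_scans - o}"
        )
    if basal is None:
        basal = basal_estimate(tc)
    seg = tc.concentrations[o : o + n_points] - basal
    t = tc.times[o : o + n_points]
    return integrate.trapezoid(seg, x=t, axis=0)


def summarize_stimulations(
    tc: TimecoursePrediction,
    onsets: tuple[int, ...] | None = None,
    basal_scans: int = BASAL_SCANS,
    auc_points: int = AUC_POINTS,
) -> StimSummary:
    """Basal average plus the per-stimulation AUC table for one trace."""
    onsets = tc.stim_onsets if onsets is None else tuple(int(o) for o in onsets)
    basal = basal_estimate(tc, basal_scans)
    auc = np.vstack([stim_auc(tc, o, auc_points, basal) for o in onsets]) if onsets \
        else np.empty((0, len(tc.analytes)))
    return StimSummary(tc.analytes, basal, auc, basal_scans, auc_points, onsets)


@dataclass
class ConditionComparison:
    """Two-sample, two-tailed t-test between conditions with group
    means ± SEM."""

    statistic: float
    pvalue: float
    mean_pre: float
    sem_pre: float
    mean_post: float
    sem_post: float
    welch: bool

    @property
    def significant(self) -> bool:
        """Conventional P < 0.05 threshold."""
        return self.pvalue < 0.05


def compare_conditions(
    values_pre, values_post, welch: bool = True
) -> ConditionComparison:
    """Two-tailed t-test (Welch by default) comparing e.g. pre- vs
    post-drug basal levels or stimulation AUCs."""
    a = np.asarray(values_pre, dtype=float)
    b = np.asarray(values_post, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidSpecError("each group needs at least 2 values")
    if np.std(a) == 0 and np.std(b) == 0:
        raise InvalidSpecError("both groups have zero variance; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return ConditionComparison(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        mean_pre=float(a.mean()),
        sem_pre=float(stats.sem(a)),
        mean_post=float(b.mean()),
        sem_post=float(stats.sem(b)),
        welch=welch,
    )
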