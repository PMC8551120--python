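"""Preprocessing transforms for voltammogram matrices.

The vocabulary is deliberately small and composable:

* optional background subtraction against the mean voltammogram of a
  reference scan window;
* mean-centering (per-feature means across scans set to zero);
* either standardization (per-feature unit variance, using training
  statistics) or normalization of each scan to unit ℓ1/ℓ2/max norm.

The transform order is fixed: background-subtract → per-scan normalization
→ center → column scaling (standardize or per-feature norms).  Per-scan
normalization precedes centering because it corrects acquisition magnitude
scan by scan; centering a scan first would leave only residuals, whose norm
depends on the analyte signal itself, and dividing by it would destroy the
linearity the calibration relies on.  All transforms are pure (inputs never
mutated) and train/apply state is kept in :class:`FittedScaler` so held-out
data is always transformed with training statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError, NotFittedError

NORMS = ("l1", "l2", "max")
SCALE_MODES = ("none", "standardize", "normalize")


@dataclass(frozen=True)
class PreprocessSpec:
    """Declarative description of a preprocessing pipeline.

    Parameters
    ----------
    background_subtract
        Subtract the mean voltammogram of ``reference_scans`` (a half-open
        scan-index range) from every scan.
    center
        Subtract per-feature training means.
    scale_mode
        ``'none'``, ``'standardize'`` (per-feature z-scoring) or
        ``'normalize'`` (rescale each scan to unit norm).
    norm
        Which norm to use when ``scale_mode == 'normalize'``.
    per_feature_normalize
        Normalize feature columns (training norms) instead of scan rows.
        Row-wise is the default reading of norm selection by grid search.
    """

    background_subtract: bool = False
    reference_scans: tuple[int, int] | None = None
    center: bool = True
    scale_mode: str = "none"
    norm: str | None = None
    per_feature_normalize: bool = False

    def __post_init__(self) -> None:
        if self.scale_mode not in SCALE_MODES:
            raise InvalidSpecError(f"scale_mode must be one of {SCALE_MODES}")
        if self.scale_mode == "normalize":
            if self.norm not in NORMS:
                raise InvalidSpecError(f"norm must be one of {NORMS} when normalizing")
        elif self.norm is not None:
            raise InvalidSpecError("norm is only meaningful with scale_mode='normalize'")
        if self.background_subtract and self.reference_scans is not None:
            lo, hi = self.reference_scans
            if hi <= lo:
                raise InvalidSpecError("reference_scans range must be non-empty")

    def to_dict(self) -> dict:
        return {
            "background_subtract": self.background_subtract,
            "reference_scans": list(self.reference_scans)
            if self.reference_scans is not None
            else None,
            "center": self.center,
            "scale_mode": self.scale_mode,
            "norm": self.norm,
            "per_feature_normalize": self.per_feature_normalize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        ref = d.get("reference_scans")
        return cls(
            background_subtract=d.get("background_subtract", False),
            reference_scans=tuple(ref) if ref is not None else None,
            center=d.get("center", True),
            scale_mode=d.get("scale_mode", "none"),
            norm=d.get("norm"),
            per_feature_normalize=d.get("per_feature_normalize", False),
        )


def background_subtract(matrix: np.ndarray, reference_scans: tuple[int, int]) -> np.ndarray:
    """Subtract the mean voltammogram of ``reference_scans`` from every scan.

    ``reference_scans`` is a 0-based half-open ``(start, stop)`` row range.
    """
    X = np.asarray(matrix, dtype=float)
    lo, hi = int(reference_scans[0]), int(reference_scans[1])
    if hi <= lo or lo < 0 or hi > X.shape[0]:
        raise InvalidSpecError(
            f"reference range [{lo}, {hi}) is empty or outside 0..{X.shape[0]}"
        )
    return X - X[lo:hi].mean(axis=0)


def _row_norms(X: np.ndarray, norm: str) -> np.ndarray:
    if norm == "l1":
        n = np.abs(X).sum(axis=1)
    elif norm == "l2":
        n = np.sqrt((X**2).sum(axis=1))
    else:  # max
        n = np.abs(X).max(axis=1)
    return np.where(n == 0, 1.0, n)


@dataclass
class FittedScaler:
    """Training-set statistics backing a :class:`PreprocessSpec`."""

    spec: PreprocessSpec
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    feature_norms: np.ndarray | None = None
    background: np.ndarray | None = None
    n_features: int = 0

    def to_json(self) -> str:
        def arr(a):
            return a.tolist() if a is not None else None

        return json.dumps(
            {
                "spec": self.spec.to_dict(),
                "means": arr(self.means),
                "sds": arr(self.sds),
                "feature_norms": arr(self.feature_norms),
                "background": arr(self.background),
                "n_features": self.n_features,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FittedScaler":
        d = json.loads(s)

        def arr(a):
            return np.asarray(a, dtype=float) if a is not None else None

        return cls(
            spec=PreprocessSpec.from_dict(d["spec"]),
            means=arr(d["means"]),
            sds=arr(d["sds"]),
            feature_norms=arr(d["feature_norms"]),
            background=arr(d["background"]),
            n_features=int(d["n_features"]),
        )


def fit_scaler(train_matrix: np.ndarray, spec: PreprocessSpec) -> FittedScaler:
    """Learn preprocessing statistics from a training matrix (scans × features)."""
    X = np.asarray(train_matrix, dtype=float)
    if X.ndim != 2:
        raise InvalidSpecError("training matrix must be 2-D (scans × features)")
    scaler = FittedScaler(spec=spec, n_features=X.shape[1])
    if spec.background_subtract:
        if spec.reference_scans is None:
            raise InvalidSpecError("background_subtract requires reference_scans")
        lo, hi = spec.reference_scans
        if hi <= lo or lo < 0 or hi > X.shape[0]:
            raise InvalidSpecError("reference_scans outside training matrix")
        scaler.background = X[lo:hi].mean(axis=0)
        X = X - scaler.background
    if spec.scale_mode == "normalize" and not spec.per_feature_normalize:
        X = X / _row_norms(X, spec.norm)[:, None]
    if spec.center:
        scaler.means = X.mean(axis=0)
        X = X - scaler.means
    if spec.scale_mode == "standardize":
        sds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        zero = sds <= 0
        if np.any(zero):
            warnings.warn(
                f"{int(zero.sum())} zero-variance feature(s) centered but not scaled",
                stacklevel=2,
            )
        scaler.sds = np.where(zero, 1.0, sds)
    elif spec.scale_mode == "normalize" and spec.per_feature_normalize:
        norms = _row_norms(X.T, spec.norm)  # column norms of X
        scaler.feature_norms = norms
    return scaler


def apply_scaler(scaler: FittedScaler, matrix: np.ndarray) -> np.ndarray:
    """Transform a matrix with previously fitted statistics."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != scaler.n_features:
        raise NotFittedError(
            f"scaler fitted for {scaler.n_features} features, got {X.shape[1]}"
        )
    spec = scaler.spec
    if spec.background_subtract and scaler.background is not None:
        X = X - scaler.background
    if spec.scale_mode == "normalize" and not spec.per_feature_normalize:
        X = X / _row_norms(X, spec.norm)[:, None]
    if spec.center and scaler.means is not None:
        X = X - scaler.means
    if spec.scale_mode == "standardize":
        X = X / scaler.sds
    elif spec.scale_mode == "normalize" and spec.per_feature_normalize:
        X = X / scaler.feature_norms
    return X


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    ``window`` must be odd so the kernel is symmetric; output length equals
    input length.  2-D input is smoothed along axis 0 (per column).
    """
    if window < 1 or window % 2 == 0:
        raise InvalidSpecError(f"window must be a positive odd integer, got {window}")
    x = np.asarray(series, dtype=float)
    if window == 1:
        return x.copy()
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    n = x.shape[0]
    half = window // 2
    cs = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    out = (cs[hi] - cs[lo]) / (hi - lo)[:, None]
    return out[:, 0] if one_d else out
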