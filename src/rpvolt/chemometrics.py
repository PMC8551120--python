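"""Latent-variable calibration models for voltammetry.

The modeling core implements PLS2 regression via NIPALS and principal
components regression (PCR), together with the diagnostics used to decide
what a model looks at and how well it generalizes:

* R²Y — fraction of concentration variance explained on training data;
* Q²Y — leave-one-out cross-validated R²Y (1 − PRESS/TSS, may be negative);
* VIP — variable importance in the projection, with the conventional
  VIP > 1 importance threshold and the Σ VIP² = p normalization;
* loadings-projection correlation shading — the per-feature magnitude of
  the projection of X loadings onto Y loadings, smoothed and bucketed into
  low/medium/high bands per analyte;
* component-count selection (elbow of the Q²Y curve) and preprocessing
  grid search over ℓ1/ℓ2/max normalization candidates.

PLS2 is fit jointly for both analytes on centered X (optionally scaled per
the preprocessing spec) and centered, never scaled, Y.  X is deflated per
component; weights are sign-fixed so the largest-magnitude entry of each
weight vector is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConvergenceError, InvalidSpecError, NotFittedError
from .preprocess import FittedScaler, PreprocessSpec, apply_scaler, fit_scaler, moving_average

DEFAULT_ANALYTE_NAMES = ("DA", "5-HT")

NIPALS_TOL = 1e-13
NIPALS_MAX_ITER = 50_000


@dataclass
class CalibrationSet:
    """Paired voltammogram matrix X (n scans × p features, nA) and known
    concentration matrix Y (n × m, μM)."""

    X: np.ndarray
    Y: np.ndarray
    analytes: tuple[str, ...] = DEFAULT_ANALYTE_NAMES
    step_index: np.ndarray | None = None
    kind: str = "pulse"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if self.X.ndim != 2 or self.X.shape[0] != self.Y.shape[0]:
            raise InvalidSpecError("X and Y must be row-aligned 2-D arrays")
        if self.X.shape[0] < 2:
            raise InvalidSpecError("calibration needs at least 2 scans")
        if np.isnan(self.X).any() or np.isnan(self.Y).any():
            raise InvalidSpecError("calibration data contains missing values")
        if len(self.analytes) != self.Y.shape[1]:
            raise InvalidSpecError("analyte names must match Y columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class LatentModel:
    """A fitted PLSR or PCR factorization plus its preprocessing state.

    Prediction contract: ``Y_hat = (scale(x) − x_mean) @ B + y_mean`` where
    ``scale`` applies the stored :class:`FittedScaler`.
    """

    algorithm: str  # 'plsr' | 'pcr'
    A: int
    W: np.ndarray  # (p, A) weights (PCR: right singular vectors)
    P: np.ndarray  # (p, A) X-loadings
    Q_load: np.ndarray  # (m, A) Y-loadings
    T: np.ndarray  # (n, A) scores
    B: np.ndarray  # (p, m) regression coefficients
    x_mean: np.ndarray
    y_mean: np.ndarray
    scaler: FittedScaler
    analytes: tuple[str, ...] = DEFAULT_ANALYTE_NAMES

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.Q_load.shape[0]


def _fix_sign(w: np.ndarray) -> float:
    """Return ±1 so that the largest-|entry| of w becomes positive."""
    j = int(np.argmax(np.abs(w)))
    return 1.0 if w[j] >= 0 else -1.0


def _nipals_pls2(
    X0: np.ndarray,
    Y0: np.ndarray,
    A: int,
    tol: float = NIPALS_TOL,
    max_iter: int = NIPALS_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS PLS2 on centered X0, Y0 with X-deflation only.

    Returns (W, P, Q, T) with W (p,A), P (p,A), Q (m,A), T (n,A).

    Convergence is measured on the successive change of the unit weight
    vector.  The inner loop is a power iteration whose rate is set by the
    ratio of the cross-covariance singular values, so the iteration cap is
    generous: near-degenerate pairs converge slowly but cheaply.
    """
    n, p = X0.shape
    m = Y0.shape[1]
    Xd = X0.copy()
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((m, A))
    T = np.zeros((n, A))
    x_scale = np.linalg.norm(X0)
    for a in range(A):
        if np.linalg.norm(Xd) <= 1e-12 * max(x_scale, 1e-300):
            raise ConvergenceError(
                f"component {a + 1}: X residual exhausted "
                f"(effective rank {a}); request fewer components"
            )
        # start from the Y column with the largest residual-covariance pull
        u = Y0[:, int(np.argmax(np.linalg.norm(Xd.T @ Y0, axis=0)))].copy()
        if np.linalg.norm(u) == 0:
            u = Y0[:, 0] + 1e-30
        w_old = np.zeros(p)
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ConvergenceError(
                    f"component {a + 1}: X residual carries no Y covariance"
                )
            w /= nw
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                raise ConvergenceError(f"component {a + 1}: degenerate scores")
            q = Y0.T @ t / tt
            u = Y0 @ q / (q @ q)
            # sign-insensitive: the dominant pair is defined up to ±1
            if min(np.linalg.norm(w - w_old), np.linalg.norm(w + w_old)) < tol:
                break
            w_old = w
        else:
            raise ConvergenceError(
                f"component {a + 1}: NIPALS did not converge in {max_iter} iterations"
            )
        s = _fix_sign(w)
        w, t, q = s * w, s * t, s * q
        tt = t @ t
        p_a = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p_a)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q, t
    return W, P, Q, T


def _check_components(A: int, n: int, p: int) -> None:
    if A < 1:
        raise InvalidSpecError("component count must be ≥ 1")
    if A > min(n - 1, p):
        raise InvalidSpecError(
            f"A={A} exceeds min(n−1, p) = {min(n - 1, p)} for n={n}, p={p}"
        )


def _preprocessed(cal: CalibrationSet, preprocess: PreprocessSpec):
    scaler = fit_scaler(cal.X, preprocess)
    Xs = apply_scaler(scaler, cal.X)
    x_mean = Xs.mean(axis=0)
    y_mean = cal.Y.mean(axis=0)
    return scaler, Xs - x_mean, cal.Y - y_mean, x_mean, y_mean


def fit_plsr(
    cal: CalibrationSet, A: int, preprocess: PreprocessSpec | None = None
) -> LatentModel:
    """Fit a PLS2 model with ``A`` latent components.

    X is preprocessed per ``preprocess`` (default: mean-centering only) and
    then centered within the model; Y is centered only.
    """
    preprocess = preprocess if preprocess is not None else PreprocessSpec()
    _check_components(A, cal.n, cal.p)
    scaler, X0, Y0, x_mean, y_mean = _preprocessed(cal, preprocess)
    W, P, Q, T = _nipals_pls2(X0, Y0, A)
    # B = W (PᵀW)⁻¹ Qᵀ maps centered, scaled X to centered Y
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return LatentModel(
        algorithm="plsr",
        A=A,
        W=W,
        P=P,
        Q_load=Q,
        T=T,
        B=B,
        x_mean=x_mean,
        y_mean=y_mean,
        scaler=scaler,
        analytes=cal.analytes,
    )


def fit_pcr(
    cal: CalibrationSet, A: int, preprocess: PreprocessSpec | None = None
) -> LatentModel:
    """Fit principal components regression: PCA of X, then least squares of
    centered Y on the top-``A`` scores."""
    preprocess = preprocess if preprocess is not None else PreprocessSpec()
    _check_components(A, cal.n, cal.p)
    scaler, X0, Y0, x_mean, y_mean = _preprocessed(cal, preprocess)
    U, s, Vt = np.linalg.svd(X0, full_matrices=False)
    V = Vt[:A].T.copy()
    for a in range(A):
        V[:, a] *= _fix_sign(V[:, a])
    T = X0 @ V
    coef, *_ = np.linalg.lstsq(T, Y0, rcond=None)  # (A, m)
    B = V @ coef
    return LatentModel(
        algorithm="pcr",
        A=A,
        W=V,
        P=V,
        Q_load=coef.T,
        T=T,
        B=B,
        x_mean=x_mean,
        y_mean=y_mean,
        scaler=scaler,
        analytes=cal.analytes,
    )


def fit(
    cal: CalibrationSet,
    A: int,
    preprocess: PreprocessSpec | None = None,
    algorithm: str = "plsr",
) -> LatentModel:
    if algorithm == "plsr":
        return fit_plsr(cal, A, preprocess)
    if algorithm == "pcr":
        return fit_pcr(cal, A, preprocess)
    raise InvalidSpecError(f"unknown algorithm {algorithm!r}")


def predict(model: LatentModel, X_new: np.ndarray, clip_negative: bool = False) -> np.ndarray:
    """Predict concentrations (μM) for new scans.

    Predictions may be negative; pass ``clip_negative=True`` to floor at 0.
    """
    X = np.asarray(X_new, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[None, :]
    if X.shape[1] != model.p:
        raise NotFittedError(
            f"model expects {model.p} features, got {X.shape[1]}"
        )
    Xs = apply_scaler(model.scaler, X)
    Y_hat = (Xs - model.x_mean) @ model.B + model.y_mean
    if clip_negative:
        Y_hat = np.maximum(Y_hat, 0.0)
    return Y_hat[0] if squeeze else Y_hat


def r2y(model: LatentModel, X: np.ndarray, Y: np.ndarray) -> float:
    """R²Y = 1 − Σ‖Y − Ŷ‖² / Σ‖Y − Ȳ‖², pooled over analytes."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Y_hat = predict(model, X)
    ss_res = float(np.sum((Y - Y_hat) ** 2))
    ss_tot = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    if ss_tot == 0:
        raise InvalidSpecError("Y has no variance; R²Y undefined")
    return 1.0 - ss_res / ss_tot


def q2y_loo(
    cal: CalibrationSet,
    A: int,
    preprocess: PreprocessSpec | None = None,
    algorithm: str = "plsr",
    groups: Sequence | None = None,
) -> float:
    """Leave-one-out cross-validated R²Y (Q²Y = 1 − PRESS/TSS).

    Each fold drops one scan (or one group, if ``groups`` labels are given),
    refits the preprocessing scaler and the model on the remainder, and
    predicts the held-out scans.  TSS uses the full-data Y mean.  Q²Y may be
    negative when the model predicts worse than the mean.
    """
    if cal.n < 3:
        raise InvalidSpecError("leave-one-out needs at least 3 scans")
    if groups is None:
        fold_masks = [np.arange(cal.n) == i for i in range(cal.n)]
    else:
        groups = np.asarray(groups)
        fold_masks = [groups == g for g in pd.unique(groups)]
    n_min = min(int((~m).sum()) for m in fold_masks)
    if A > min(n_min - 1, cal.p):
        raise InvalidSpecError(
            f"A={A} leaves rank-deficient folds (smallest fold keeps {n_min} scans)"
        )
    press = 0.0
    for mask in fold_masks:
        sub = CalibrationSet(
            cal.X[~mask], cal.Y[~mask], analytes=cal.analytes, kind=cal.kind
        )
        m = fit(sub, A, preprocess, algorithm)
        press += float(np.sum((cal.Y[mask] - predict(m, cal.X[mask])) ** 2))
    tss = float(np.sum((cal.Y - cal.Y.mean(axis=0)) ** 2))
    return 1.0 - press / tss


@dataclass
class FitMetrics:
    """R²Y and Q²Y per candidate component count."""

    components: tuple[int, ...]
    r2y: tuple[float, ...]
    q2y: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"components": self.components, "r2y": self.r2y, "q2y": self.q2y}
        )


def compute_metrics(
    cal: CalibrationSet,
    components: Sequence[int],
    preprocess: PreprocessSpec | None = None,
    algorithm: str = "plsr",
) -> FitMetrics:
    """Fit at each candidate component count and collect R²Y / Q²Y (LOO)."""
    r2, q2 = [], []
    for A in components:
        m = fit(cal, A, preprocess, algorithm)
        r2.append(r2y(m, cal.X, cal.Y))
        q2.append(q2y_loo(cal, A, preprocess, algorithm))
    return FitMetrics(tuple(components), tuple(r2), tuple(q2))


@dataclass
class VIPProfile:
    """Per-feature variable importance in the projection."""

    vip: np.ndarray
    important_mask: np.ndarray
    n_important: int
    threshold: float = 1.0


def vip(model: LatentModel, threshold: float = 1.0) -> VIPProfile:
    """VIP scores of a fitted PLSR model.

    ``VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`` with
    ``SSY_a = ‖q_a‖² t_aᵀt_a`` (the standard multivariate-Y generalization).
    Scores satisfy mean(VIP²) = 1; features with VIP > 1 are conventionally
    called important.
    """
    if model.algorithm != "plsr":
        raise NotFittedError("VIP is defined for PLSR models only")
    W, Q, T = model.W, model.Q_load, model.T
    p = model.p
    ssy = np.einsum("ma,ma->a", Q, Q) * np.einsum("na,na->a", T, T)  # (A,)
    wnorm2 = (W**2).sum(axis=0)
    wnorm2 = np.where(wnorm2 == 0, 1.0, wnorm2)
    vip2 = p * (W**2 / wnorm2) @ ssy / ssy.sum()
    scores = np.sqrt(vip2)
    mask = scores > threshold
    return VIPProfile(scores, mask, int(mask.sum()), threshold)


@dataclass
class CorrelationShading:
    """Per-feature magnitude of the X-loading → Y-loading projection,
    smoothed and bucketed into low/medium/high bands per analyte.

    ``category`` holds 0 (low / no shading), 1 (medium / 50%) or
    2 (high / 100%); sign is discarded throughout.
    """

    raw: np.ndarray  # (p, m)
    smoothed: np.ndarray  # (p, m)
    category: np.ndarray  # (p, m) ints in {0,1,2}
    analytes: tuple[str, ...]
    smoothing_window: int
    thresholds: tuple[float, float]


def loadings_correlation(
    model: LatentModel,
    smoothing_window: int = 25,
    thresholds: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
) -> CorrelationShading:
    """Project X loadings onto Y loadings per analyte and bucket features.

    ``raw_jk = |Σ_a P_ja Q_ka|`` is smoothed with a centered moving average
    and each feature is assigned low/medium/high at fractions ``thresholds``
    of the per-analyte maximum of the smoothed profile, so the bands are
    invariant to the units of Y.
    """
    if model.A < 1:
        raise NotFittedError("model has no components")
    lo, hi = thresholds
    if not (0 <= lo < hi <= 1):
        raise InvalidSpecError("thresholds must satisfy 0 ≤ lo < hi ≤ 1")
    raw = np.abs(model.P @ model.Q_load.T)  # (p, m)
    smoothed = moving_average(raw, smoothing_window)
    peak = smoothed.max(axis=0)
    peak = np.where(peak == 0, 1.0, peak)
    frac = smoothed / peak
    category = np.where(frac >= hi, 2, np.where(frac >= lo, 1, 0))
    return CorrelationShading(
        raw, smoothed, category, model.analytes, smoothing_window, thresholds
    )


def select_components(
    metrics: FitMetrics, strategy: str = "elbow", fixed: int | None = None
) -> int:
    """Choose a component count from a Q²Y curve.

    ``elbow`` returns the smallest listed count maximizing the drop in
    marginal Q²Y gain (the first listed count serves as baseline); if the
    gains are flat no elbow exists and the largest count is returned with a
    warning.  ``max_q2y`` returns the count with the highest Q²Y; ``fixed``
    returns the user's value (logged — deliberately trading cross-validation
    score for a simpler model is a legitimate choice).
    """
    import warnings

    comps = metrics.components
    q2 = np.asarray(metrics.q2y, dtype=float)
    if strategy == "fixed":
        if fixed is None or fixed not in comps:
            raise InvalidSpecError("fixed strategy requires a listed component count")
        warnings.warn(f"component count fixed at {fixed} by user choice", stacklevel=2)
        return int(fixed)
    if strategy == "max_q2y":
        return int(comps[int(np.argmax(q2))])
    if strategy != "elbow":
        raise InvalidSpecError(f"unknown strategy {strategy!r}")
    if len(comps) < 3:
        return int(comps[int(np.argmax(q2))])
    gains = np.diff(q2)  # gain[i] belongs to comps[i+1]
    drops = gains[:-1] - gains[1:]  # drop[i] belongs to comps[i+1]
    if np.all(np.abs(drops) < 1e-12):
        warnings.warn("Q²Y gains are linear; no elbow — returning largest count",
                      stacklevel=2)
        return int(comps[-1])
    return int(comps[1 + int(np.argmax(drops))])


def grid_search_preprocess(
    cal: CalibrationSet,
    A: int,
    candidates: Sequence[PreprocessSpec],
    algorithm: str = "plsr",
) -> tuple[PreprocessSpec, pd.DataFrame]:
    """Pick the preprocessing candidate maximizing Q²Y at ``A`` components.

    Ties break toward the earlier candidate; the full audit table of
    per-candidate Q²Y is returned alongside the winner.
    """
    if not candidates:
        raise InvalidSpecError("need at least one preprocessing candidate")
    rows = []
    for i, spec in enumerate(candidates):
        q2 = q2y_loo(cal, A, spec, algorithm)
        rows.append(
            {"candidate": i, "scale_mode": spec.scale_mode, "norm": spec.norm, "q2y": q2}
        )
    table = pd.DataFrame(rows)
    best = int(table["q2y"].idxmax())  # idxmax returns the first maximizer
    return candidates[best], table


DEFAULT_NORM_CANDIDATES = tuple(
    PreprocessSpec(center=True, scale_mode="normalize", norm=n) for n in ("l1", "l2", "max")
)
"""The ℓ1/ℓ2/max normalization grid conventionally searched over."""
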