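"""Independent reference implementations used only as test oracles.

These deliberately take different computational routes from the package
(SVD instead of NIPALS power iteration, explicit loops instead of
vectorized identities) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def svd_pls2_coefficients(X0: np.ndarray, Y0: np.ndarray, A: int) -> np.ndarray:
    """PLS2 regression coefficients via SVD of the cross-covariance.

    Each component's weight vector is the dominant left singular vector of
    ``Xdᵀ Y`` (the fixed point NIPALS iterates toward); X is deflated by
    the rank-one score/loading update.  Returns B (p × m) mapping centered
    X to centered Y.
    """
    Xd = X0.copy().astype(float)
    p, m = X0.shape[1], Y0.shape[1]
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    Q = np.zeros((m, A))
    for a in range(A):
        U, s, Vt = np.linalg.svd(Xd.T @ Y0, full_matrices=False)
        w = U[:, 0]
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xd @ w
        tt = t @ t
        P[:, a] = Xd.T @ t / tt
        Q[:, a] = Y0.T @ t / tt
        W[:, a] = w
        Xd = Xd - np.outer(t, P[:, a])
    return W @ np.linalg.solve(P.T @ W, Q.T)


def vip_by_loops(W: np.ndarray, Q: np.ndarray, T: np.ndarray) -> np.ndarray:
    """VIP scores computed feature by feature with explicit summations."""
    p, A = W.shape
    ssy = [float(Q[:, a] @ Q[:, a]) * float(T[:, a] @ T[:, a]) for a in range(A)]
    total = sum(ssy)
    out = np.empty(p)
    for j in range(p):
        acc = 0.0
        for a in range(A):
            wnorm2 = float(W[:, a] @ W[:, a])
            acc += ssy[a] * (W[j, a] ** 2 / wnorm2)
        out[j] = np.sqrt(p * acc / total)
    return out


def pca_scores_eig(X0: np.ndarray, A: int) -> np.ndarray:
    """PCA scores from the eigendecomposition of the covariance matrix,
    sign-fixed the same way as the package (largest |loading| positive)."""
    C = X0.T @ X0
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    V = vecs[:, order[:A]].copy()
    for a in range(A):
        j = int(np.argmax(np.abs(V[:, a])))
        if V[j, a] < 0:
            V[:, a] = -V[:, a]
    return X0 @ V


def welch_t(a, b) -> tuple[float, float]:
    """Welch's t statistic and degrees of freedom from the textbook formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df
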