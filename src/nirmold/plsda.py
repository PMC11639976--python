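"""NIPALS PLS1 discriminant analysis, VIP scores, and PCA diagnostics.

PLS-DA here is the standard two-class reduction: regress a 0/1 dummy response
(1 = mold-damaged) on the mean-centred spectra with PLS1, then threshold the
predicted response at 0.5.  Per component ``a`` NIPALS computes

    w_a = X_a' y / ||X_a' y||        (unit-norm weight)
    t_a = X_a w_a                    (score)
    p_a = X_a' t_a / (t_a' t_a)      (x-loading)
    q_a = y' t_a / (t_a' t_a)        (y-loading)
    X_{a+1} = X_a - t_a p_a'         (deflation; y is not deflated)

and the regression vector is b = W (P'W)^{-1} q, with intercept
``y_mean - x_mean' b``.  Scores are orthogonal (T'T diagonal) and weights
unit-norm by construction; both are asserted by the test suite.

VIP (variable importance in projection) for variable j:

    VIP_j = sqrt( p * Σ_a SSY_a (w_ja / ||w_a||)^2 / Σ_a SSY_a ),
    SSY_a = q_a^2 (t_a' t_a)

so that Σ_j VIP_j^2 = p; wavelengths with VIP > 1 contribute more than
average.  PCA (SVD on centred data) is provided as the unsupervised
diagnostic only — no class decision is derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLSDAModel",
    "fit_plsda",
    "predict_scores",
    "predict_classes",
    "vip",
    "regression_coefficients",
    "pca_scores",
]


@dataclass(frozen=True)
class PLSDAModel:
    """Fitted PLS1 discriminant model (0/1 encoding, threshold 0.5)."""

    x_mean: np.ndarray  # (p,)
    y_mean: float
    W: np.ndarray       # (p, k) unit-norm weight columns
    P: np.ndarray       # (p, k) x-loadings
    q: np.ndarray       # (k,) y-loadings
    T: np.ndarray       # (n, k) calibration scores
    b: np.ndarray       # (p,) regression coefficients
    k: int
    class_threshold: float = 0.5

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.b)


def _nipals(Xc: np.ndarray, yc: np.ndarray, k: int):
    """Run k NIPALS PLS1 components on centred data; raises on rank exhaustion."""
    n, p = Xc.shape
    W = np.empty((p, k))
    P = np.empty((p, k))
    T = np.empty((n, k))
    q = np.empty(k)
    X_defl = Xc.copy()
    for a in range(k):
        w = X_defl.T @ yc
        norm = np.linalg.norm(w)
        if norm <= 1e-12 * max(1.0, np.abs(yc).sum()):
            raise np.linalg.LinAlgError(
                f"rank exhausted: zero-norm weight at component {a + 1} of {k}"
            )
        w /= norm
        t = X_defl @ w
        tt = t @ t
        if tt <= 0:
            raise np.linalg.LinAlgError(
                f"rank exhausted: zero-variance score at component {a + 1} of {k}"
            )
        W[:, a] = w
        T[:, a] = t
        P[:, a] = X_defl.T @ t / tt
        q[a] = yc @ t / tt
        X_defl -= np.outer(t, P[:, a])
    return W, P, q, T


def coefficients_from_components(W, P, q) -> np.ndarray:
    """b = W (P'W)^{-1} q for the leading components of a NIPALS fit."""
    return W @ np.linalg.solve(P.T @ W, q)


def fit_plsda(X_cal, y_cal, k: int) -> PLSDAModel:
    """Fit a k-component PLS1 discriminant model on calibration data.

    Requires both classes present and ``k <= min(n - 1, p)``; raises
    ``numpy.linalg.LinAlgError`` naming the attained component if the data
    rank is exhausted earlier.
    """
    X = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y = np.asarray(y_cal, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"y has length {y.size}, expected {n}")
    if np.unique(y).size < 2:
        raise ValueError("calibration labels contain a single class")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} outside the feasible range 1..{min(n - 1, p)}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals(X - x_mean, y - y_mean, k)
    b = coefficients_from_components(W, P, q)
    return PLSDAModel(x_mean=x_mean, y_mean=y_mean, W=W, P=P, q=q, T=T, b=b, k=k)


def predict_scores(model: PLSDAModel, X) -> np.ndarray:
    """Continuous response scores: (x - x_mean)' b + y_mean, one per row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"dimension mismatch: model expects {model.x_mean.size} wavelengths, "
            f"got {X.shape[1]}"
        )
    return (X - model.x_mean) @ model.b + model.y_mean


def predict_classes(model: PLSDAModel, X, return_tie_count: bool = False):
    """Threshold the response scores at ``class_threshold``.

    Scores strictly above the threshold are class 1 (mold-damaged); scores
    exactly on the threshold go to class 0 and are counted as ties, returned
    when ``return_tie_count`` is set.
    """
    scores = predict_scores(model, X)
    classes = (scores > model.class_threshold).astype(int)
    if return_tie_count:
        return classes, int(np.sum(scores == model.class_threshold))
    return classes


def vip(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection; Σ_j VIP_j² = p by construction."""
    tt = np.einsum("ij,ij->j", model.T, model.T)
    ssy = model.q**2 * tt
    total = ssy.sum()
    if total <= 0:
        raise ValueError("degenerate fit: zero explained response variance")
    wnorm2 = model.W**2 / np.sum(model.W**2, axis=0)
    p = model.W.shape[0]
    return np.sqrt(p * (wnorm2 @ ssy) / total)


def regression_coefficients(model: PLSDAModel) -> tuple[np.ndarray, float]:
    """The regression vector b and its intercept."""
    return model.b.copy(), model.intercept


def pca_scores(X, n_components: int) -> np.ndarray:
    """Column-centred SVD scores, variance-ordered, deterministic sign.

    Sign convention: per component, the largest-magnitude loading element is
    made positive.  Used only as the unsupervised diagnostic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} outside the feasible range "
            f"1..{min(n - 1, p)}"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for a in range(n_components):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] = -Vt[a]
            U[:, a] = -U[:, a]
    return U[:, :n_components] * s[:n_components]
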