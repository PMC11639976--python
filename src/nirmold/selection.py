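"""Wavelength selection: randomization test (RT), CARS, and MCUVE.

All three selectors operate on calibration data only and return a
:class:`SelectionResult` carrying the selected wavelength indices plus a
per-variable score vector:

* **RT** — permutation significance of each PLS regression coefficient.
  The observed |b_j| at the chosen latent count is compared with its
  distribution over label-permutation refits; the add-one p-value
  ``p_j = (1 + #{|b_perm| >= |b_obs|}) / (n_perm + 1)`` is thresholded at
  ``alpha``.  Scores are the p-values; the method may legitimately select
  nothing.
* **CARS** — competitive adaptive reweighted sampling: over N iterations the
  retained-variable count follows an exponentially decreasing function (all p
  variables at i=1 down to 2 at i=N); each iteration refits PLS-DA on a
  random sample subset (the Monte Carlo reweighting), keeps the top-ranked
  variables by |b_j| up to the enforced count, and scores the subset by
  cross-validated misclassification; the subset with minimum CV error wins
  (ties: fewer variables, then earlier iteration).  Scores are per-variable
  retention frequencies.
* **MCUVE** — Monte Carlo uninformative variable elimination: p artificial
  uniform-noise variables are appended, PLS-DA is refitted on many random
  sample subsets, and each variable's stability ``s_j = mean(b_j)/sd(b_j)``
  over runs is compared with the largest |s| attained by any noise variable;
  real variables above that cutoff survive.  Scores are |s_j|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .plsda import fit_plsda

__all__ = [
    "SelectionResult",
    "rt_select",
    "cars_select",
    "edf_retention",
    "mcuve_select",
]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one wavelength-selection run."""

    method: str
    selected_indices: np.ndarray
    scores: np.ndarray
    params: dict = field(default_factory=dict)
    chosen_k_inner: int = 1

    def __post_init__(self) -> None:
        idx = np.sort(np.asarray(self.selected_indices, dtype=int))
        object.__setattr__(self, "selected_indices", idx)
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        p = self.scores.size
        if idx.size and (idx[0] < 0 or idx[-1] >= p):
            raise ValueError("selected indices outside the variable range")

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)


def _check_two_class(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ValueError("calibration labels contain a single class")


def _feasible_k(k: int, n: int, p: int) -> int:
    return max(1, min(k, n - 1, p))


def _rt_statistic(Xc: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Normalized covariance screening statistic per response column.

    For centred spectra ``Xc`` and one or more centred response columns
    ``Y``, returns |Xc' y| / ||Xc' y|| per column — the magnitude profile of
    the first PLS weight vector.  Normalizing each profile to unit length
    makes profiles comparable across refits (a label-permuted refit that
    chases noise inflates every coefficient together; the relative profile
    is what carries the variable ranking).
    """
    W = Xc.T @ Y  # (p, m)
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    return np.abs(W) / norms


def rt_select(X_cal, y_cal, k: int, n_perm: int = 1000, alpha: float = 0.05,
              seed: int = 0) -> SelectionResult:
    """Randomization-test wavelength selection against a label-permutation null.

    The per-wavelength screening statistic is the normalized magnitude of the
    first PLS weight vector (the spectra-response covariance profile); the
    observed value is compared with its distribution over ``n_perm`` random
    label permutations and wavelengths with add-one p-value
    ``p_j = (1 + #{perm >= obs}) / (n_perm + 1)`` at most ``alpha`` are kept.
    Exchangeability of the permuted labels makes the p-values exactly valid,
    so on class-uninformative data a fraction ~``alpha`` of wavelengths is
    selected; with ``alpha < 1/(n_perm + 1)`` the selection is empty.

    ``k`` (the latent count of the surrounding model) is recorded in the
    result but does not enter the screening statistic.
    """
    X = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y = np.asarray(y_cal, dtype=float).ravel()
    _check_two_class(y)
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    n, p = X.shape
    k = _feasible_k(k, n, p)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    obs = _rt_statistic(Xc, yc[:, None])[:, 0]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(p, dtype=int)
    chunk = 128  # permutations per matmul batch
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        Y = np.empty((n, m))
        for col in range(m):
            Y[:, col] = rng.permutation(yc)
        exceed += np.sum(_rt_statistic(Xc, Y) >= obs[:, None], axis=1)
        done += m
    p_values = (1.0 + exceed) / (n_perm + 1.0)
    selected = np.flatnonzero(p_values <= alpha)
    return SelectionResult(
        method="RT",
        selected_indices=selected,
        scores=p_values,
        params={"n_perm": n_perm, "alpha": alpha, "seed": seed},
        chosen_k_inner=k,
    )


def edf_retention(p: int, N: int, i: int) -> int:
    """Exponentially decreasing retention count of CARS at iteration i.

    The fraction ``f_i = a * exp(-k i)`` is pinned by ``f_1 = 1`` and
    ``f_N = 2/p`` (all variables at the first iteration, two at the last);
    the count is ``max(2, round(f_i * p))``.
    """
    if p < 2:
        raise ValueError(f"p must be >= 2, got {p}")
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    if not 1 <= i <= N:
        raise ValueError(f"iteration i={i} outside 1..{N}")
    rate = np.log(p / 2.0) / (N - 1)
    a = np.exp(rate)
    f_i = a * np.exp(-rate * i)
    return max(2, int(round(f_i * p)))


def _cv_misclassification(X, y, k, folds, rng) -> float:
    """Misclassification rate of PLS-DA over random folds (both classes in
    every training part; bounded redraws)."""
    n = X.shape[0]
    folds = min(folds, n)
    for _ in range(100):
        perm = rng.permutation(n)
        parts = np.array_split(perm, folds)
        if all(np.unique(y[np.setdiff1d(perm, part)]).size == 2 for part in parts):
            break
    else:
        raise ValueError("could not build CV folds with both classes in training")
    wrong = 0
    for part in parts:
        train = np.setdiff1d(perm, part)
        model = fit_plsda(X[train], y[train],
                          _feasible_k(k, train.size, X.shape[1]))
        pred = ((X[part] - model.x_mean) @ model.b + model.y_mean) > 0.5
        wrong += int(np.sum(pred.astype(int) != y[part]))
    return wrong / n


def cars_select(X_cal, y_cal, k: int, n_iterations: int = 50,
                sampling_fraction: float = 0.8, cv_folds: int = 5,
                seed: int = 0) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Each iteration fits PLS-DA on a random ``sampling_fraction`` subset of
    calibration samples restricted to the retained variables and ranks the
    retained variables by |b_j|; the enforced retention schedule
    :func:`edf_retention` then keeps exactly the top ``r_i`` of them — the
    "survival of the fittest" competition, with the stochastic reweighting
    supplied by the Monte Carlo sample resampling that perturbs the ranking
    between iterations.  Every iteration's subset is scored by
    ``cv_folds``-fold misclassification on the full calibration set and the
    best subset is returned (ties: fewer variables, then earlier iteration).
    """
    X = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y = np.asarray(y_cal, dtype=float).ravel()
    _check_two_class(y)
    if n_iterations < 2:
        raise ValueError(f"n_iterations must be >= 2, got {n_iterations}")
    if not 0.0 < sampling_fraction <= 1.0:
        raise ValueError(
            f"sampling_fraction must lie in (0, 1], got {sampling_fraction}"
        )
    n, p = X.shape
    rng = np.random.default_rng(seed)
    retained = np.arange(p)
    retention_count = np.zeros(p)
    history: list[tuple[float, int, int, np.ndarray]] = []
    n_sub = max(2, int(round(sampling_fraction * n)))
    for i in range(1, n_iterations + 1):
        r_i = edf_retention(p, n_iterations, i)
        if i > 1:
            sub = rng.permutation(n)[:n_sub]
            if np.unique(y[sub]).size < 2:  # redraw once; balanced data rarely needs it
                sub = rng.permutation(n)[:n_sub]
            model = fit_plsda(X[np.ix_(sub, retained)], y[sub],
                              _feasible_k(k, n_sub, retained.size))
            weights = np.abs(model.b)
            r_i = min(r_i, retained.size)
            keep = np.argsort(weights, kind="stable")[::-1][:r_i]
            retained = np.sort(retained[keep])
        if retained.size < 2:
            raise RuntimeError("CARS retained set collapsed below 2 variables")
        retention_count[retained] += 1
        cv_err = _cv_misclassification(X[:, retained], y,
                                       _feasible_k(k, n, retained.size),
                                       cv_folds, rng)
        history.append((cv_err, retained.size, i, retained.copy()))
    best = min(history, key=lambda h: (h[0], h[1], h[2]))
    return SelectionResult(
        method="CARS",
        selected_indices=best[3],
        scores=retention_count / n_iterations,
        params={
            "n_iterations": n_iterations,
            "sampling_fraction": sampling_fraction,
            "cv_folds": cv_folds,
            "seed": seed,
            "best_cv_error": best[0],
            "best_iteration": best[2],
        },
        chosen_k_inner=k,
    )


def mcuve_select(X_cal, y_cal, k: int, n_runs: int = 500,
                 sampling_fraction: float = 0.8, seed: int = 0) -> SelectionResult:
    """Monte Carlo uninformative variable elimination with a noise cutoff.

    Appends ``p`` artificial uniform-noise variables, refits PLS-DA on
    ``n_runs`` random sample subsets, computes each variable's stability
    ``mean(b)/sd(b)`` over runs, and keeps real variables whose |stability|
    exceeds the largest |stability| among the noise variables — so no noise
    variable can ever be selected.
    """
    X = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y = np.asarray(y_cal, dtype=float).ravel()
    _check_two_class(y)
    if n_runs < 50:
        raise ValueError(f"n_runs must be >= 50, got {n_runs}")
    if not 0.0 < sampling_fraction <= 1.0:
        raise ValueError(
            f"sampling_fraction must lie in (0, 1], got {sampling_fraction}"
        )
    n, p = X.shape
    rng = np.random.default_rng(seed)
    noise = rng.uniform(size=(n, p))
    X_aug = np.hstack([X, noise])
    n_sub = max(3, int(round(sampling_fraction * n)))
    B = np.empty((n_runs, 2 * p))
    for run in range(n_runs):
        for _ in range(100):
            sub = rng.permutation(n)[:n_sub]
            if np.unique(y[sub]).size == 2:
                break
        else:
            raise ValueError("could not draw a subset with both classes")
        model = fit_plsda(X_aug[sub], y[sub], _feasible_k(k, n_sub, 2 * p))
        B[run] = model.b
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    zero_sd = sd == 0
    if np.any(zero_sd):
        warnings.warn(
            f"{int(zero_sd.sum())} variables had zero coefficient spread; "
            "stability set to +inf",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        stability = np.where(zero_sd, np.inf * np.sign(mean), mean / sd)
        stability = np.where(zero_sd & (mean == 0), np.inf, stability)
    abs_stab = np.abs(stability)
    cutoff = abs_stab[p:].max()
    selected = np.flatnonzero(abs_stab[:p] > cutoff)
    return SelectionResult(
        method="MCUVE",
        selected_indices=selected,
        scores=abs_stab[:p],
        params={
            "n_runs": n_runs,
            "sampling_fraction": sampling_fraction,
            "seed": seed,
            "cutoff": float(cutoff),
            "n_zero_sd": int(zero_sd.sum()),
        },
        chosen_k_inner=k,
    )
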