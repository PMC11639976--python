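"""Sample splitting and model-complexity selection.

Three pieces:

* Kennard–Stone (KS) maximin splitting into calibration/test sets (default
  ratio 2:1), so the calibration set spans the spectral space.
* Monte Carlo cross-validation (MCCV): repeated random holdouts used to
  estimate held-out prediction error per latent-variable count.
* The adjusted Wold's R stopping rule on the MCCV PRESS curve: stop adding
  components once the PRESS ratio of successive models exceeds a threshold
  (default 0.95, i.e. less than 5 % improvement).

KS runs on the raw (unpretreated) spectra once per dataset so that every
pretreatment branch shares the identical split, isolating the pretreatment
effect in branch comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SplitResult
from .plsda import _nipals, coefficients_from_components

__all__ = [
    "MCCVPlan",
    "LVSelectionResult",
    "kennard_stone_split",
    "mccv_splits",
    "wold_r_decision",
    "select_latent_variables",
]


@dataclass(frozen=True)
class MCCVPlan:
    """Monte Carlo cross-validation resampling plan."""

    n_iterations: int = 100
    holdout_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError(
                f"holdout_fraction must lie in (0, 1), got {self.holdout_fraction}"
            )


@dataclass(frozen=True)
class LVSelectionResult:
    """MCCV error curves over k = 1..k_max and the chosen latent count."""

    press_by_k: np.ndarray
    error_rate_by_k: np.ndarray
    chosen_k: int


def kennard_stone_split(X, calibration_fraction: float = 2.0 / 3.0) -> SplitResult:
    """Classic KS maximin selection of ``ceil(fraction * n)`` calibration rows.

    Seeds with the two mutually farthest samples (Euclidean distance), then
    repeatedly adds the sample maximizing its minimum distance to the chosen
    set; ties break to the lowest index.  The remainder is the test set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"Kennard-Stone needs at least 3 samples, got {n}")
    if not 0.0 < calibration_fraction < 1.0:
        raise ValueError(
            f"calibration_fraction must lie in (0, 1), got {calibration_fraction}"
        )
    n_cal = int(np.ceil(calibration_fraction * n))
    if n_cal < 2:
        raise ValueError(f"calibration size {n_cal} too small (need >= 2)")
    if n_cal > n - 1:
        raise ValueError(f"calibration size {n_cal} leaves no test samples")

    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, -np.inf)
    # argmax on the flattened matrix -> row-major first occurrence = lowest
    # index pair under ties
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    selected = [min(i, j), max(i, j)]
    np.fill_diagonal(d2, np.inf)
    mind = np.minimum(d2[selected[0]], d2[selected[1]])
    chosen = np.zeros(n, dtype=bool)
    chosen[selected] = True
    while len(selected) < n_cal:
        cand = np.where(chosen, -np.inf, mind)
        nxt = int(np.argmax(cand))
        selected.append(nxt)
        chosen[nxt] = True
        mind = np.minimum(mind, d2[nxt])
    cal = np.sort(np.asarray(selected))
    test = np.setdiff1d(np.arange(n), cal)
    return SplitResult(calibration_indices=cal, test_indices=test)


def mccv_splits(n: int, plan: MCCVPlan) -> list[SplitResult]:
    """Independent uniform random holdouts; reproducible from the plan seed.

    Each split holds out ``floor(holdout_fraction * n)`` samples (the split's
    ``test_indices``) and retains the rest for fitting.
    """
    n_hold = int(np.floor(plan.holdout_fraction * n))
    if n_hold < 1:
        raise ValueError(
            f"holdout of {plan.holdout_fraction} * {n} leaves nothing held out"
        )
    if n - n_hold < 2:
        raise ValueError(f"only {n - n_hold} samples retained; need >= 2")
    rng = np.random.default_rng(plan.seed)
    splits = []
    for _ in range(plan.n_iterations):
        perm = rng.permutation(n)
        splits.append(SplitResult(
            calibration_indices=np.sort(perm[n_hold:]),
            test_indices=np.sort(perm[:n_hold]),
        ))
    return splits


def wold_r_decision(press_by_k, threshold: float = 0.95) -> int:
    """Adjusted Wold's R rule on a PRESS curve indexed by k = 1..k_max.

    Scanning upward, the first k where ``press[k+1] / press[k] > threshold``
    (adding a component improves by less than ``1 - threshold``) is chosen;
    if the ratio never exceeds the threshold, k_max is returned.  Invariant
    to positive rescaling of the curve.
    """
    press = np.asarray(press_by_k, dtype=float).ravel()
    if press.size < 1:
        raise ValueError("press_by_k must be non-empty")
    if np.any(press <= 0) or not np.all(np.isfinite(press)):
        raise ValueError("press_by_k must be positive and finite")
    for k in range(press.size - 1):
        if press[k + 1] / press[k] > threshold:
            return k + 1
    return press.size


def _press_curves(X_fit, y_fit, X_out, y_out, k_max: int, threshold: float = 0.5):
    """Held-out squared error and misclassification per k = 1..k_eff.

    One incremental NIPALS pass; returns arrays padded with the last attained
    value if the data rank is exhausted before k_max.
    """
    x_mean = X_fit.mean(axis=0)
    y_mean = y_fit.mean()
    try:
        W, P, q, _ = _nipals(X_fit - x_mean, y_fit - y_mean, k_max)
        attained = k_max
    except np.linalg.LinAlgError:
        attained = 0
        for k in range(k_max - 1, 0, -1):
            try:
                W, P, q, _ = _nipals(X_fit - x_mean, y_fit - y_mean, k)
                attained = k
                break
            except np.linalg.LinAlgError:
                continue
        if attained == 0:
            raise
    Xo = X_out - x_mean
    press = np.empty(k_max)
    err = np.empty(k_max)
    for k in range(1, attained + 1):
        b = coefficients_from_components(W[:, :k], P[:, :k], q[:k])
        pred = Xo @ b + y_mean
        press[k - 1] = np.mean((y_out - pred) ** 2)
        err[k - 1] = np.mean((pred > threshold).astype(int) != y_out)
    press[attained:] = press[attained - 1]
    err[attained:] = err[attained - 1]
    return press, err


def select_latent_variables(X_cal, y_cal, k_max: int = 15,
                            plan: MCCVPlan | None = None,
                            threshold: float = 0.95) -> LVSelectionResult:
    """Choose the latent-variable count by MCCV + adjusted Wold's R.

    For every MCCV split a PLS-DA model is fitted on the retained part with
    k = 1..k_max components; held-out squared error (PRESS) and
    misclassification rate are averaged over splits and the PRESS curve is
    handed to :func:`wold_r_decision`.
    """
    X = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y = np.asarray(y_cal, dtype=float).ravel()
    n, p = X.shape
    if plan is None:
        plan = MCCVPlan()
    n_hold = int(np.floor(plan.holdout_fraction * n))
    if not 1 <= k_max <= min(n - n_hold - 1, p):
        raise ValueError(
            f"k_max={k_max} exceeds the rank bound "
            f"min(n_retained - 1, p) = {min(n - n_hold - 1, p)}"
        )
    rng = np.random.default_rng(plan.seed)
    press_sum = np.zeros(k_max)
    err_sum = np.zeros(k_max)
    n_used = 0
    for split in mccv_splits(n, plan):
        fit_idx = split.calibration_indices
        out_idx = split.test_indices
        if np.unique(y[fit_idx]).size < 2:
            # degenerate resample; redraw deterministically from the same stream
            for _ in range(100):
                perm = rng.permutation(n)
                fit_idx, out_idx = np.sort(perm[n_hold:]), np.sort(perm[:n_hold])
                if np.unique(y[fit_idx]).size == 2:
                    break
            else:
                raise ValueError("could not draw an MCCV split with both classes")
        press, err = _press_curves(X[fit_idx], y[fit_idx], X[out_idx], y[out_idx],
                                   k_max)
        press_sum += press
        err_sum += err
        n_used += 1
    press_by_k = press_sum / n_used
    error_rate_by_k = err_sum / n_used
    return LVSelectionResult(
        press_by_k=press_by_k,
        error_rate_by_k=error_rate_by_k,
        chosen_k=wold_r_decision(press_by_k, threshold),
    )
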