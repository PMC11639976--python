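"""Spectral pretreatments: de-bias, detrend, derivatives, CWT, Min-Max, MSC, SNV.

Each transform is pure and row-wise; only MSC carries fitted state (the mean
calibration spectrum), which must be estimated on the calibration set and then
applied unchanged to test and independent-test spectra — the dispatcher
:func:`apply_pretreatment` enforces that contract.

Conventions fixed for reproducibility:

* SNV uses the sample (n-1 denominator) standard deviation.
* Savitzky–Golay derivatives are expressed per nanometre (``delta`` = grid
  step); defaults are window 15 / polyorder 2 for the first derivative and
  window 21 / polyorder 3 for the second (differentiating twice amplifies
  instrument noise, so the second derivative gets the wider frame).
* The CWT is a single-scale Mexican-hat filter (default scale 10 grid steps,
  matched to the width of typical analyte bands) with symmetric-reflection
  edge padding, so the output stays a length-p vector per spectrum.
* Detrend removes a per-row least-squares polynomial (default quadratic) in
  the wavelength coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import savgol_filter

from .dataset import SpectrumSet

__all__ = [
    "PretreatmentSpec",
    "MSCReference",
    "METHODS",
    "snv",
    "de_bias",
    "detrend",
    "min_max",
    "sg_derivative",
    "cwt_transform",
    "msc_fit",
    "msc_apply",
    "apply_pretreatment",
    "pretreat_sets",
]

#: Canonical method names, in the order the branch reports use.
METHODS = ("none", "de-bias", "detrend", "1st", "2nd", "cwt", "min-max", "msc", "snv")

_ALIASES = {
    "none": "none",
    "original": "none",
    "de-bias": "de-bias",
    "debias": "de-bias",
    "detrend": "detrend",
    "dt": "detrend",
    "1st": "1st",
    "2nd": "2nd",
    "cwt": "cwt",
    "min-max": "min-max",
    "minmax": "min-max",
    "msc": "msc",
    "snv": "snv",
}

_DEFAULT_PARAMS = {
    "none": {},
    "de-bias": {},
    "detrend": {"detrend_order": 2},
    "1st": {"window": 15, "polyorder": 2},
    "2nd": {"window": 21, "polyorder": 3},
    "cwt": {"scale": 10.0},
    "min-max": {},
    "msc": {},
    "snv": {},
}


@dataclass(frozen=True)
class PretreatmentSpec:
    """A named pretreatment plus its (defaulted) parameters."""

    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        name = _ALIASES.get(str(self.method).strip().lower())
        if name is None:
            raise ValueError(
                f"unknown pretreatment method {self.method!r}; "
                f"choose from {METHODS}"
            )
        object.__setattr__(self, "method", name)
        merged = {**_DEFAULT_PARAMS[name], **dict(self.params)}
        object.__setattr__(self, "params", merged)


@dataclass(frozen=True)
class MSCReference:
    """MSC state: the mean calibration spectrum each row is regressed on."""

    reference_spectrum: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_spectrum, dtype=float).ravel()
        if ref.size == 0 or not np.all(np.isfinite(ref)):
            raise ValueError("reference spectrum must be non-empty and finite")
        object.__setattr__(self, "reference_spectrum", ref)


def _as_matrix(X) -> np.ndarray:
    return np.atleast_2d(np.asarray(X, dtype=float))


def snv(X) -> np.ndarray:
    """Standard normal variate: centre each row, scale to unit sample sd."""
    X = _as_matrix(X)
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        row = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"SNV undefined for constant row {row}")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def de_bias(X) -> np.ndarray:
    """Offset removal: subtract each row's own mean."""
    X = _as_matrix(X)
    return X - X.mean(axis=1, keepdims=True)


def detrend(X, order: int = 2, wavelengths=None) -> np.ndarray:
    """Subtract a per-row least-squares polynomial baseline of given order.

    The residual is exactly orthogonal to the polynomial basis (computed via
    an orthonormal QR basis of the Vandermonde matrix in a rescaled
    wavelength coordinate).
    """
    X = _as_matrix(X)
    p = X.shape[1]
    if order >= p:
        raise ValueError(f"detrend order {order} must be < number of points {p}")
    x = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    span = x[-1] - x[0]
    t = (x - x.mean()) / (span / 2.0 if span else 1.0)
    basis = np.vander(t, order + 1, increasing=True)
    q, _ = np.linalg.qr(basis)
    return X - (X @ q) @ q.T


def min_max(X) -> np.ndarray:
    """Map each row onto [0, 1] via (x - min) / (max - min)."""
    X = _as_matrix(X)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    if np.any(span == 0):
        row = int(np.flatnonzero(span.ravel() == 0)[0])
        raise ValueError(f"Min-Max undefined for constant row {row}")
    return (X - lo) / span


def sg_derivative(X, order: int, window: int = 15, polyorder: int | None = None,
                  delta: float = 1.0) -> np.ndarray:
    """Savitzky–Golay derivative per row, per unit of ``delta`` (nm).

    ``order`` is 1 or 2; edges are handled by the boundary polynomial fit
    (``mode='interp'``) so the output keeps length p.
    """
    X = _as_matrix(X)
    p = X.shape[1]
    if order not in (1, 2):
        raise ValueError(f"derivative order must be 1 or 2, got {order}")
    if polyorder is None:
        polyorder = _DEFAULT_PARAMS["1st" if order == 1 else "2nd"]["polyorder"]
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > p:
        raise ValueError(f"window {window} exceeds spectrum length {p}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if order > polyorder:
        raise ValueError(f"derivative order {order} must be <= polyorder {polyorder}")
    return savgol_filter(X, window_length=window, polyorder=polyorder,
                         deriv=order, delta=delta, axis=1, mode="interp")


def _mexican_hat_kernel(scale: float) -> np.ndarray:
    half = int(np.ceil(5.0 * scale))
    t = np.arange(-half, half + 1, dtype=float) / scale
    kernel = (2.0 / (np.sqrt(3.0) * np.pi**0.25)) * (1.0 - t**2) * np.exp(-t**2 / 2.0)
    kernel /= np.sqrt(scale)
    # the sampled wavelet is only approximately zero-mean; remove the residual
    # so constants map exactly to zero
    return kernel - kernel.mean()


def cwt_transform(X, scale: float = 20.0, wavelet: str = "mexican_hat") -> np.ndarray:
    """Single-scale Mexican-hat wavelet coefficients per row (length p).

    ``scale`` is in grid steps; edges use symmetric reflection.  Acts as a
    band-pass background remover: smooth baselines vanish, features near the
    wavelet scale are enhanced.
    """
    if wavelet != "mexican_hat":
        raise ValueError(f"unsupported wavelet {wavelet!r}; only 'mexican_hat'")
    if not scale >= 1.0:
        raise ValueError(f"scale must be >= 1 grid step, got {scale}")
    X = _as_matrix(X)
    kernel = _mexican_hat_kernel(float(scale))
    return convolve1d(X, kernel, axis=1, mode="reflect")


def msc_fit(X_cal) -> MSCReference:
    """Fit MSC state: reference = column-mean calibration spectrum."""
    X = _as_matrix(X_cal)
    if X.shape[0] < 1 or X.size == 0:
        raise ValueError("MSC reference requires at least one calibration spectrum")
    return MSCReference(X.mean(axis=0))


def msc_apply(X, ref: MSCReference) -> np.ndarray:
    """Correct each row by inverting its OLS fit x = a + b * reference."""
    X = _as_matrix(X)
    r = ref.reference_spectrum
    if X.shape[1] != r.size:
        raise ValueError(
            f"grid mismatch: spectra have {X.shape[1]} points, reference {r.size}"
        )
    rc = r - r.mean()
    denom = rc @ rc
    slope = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(slope) <= 1e-8):
        row = int(np.flatnonzero(np.abs(slope) <= 1e-8)[0])
        raise ValueError(
            f"MSC slope ~0 for row {row}: spectrum uncorrelated with reference"
        )
    intercept = X.mean(axis=1) - slope * r.mean()
    return (X - intercept[:, None]) / slope[:, None]


def apply_pretreatment(spec: PretreatmentSpec, X_cal, *X_more, wavelengths=None):
    """Apply one pretreatment to the calibration matrix and any further sets.

    Stateless methods act row-wise on every matrix independently; MSC is
    fitted on ``X_cal`` only and that reference corrects all matrices.

    Returns ``(matrices, state)`` where ``matrices`` is a list (calibration
    first) and ``state`` is the fitted :class:`MSCReference` or None.
    """
    spec = spec if isinstance(spec, PretreatmentSpec) else PretreatmentSpec(spec)
    matrices = [_as_matrix(X_cal)] + [_as_matrix(X) for X in X_more]
    params = spec.params
    step = 1.0
    if wavelengths is not None:
        wavelengths = np.asarray(wavelengths, dtype=float)
        if wavelengths.size >= 2:
            step = float(np.mean(np.diff(wavelengths)))

    state = None
    if spec.method == "none":
        out = [X.copy() for X in matrices]
    elif spec.method == "de-bias":
        out = [de_bias(X) for X in matrices]
    elif spec.method == "detrend":
        out = [detrend(X, order=params["detrend_order"], wavelengths=wavelengths)
               for X in matrices]
    elif spec.method in ("1st", "2nd"):
        order = 1 if spec.method == "1st" else 2
        out = [sg_derivative(X, order, window=params["window"],
                             polyorder=params["polyorder"], delta=step)
               for X in matrices]
    elif spec.method == "cwt":
        out = [cwt_transform(X, scale=params["scale"]) for X in matrices]
    elif spec.method == "min-max":
        out = [min_max(X) for X in matrices]
    elif spec.method == "msc":
        state = msc_fit(matrices[0])
        out = [msc_apply(X, state) for X in matrices]
    elif spec.method == "snv":
        out = [snv(X) for X in matrices]
    else:  # pragma: no cover - spec validation forbids this
        raise ValueError(f"unknown method {spec.method!r}")
    return out, state


def pretreat_sets(spec: PretreatmentSpec, calibration: SpectrumSet,
                  *others: SpectrumSet):
    """SpectrumSet-level wrapper around :func:`apply_pretreatment`."""
    matrices, state = apply_pretreatment(
        spec, calibration.absorbance,
        *[s.absorbance for s in others],
        wavelengths=calibration.wavelengths_nm,
    )
    sets = []
    for source, X in zip((calibration, *others), matrices):
        sets.append(SpectrumSet(
            wavelengths_nm=source.wavelengths_nm,
            absorbance=X,
            labels=source.labels,
            sample_ids=list(source.sample_ids),
            metadata={**source.metadata, "pretreatment": spec.method},
        ))
    return sets, state
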