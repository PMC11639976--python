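"""Core domain types, spectra CSV I/O, and classification metrics.

A :class:`SpectrumSet` is the universal exchange object of the toolkit: a
strictly increasing wavelength grid (nm), an ``n x p`` absorbance matrix,
optional binary class labels (1 = mold-damaged, 0 = undamaged), unique sample
ids, and free-form metadata.  Everything downstream — pretreatment, splitting,
PLS-DA, wavelength selection — consumes and produces this type.

On disk a spectrum set is a wide CSV: one row per sample, first column the
sample id, second column the label (if present), remaining columns named by
wavelength in nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "ConfusionMetrics",
    "SplitResult",
    "load_spectra",
    "save_spectra",
    "classification_metrics",
]

_ID_COLUMN = "id"
_FLOAT_FORMAT = "%.12g"


@dataclass
class SpectrumSet:
    """Wavelength grid, absorbance matrix, optional binary labels, ids, metadata.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing grid of length ``p`` in nanometres.
    absorbance
        ``n x p`` matrix of reflectance-derived absorbance values (finite).
    labels
        Optional length-``n`` vector with values in {0, 1};
        1 marks the mold-damaged (positive) class.
    sample_ids
        ``n`` unique strings; generated as ``s0000..`` if omitted.
    metadata
        Free-form key-value map (e.g. ``surface``, ``role``, generator seed).
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    labels: np.ndarray | None = None
    sample_ids: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        n, p = self.absorbance.shape
        if self.wavelengths_nm.size != p:
            raise ValueError(
                f"wavelength grid has {self.wavelengths_nm.size} points but the "
                f"absorbance matrix has {p} columns"
            )
        if p >= 2 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        if not np.all(np.isfinite(self.wavelengths_nm)):
            raise ValueError("wavelengths_nm contains non-finite values")
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise ValueError(
                f"absorbance contains a non-finite value at row {bad[0]}, "
                f"column {bad[1]}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels).ravel()
            if self.labels.size != n:
                raise ValueError(
                    f"labels has length {self.labels.size}, expected {n}"
                )
            bad_values = set(np.unique(self.labels)) - {0, 1}
            if bad_values:
                raise ValueError(
                    f"labels must be binary 0/1; found {sorted(bad_values)}"
                )
            self.labels = self.labels.astype(int)
        if self.sample_ids is None:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != n:
                raise ValueError(
                    f"sample_ids has length {len(self.sample_ids)}, expected {n}"
                )
            if len(set(self.sample_ids)) != n:
                raise ValueError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, indices: Sequence[int], **metadata) -> "SpectrumSet":
        """Row subset (samples) as a new SpectrumSet; metadata is merged."""
        idx = np.asarray(indices, dtype=int)
        return SpectrumSet(
            wavelengths_nm=self.wavelengths_nm,
            absorbance=self.absorbance[idx],
            labels=None if self.labels is None else self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            metadata={**self.metadata, **metadata},
        )

    def select_wavelengths(self, indices: Sequence[int]) -> "SpectrumSet":
        """Column subset (wavelengths) as a new SpectrumSet."""
        idx = np.sort(np.asarray(indices, dtype=int))
        return SpectrumSet(
            wavelengths_nm=self.wavelengths_nm[idx],
            absorbance=self.absorbance[:, idx],
            labels=self.labels,
            sample_ids=list(self.sample_ids),
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/test partition of a sample index range."""

    calibration_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration_indices, dtype=int)
        test = np.asarray(self.test_indices, dtype=int)
        object.__setattr__(self, "calibration_indices", cal)
        object.__setattr__(self, "test_indices", test)
        if cal.size == 0 or test.size == 0:
            raise ValueError("both calibration and test partitions must be non-empty")
        if np.intersect1d(cal, test).size:
            raise ValueError("calibration and test indices overlap")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Two-class confusion counts and rates; positive class = mold-damaged (1).

    Rates are stored as percentages in [0, 100].  A rate whose defining class
    is absent from the truth vector is NaN (undefined), never silently zero.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def classification_metrics(truth, predicted) -> ConfusionMetrics:
    """Confusion counts plus accuracy / sensitivity / specificity (percent).

    Sensitivity is the correct-classification rate of the mold-damaged class
    (label 1), specificity that of the undamaged class (label 0).  If a class
    is absent from ``truth`` its rate is NaN.
    """
    t = np.asarray(truth).ravel()
    p = np.asarray(predicted).ravel()
    if t.size == 0:
        raise ValueError("empty truth vector")
    if t.size != p.size:
        raise ValueError(f"length mismatch: truth {t.size} vs predicted {p.size}")
    for name, v in (("truth", t), ("predicted", p)):
        if set(np.unique(v)) - {0, 1}:
            raise ValueError(f"{name} must be binary 0/1")
    tp = int(np.sum((t == 1) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    sensitivity = 100.0 * tp / n_pos if n_pos else math.nan
    specificity = 100.0 * tn / n_neg if n_neg else math.nan
    accuracy = 100.0 * (tp + tn) / t.size
    return ConfusionMetrics(tp, fn, tn, fp, accuracy, sensitivity, specificity)


def save_spectra(data: SpectrumSet, path) -> None:
    """Write a SpectrumSet as a wide CSV (id, [label], one column per nm)."""
    columns: dict[str, object] = {_ID_COLUMN: data.sample_ids}
    if data.labels is not None:
        columns["label"] = data.labels
    for j, wl in enumerate(data.wavelengths_nm):
        columns[_FLOAT_FORMAT % wl] = data.absorbance[:, j]
    frame = pd.DataFrame(columns)
    frame.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def load_spectra(path, label_column: str = "label") -> SpectrumSet:
    """Read a wide spectra CSV into a validated SpectrumSet.

    Column headers other than the id column and ``label_column`` must parse as
    wavelengths in nm; columns are sorted into increasing wavelength order if
    needed.  Labels, when present, must be 0/1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectra file not found: {path}")
    frame = pd.read_csv(path)
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: no sample rows")
    sample_ids = None
    if frame.columns[0].strip().lower() in (_ID_COLUMN, "sample_id"):
        sample_ids = frame.iloc[:, 0].astype(str).tolist()
        frame = frame.iloc[:, 1:]
    labels = None
    if label_column in frame.columns:
        raw = frame[label_column]
        bad = set(pd.unique(raw)) - {0, 1}
        if bad:
            raise ValueError(
                f"label column {label_column!r} contains non-binary values: "
                f"{sorted(bad)}"
            )
        labels = raw.to_numpy(dtype=int)
        frame = frame.drop(columns=[label_column])
    wavelengths = []
    for name in frame.columns:
        try:
            wavelengths.append(float(name))
        except ValueError:
            raise ValueError(
                f"column header {name!r} does not parse as a wavelength in nm"
            ) from None
    wavelengths = np.asarray(wavelengths)
    matrix = frame.to_numpy(dtype=float)
    order = np.argsort(wavelengths, kind="stable")
    return SpectrumSet(
        wavelengths_nm=wavelengths[order],
        absorbance=matrix[:, order],
        labels=labels,
        sample_ids=sample_ids,
        metadata={"source": str(path)},
    )
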