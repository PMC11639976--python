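"""Synthetic two-class NIR spectra with known informative bands.

The generator emulates diffuse-reflectance NIR spectra of dried tangerine peel
on a 511-point grid over 890–1720 nm: smooth Gaussian absorption bands in the
C-H / O-H / N-H overtone regions, per-sample multiplicative scatter (log-normal
gain), low-order polynomial baseline drift, per-band amplitude jitter, and
additive instrument noise.  Class membership (0 = undamaged, 1 = mold-damaged)
shifts the amplitudes of the bands centred in the 1350–1490 nm O-H first
overtone region, where moisture and compositional change from mold growth
shows up.  A boolean truth mask over the grid marks the wavelengths carrying
class information, giving every selection algorithm an unambiguous target.

Model for sample ``i`` of class ``c`` at wavelength ``λ``::

    x_i(λ) = g_i * Σ_b (A_b + c·δ_b + j_ib) exp(-(λ-μ_b)²/(2 σ_b²))
             + β_i0 + β_i1 u + β_i2 u²  + ε_i(λ)

with ``u`` the wavelength rescaled to [-1, 1], ``g_i`` log-normal gain,
``j_ib`` per-band amplitude jitter, and ``ε`` i.i.d. Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import SpectrumSet

__all__ = ["BandSpec", "GeneratorConfig", "default_band_layout", "generate_dataset"]

#: Default grid matching a portable grating NIR instrument.
DEFAULT_GRID = (890.0, 1720.0, 511)

#: Informative region: class-difference bands live at 1350–1490 nm.
INFORMATIVE_REGION = (1350.0, 1490.0)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``class_delta`` is the amplitude shift applied to the mold-damaged class;
    a band is informative iff it is non-zero.
    """

    center_nm: float
    width_nm: float
    base_amplitude: float
    class_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError(f"width_nm must be positive, got {self.width_nm}")

    @property
    def informative(self) -> bool:
        return self.class_delta != 0.0


def default_band_layout() -> list[BandSpec]:
    """Five-band layout mimicking the overtone structure of peel spectra.

    Two broad inert bands sit at 1200 nm (C-H second overtone) and 1620 nm
    (C-H first overtone); three narrower bands at 1380/1430/1480 nm model the
    O-H / N-H first overtone complex whose amplitudes respond to mold damage
    (moisture and compositional change), so only they carry class information.
    """
    bands = [
        BandSpec(1200.0, 45.0, 0.45, 0.0),
        BandSpec(1380.0, 14.0, 0.20, 0.040),
        BandSpec(1430.0, 14.0, 0.22, 0.044),
        BandSpec(1480.0, 14.0, 0.18, 0.035),
        BandSpec(1620.0, 50.0, 0.40, 0.0),
    ]
    lo, hi = INFORMATIVE_REGION
    assert all(lo <= b.center_nm <= hi for b in bands if b.informative)
    return bands


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults give the high-SNR regime: classes separable by PLS-DA to ~100%
    while no single wavelength alone discriminates reliably, so wavelength
    selection has genuine work to do.  Noise scales are in absorbance units.
    """

    grid: tuple[float, float, int] = DEFAULT_GRID
    n_per_class: int = 200
    bands: list[BandSpec] = field(default_factory=default_band_layout)
    baseline_coeff_sd: tuple[float, float, float] = (0.005, 0.003, 0.002)
    gain_sd: float = 0.005
    noise_sd: float = 0.015
    amplitude_jitter_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi, n_points = self.grid
        if n_points < 2:
            raise ValueError(f"grid n_points must be >= 2, got {n_points}")
        if not hi > lo:
            raise ValueError(f"grid bounds must satisfy max > min, got {self.grid}")
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        for name in ("gain_sd", "noise_sd", "amplitude_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if any(sd < 0 for sd in self.baseline_coeff_sd):
            raise ValueError(
                f"baseline_coeff_sd entries must be >= 0, got {self.baseline_coeff_sd}"
            )

    def with_delta_scale(self, factor: float) -> "GeneratorConfig":
        """Copy with every band's class_delta scaled by ``factor``."""
        bands = [replace(b, class_delta=b.class_delta * factor) for b in self.bands]
        return replace(self, bands=bands)


def generate_dataset(config: GeneratorConfig) -> tuple[SpectrumSet, np.ndarray]:
    """Draw one dataset; returns (SpectrumSet, truth_mask).

    ``truth_mask[j]`` is True when grid point ``j`` lies within one band width
    of an informative band centre.  Labels are balanced (``n_per_class`` each,
    class 0 first).  Identical config (including seed) gives bitwise-identical
    output.
    """
    lo, hi, p = config.grid
    wavelengths = np.linspace(lo, hi, p)
    u = (wavelengths - (lo + hi) / 2.0) / ((hi - lo) / 2.0)
    rng = np.random.default_rng(config.seed)

    n = 2 * config.n_per_class
    labels = np.repeat([0, 1], config.n_per_class)
    profiles = np.stack(
        [np.exp(-((wavelengths - b.center_nm) ** 2) / (2.0 * b.width_nm**2))
         for b in config.bands]
    )  # (n_bands, p)
    base = np.array([b.base_amplitude for b in config.bands])
    delta = np.array([b.class_delta for b in config.bands])

    amplitudes = (
        base[None, :]
        + labels[:, None] * delta[None, :]
        + rng.normal(0.0, config.amplitude_jitter_sd, size=(n, len(config.bands)))
    )
    signal = amplitudes @ profiles
    gain = np.exp(rng.normal(0.0, config.gain_sd, size=n))
    coeff = rng.normal(0.0, 1.0, size=(n, 3)) * np.asarray(config.baseline_coeff_sd)
    baseline = coeff @ np.stack([np.ones_like(u), u, u**2])
    noise = rng.normal(0.0, config.noise_sd, size=(n, p))
    X = gain[:, None] * signal + baseline + noise

    truth_mask = np.zeros(p, dtype=bool)
    for b in config.bands:
        if b.informative:
            truth_mask |= np.abs(wavelengths - b.center_nm) <= b.width_nm

    data = SpectrumSet(
        wavelengths_nm=wavelengths,
        absorbance=X,
        labels=labels,
        sample_ids=[f"synth{config.seed}-{i:04d}" for i in range(n)],
        metadata={"source": "synthetic", "seed": config.seed},
    )
    return data, truth_mask
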