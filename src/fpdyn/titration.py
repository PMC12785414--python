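"""Chromophore ionization model, species-mixture spectra and ratiometric pKa fits.

The M66C chromophore carries two titratable groups: the tyrosine-derived
phenol and the newly introduced cysteine thiol.  Deprotonation is modelled
as strictly sequential (phenol first), giving three spectral species::

    SH/OH  --pKa1-->  SH/O-  --pKa2-->  S-/O-
    420 nm            566 nm            543 nm

With proton activity h = 10^-pH and K1, K2 the ionization constants, the
populations are p(SH/OH) = h^2/D, p(SH/O-) = h*K1/D, p(S-/O-) = K1*K2/D
with D = h^2 + h*K1 + K1*K2.  The parent protein has a single phenol
transition (OH <-> O-).

pKa values are read out ratiometrically: the absorbance at the neutral-pH
main peak is divided by the absorbance at a reference wavelength and the
Henderson-Hasselbalch sigmoid

    R(pH) = R_lo + (R_hi - R_lo) / (1 + 10^(pKa - pH))

is fitted (Hill coefficient fixed at 1 by default).  A two-wavelength ratio
reports the underlying constant without crosstalk bias exactly when the
reference wavelength is an isosbestic point of the transition, so the
default synthetic basis is constructed to place its isosbestic points at the
reference wavelengths used experimentally (425 nm for the low-range phenol
transition, 544 nm for the high-range thiol transition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "Band",
    "SpeciesSpectrum",
    "IonizationModel",
    "TitrationSeries",
    "RatioCurve",
    "PkaFit",
    "species_fractions",
    "predict_spectrum",
    "ratio_curve",
    "fit_pka",
    "default_mcoral_model",
    "default_mcherry_model",
    "default_mcoral_basis",
    "default_mcherry_basis",
    "DEFAULT_PH_POINTS",
    "DEFAULT_WAVELENGTHS",
    "LOW_RANGE_WINDOW",
    "HIGH_RANGE_WINDOW",
    "MAIN_PEAK_MCORAL",
    "LOW_REF_WAVELENGTH",
    "HIGH_REF_WAVELENGTH",
    "MAIN_PEAK_MCHERRY",
]

DEFAULT_PH_POINTS = (4.5, 5.0, 5.5, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0)
DEFAULT_WAVELENGTHS = np.arange(350.0, 651.0, 1.0)

MAIN_PEAK_MCORAL = 566.0  # neutral-pH main absorbance peak
MAIN_PEAK_MCHERRY = 587.0
LOW_REF_WAVELENGTH = 425.0  # reference for the phenol (low-range) transition
HIGH_REF_WAVELENGTH = 544.0  # reference for the thiol (high-range) transition
LOW_RANGE_WINDOW = (4.5, 8.0)
HIGH_RANGE_WINDOW = (6.0, 11.0)


@dataclass(frozen=True)
class Band:
    """A Gaussian absorbance band: amplitude * exp(-(wl-center)^2 / 2 width^2)."""

    center_nm: float
    width_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")

    def __call__(self, wavelengths: np.ndarray | float) -> np.ndarray | float:
        wl = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(-((wl - self.center_nm) ** 2) / (2 * self.width_nm**2))


@dataclass(frozen=True)
class SpeciesSpectrum:
    """Basis spectrum of one protonation species (one or more Gaussian bands)."""

    label: str
    bands: tuple[Band, ...]

    @property
    def center_nm(self) -> float:
        return max(self.bands, key=lambda b: b.amplitude).center_nm

    def absorbance(self, wavelengths: np.ndarray | float) -> np.ndarray | float:
        return sum(b(wavelengths) for b in self.bands)


@dataclass(frozen=True)
class IonizationModel:
    """One- or two-site sequential ionization constants (pKa units)."""

    pkas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.pkas) not in (1, 2):
            raise ValueError("model supports 1 or 2 ionizable sites")
        if not all(np.isfinite(self.pkas)):
            raise ValueError("pKa values must be finite")
        if len(self.pkas) == 2 and not self.pkas[0] < self.pkas[1]:
            raise ValueError("sequential scheme requires pka1 < pka2")

    @property
    def n_sites(self) -> int:
        return len(self.pkas)

    @property
    def species_labels(self) -> tuple[str, ...]:
        return ("SH/OH", "SH/O-", "S-/O-") if self.n_sites == 2 else ("OH", "O-")


def default_mcoral_model() -> IonizationModel:
    return IonizationModel(pkas=(5.7, 8.8))


def default_mcherry_model() -> IonizationModel:
    return IonizationModel(pkas=(4.4,))


def species_fractions(
    ph: float | np.ndarray, model: IonizationModel
) -> dict[str, np.ndarray | float]:
    """Equilibrium population of each species at the given pH."""
    h = np.power(10.0, -np.asarray(ph, dtype=float))
    if model.n_sites == 1:
        k = 10.0 ** (-model.pkas[0])
        d = h + k
        fracs = (h / d, k / d)
    else:
        k1 = 10.0 ** (-model.pkas[0])
        k2 = 10.0 ** (-model.pkas[1])
        d = h * h + h * k1 + k1 * k2
        fracs = (h * h / d, h * k1 / d, k1 * k2 / d)
    return dict(zip(model.species_labels, fracs))


def _isosbestic_amplitude(
    reference_wl: float,
    target_absorbance: float,
    existing: tuple[Band, ...],
    band_center: float,
    band_width: float,
) -> float:
    """Amplitude of an added band so the species hits ``target_absorbance``
    at ``reference_wl`` (the isosbestic construction)."""
    present = sum(float(b(reference_wl)) for b in existing)
    shortfall = target_absorbance - present
    unit = float(Band(band_center, band_width, 1.0)(reference_wl))
    if shortfall < 0 or unit <= 0:
        raise ValueError("isosbestic construction infeasible for these bands")
    return shortfall / unit


def default_mcoral_basis(width_nm: float = 30.0) -> tuple[SpeciesSpectrum, ...]:
    """Three-species basis with isosbestic points at the reference wavelengths.

    The neutral (SH/OH) band at 420 nm is weak relative to the anionic main
    band, as for neutral chromophore states generally.  The anionic species
    carries a secondary blue band sized so that 425 nm is an isosbestic
    point of the phenol transition, and the doubly deprotonated band
    amplitude is sized so that 544 nm is an isosbestic point of the thiol
    transition — the condition under which each two-wavelength ratio is an
    exact Henderson-Hasselbalch function of pH with midpoint at the
    corresponding constant.
    """
    neutral = SpeciesSpectrum("SH/OH", (Band(420.0, width_nm, 0.45),))
    a_ref_low = float(neutral.absorbance(LOW_REF_WAVELENGTH))
    anion_main = Band(566.0, width_nm, 1.0)
    blue_amp = _isosbestic_amplitude(
        LOW_REF_WAVELENGTH, a_ref_low, (anion_main,), LOW_REF_WAVELENGTH, width_nm
    )
    anion = SpeciesSpectrum(
        "SH/O-", (anion_main, Band(LOW_REF_WAVELENGTH, width_nm, blue_amp))
    )
    a_ref_high = float(anion.absorbance(HIGH_REF_WAVELENGTH))
    di_amp = a_ref_high / float(Band(543.0, width_nm, 1.0)(HIGH_REF_WAVELENGTH))
    dianion = SpeciesSpectrum("S-/O-", (Band(543.0, width_nm, di_amp),))
    return (neutral, anion, dianion)


def default_mcherry_basis(width_nm: float = 30.0) -> tuple[SpeciesSpectrum, ...]:
    """One-site basis: weak neutral band at 438 nm, anionic main band at 587 nm,
    with 425 nm constructed as the isosbestic point of the transition."""
    neutral = SpeciesSpectrum("OH", (Band(438.0, width_nm, 0.35),))
    a_ref = float(neutral.absorbance(LOW_REF_WAVELENGTH))
    anion_main = Band(587.0, width_nm, 1.0)
    blue_amp = _isosbestic_amplitude(
        LOW_REF_WAVELENGTH, a_ref, (anion_main,), LOW_REF_WAVELENGTH, width_nm
    )
    anion = SpeciesSpectrum(
        "O-", (anion_main, Band(LOW_REF_WAVELENGTH, width_nm, blue_amp))
    )
    return (neutral, anion)


def predict_spectrum(
    ph: float,
    model: IonizationModel,
    basis: tuple[SpeciesSpectrum, ...],
    wavelengths: np.ndarray = DEFAULT_WAVELENGTHS,
) -> np.ndarray:
    """Population-weighted mixture spectrum at one pH."""
    by_label = {s.label: s for s in basis}
    missing = set(model.species_labels) - set(by_label)
    if missing:
        raise ValueError(f"basis is missing species {sorted(missing)}")
    fracs = species_fractions(ph, model)
    wl = np.asarray(wavelengths, dtype=float)
    out = np.zeros_like(wl)
    for label in model.species_labels:
        out += float(fracs[label]) * np.asarray(by_label[label].absorbance(wl))
    return out


@dataclass(frozen=True)
class TitrationSeries:
    """Absorbance spectra on a common wavelength grid at a series of pH values."""

    ph: np.ndarray  # (n,)
    wavelengths: np.ndarray  # (m,)
    absorbance: np.ndarray  # (n, m), >= 0

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if ab.shape != (len(ph), len(wl)):
            raise ValueError("absorbance must be (n_ph, n_wavelengths)")
        if (ab < 0).any():
            raise ValueError("absorbance must be non-negative")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)

    def absorbance_at(self, wavelength: float, tol: float = 0.51) -> np.ndarray:
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[i] - wavelength) > tol:
            raise ValueError(
                f"wavelength {wavelength} nm is outside the measured grid "
                f"(nearest {self.wavelengths[i]} nm)"
            )
        return self.absorbance[:, i]

    def to_frame(self) -> pd.DataFrame:
        ph = np.repeat(self.ph, len(self.wavelengths))
        wl = np.tile(self.wavelengths, len(self.ph))
        return pd.DataFrame(
            {"pH": ph, "wavelength_nm": wl, "absorbance": self.absorbance.ravel()}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TitrationSeries":
        pivot = df.pivot_table(index="pH", columns="wavelength_nm", values="absorbance")
        return cls(
            ph=pivot.index.to_numpy(),
            wavelengths=pivot.columns.to_numpy(),
            absorbance=pivot.to_numpy(),
        )

    @classmethod
    def from_csv(cls, path) -> "TitrationSeries":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class RatioCurve:
    ph: np.ndarray
    ratio: np.ndarray
    num_wavelength: float
    den_wavelength: float


def ratio_curve(
    series: TitrationSeries,
    num_wavelength: float,
    den_wavelength: float,
    window: tuple[float, float] | None = None,
    den_floor: float = 1e-4,
) -> RatioCurve:
    """Per-pH absorbance ratio A(num)/A(den), optionally restricted to a pH window.

    Points whose denominator falls below ``den_floor`` are dropped with a
    warning rather than producing unstable ratios.
    """
    num = series.absorbance_at(num_wavelength)
    den = series.absorbance_at(den_wavelength)
    ph = series.ph
    keep = np.ones(len(ph), dtype=bool)
    if window is not None:
        lo, hi = window
        keep &= (ph >= lo - 1e-9) & (ph <= hi + 1e-9)
    small = keep & (den < den_floor)
    if small.any():
        warnings.warn(
            f"dropping {int(small.sum())} pH point(s) with denominator below "
            f"{den_floor} at {den_wavelength} nm",
            stacklevel=2,
        )
        keep &= ~small
    return RatioCurve(
        ph=ph[keep],
        ratio=num[keep] / den[keep],
        num_wavelength=num_wavelength,
        den_wavelength=den_wavelength,
    )


@dataclass(frozen=True)
class PkaFit:
    pka: float
    r_lo: float
    r_hi: float
    hill: float
    residual_norm: float
    n_points: int


def _hh(ph: np.ndarray, r_lo: float, r_hi: float, pka: float, hill: float) -> np.ndarray:
    return r_lo + (r_hi - r_lo) / (1.0 + 10.0 ** (hill * (pka - ph)))


def fit_pka(curve: RatioCurve, free_hill: bool = False) -> PkaFit:
    """Least-squares Henderson-Hasselbalch fit of a ratio curve.

    The Hill coefficient is fixed at 1 unless ``free_hill``; a flat curve is
    rejected ("no transition") and non-convergence raises with diagnostics.
    """
    ph, r = curve.ph, curve.ratio
    if len(ph) < 4:
        raise ValueError("pKa fit requires at least 4 points")
    span = float(np.ptp(r))
    if span < 1e-12 * max(1.0, float(np.abs(r).max())):
        raise ValueError("no transition: ratio curve is flat")
    order = np.argsort(ph)
    ph, r = ph[order], r[order]
    mid = (r[0] + r[-1]) / 2.0
    crossing = np.nonzero(np.diff(np.sign(r - mid)))[0]
    pka0 = float(ph[crossing[0]]) if crossing.size else float(np.median(ph))

    if free_hill:
        def f(x, r_lo, r_hi, pka, hill):
            return _hh(x, r_lo, r_hi, pka, hill)
        p0 = [float(r[0]), float(r[-1]), pka0, 1.0]
        bounds = ([-np.inf, -np.inf, 0.0, 0.05], [np.inf, np.inf, 14.0, 10.0])
    else:
        def f(x, r_lo, r_hi, pka):
            return _hh(x, r_lo, r_hi, pka, 1.0)
        p0 = [float(r[0]), float(r[-1]), pka0]
        bounds = ([-np.inf, -np.inf, 0.0], [np.inf, np.inf, 14.0])
    try:
        popt, _ = curve_fit(f, ph, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"pKa fit did not converge (start {p0}): {exc}") from exc
    resid = r - f(ph, *popt)
    hill = float(popt[3]) if free_hill else 1.0
    return PkaFit(
        pka=float(popt[2]),
        r_lo=float(popt[0]),
        r_hi=float(popt[1]),
        hill=hill,
        residual_norm=float(np.linalg.norm(resid)),
        n_points=len(ph),
    )
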