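"""Spectral data types and weighted-integral computations.

The :class:`Spectrum` is the currency of all photometric computation in this
package: a non-negative power distribution on an ascending wavelength grid,
tagged with units (spectral irradiance, spectral radiance, or raw counts).
All integral quantities — α-opic irradiance, photopic illuminance,
chromaticity, and the blue-light-hazard weighted radiance — are rectangle-rule
sums Σ value·weight·Δλ over the common grid, with Δλ the local grid step.
By this convention a unit-constant spectrum times a unit-constant weight over
400–500 nm at Δλ = 1 nm integrates to 101 (one term per sample, not per
interval).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import cie
from .cie import DEFAULT_GRID, WeightingFunction
from .exceptions import DomainError, GridError, UnitsError

#: Units tags accepted on a Spectrum.
IRRADIANCE = "irradiance"  # W m^-2 nm^-1
RADIANCE = "radiance"  # W m^-2 sr^-1 nm^-1
COUNTS = "counts"  # raw sensor counts per wavelength bin
_VALID_UNITS = (IRRADIANCE, RADIANCE, COUNTS)

#: Base blue-light-hazard limits from the photobiological safety standard.
RADIANCE_LIMIT_LONG = 100.0  # W m^-2 sr^-1, exposures > 10^4 s
DOSE_LIMIT_SHORT = 1.0e6  # J m^-2 sr^-1, exposures <= 10^4 s
LONG_EXPOSURE_S = 1.0e4


@dataclass(frozen=True)
class Spectrum:
    """A spectral power distribution on an ascending wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres.
    values
        Non-negative, finite power values, one per wavelength.
    units
        One of ``"irradiance"`` (W·m⁻²·nm⁻¹), ``"radiance"``
        (W·m⁻²·sr⁻¹·nm⁻¹) or ``"counts"``.
    meta
        Free-form metadata (e.g. spectrometer integration time, saturation).
    """

    wavelengths_nm: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    units: str = IRRADIANCE
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise GridError("wavelengths must be a strictly increasing 1-d grid")
        if v.shape != wl.shape:
            raise GridError("values length must equal wavelength grid length")
        if not np.all(np.isfinite(v)):
            raise GridError("spectral values must be finite")
        if self.units not in _VALID_UNITS:
            raise UnitsError(f"unknown units tag {self.units!r}")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)

    # -- convenience ---------------------------------------------------
    @classmethod
    def zeros(cls, wl: np.ndarray | None = None, units: str = IRRADIANCE) -> "Spectrum":
        wl = DEFAULT_GRID if wl is None else np.asarray(wl, dtype=float)
        return cls(wl, np.zeros_like(wl), units)

    @classmethod
    def monochromatic(
        cls,
        peak_nm: float,
        value: float = 1.0,
        wl: np.ndarray | None = None,
        units: str = IRRADIANCE,
    ) -> "Spectrum":
        """A single-bin line source: `value` in the grid bin nearest `peak_nm`."""
        wl = DEFAULT_GRID if wl is None else np.asarray(wl, dtype=float)
        v = np.zeros_like(wl)
        v[int(np.argmin(np.abs(wl - peak_nm)))] = value
        return cls(wl, v, units)

    @classmethod
    def gaussian(
        cls,
        peak_nm: float,
        fwhm_nm: float,
        amplitude: float = 1.0,
        wl: np.ndarray | None = None,
        units: str = IRRADIANCE,
    ) -> "Spectrum":
        wl = DEFAULT_GRID if wl is None else np.asarray(wl, dtype=float)
        sigma = fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return cls(wl, amplitude * np.exp(-0.5 * ((wl - peak_nm) / sigma) ** 2), units)

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, values=self.values * factor)

    def __add__(self, other: "Spectrum") -> "Spectrum":
        if self.units != other.units:
            raise UnitsError("cannot add spectra with different units")
        if not np.array_equal(self.wavelengths_nm, other.wavelengths_nm):
            other = resample(other, self.wavelengths_nm)
        return Spectrum(self.wavelengths_nm, self.values + other.values, self.units)

    @property
    def total(self) -> float:
        """Unweighted integral Σ value·Δλ (e.g. irradiance in W·m⁻²)."""
        return float(np.sum(self.values * np.gradient(self.wavelengths_nm)))


@dataclass(frozen=True)
class AopicVector:
    """The five α-opic (ir)radiances, W·m⁻², in S/M/L/rhodopic/melanopic order."""

    sc: float
    mc: float
    lc: float
    rh: float
    mel: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sc, self.mc, self.lc, self.rh, self.mel])

    @classmethod
    def from_array(cls, a) -> "AopicVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (5,):
            raise DomainError("AopicVector requires exactly 5 values")
        return cls(*a.tolist())

    labels = cie.AOPIC_CHANNELS


@dataclass(frozen=True)
class HazardResult:
    """Outcome of the blue-light-hazard assessment of a radiance spectrum.

    ``exposure_limit`` is the base limit divided by the pupil correction
    factor, in W·m⁻²·sr⁻¹ for long exposures and J·m⁻²·sr⁻¹ (a dose) for
    exposures of at most 10⁴ s.  ``within_limit`` compares ``l_b`` (or the
    dose ``l_b × t``) against that applied limit.  Full precision is stored;
    :meth:`report` truncates to one decimal for display.
    """

    l_b: float
    exposure_s: float
    pupil_correction_factor: float
    exposure_limit: float
    limit_units: str
    within_limit: bool

    def report(self) -> dict:
        def trunc1(x: float) -> float:
            return math.floor(x * 10.0) / 10.0

        return {
            "blue_light_weighted_radiance_w_m2_sr": trunc1(self.l_b),
            "exposure_s": self.exposure_s,
            "pupil_correction_factor": self.pupil_correction_factor,
            "exposure_limit": trunc1(self.exposure_limit),
            "limit_units": self.limit_units,
            "within_limit": self.within_limit,
        }


# ---------------------------------------------------------------------------
# operations


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid (zero outside support)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise GridError("target grid must be strictly increasing")
    if grid[0] < 300.0 or grid[-1] > 800.0:
        raise GridError("target grid must lie within 300-800 nm")
    v = np.interp(grid, spectrum.wavelengths_nm, spectrum.values, left=0.0, right=0.0)
    return Spectrum(grid, v, spectrum.units, dict(spectrum.meta))


def weighted_integral(spectrum: Spectrum, w: WeightingFunction) -> float:
    """Rectangle-rule sum Σ value·weight·Δλ on the overlap of the two supports.

    The sum runs over the spectrum's own grid points inside the overlap, with
    the weighting function linearly interpolated onto them and Δλ the local
    grid spacing.  Disjoint supports yield 0.0 with a warning.
    """
    lo = max(spectrum.wavelengths_nm[0], w.wavelengths_nm[0])
    hi = min(spectrum.wavelengths_nm[-1], w.wavelengths_nm[-1])
    sel = (spectrum.wavelengths_nm >= lo) & (spectrum.wavelengths_nm <= hi)
    if lo > hi or sel.sum() == 0:
        warnings.warn("disjoint spectral supports; weighted integral is zero")
        return 0.0
    wl = spectrum.wavelengths_nm[sel]
    weights = np.interp(wl, w.wavelengths_nm, w.weights)
    dl = np.gradient(wl) if wl.size > 1 else np.ones(1)
    return float(np.sum(spectrum.values[sel] * weights * dl))


def _require_units(spectrum: Spectrum, units: str, op: str) -> None:
    if spectrum.units != units:
        raise UnitsError(f"{op} requires a {units}-tagged spectrum, got {spectrum.units!r}")


def aopic_irradiance(spectrum: Spectrum) -> AopicVector:
    """The five α-opic irradiances of an irradiance spectrum, W·m⁻²."""
    _require_units(spectrum, IRRADIANCE, "aopic_irradiance")
    return AopicVector(*(weighted_integral(spectrum, w) for w in cie.alpha_opic_bank()))


def photopic_illuminance(spectrum: Spectrum) -> float:
    """Photopic illuminance in lux: 683 · Σ E(λ)·V(λ)·Δλ."""
    _require_units(spectrum, IRRADIANCE, "photopic_illuminance")
    return 683.0 * weighted_integral(spectrum, cie.photopic_vlambda())


def chromaticity_xy(spectrum: Spectrum) -> tuple[float, float]:
    """CIE 1931 (x, y) chromaticity coordinates (2° observer)."""
    xw, yw, zw = cie.cmf_weighting_functions()
    X = weighted_integral(spectrum, xw)
    Y = weighted_integral(spectrum, yw)
    Z = weighted_integral(spectrum, zw)
    s = X + Y + Z
    if s <= 0.0:
        raise DomainError("chromaticity undefined for a zero spectrum")
    return X / s, Y / s


def pupil_correction_factor(reference_mm: float, actual_mm: float) -> float:
    """Area ratio (actual/reference)² of two pupil diameters.

    With the standard's 3 mm reference pupil and a 7 mm dark-adapted pupil
    this is (7/3)² ≈ 5.4, conventionally rounded up to 6 when applied.
    """
    if reference_mm <= 0 or actual_mm <= 0:
        raise DomainError("pupil diameters must be positive")
    return (actual_mm / reference_mm) ** 2


def blue_light_hazard(
    spectrum: Spectrum,
    exposure_s: float,
    pupil_correction_factor: float = 1.0,
) -> HazardResult:
    """Assess a radiance spectrum against the blue-light-hazard limits.

    L_B = Σ L(λ)·B(λ)·Δλ is compared against the standard's limits, divided
    by the pupil correction factor: for exposures t ≤ 10⁴ s the dose L_B·t
    must not exceed 10⁶ J·m⁻²·sr⁻¹; for t > 10⁴ s, L_B must not exceed
    100 W·m⁻²·sr⁻¹.
    """
    _require_units(spectrum, RADIANCE, "blue_light_hazard")
    if exposure_s <= 0:
        raise DomainError("exposure duration must be positive")
    if pupil_correction_factor < 1.0:
        raise DomainError("pupil correction factor must be >= 1")
    l_b = weighted_integral(spectrum, cie.blue_light_hazard_function())
    if exposure_s <= LONG_EXPOSURE_S:
        limit = DOSE_LIMIT_SHORT / pupil_correction_factor
        within = l_b * exposure_s <= limit
        units = "J m^-2 sr^-1"
    else:
        limit = RADIANCE_LIMIT_LONG / pupil_correction_factor
        within = l_b <= limit
        units = "W m^-2 sr^-1"
    return HazardResult(l_b, exposure_s, pupil_correction_factor, limit, units, within)


# ---------------------------------------------------------------------------
# CSV I/O: two columns (wavelength_nm, value), units tag in a comment header


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# units: {spectrum.units}\n")
        fh.write("wavelength_nm,value\n")
        for wl, v in zip(spectrum.wavelengths_nm, spectrum.values):
            fh.write(f"{wl:.6g},{v:.12g}\n")


def read_spectrum_csv(path) -> Spectrum:
    units = IRRADIANCE
    wls, vals = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "units:" in line:
                    units = line.split("units:")[1].strip()
                continue
            if line.lower().startswith("wavelength"):
                continue
            a, b = line.split(",")
            wls.append(float(a))
            vals.append(float(b))
    return Spectrum(np.array(wls), np.array(vals), units)
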