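"""Spectral weighting functions for photometric and photobiological quantities.

All functions are generated in code from published closed forms rather than
shipped as data tables:

* CIE 1931 2° colour-matching functions: the piecewise-Gaussian analytic fits
  of Wyman, Sloan & Shirley (2013), accurate to about one percent of peak.
* Photopic luminous efficiency V(λ): the fitted ȳ(λ), renormalised so that
  V(555 nm) = 1 exactly (the definitional anchor of the lumen).
* The five photoreceptor (α-opic) action spectra — S-, M-, L-cone-opic,
  rhodopic and melanopic: the Govardovskii et al. (2000) A1 visual-pigment
  template (α and β bands) placed at the standard corneal peak wavelengths
  440 / 545 / 570 / 510 / 490 nm and normalised to unit maximum.  These are
  smooth analytic stand-ins for the standardised tabulated functions; they
  reproduce peak positions and bandwidths, not table values to the last digit.
* Blue-light hazard B(λ): the 5 nm table printed in the photobiological
  safety standard (IEC/BS EN 62471), 300–700 nm, linearly interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GridError

#: Default wavelength grid for all spectral computation (nm).
DEFAULT_GRID = np.arange(380.0, 781.0, 1.0)

#: α-opic channel names, in the conventional S/M/L/rhodopic/melanopic order.
AOPIC_CHANNELS = ("S-cone-opic", "M-cone-opic", "L-cone-opic", "rhodopic", "melanopic")

# Corneal (post ocular-media) peak wavelengths of the five action spectra, nm.
_AOPIC_PEAKS_NM = {
    "S-cone-opic": 440.0,
    "M-cone-opic": 545.0,
    "L-cone-opic": 570.0,
    "rhodopic": 510.0,
    "melanopic": 490.0,
}


@dataclass(frozen=True)
class WeightingFunction:
    """A dimensionless spectral weighting function on a wavelength grid.

    Parameters
    ----------
    name
        Identifier, e.g. ``"melanopic"`` or ``"photopic V(lambda)"``.
    wavelengths_nm
        Strictly increasing grid in nanometres.
    weights
        Non-negative weights, same length as the grid.
    """

    name: str
    wavelengths_nm: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise GridError(f"{self.name}: wavelengths must be strictly increasing")
        if w.shape != wl.shape:
            raise GridError(f"{self.name}: weights/wavelengths length mismatch")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise GridError(f"{self.name}: weights must be finite and non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "weights", w)

    @property
    def peak_nm(self) -> float:
        return float(self.wavelengths_nm[int(np.argmax(self.weights))])


def _split_gauss(wl: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    """Piecewise Gaussian with different widths below/above the mode."""
    s = np.where(wl < mu, s1, s2)
    return np.exp(-0.5 * ((wl - mu) / s) ** 2)


def cie1931_cmfs(wl: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CIE 1931 2° colour-matching functions x̄, ȳ, z̄ (analytic fit)."""
    wl = DEFAULT_GRID if wl is None else np.asarray(wl, dtype=float)
    xbar = (
        1.056 * _split_gauss(wl, 599.8, 37.9, 31.0)
        + 0.362 * _split_gauss(wl, 442.0, 16.0, 26.7)
        - 0.065 * _split_gauss(wl, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * _split_gauss(wl, 568.8, 46.9, 40.5) + 0.286 * _split_gauss(
        wl, 530.9, 16.3, 31.1
    )
    zbar = 1.217 * _split_gauss(wl, 437.0, 11.8, 36.0) + 0.681 * _split_gauss(
        wl, 459.0, 26.0, 13.8
    )
    return np.clip(xbar, 0.0, None), np.clip(ybar, 0.0, None), np.clip(zbar, 0.0, None)


def photopic_vlambda(wl: np.ndarray | None = None) -> WeightingFunction:
    """Photopic luminous efficiency V(λ), anchored to V(555) = 1."""
    wl = DEFAULT_GRID if wl is None else np.asarray(wl, dtype=float)
    _, ybar_at_555, _ = cie1931_cmfs(np.array([555.0]))
    _, ybar, _ = cie1931_cmfs(wl)
    return WeightingFunction("photopic V(lambda)", wl, ybar / ybar_at_555[0])


def cmf_weighting_functions(
    wl: np.ndarray | None = None,
) -> tuple[WeightingFunction, WeightingFunction, WeightingFunction]:
    wl = DEFAULT_GRID if wl is None else np.asarray(wl, dtype=float)
    xbar, ybar, zbar = cie1931_cmfs(wl)
    return (
        WeightingFunction("CIE xbar", wl, xbar),
        WeightingFunction("CIE ybar", wl, ybar),
        WeightingFunction("CIE zbar", wl, zbar),
    )


def pigment_template(wl: np.ndarray, lambda_max: float) -> np.ndarray:
    """Govardovskii A1 visual-pigment absorbance template (α + β bands).

    Normalised to unit maximum on the supplied grid.
    """
    wl = np.asarray(wl, dtype=float)
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha_band = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lm_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta_band = 0.26 * np.exp(-(((wl - lm_beta) / b_beta) ** 2))
    s = alpha_band + beta_band
    return s / s.max()


def alpha_opic(channel: str, wl: np.ndarray | None = None) -> WeightingFunction:
    """One of the five α-opic action spectra, unit peak."""
    if channel not in _AOPIC_PEAKS_NM:
        raise KeyError(f"unknown alpha-opic channel {channel!r}")
    wl = DEFAULT_GRID if wl is None else np.asarray(wl, dtype=float)
    return WeightingFunction(channel, wl, pigment_template(wl, _AOPIC_PEAKS_NM[channel]))


def alpha_opic_bank(wl: np.ndarray | None = None) -> tuple[WeightingFunction, ...]:
    """All five α-opic action spectra in canonical order."""
    return tuple(alpha_opic(c, wl) for c in AOPIC_CHANNELS)


# Blue-light hazard weighting B(λ), 5 nm steps.  300–380 nm and the analytic
# segments beyond 500 nm are filled in programmatically below.
_BLH_EXPLICIT = {
    385: 0.013, 390: 0.025, 395: 0.05, 400: 0.10, 405: 0.20, 410: 0.40,
    415: 0.80, 420: 0.90, 425: 0.95, 430: 0.98, 435: 1.00, 440: 1.00,
    445: 0.97, 450: 0.94, 455: 0.90, 460: 0.80, 465: 0.70, 470: 0.62,
    475: 0.55, 480: 0.45, 485: 0.40, 490: 0.22, 495: 0.16, 500: 0.10,
}


def _blh_table() -> tuple[np.ndarray, np.ndarray]:
    wl = np.arange(300, 701, 5)
    vals = np.empty(wl.shape)
    for i, l in enumerate(wl):
        if l <= 380:
            vals[i] = 0.01
        elif l <= 500:
            vals[i] = _BLH_EXPLICIT[int(l)]
        elif l <= 600:
            vals[i] = 10.0 ** ((450.0 - l) / 50.0)
        else:
            vals[i] = 0.001
    return wl.astype(float), vals


def blue_light_hazard_function(wl: np.ndarray | None = None) -> WeightingFunction:
    """Blue-light hazard weighting B(λ).

    Native support is the standard's 300–700 nm table; a custom grid is
    linearly interpolated from the 5 nm table (zero outside support).
    """
    twl, tv = _blh_table()
    if wl is None:
        wl = np.arange(300.0, 701.0, 1.0)
    else:
        wl = np.asarray(wl, dtype=float)
    return WeightingFunction(
        "blue-light hazard B(lambda)", wl, np.interp(wl, twl, tv, left=0.0, right=0.0)
    )
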