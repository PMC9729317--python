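"""Build and query a calibrated forward model of the light engine.

The calibration procedure samples each LED channel independently over the
12-bit intensity range (by default in steps of 65, i.e. 63 evenly spaced
levels ending at 4095), measures each level with the (simulated)
spectrometer, dark-corrects the readings, and assembles a
:class:`CalibrationContext`: per-LED lookup tables over the full integer
intensity range, obtained by linear interpolation over intensity at every
wavelength, with derived α-opic irradiance, photopic illuminance (lux) and
unweighted irradiance tables.  Beta cumulative distribution functions are
fitted to the per-channel input→lux relationship; their inverse corrects a
desired relative-output profile for departures from linearity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit
from scipy.stats import beta as beta_dist

from .engine import (
    MAX_SETTING,
    N_CHANNELS,
    DeviceSettings,
    EngineGroundTruth,
    SpectrometerModel,
    DEFAULT_SPECTROMETER,
    correct_reading,
    simulate_output,
    simulate_spectrometer,
)
from .exceptions import DomainError, FitError, InsufficientDataError
from .spectra import IRRADIANCE, Spectrum, aopic_irradiance, photopic_illuminance

log = logging.getLogger(__name__)


def sampling_plan(step: int = 65, include_zero: bool = False) -> list[int]:
    """Intensity levels to measure per LED: multiples of `step` in [1, 4095].

    The default step of 65 gives 63 evenly spaced levels ending exactly at
    4095.  Level 0 may be included for an explicit dark anchor.
    """
    if not 1 <= step <= MAX_SETTING:
        raise DomainError(f"step must be in [1, {MAX_SETTING}]")
    levels = list(range(step, MAX_SETTING + 1, step))
    if include_zero:
        levels = [0] + levels
    return levels


@dataclass
class CalibrationTable:
    """Raw calibrated measurements: one spectrum per (led, intensity) pair."""

    records: dict = field(default_factory=dict)  # (led, intensity) -> Spectrum

    def add(self, led: int, intensity: int, spectrum: Spectrum) -> None:
        self.records[(int(led), int(intensity))] = spectrum

    def levels(self, led: int) -> list[int]:
        return sorted(i for (l, i) in self.records if l == led)

    def spectrum(self, led: int, intensity: int) -> Spectrum:
        return self.records[(led, intensity)]

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return next(iter(self.records.values())).wavelengths_nm

    # long-format CSV: led, intensity, wavelength_nm, value -------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (led, inten), sp in sorted(self.records.items()):
            rows.append(
                pd.DataFrame(
                    {
                        "led": led,
                        "intensity": inten,
                        "wavelength_nm": sp.wavelengths_nm,
                        "value": sp.values,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CalibrationTable":
        table = cls()
        for (led, inten), grp in df.groupby(["led", "intensity"]):
            grp = grp.sort_values("wavelength_nm")
            table.add(
                int(led),
                int(inten),
                Spectrum(grp["wavelength_nm"].to_numpy(), grp["value"].to_numpy(), IRRADIANCE),
            )
        return table

    @classmethod
    def from_csv(cls, path) -> "CalibrationTable":
        return cls.from_frame(pd.read_csv(path))


def acquire_calibration(
    truth: EngineGroundTruth,
    plan: list[int] | None = None,
    integration_ms: float = 100.0,
    temperature_c: float = 25.0,
    seed: int | None = None,
    spectrometer: SpectrometerModel = DEFAULT_SPECTROMETER,
) -> CalibrationTable:
    """Measure every (LED, level) in the plan with the simulated rig.

    Each reading is dark-corrected and divided by gain·integration to
    calibrated irradiance units.  Saturated readings are excluded and logged.
    """
    plan = sampling_plan() if plan is None else list(plan)
    seq = np.random.SeedSequence(seed)
    table = CalibrationTable()
    for led in range(N_CHANNELS):
        for level in plan:
            sub_seed = int(seq.spawn(1)[0].generate_state(1)[0] % (2**31))
            out = simulate_output(truth, DeviceSettings.single(led, level), seed=sub_seed)
            reading = simulate_spectrometer(
                out, integration_ms, temperature_c, seed=sub_seed + 1, model=spectrometer
            )
            if reading.meta["saturated"]:
                log.warning("saturated reading at led=%d level=%d excluded", led, level)
                continue
            table.add(led, level, correct_reading(reading, spectrometer))
    return table


@dataclass
class CalibrationCurve:
    """Fitted beta-CDF input→output curve of one LED channel.

    Normalised illuminance y/y_max as a function of normalised intensity
    s/4095 is modelled as betaCDF(x; α, β); ``scale`` is the channel's
    maximum illuminance in lux.
    """

    led_index: int
    alpha: float
    beta: float
    scale: float

    def forward(self, relative_intensity) -> np.ndarray:
        """Relative output in [0, 1] for relative intensity in [0, 1]."""
        return beta_dist.cdf(relative_intensity, self.alpha, self.beta)

    def inverse(self, relative_output) -> np.ndarray:
        """Relative intensity achieving a desired relative output."""
        return beta_dist.ppf(relative_output, self.alpha, self.beta)


class CalibrationContext:
    """Dense per-LED lookup tables built from a calibration table.

    For every LED, spectra measured at the planned levels are linearly
    interpolated over intensity (per wavelength) onto the full 0–4095 integer
    grid.  If level 0 was not measured, the interpolation is anchored at
    (0, zero spectrum): dark-corrected output at zero drive is physically
    zero.  Illuminance, α-opic and unweighted-irradiance lookups are linear
    functionals of the spectrum, hence computed at the knots and interpolated
    with the same rule.
    """

    def __init__(self, wavelengths_nm, led_levels, led_spectra):
        self.wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
        self.led_levels: list[np.ndarray] = []  # knot intensities per LED
        self.led_spectra: list[np.ndarray] = []  # (n_knots, n_wl) per LED
        for levels, spectra in zip(led_levels, led_spectra):
            levels = np.asarray(levels, dtype=float)
            spectra = np.asarray(spectra, dtype=float)
            if levels.size < 2:
                raise InsufficientDataError("need >= 2 calibration levels per LED")
            if levels[0] != 0:
                log.info("anchoring interpolation at (0, zero spectrum)")
                levels = np.concatenate([[0.0], levels])
                spectra = np.vstack([np.zeros(spectra.shape[1]), spectra])
            self.led_levels.append(levels)
            self.led_spectra.append(spectra)
        self._build_derived()

    def _build_derived(self):
        grid = np.arange(MAX_SETTING + 1, dtype=float)
        self.lux = np.zeros((N_CHANNELS, MAX_SETTING + 1))
        self.irradiance = np.zeros((N_CHANNELS, MAX_SETTING + 1))
        self.aopic = np.zeros((N_CHANNELS, MAX_SETTING + 1, 5))
        for led in range(N_CHANNELS):
            levels = self.led_levels[led]
            lux_k = np.array(
                [photopic_illuminance(self._knot(led, i)) for i in range(levels.size)]
            )
            irr_k = np.array([self._knot(led, i).total for i in range(levels.size)])
            aop_k = np.array(
                [aopic_irradiance(self._knot(led, i)).as_array() for i in range(levels.size)]
            )
            self.lux[led] = np.interp(grid, levels, lux_k)
            self.irradiance[led] = np.interp(grid, levels, irr_k)
            for c in range(5):
                self.aopic[led, :, c] = np.interp(grid, levels, aop_k[:, c])

    def _knot(self, led: int, idx: int) -> Spectrum:
        return Spectrum(self.wavelengths_nm, self.led_spectra[led][idx], IRRADIANCE)

    # queries ----------------------------------------------------------
    def spd(self, led: int, intensity: float) -> Spectrum:
        """Interpolated spectrum of one LED at an intensity in [0, 4095]."""
        levels = self.led_levels[led]
        spectra = self.led_spectra[led]
        vals = np.empty(self.wavelengths_nm.size)
        idx = np.clip(np.searchsorted(levels, intensity), 1, levels.size - 1)
        lo, hi = levels[idx - 1], levels[idx]
        t = 0.0 if hi == lo else (np.clip(intensity, levels[0], levels[-1]) - lo) / (hi - lo)
        vals = (1 - t) * spectra[idx - 1] + t * spectra[idx]
        return Spectrum(self.wavelengths_nm, np.clip(vals, 0.0, None), IRRADIANCE)

    def predict_spd(self, settings: DeviceSettings) -> Spectrum:
        """Predicted spectral output for ten 12-bit values (additivity)."""
        total = np.zeros(self.wavelengths_nm.size)
        for led, s in enumerate(settings):
            if s > 0:
                total += self.spd(led, s).values
        return Spectrum(self.wavelengths_nm, total, IRRADIANCE)

    # persistence: directory of per-LED long CSVs + curves YAML ---------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for led in range(N_CHANNELS):
            df = pd.DataFrame(
                {
                    "intensity": np.repeat(self.led_levels[led], self.wavelengths_nm.size),
                    "wavelength_nm": np.tile(self.wavelengths_nm, self.led_levels[led].size),
                    "value": self.led_spectra[led].ravel(),
                }
            )
            df.to_csv(directory / f"led{led}.csv", index=False)

    @classmethod
    def load(cls, directory) -> "CalibrationContext":
        directory = Path(directory)
        led_levels, led_spectra, wl = [], [], None
        for led in range(N_CHANNELS):
            df = pd.read_csv(directory / f"led{led}.csv")
            levels = np.sort(df["intensity"].unique())
            piv = df.pivot(index="intensity", columns="wavelength_nm", values="value")
            piv = piv.sort_index()
            wl = piv.columns.to_numpy(dtype=float)
            led_levels.append(levels)
            led_spectra.append(piv.to_numpy())
        return cls(wl, led_levels, led_spectra)


def build_context(table: CalibrationTable) -> CalibrationContext:
    """Assemble dense lookup tables from raw calibrated measurements."""
    led_levels, led_spectra = [], []
    for led in range(N_CHANNELS):
        levels = table.levels(led)
        if len(levels) < 2:
            raise InsufficientDataError(f"LED {led}: fewer than 2 calibration levels")
        led_levels.append(np.array(levels, dtype=float))
        led_spectra.append(np.vstack([table.spectrum(led, l).values for l in levels]))
    return CalibrationContext(table.wavelengths_nm, led_levels, led_spectra)


def fit_curves(ctx: CalibrationContext) -> list[CalibrationCurve]:
    """Fit a beta CDF to each channel's normalised input→illuminance curve.

    Unweighted least squares of y/y_max against betaCDF(s/4095; α, β) at the
    measured knots.
    """
    curves = []
    for led in range(N_CHANNELS):
        levels = ctx.led_levels[led]
        lux_k = ctx.lux[led][levels.astype(int)]
        y_max = lux_k[-1]
        if y_max <= 0:
            raise FitError(f"LED {led}: no measurable output to fit", led_index=led)
        x = levels / MAX_SETTING
        y = lux_k / y_max
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    lambda x, a, b: beta_dist.cdf(x, a, b),
                    x,
                    y,
                    p0=(1.0, 1.0),
                    bounds=([1e-3, 1e-3], [100.0, 100.0]),
                    maxfev=10000,
                )
        except RuntimeError as exc:
            raise FitError(f"LED {led}: beta-CDF fit failed: {exc}", led_index=led)
        curves.append(CalibrationCurve(led, float(popt[0]), float(popt[1]), float(y_max)))
    return curves


def optimise_profile(curves: list[CalibrationCurve], desired_relative_output) -> DeviceSettings:
    """Settings whose fitted forward output matches a desired relative profile.

    Per LED, setting = round(4095 · betaCDF⁻¹(desired; α, β)); pushing the
    result back through the fitted curve reproduces the desired relative
    output within quantisation error.
    """
    desired = np.asarray(desired_relative_output, dtype=float)
    if desired.shape != (N_CHANNELS,):
        raise DomainError(f"expected {N_CHANNELS} desired outputs")
    if np.any((desired < 0) | (desired > 1)):
        raise DomainError("desired relative outputs must lie in [0, 1]")
    vals = [
        int(round(MAX_SETTING * float(curve.inverse(d))))
        for curve, d in zip(curves, desired)
    ]
    return DeviceSettings(tuple(vals))


def save_curves(curves: list[CalibrationCurve], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [
                {"led_index": c.led_index, "alpha": c.alpha, "beta": c.beta, "scale": c.scale}
                for c in curves
            ],
            fh,
        )


def load_curves(path) -> list[CalibrationCurve]:
    with open(path) as fh:
        docs = yaml.safe_load(fh)
    return [CalibrationCurve(d["led_index"], d["alpha"], d["beta"], d["scale"]) for d in docs]
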