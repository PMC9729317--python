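"""Model of a 10-primary, 12-bit light engine and its simulated backends.

The physical device accepts arrays of ten 12-bit integers (one per LED
channel) and, in asynchronous playback, switches spectra no faster than once
every 10 ms from a JSON "video file".  This module provides:

* :class:`DeviceSettings` and :class:`VideoFile` with validation and a
  documented JSON dialect (``.dsf`` extension) — a stand-in schema, not a
  bit-compatible clone of the vendor format;
* :class:`EngineGroundTruth`, a forward model of the rig (per-LED primary
  spectra, beta-CDF channel nonlinearities, dark spectrum, output noise);
* a simulated spectrometer with a linear dark model in temperature and
  integration time, used as the measurement backend for calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.stats import beta as beta_dist

from .cie import DEFAULT_GRID
from .exceptions import SettingsError, SwitchingRateError
from .spectra import COUNTS, IRRADIANCE, Spectrum

N_CHANNELS = 10
MAX_SETTING = 4095  # 12-bit
MIN_SWITCH_MS = 10  # device floor: one spectrum every ten milliseconds


@dataclass(frozen=True)
class DeviceSettings:
    """Exactly ten integer LED intensities in [0, 4095]."""

    intensities: tuple[int, ...]

    def __post_init__(self):
        vals = tuple(self.intensities)
        if len(vals) != N_CHANNELS:
            raise SettingsError(f"expected {N_CHANNELS} channel settings, got {len(vals)}")
        for v in vals:
            if not float(v).is_integer():
                raise SettingsError(f"settings must be integers, got {v!r}")
            if not 0 <= int(v) <= MAX_SETTING:
                raise SettingsError(f"setting {v} outside [0, {MAX_SETTING}]")
        object.__setattr__(self, "intensities", tuple(int(v) for v in vals))

    @classmethod
    def zeros(cls) -> "DeviceSettings":
        return cls((0,) * N_CHANNELS)

    @classmethod
    def maximum(cls) -> "DeviceSettings":
        return cls((MAX_SETTING,) * N_CHANNELS)

    @classmethod
    def single(cls, led: int, intensity: int) -> "DeviceSettings":
        vals = [0] * N_CHANNELS
        vals[led] = intensity
        return cls(tuple(vals))

    def as_array(self) -> np.ndarray:
        return np.array(self.intensities, dtype=float)

    def __iter__(self):
        return iter(self.intensities)

    def __getitem__(self, i):
        return self.intensities[i]


@dataclass(frozen=True)
class VideoFile:
    """A timed sequence of device settings (the "video file" stimulus format).

    JSON schema: ``{"metadata": {...}, "frames": [{"time_ms": int,
    "settings": [10 ints]}, ...]}``, written with a ``.dsf`` extension.
    """

    times_ms: tuple[int, ...]
    frames: tuple[DeviceSettings, ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        times = tuple(int(t) for t in self.times_ms)
        if len(times) != len(self.frames):
            raise SettingsError("times and frames must have equal length")
        if len(times) == 0:
            raise SettingsError("video file requires at least one frame")
        if times[0] < 0:
            raise SwitchingRateError("times must be non-negative")
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            raise SwitchingRateError("times must be strictly increasing")
        if np.any(diffs < MIN_SWITCH_MS):
            raise SwitchingRateError(
                f"spectral switching faster than {MIN_SWITCH_MS} ms is not supported"
            )
        object.__setattr__(self, "times_ms", times)
        object.__setattr__(self, "frames", tuple(self.frames))

    def to_json(self) -> str:
        doc = {
            "metadata": self.metadata,
            "frames": [
                {"time_ms": t, "settings": list(f.intensities)}
                for t, f in zip(self.times_ms, self.frames)
            ],
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "VideoFile":
        doc = json.loads(text)
        return cls(
            tuple(fr["time_ms"] for fr in doc["frames"]),
            tuple(DeviceSettings(tuple(fr["settings"])) for fr in doc["frames"]),
            doc.get("metadata", {}),
        )

    @classmethod
    def read(cls, path) -> "VideoFile":
        with open(path) as fh:
            return cls.from_json(fh.read())


def make_video_file(profile, metadata: dict | None = None) -> VideoFile:
    """Build a validated VideoFile from rows of (time_ms, settings).

    ``profile`` may be a pandas DataFrame with a ``time_ms`` column followed
    by ten LED columns, or an iterable of ``(time_ms, DeviceSettings)`` pairs.
    """
    rows = []
    if hasattr(profile, "columns"):  # DataFrame
        led_cols = [c for c in profile.columns if c != "time_ms"]
        if len(led_cols) != N_CHANNELS:
            raise SettingsError(f"expected {N_CHANNELS} LED columns, got {len(led_cols)}")
        for _, row in profile.iterrows():
            rows.append((int(row["time_ms"]), DeviceSettings(tuple(int(row[c]) for c in led_cols))))
    else:
        for t, s in profile:
            if not isinstance(s, DeviceSettings):
                s = DeviceSettings(tuple(s))
            rows.append((int(t), s))
    return VideoFile(
        tuple(t for t, _ in rows), tuple(s for _, s in rows), metadata or {}
    )


def pulse_video(settings: DeviceSettings, duration_ms: int, metadata: dict | None = None) -> VideoFile:
    """A timed pulse: `settings` at t = 0, all channels off at t = duration."""
    if duration_ms < MIN_SWITCH_MS:
        raise SwitchingRateError(f"pulse duration must be >= {MIN_SWITCH_MS} ms")
    return VideoFile(
        (0, int(duration_ms)), (settings, DeviceSettings.zeros()), metadata or {}
    )


# ---------------------------------------------------------------------------
# simulated engine


@dataclass(frozen=True)
class EngineGroundTruth:
    """Forward model of the light engine used as the simulation ground truth.

    Output for settings s is  dark + Σᵢ betaCDF(sᵢ/4095; αᵢ, βᵢ)·primaryᵢ
    plus Gaussian noise of standard deviation ``noise_sd`` per wavelength bin,
    clamped at zero.
    """

    primaries: tuple[Spectrum, ...]
    alpha: tuple[float, ...]
    beta: tuple[float, ...]
    dark_spectrum: Spectrum
    noise_sd: float = 0.0

    def __post_init__(self):
        if len(self.primaries) != N_CHANNELS:
            raise SettingsError(f"expected {N_CHANNELS} primaries")
        if len(self.alpha) != N_CHANNELS or len(self.beta) != N_CHANNELS:
            raise SettingsError("alpha/beta must have one value per channel")
        if any(a <= 0 for a in self.alpha) or any(b <= 0 for b in self.beta):
            raise SettingsError("beta-CDF shape parameters must be positive")

    @classmethod
    def default(
        cls,
        alpha: float | tuple = 1.0,
        beta: float | tuple = 1.0,
        peak_irradiance: float = 0.02,
        fwhm_nm: float = 24.0,
        noise_sd: float = 0.0,
        dark_level: float = 0.0,
        wl: np.ndarray | None = None,
    ) -> "EngineGroundTruth":
        """Ten Gaussian primaries peaking 420–660 nm, ~24 nm FWHM."""
        wl = DEFAULT_GRID if wl is None else np.asarray(wl, dtype=float)
        peaks = np.linspace(420.0, 660.0, N_CHANNELS)
        primaries = tuple(
            Spectrum.gaussian(p, fwhm_nm, peak_irradiance, wl=wl) for p in peaks
        )
        a = tuple(float(v) for v in np.broadcast_to(alpha, N_CHANNELS))
        b = tuple(float(v) for v in np.broadcast_to(beta, N_CHANNELS))
        dark = Spectrum(wl, np.full_like(wl, dark_level), IRRADIANCE)
        return cls(primaries, a, b, dark, noise_sd)

    # YAML persistence -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": self.dark_spectrum.wavelengths_nm.tolist(),
            "primaries": [p.values.tolist() for p in self.primaries],
            "alpha": list(self.alpha),
            "beta": list(self.beta),
            "dark": self.dark_spectrum.values.tolist(),
            "noise_sd": float(self.noise_sd),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EngineGroundTruth":
        wl = np.asarray(d["wavelengths_nm"], dtype=float)
        return cls(
            tuple(Spectrum(wl, np.asarray(v), IRRADIANCE) for v in d["primaries"]),
            tuple(d["alpha"]),
            tuple(d["beta"]),
            Spectrum(wl, np.asarray(d["dark"]), IRRADIANCE),
            float(d["noise_sd"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "EngineGroundTruth":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def channel_response(truth: EngineGroundTruth, led: int, setting: int) -> float:
    """Relative output of one channel at a 12-bit setting: betaCDF(s/4095)."""
    return float(beta_dist.cdf(setting / MAX_SETTING, truth.alpha[led], truth.beta[led]))


def simulate_output(
    truth: EngineGroundTruth, settings: DeviceSettings, seed: int | None = None
) -> Spectrum:
    """Spectral output of the simulated engine for the given settings."""
    wl = truth.dark_spectrum.wavelengths_nm
    out = truth.dark_spectrum.values.copy()
    for led, s in enumerate(settings):
        if s > 0:
            out = out + channel_response(truth, led, s) * truth.primaries[led].values
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, truth.noise_sd, size=out.shape)
    return Spectrum(wl, np.clip(out, 0.0, None), IRRADIANCE)


# ---------------------------------------------------------------------------
# simulated spectrometer


@dataclass(frozen=True)
class SpectrometerModel:
    """Simulated spectrometer with a linear dark model.

    counts(λ) = value(λ)·gain·t_int + dark(T, t_int) + noise, where the dark
    offset is linear in both PCB temperature and integration time:
    dark = d0 + d1·T + d2·t_int.  Noise is zero-mean Gaussian with per-bin
    standard deviation sqrt(read_noise_sd² + shot_scale²·signal), seeded.
    The same coefficients are shared with the calibration correction step, so
    dark correction is exact when noise is off.
    """

    gain: float = 1000.0  # counts per (W m^-2 nm^-1 · ms)
    dark_base: float = 30.0  # d0, counts
    dark_per_degc: float = 0.5  # d1, counts per °C
    dark_per_ms: float = 0.1  # d2, counts per ms integration
    read_noise_sd: float = 0.0  # counts
    shot_scale: float = 0.0  # dimensionless
    full_scale: float = 16383.0  # saturation level, counts

    def dark_offset(self, temperature_c: float, integration_ms: float) -> float:
        return self.dark_base + self.dark_per_degc * temperature_c + self.dark_per_ms * integration_ms

    def noise_sd(self, signal_counts: np.ndarray) -> np.ndarray:
        return np.sqrt(
            self.read_noise_sd**2 + self.shot_scale**2 * np.clip(signal_counts, 0.0, None)
        )


DEFAULT_SPECTROMETER = SpectrometerModel()


def simulate_spectrometer(
    spectrum: Spectrum,
    integration_ms: float,
    temperature_c: float = 25.0,
    seed: int | None = None,
    model: SpectrometerModel = DEFAULT_SPECTROMETER,
) -> Spectrum:
    """A raw (counts) spectrometer reading of a spectrum.

    Saturated readings (any bin above full scale) are flagged in
    ``meta["saturated"]`` rather than clipped.
    """
    if integration_ms <= 0:
        raise SettingsError("integration time must be positive")
    signal = spectrum.values * model.gain * integration_ms
    counts = signal + model.dark_offset(temperature_c, integration_ms)
    if model.read_noise_sd > 0 or model.shot_scale > 0:
        rng = np.random.default_rng(seed)
        counts = counts + rng.normal(0.0, 1.0, size=counts.shape) * model.noise_sd(signal)
    counts = np.clip(counts, 0.0, None)
    meta = {
        "integration_ms": float(integration_ms),
        "temperature_c": float(temperature_c),
        "saturated": bool(np.any(counts > model.full_scale)),
    }
    return Spectrum(spectrum.wavelengths_nm, counts, COUNTS, meta)


def correct_reading(
    reading: Spectrum,
    model: SpectrometerModel = DEFAULT_SPECTROMETER,
) -> Spectrum:
    """Dark-correct a counts reading and scale to calibrated irradiance units.

    Noise residuals may leave small negative values; they are kept rather
    than clipped, because clipping at zero would bias low-light calibration
    levels upward.  The calibration context clips at query time.
    """
    t_int = reading.meta["integration_ms"]
    temp = reading.meta["temperature_c"]
    vals = (reading.values - model.dark_offset(temp, t_int)) / (model.gain * t_int)
    return Spectrum(reading.wavelengths_nm, vals, IRRADIANCE, dict(reading.meta))
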