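"""Ground-truth generators: parametric PLR/PIPR pupil traces with blinks and
noise, camera frame streams with luminance steps, and session fixtures laid
out like an eye-tracker export.

The pupil waveform is piecewise: a flat baseline B; after the constriction
latency, a C¹ smoothstep descent of amplitude A over the constriction
duration (the smoothstep makes the peak-constriction time exact and puts the
negative acceleration peak at the onset of constriction); then exponential
recovery toward B − f·A with time constant τ, where f is the sustained
fraction (f > 0 emulates melanopsin-driven sustained constriction after
short-wavelength stimuli).  For f < 0.25 the 75% recovery time has the
closed form T75 = τ·ln((1−f)/(0.25−f)), which reduces to τ·ln 4 when f = 0.

Every generator is a pure function of its spec and seed: same seed, same
series, bit for bit.  Default parameters echo the scale of adult PLR data
(baseline ≈ 5.5 mm, constriction amplitude ≈ 2.7 mm, latency ≈ 0.25 s,
120 Hz sampling).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .stamper import Frame

MM_TO_PX = 37.0  # nominal image scale used for the 2-d diameter column


@dataclass(frozen=True)
class PLRSpec:
    """Parameters of one synthetic pupillary light reflex trace."""

    baseline_mm: float = 5.5
    amplitude_mm: float = 2.7
    latency_s: float = 0.25
    constriction_duration_s: float = 1.0
    recovery_tau_s: float = 3.0
    sustained_fraction: float = 0.0
    noise_sd_mm: float = 0.05
    blink_rate_hz: float = 0.0
    sample_rate_hz: float = 120.0
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.amplitude_mm < self.baseline_mm:
            raise DomainError("amplitude must be positive and below baseline")
        if min(self.latency_s, self.constriction_duration_s, self.recovery_tau_s) <= 0:
            raise DomainError("durations must be positive")
        if not 0.0 <= self.sustained_fraction < 1.0:
            raise DomainError("sustained fraction must lie in [0, 1)")
        if self.sample_rate_hz <= 0 or self.noise_sd_mm < 0 or self.blink_rate_hz < 0:
            raise DomainError("rates and noise must be non-negative")

    @property
    def t75_analytic_s(self) -> float:
        """Closed-form 75% recovery time (NaN when the plateau sits above it)."""
        f = self.sustained_fraction
        if f >= 0.25:
            return math.nan
        return self.recovery_tau_s * math.log((1.0 - f) / (0.25 - f))

    def truth(self) -> dict:
        return {
            "baseline_mm": self.baseline_mm,
            "amplitude_mm": self.amplitude_mm,
            "latency_s": self.latency_s,
            "constriction_duration_s": self.constriction_duration_s,
            "recovery_tau_s": self.recovery_tau_s,
            "sustained_fraction": self.sustained_fraction,
            "t_peak_s": self.latency_s + self.constriction_duration_s,
            "t75_s": self.t75_analytic_s,
        }


def plr_waveform(t_since_onset: np.ndarray, spec: PLRSpec) -> np.ndarray:
    """Noiseless pupil diameter (mm) as a function of time since onset."""
    t = np.asarray(t_since_onset, dtype=float)
    B, A, f = spec.baseline_mm, spec.amplitude_mm, spec.sustained_fraction
    lat, dur, tau = spec.latency_s, spec.constriction_duration_s, spec.recovery_tau_s
    y = np.full(t.shape, B)
    u = (t - lat) / dur
    con = (u >= 0) & (u <= 1)
    y[con] = B - A * (3.0 * u[con] ** 2 - 2.0 * u[con] ** 3)  # smoothstep
    rec = u > 1
    t_rec = t[rec] - (lat + dur)
    y[rec] = B - A * (f + (1.0 - f) * np.exp(-t_rec / tau))
    return y


def generate_plr(
    spec: PLRSpec, pre_s: float = 5.0, post_s: float = 65.0
) -> tuple[pd.DataFrame, dict]:
    """One synthetic trial as per-sample pupil records, plus its ground truth.

    The returned table mimics a pupil-positions export (timestamp, eye id,
    confidence, diameter in px and mm); stimulus onset is at ``pre_s``
    seconds after the start of the recording.
    """
    if pre_s <= 0 or post_s <= 0:
        raise DomainError("pre/post windows must be positive")
    rng = np.random.default_rng(spec.seed)
    n = int(round((pre_s + post_s) * spec.sample_rate_hz)) + 1
    t = np.arange(n) / spec.sample_rate_hz
    onset = pre_s
    mm = plr_waveform(t - onset, spec)
    if spec.noise_sd_mm > 0:
        mm = mm + rng.normal(0.0, spec.noise_sd_mm, size=mm.shape)
    df = pd.DataFrame(
        {
            "pupil_timestamp": t,
            "eye_id": 0,
            "confidence": np.ones(n),
            "diameter": mm * MM_TO_PX,
            "diameter_3d": mm,
        }
    )
    events = []
    if spec.blink_rate_hz > 0:
        df, events = inject_blinks(
            df, spec.blink_rate_hz, seed=None if spec.seed is None else spec.seed + 1
        )
    truth = spec.truth() | {"onset_timestamp": onset, "blink_events": events}
    return df, truth


def inject_blinks(
    records: pd.DataFrame,
    rate_hz: float,
    duration_ms: tuple[float, float] = (50.0, 150.0),
    seed: int | None = None,
) -> tuple[pd.DataFrame, list]:
    """Add Poisson-placed blink artifacts to single-eye pupil records.

    During each event the measured diameter collapses toward zero (linear
    ramp over three samples on each side of a near-zero hold) and confidence
    drops to 0.1, well below the conventional 0.95 quality threshold, so the
    standard masking step flags the event.  Returns the modified records and
    an event log of (start_s, end_s) pairs.
    """
    if rate_hz < 0:
        raise DomainError("blink rate must be non-negative")
    if rate_hz == 0 or len(records) == 0:
        return records, []
    rng = np.random.default_rng(seed)
    t = records["pupil_timestamp"].to_numpy(dtype=float)
    span = t[-1] - t[0]
    n_events = rng.poisson(rate_hz * span)
    out = records.copy()
    diam_mm = out["diameter_3d"].to_numpy(dtype=float).copy()
    conf = out["confidence"].to_numpy(dtype=float).copy()
    events = []
    for _ in range(n_events):
        start = t[0] + rng.uniform(0.0, span)
        dur = rng.uniform(*duration_ms) / 1000.0
        sel = np.flatnonzero((t >= start) & (t <= start + dur))
        if sel.size == 0:
            continue
        envelope = np.full(sel.size, 0.05)
        ramp = min(3, sel.size // 2)
        if ramp > 0:
            envelope[:ramp] = np.linspace(1.0, 0.05, ramp + 1)[1:]
            envelope[-ramp:] = np.linspace(0.05, 1.0, ramp + 1)[:-1]
        diam_mm[sel] = diam_mm[sel] * envelope
        conf[sel] = 0.1
        events.append((float(t[sel[0]]), float(t[sel[-1]])))
    out["diameter_3d"] = diam_mm
    out["diameter"] = diam_mm * MM_TO_PX
    out["confidence"] = conf
    return out, events


# ---------------------------------------------------------------------------
# camera frame streams


@dataclass(frozen=True)
class FrameStreamSpec:
    """A scene-camera stream with a luminance step at a known frame."""

    fps: float = 120.0
    duration_s: float = 5.0
    baseline_mean_rgb: float = 100.0
    step_frame_index: int = 240
    step_delta: float = 40.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        n = int(round(self.fps * self.duration_s))
        if not 0 < self.step_frame_index < n:
            raise DomainError("step frame must lie inside the stream")


def generate_frames(spec: FrameStreamSpec) -> tuple[list[Frame], dict]:
    """Frames with mean intensity stepping up at the planted frame index."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fps * spec.duration_s))
    t = np.arange(n) / spec.fps
    mean_rgb = np.full(n, spec.baseline_mean_rgb)
    mean_rgb[spec.step_frame_index :] += spec.step_delta
    if spec.noise_sd > 0:
        mean_rgb = mean_rgb + rng.normal(0.0, spec.noise_sd, size=n)
    frames = [Frame(float(ts), float(m)) for ts, m in zip(t, mean_rgb)]
    truth = {
        "step_frame_index": spec.step_frame_index,
        "step_timestamp": float(t[spec.step_frame_index]),
    }
    return frames, truth


def sample_stream(
    duration_s: float,
    rate_hz: float = 120.0,
    topics: tuple[str, ...] = ("pupil.0.3d",),
    seed: int | None = None,
):
    """A stream of topic-keyed records, one per topic per sample tick."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    for i in range(n):
        for topic in topics:
            yield {
                "topic": topic,
                "timestamp": i / rate_hz,
                "diameter_3d": 5.5 + rng.normal(0.0, 0.05),
                "confidence": 1.0,
            }


# ---------------------------------------------------------------------------
# session fixtures


def generate_session(
    trials: list[tuple[str, PLRSpec]],
    spacing_s: float = 80.0,
    jitter_s: tuple[float, float] = (5.0, 10.0),
    lead_in_s: float = 10.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """A continuous binocular recording with several stimulus trials.

    Each trial is a (condition label, PLRSpec) pair; onsets follow a cue by a
    jittered 5–10 s interval (avoiding expectancy effects) and are spaced
    ``spacing_s`` apart.  Responses decay back to baseline between trials.
    Eye 0 carries the primary (high-confidence) signal; eye 1 is an
    independent noisier copy with lower confidence, so confidence-based eye
    selection has a planted answer.  Returns (pupil records, annotations,
    ground truth).
    """
    rng = np.random.default_rng(seed)
    if not trials:
        empty = pd.DataFrame(
            columns=["pupil_timestamp", "eye_id", "confidence", "diameter", "diameter_3d"]
        )
        return empty, pd.DataFrame(columns=["label", "timestamp"]), {"trials": []}

    rate = trials[0][1].sample_rate_hz
    onsets = []
    for k in range(len(trials)):
        cue = lead_in_s + k * spacing_s
        onsets.append(cue + rng.uniform(*jitter_s))
    total_s = onsets[-1] + 70.0 + 10.0
    n = int(round(total_s * rate)) + 1
    t = np.arange(n) / rate

    baseline = trials[0][1].baseline_mm
    mm = np.full(n, baseline)
    for (label, spec), onset in zip(trials, onsets):
        rel = t - onset
        win = (rel >= 0) & (rel <= 66.0)
        mm[win] = plr_waveform(rel[win], spec) + (baseline - spec.baseline_mm)
        # ease any residual sustained constriction back to baseline over 5 s
        ramp = (rel > 66.0) & (rel <= 71.0)
        if ramp.any():
            end_val = plr_waveform(np.array([66.0]), spec)[0] + (baseline - spec.baseline_mm)
            mm[ramp] = end_val + (baseline - end_val) * (rel[ramp] - 66.0) / 5.0

    eyes = []
    for eye_id, (noise_scale, conf_level) in enumerate([(1.0, 1.0), (1.5, 0.90)]):
        noise_sd = trials[0][1].noise_sd_mm * noise_scale
        vals = mm + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else mm.copy()
        df = pd.DataFrame(
            {
                "pupil_timestamp": t,
                "eye_id": eye_id,
                "confidence": np.full(n, conf_level),
                "diameter": vals * MM_TO_PX,
                "diameter_3d": vals,
            }
        )
        blink_rate = trials[0][1].blink_rate_hz
        if blink_rate > 0:
            df, _ = inject_blinks(df, blink_rate, seed=int(rng.integers(2**31)))
        eyes.append(df)
    records = pd.concat(eyes, ignore_index=True)

    annotations = pd.DataFrame(
        {"label": [label for label, _ in trials], "timestamp": onsets}
    )
    truth = {
        "sample_rate_hz": rate,
        "trials": [
            {"label": label, "onset_timestamp": float(onset)} | spec.truth()
            for (label, spec), onset in zip(trials, onsets)
        ],
    }
    return records, annotations, truth


def write_fixture_session(
    trials: list[tuple[str, PLRSpec]],
    out_dir,
    spacing_s: float = 80.0,
    seed: int | None = None,
) -> dict:
    """Write a session fixture laid out like an eye-tracker export.

    Emits ``pupil_positions.csv``, ``annotations.csv`` and
    ``ground_truth.json`` into ``out_dir`` and returns the ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, annotations, truth = generate_session(trials, spacing_s=spacing_s, seed=seed)
    records.to_csv(out_dir / "pupil_positions.csv", index=False)
    annotations.to_csv(out_dir / "annotations.csv", index=False)
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth


def pipr_session_trials(
    n_per_condition: int = 3,
    blue_sustained_fraction: float = 0.10,
    red_sustained_fraction: float = 0.0,
    noise_sd_mm: float = 0.05,
    blink_rate_hz: float = 0.05,
    seed: int | None = None,
) -> list[tuple[str, PLRSpec]]:
    """Alternating blue/red trial specs for a PIPR-style session.

    Blue trials carry a planted sustained constriction fraction (melanopsin
    signature); red trials fully recover.  Order is shuffled with the seed.
    """
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_per_condition):
        trials.append(("blue", PLRSpec(sustained_fraction=blue_sustained_fraction,
                                       noise_sd_mm=noise_sd_mm, blink_rate_hz=blink_rate_hz)))
        trials.append(("red", PLRSpec(sustained_fraction=red_sustained_fraction,
                                      noise_sd_mm=noise_sd_mm, blink_rate_hz=blink_rate_hz)))
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]
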