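"""Pupillometer-style parametrisation of PLR trials and PIPR summaries.

A single constriction trial is summarised by the parameters a clinical
pupillometer reports: baseline diameter, peak constriction, constriction
latency (time from stimulus onset to the negative acceleration peak of the
initial constriction), average and maximum constriction velocity, average
redilation velocity, and the 75% recovery time T75 — the time from peak
constriction until the pupil has recovered 75% of the constriction amplitude
toward baseline.  Velocities are signed: negative during constriction,
positive during redilation.  Parameters that cannot be computed (no
constriction; recovery threshold never reached in-window) are not-a-number
and are excluded from session averages, with the exclusion count reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .exceptions import DomainError, InsufficientDataError
from .preprocess import TrialSegment

PARAM_NAMES = (
    "baseline_mm",
    "peak_con_mm",
    "latency_s",
    "vcon_ave_mm_s",
    "vcon_max_mm_s",
    "vred_ave_mm_s",
    "t75_rec_s",
)


@dataclass(frozen=True)
class PLRParameters:
    """Summary parameters of one pupillary light reflex trial."""

    baseline_mm: float
    peak_con_mm: float
    latency_s: float
    vcon_ave_mm_s: float
    vcon_max_mm_s: float
    vred_ave_mm_s: float
    t75_rec_s: float
    acc_peak_s: float = math.nan  # diagnostic: time of the acceleration minimum
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def undefined(cls) -> "PLRParameters":
        return cls(*([math.nan] * 8), degenerate=True)


def derivatives(segment: TrialSegment) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and acceleration by central differences (one-sided at ends).

    Acceleration uses the compact three-point second difference rather than
    a repeated first-difference pass: the narrow stencil keeps the negative
    acceleration peak of a constriction onset within about one sample of the
    true onset, which matters for the latency estimate.
    """
    t = segment.t_rel_s
    y = segment.values
    if t.size < 5:
        raise InsufficientDataError("need at least 5 samples for derivatives")
    velocity = np.gradient(y, t)
    h1 = t[1:-1] - t[:-2]
    h2 = t[2:] - t[1:-1]
    acceleration = np.empty_like(y)
    acceleration[1:-1] = 2.0 * (
        y[:-2] / (h1 * (h1 + h2)) - y[1:-1] / (h1 * h2) + y[2:] / (h2 * (h1 + h2))
    )
    acceleration[0] = acceleration[1]
    acceleration[-1] = acceleration[-2]
    return velocity, acceleration


def parametrise(
    segment: TrialSegment,
    baseline_window_s: float = 5.0,
    recovery_fraction: float = 0.75,
) -> PLRParameters:
    """Compute PLR parameters from a millimetre trial segment.

    The segment's time axis must be relative to stimulus onset (onset at
    t = 0) and cover both the pre-stimulus baseline window and the
    post-stimulus response.  ``recovery_fraction`` sets the recovery
    threshold for T75: recovery of that fraction of the constriction
    amplitude from peak back toward baseline.
    """
    t = segment.t_rel_s
    v = segment.values
    base_sel = (t >= -baseline_window_s) & (t < 0.0)
    post_sel = t > 0.0
    if not base_sel.any() or not post_sel.any():
        raise DomainError("segment must cover baseline and post-onset windows")
    baseline = float(v[base_sel].mean())

    post_idx = np.flatnonzero(post_sel)
    peak_local = int(np.argmin(v[post_idx]))
    peak_idx = post_idx[peak_local]
    peak = float(v[peak_idx])
    t_peak = float(t[peak_idx])
    if peak >= baseline:
        return PLRParameters.undefined()

    velocity, acceleration = derivatives(segment)

    # latency: negative acceleration peak of the initial constriction,
    # searched in (0, t_peak]
    con_sel = (t > 0.0) & (t <= t_peak)
    con_idx = np.flatnonzero(con_sel)
    acc_min_idx = con_idx[int(np.argmin(acceleration[con_idx]))]
    latency = float(t[acc_min_idx])

    vcon_ave = (peak - baseline) / (t_peak - latency) if t_peak > latency else math.nan
    vel_sel = (t > latency) & (t <= t_peak)
    vcon_max = float(velocity[vel_sel].min()) if vel_sel.any() else math.nan

    # recovery: first time after the peak at which the threshold is crossed
    threshold = peak + recovery_fraction * (baseline - peak)
    rec_idx = np.flatnonzero((t > t_peak) & (v >= threshold))
    if rec_idx.size:
        t75_time = float(t[rec_idx[0]])
        t75 = t75_time - t_peak
    else:
        t75_time = float(t[-1])
        t75 = math.nan

    red_sel = (t >= t_peak) & (t <= t75_time)
    vred_ave = float(velocity[red_sel].mean()) if red_sel.any() else math.nan

    return PLRParameters(
        baseline_mm=baseline,
        peak_con_mm=peak,
        latency_s=latency,
        vcon_ave_mm_s=vcon_ave,
        vcon_max_mm_s=vcon_max,
        vred_ave_mm_s=vred_ave,
        t75_rec_s=t75,
        acc_peak_s=latency,
    )


@dataclass(frozen=True)
class SessionSummary:
    """NaN-aware per-parameter mean and SD over a session's trials."""

    mean: dict
    sd: dict
    n_trials: int
    n_undefined: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "sd": self.sd, "n_undefined": self.n_undefined}
        )


def summarise(trials: list[PLRParameters]) -> SessionSummary:
    """Average PLR parameters over trials, excluding undefined values.

    A trial whose parameter is not-a-number does not contribute to that
    parameter's mean or SD; the count of such exclusions is reported.  For a
    single defined value the SD is reported as 0.
    """
    if not trials:
        raise DomainError("need at least one trial to summarise")
    df = pd.DataFrame([{k: tr.as_dict()[k] for k in PARAM_NAMES} for tr in trials])
    mean, sd, n_undef = {}, {}, {}
    for col in PARAM_NAMES:
        vals = df[col].dropna()
        n_undef[col] = int(df[col].isna().sum())
        if len(vals) == 0:
            mean[col] = math.nan
            sd[col] = math.nan
        else:
            mean[col] = float(vals.mean())
            sd[col] = 0.0 if len(vals) == 1 else float(vals.std(ddof=1))
    return SessionSummary(mean, sd, len(trials), n_undef)


@dataclass(frozen=True)
class PiprSummary:
    """Per-condition mean traces and the sustained post-illumination metric."""

    t_rel_s: np.ndarray
    mean_traces: dict  # condition -> np.ndarray
    sustained: dict  # condition -> float (mean %-change in the late window)
    window_s: tuple
    blue_minus_red: float | None


def pipr_summary(
    segments_by_condition: dict[str, list[TrialSegment]],
    window_post_offset_s: tuple[float, float] = (10.0, 30.0),
    stimulus_duration_s: float = 1.0,
) -> PiprSummary:
    """Summarise a PIPR session of %-change trials grouped by condition.

    The sustained metric is the mean %-change over a late window (default
    10–30 s after stimulus offset, i.e. onset + stimulus duration).  When
    both a ``"blue"`` and a ``"red"`` condition are present, their sustained
    difference (blue − red) is reported: the signature of melanopsin-driven
    sustained constriction.
    """
    if not segments_by_condition:
        raise DomainError("need at least one condition")
    first = next(iter(segments_by_condition.values()))[0]
    t_ref = first.t_rel_s
    mean_traces, sustained = {}, {}
    lo = stimulus_duration_s + window_post_offset_s[0]
    hi = stimulus_duration_s + window_post_offset_s[1]
    win = (t_ref >= lo) & (t_ref <= hi)
    for cond, segments in segments_by_condition.items():
        if not segments:
            raise DomainError(f"condition {cond!r} has no trials")
        stack = []
        for seg in segments:
            if seg.t_rel_s.shape == t_ref.shape and np.allclose(seg.t_rel_s, t_ref):
                stack.append(seg.values)
            else:  # mismatched grids: regrid onto the reference axis
                stack.append(np.interp(t_ref, seg.t_rel_s, seg.values))
        mean_trace = np.mean(stack, axis=0)
        mean_traces[cond] = mean_trace
        sustained[cond] = float(mean_trace[win].mean())
    bmr = None
    if "blue" in sustained and "red" in sustained:
        bmr = sustained["blue"] - sustained["red"]
    return PiprSummary(t_ref, mean_traces, sustained, window_post_offset_s, bmr)
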