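"""Find device settings matching a target's α-opic irradiances.

Two solvers are provided.  The linear-algebra route assumes each channel's
α-opic contribution is proportional to its 12-bit setting (column j of the
5×10 matrix A is LED j's α-opic vector at maximum divided by 4095) and
solves a bounded least-squares problem min ‖A·s − target‖² with
0 ≤ s ≤ 4095.  The local route minimises the same objective with a
gradient-based solver from a supplied start.  Both round to integer settings
afterwards and recompute the achieved α-opic output through the calibrated
forward model, so the reported residual reflects the deliverable stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear, minimize
from scipy.stats import beta as beta_dist

from .calibration import CalibrationContext, CalibrationCurve
from .engine import MAX_SETTING, N_CHANNELS, DeviceSettings
from .exceptions import DomainError
from .spectra import AopicVector, aopic_irradiance


@dataclass(frozen=True)
class MatchResult:
    """Solution of one α-opic matching problem."""

    settings: DeviceSettings
    achieved: AopicVector
    target: AopicVector
    residual: float
    method: str
    in_gamut: bool = True
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "settings": list(self.settings.intensities),
            "achieved": self.achieved.as_array().tolist(),
            "target": self.target.as_array().tolist(),
            "residual": self.residual,
            "method": self.method,
            "in_gamut": self.in_gamut,
            "converged": self.converged,
        }


def aopic_matrix(ctx: CalibrationContext) -> np.ndarray:
    """Per-unit-setting α-opic contributions, one 5-vector column per LED."""
    A = np.zeros((5, N_CHANNELS))
    for led in range(N_CHANNELS):
        A[:, led] = ctx.aopic[led, MAX_SETTING, :] / MAX_SETTING
    return A


def _finalise(
    ctx: CalibrationContext,
    s_continuous: np.ndarray,
    target: AopicVector,
    method: str,
    gamut_tol: float,
    converged: bool = True,
) -> MatchResult:
    settings = DeviceSettings(tuple(int(round(v)) for v in np.clip(s_continuous, 0, MAX_SETTING)))
    achieved = aopic_irradiance(ctx.predict_spd(settings))
    diff = achieved.as_array() - target.as_array()
    residual = float(diff @ diff)
    tnorm = float(np.linalg.norm(target.as_array()))
    in_gamut = residual <= (gamut_tol * max(tnorm, 1e-30)) ** 2
    if not in_gamut:
        warnings.warn(
            f"target outside gamut: residual {residual:.3g} exceeds tolerance; "
            "best-effort settings returned"
        )
    return MatchResult(settings, achieved, target, residual, method, in_gamut, converged)


def match_linear(
    ctx: CalibrationContext, target: AopicVector, gamut_tol: float = 0.01
) -> MatchResult:
    """Bounded linear least squares match of the five α-opic irradiances."""
    t = target.as_array()
    if np.any(t < 0):
        raise DomainError("target alpha-opic irradiances must be non-negative")
    A = aopic_matrix(ctx)
    sol = lsq_linear(A, t, bounds=(0.0, float(MAX_SETTING)))
    return _finalise(ctx, sol.x, target, "linear", gamut_tol)


def match_local(
    ctx: CalibrationContext,
    target: AopicVector,
    start: DeviceSettings | None = None,
    gamut_tol: float = 0.01,
) -> MatchResult:
    """Gradient-based local minimisation of the α-opic mismatch.

    Starts from `start` (or the linear solution) and minimises
    Σ(A·s − target)² over continuous s ∈ [0, 4095]¹⁰ with L-BFGS-B; the
    residual at the solution never exceeds the residual at the start.
    """
    t = target.as_array()
    if np.any(t < 0):
        raise DomainError("target alpha-opic irradiances must be non-negative")
    A = aopic_matrix(ctx)
    if start is None:
        x0 = lsq_linear(A, t, bounds=(0.0, float(MAX_SETTING))).x
    else:
        x0 = start.as_array()

    def objective(s):
        r = A @ s - t
        return float(r @ r), 2.0 * (A.T @ r)

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, float(MAX_SETTING))] * N_CHANNELS,
    )
    return _finalise(ctx, res.x, target, "local", gamut_tol, converged=bool(res.success))


def scale_stimulus(
    settings: DeviceSettings,
    factor: float,
    curves: list[CalibrationCurve] | None = None,
) -> DeviceSettings:
    """Scale a stimulus by `factor` in the linearised output domain.

    Each channel's setting is mapped through its fitted curve to relative
    output, multiplied by the factor, and mapped back through the inverse
    curve.  Without curves the channels are assumed linear.  Channels whose
    scaled output exceeds the maximum are clipped with a saturation warning.
    """
    if factor <= 0:
        raise DomainError("scale factor must be positive")
    rel = settings.as_array() / MAX_SETTING
    if curves is not None:
        rel = np.array([c.forward(r) for c, r in zip(curves, rel)])
    scaled = rel * factor
    clipped = scaled > 1.0
    scaled = np.clip(scaled, 0.0, 1.0)
    if curves is not None:
        out = np.array([c.inverse(r) for c, r in zip(curves, scaled)])
    else:
        out = scaled
    if np.any(clipped):
        warnings.warn(
            f"scaling by {factor} saturates channels {np.flatnonzero(clipped).tolist()}"
        )
    return DeviceSettings(tuple(int(round(v * MAX_SETTING)) for v in out))
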