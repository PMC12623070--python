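"""Sigmoid fits of the ROI strain time curve: strain, buildup, release.

The ROI-mean first-eigenvalue curve of an evoked contraction rises to a
plateau during stimulation and falls back during release.  Each phase is
fitted with a four-parameter logistic

    s(t) = b + A / (1 + exp(-k (t - t0)))        (rising; +k for falling)

The steepness k is the buildup (rising) or release (falling) rate.  k has
pure time^-1 units and is reported both per second and per frame: the two
differ only by the frame interval, but published rate magnitudes are not
always explicit about their time base, so both are kept.  The plateau
b + A of the buildup fit is the "strain" of the cycle (the raw curve
maximum is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

from .strain import StrainCurve

__all__ = [
    "SigmoidFit",
    "DynamicMetrics",
    "split_curve",
    "fit_sigmoid",
    "dynamic_metrics",
]

K_MAX_PER_MS = 1.0  # upper steepness bound: ~1000 1/s, far above physiology
RMS_CONVERGENCE_FRACTION = 0.20  # converged iff residual RMS < 20% of A
N_RESTARTS = 5


@dataclass
class SigmoidFit:
    """Fitted logistic segment.

    baseline/amplitude are in curve units; steepness is positive, in 1/s
    (and per frame); midpoint in ms.  ``converged`` requires optimizer
    success and residual RMS below 20% of the fitted amplitude.
    """

    baseline: float
    amplitude: float
    steepness_per_s: float
    midpoint_ms: float
    residual_rms: float
    converged: bool
    direction: str
    steepness_per_frame: float = float("nan")
    degenerate: bool = False

    def predict(self, t_ms: np.ndarray) -> np.ndarray:
        k = self.steepness_per_s / 1000.0
        sgn = 1.0 if self.direction == "rising" else -1.0
        return self.baseline + self.amplitude / (
            1.0 + np.exp(-sgn * k * (np.asarray(t_ms) - self.midpoint_ms))
        )


@dataclass
class DynamicMetrics:
    """Per-ROI dynamic biomarkers extracted from one strain curve."""

    strain: float                 # fitted plateau b + A (buildup fit)
    strain_raw_max: float         # raw curve maximum
    buildup_rate_s: float         # 1/s
    release_rate_s: float         # 1/s
    buildup_rate_frame: float     # per frame
    release_rate_frame: float     # per frame
    buildup_fit: SigmoidFit | None
    release_fit: SigmoidFit | None


def split_curve(curve: StrainCurve) -> tuple[StrainCurve, StrainCurve,
                                             dict]:
    """Split the cycle at the frame of maximum value.

    Buildup = [start, argmax], release = [argmax, end]; exact ties go to
    the earlier frame.  A maximum at the first or last frame makes the
    corresponding segment degenerate (flagged, not an error).
    """
    if curve.times.size < 8:
        raise ValueError("need at least 8 frames to split the cycle")
    imax = int(np.argmax(curve.values))  # first occurrence on ties
    flags = {
        "argmax_frame": imax,
        "buildup_degenerate": imax == 0,
        "release_degenerate": imax == curve.times.size - 1,
    }
    buildup = StrainCurve(times=curve.times[: imax + 1],
                          values=curve.values[: imax + 1],
                          n_voxels=curve.n_voxels[: imax + 1],
                          label=curve.label)
    release = StrainCurve(times=curve.times[imax:],
                          values=curve.values[imax:],
                          n_voxels=curve.n_voxels[imax:],
                          label=curve.label)
    return buildup, release, flags


def _initial_guess(t: np.ndarray, s: np.ndarray, sign: float
                   ) -> tuple[float, float, float, float]:
    b0 = float(s.min())
    a0 = float(s.max() - s.min())
    # half-max crossing in the fit direction
    half = b0 + 0.5 * a0
    if sign > 0:
        idx = np.argmax(s >= half)
    else:
        idx = np.argmax(s <= half)
    t0 = float(t[idx])
    ds = np.abs(np.diff(s) / np.diff(t))
    k0 = 4.0 * float(ds.max()) / a0 if a0 > 0 else 0.01
    k0 = min(max(k0, 1e-5), K_MAX_PER_MS)
    return b0, a0, k0, t0


def fit_sigmoid(
    segment: StrainCurve,
    direction: Literal["rising", "falling"],
    noise_floor: float = 0.0,
    seed: int = 0,
    frame_interval: float | None = None,
) -> SigmoidFit:
    """Least-squares logistic fit of one curve segment.

    Initialization: b = min, A = range, t0 = half-maximum crossing,
    k = 4 max|ds/dt| / A (the logistic's maximum slope is A k / 4), with
    four additional seeded jittered restarts; the best residual wins.
    Bounds: A >= 0, k in (0, k_max], t0 within the fitted window.
    """
    if direction not in ("rising", "falling"):
        raise ValueError("direction must be 'rising' or 'falling'")
    t = segment.times
    s = segment.values
    failed = SigmoidFit(
        baseline=float("nan"), amplitude=float("nan"),
        steepness_per_s=float("nan"), midpoint_ms=float("nan"),
        residual_rms=float("nan"), converged=False, direction=direction,
        degenerate=True,
    )
    if t.size < 4:
        return failed
    rng_amp = float(s.max() - s.min())
    if rng_amp <= max(noise_floor, 0.0) or rng_amp == 0.0:
        return failed

    sign = 1.0 if direction == "rising" else -1.0

    def model(p: np.ndarray) -> np.ndarray:
        b, a, k, t0 = p
        return b + a / (1.0 + np.exp(-sign * k * (t - t0)))

    def resid(p: np.ndarray) -> np.ndarray:
        return model(p) - s

    b0, a0, k0, t0 = _initial_guess(t, s, sign)
    span = float(t[-1] - t[0])
    lo = np.array([-np.inf, 0.0, 1e-8, t[0] - 0.25 * span])
    hi = np.array([np.inf, np.inf, K_MAX_PER_MS, t[-1] + 0.25 * span])

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(N_RESTARTS):
        if trial == 0:
            p0 = np.array([b0, a0, k0, t0])
        else:
            p0 = np.array([
                b0 + 0.1 * a0 * rng.standard_normal(),
                a0 * np.exp(0.3 * rng.standard_normal()),
                k0 * np.exp(0.7 * rng.standard_normal()),
                t0 + 0.15 * span * rng.standard_normal(),
            ])
        p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return failed

    b, a, k, t0_fit = best.x
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    converged = bool(best.success) and a > 0 and rms < \
        RMS_CONVERGENCE_FRACTION * a
    dt = frame_interval if frame_interval is not None else float(
        np.median(np.diff(t)))
    return SigmoidFit(
        baseline=float(b),
        amplitude=float(a),
        steepness_per_s=float(k * 1000.0),
        steepness_per_frame=float(k * dt),
        midpoint_ms=float(t0_fit),
        residual_rms=rms,
        converged=converged,
        direction=direction,
    )


def dynamic_metrics(curve: StrainCurve, noise_floor: float = 0.0,
                    seed: int = 0) -> DynamicMetrics:
    """Strain, buildup rate and release rate from one ROI strain curve.

    Strain is the fitted plateau (b + A) of the buildup fit; the rates are
    the logistic steepnesses of the two phase fits.  An unconverged fit
    leaves its metrics missing (NaN) without aborting the run.
    """
    buildup, release, flags = split_curve(curve)
    nan = float("nan")
    bfit = rfit = None
    if not flags["buildup_degenerate"]:
        bfit = fit_sigmoid(buildup, "rising", noise_floor, seed)
    if not flags["release_degenerate"]:
        rfit = fit_sigmoid(release, "falling", noise_floor, seed)

    strain = (bfit.baseline + bfit.amplitude
              if bfit is not None and bfit.converged else nan)
    return DynamicMetrics(
        strain=strain,
        strain_raw_max=float(curve.values.max()),
        buildup_rate_s=(bfit.steepness_per_s
                        if bfit is not None and bfit.converged else nan),
        release_rate_s=(rfit.steepness_per_s
                        if rfit is not None and rfit.converged else nan),
        buildup_rate_frame=(bfit.steepness_per_frame
                            if bfit is not None and bfit.converged else nan),
        release_rate_frame=(rfit.steepness_per_frame
                            if rfit is not None and rfit.converged else nan),
        buildup_fit=bfit,
        release_fit=rfit,
    )
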