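"""Temporal viscosity smoothing and multi-filter fusion.

The viscosity weight is a skew-normal bump evaluated on the *increment*
between the currently measured angle and a prediction from the recent past,
rescaled so its mode maps to ``amplitude``:

    lambda(d) = amplitude * SN(d; xi, omega, alpha) / SN(mode; xi, omega, alpha)

with SN the skew-normal density (2/omega) * phi((d-xi)/omega) *
Phi(alpha (d-xi)/omega). A normal increment keeps lambda near the amplitude
so the current detection dominates; an outlier lands in the far tail, gets
weight ~0, and the previous estimate carries through.

Calibration fits (xi, omega, alpha) to observed increment samples by the
method of moments and then widens omega by ``span_factor`` so the viscosity
span strictly exceeds the empirical span — the weight must only suppress
outliers, never the normal inter-frame variation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "ViscosityParams",
    "FusionParams",
    "viscosity_weight",
    "smooth_angle",
    "calibrate_viscosity",
    "fuse_filters",
]

_MIN_SCALE_DEG = 0.5  # floor used when increments are degenerate
_MAX_ABS_SKEW = 0.99  # method-of-moments validity bound on sample skewness


@dataclass
class ViscosityParams:
    location_deg: float = 0.0  # skew-normal location xi
    scale_deg: float = 2.0  # skew-normal scale omega
    shape: float = 0.0  # skewness alpha
    amplitude: float = 1.0  # weight at the mode
    predictor: str = "previous"  # previous | linear_extrapolation

    def __post_init__(self) -> None:
        if self.scale_deg <= 0:
            raise ValueError("scale_deg must be > 0")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must lie in (0, 1]")
        if self.predictor not in {"previous", "linear_extrapolation"}:
            raise ValueError(f"unknown predictor {self.predictor!r}")


@dataclass
class FusionParams:
    epsilon: float = 1e-6
    lambda_floor: float = 1e-3
    viscosity: ViscosityParams = field(default_factory=ViscosityParams)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _mode_offset(shape: float) -> float:
    """Mode of the standard skew-normal with shape alpha (numeric)."""
    if shape == 0:
        return 0.0
    res = minimize_scalar(
        lambda x: -stats.skewnorm.pdf(x, shape),
        bounds=(-1.0, 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def viscosity_weight(increment_deg: float, vp: ViscosityParams) -> float:
    """Skew-normal weight of a measured-minus-predicted angle increment.

    Lies in [0, amplitude]; equals amplitude at the distribution mode; decays
    to ~0 for far-tail increments.
    """
    mode = vp.location_deg + vp.scale_deg * _mode_offset(vp.shape)
    peak = stats.skewnorm.pdf(mode, vp.shape, loc=vp.location_deg, scale=vp.scale_deg)
    val = stats.skewnorm.pdf(
        increment_deg, vp.shape, loc=vp.location_deg, scale=vp.scale_deg
    )
    return float(min(vp.amplitude, vp.amplitude * val / peak))


def predict_angle(prev1_deg: float, prev2_deg: float | None, vp: ViscosityParams) -> float:
    """One-step prediction from the last one or two final angles."""
    if vp.predictor == "linear_extrapolation" and prev2_deg is not None:
        return 2.0 * prev1_deg - prev2_deg
    return prev1_deg


def smooth_angle(
    measured_deg: float,
    prev1_deg: float | None,
    prev2_deg: float | None,
    vp: ViscosityParams,
) -> float:
    """Blend the measured angle with its prediction using the viscosity weight.

    final = lambda * measured + (1 - lambda) * predicted. With no history the
    measurement passes through unchanged (bootstrap).
    """
    if prev1_deg is None:
        return measured_deg
    predicted = predict_angle(prev1_deg, prev2_deg, vp)
    lam = viscosity_weight(measured_deg - predicted, vp)
    return lam * measured_deg + (1.0 - lam) * predicted


def calibrate_viscosity(
    increment_samples, span_factor: float = 2.0, predictor: str = "previous"
) -> ViscosityParams:
    """Fit viscosity parameters to observed angle increments.

    Method of moments on the skew-normal: sample mean, standard deviation and
    skewness determine (xi, omega, alpha); omega is then inflated by
    ``span_factor`` (>= 1) so normal increments keep a high weight. Requires
    at least 20 samples. Degenerate (constant) samples return a minimum-scale
    floor with a warning.
    """
    x = np.asarray(list(increment_samples), dtype=float)
    if len(x) < 20:
        raise ValueError(f"calibration needs >= 20 increment samples, got {len(x)}")
    if span_factor < 1:
        raise ValueError("span_factor must be >= 1")
    m = float(x.mean())
    s = float(x.std(ddof=1))
    if s < 1e-9:
        warnings.warn("degenerate increment samples; using minimum-scale floor")
        return ViscosityParams(
            location_deg=m, scale_deg=_MIN_SCALE_DEG, shape=0.0, predictor=predictor
        )
    g1 = float(np.clip(stats.skew(x), -_MAX_ABS_SKEW, _MAX_ABS_SKEW))
    # the skewness->shape inversion amplifies sampling noise near zero, so
    # skewness insignificant against its standard error sqrt(6/n) is dropped
    if abs(g1) < 2.0 * math.sqrt(6.0 / len(x)):
        g1 = 0.0
    # invert |skewness| = (4-pi)/2 * c^3 / (1-c^2)^{3/2},  c = delta*sqrt(2/pi)
    t = (2.0 * abs(g1) / (4.0 - math.pi)) ** (2.0 / 3.0)
    c = math.copysign(math.sqrt(t / (1.0 + t)), g1)
    delta = float(np.clip(c * math.sqrt(math.pi / 2.0), -0.995, 0.995))
    alpha = delta / math.sqrt(1.0 - delta**2)
    c = delta * math.sqrt(2.0 / math.pi)
    omega = s / math.sqrt(1.0 - c**2)
    xi = m - omega * c
    return ViscosityParams(
        location_deg=xi,
        scale_deg=span_factor * omega,
        shape=alpha,
        predictor=predictor,
    )


def fuse_filters(
    per_filter_angles, prev_final_deg: float | None, fp: FusionParams
) -> tuple[float, str]:
    """Weighted fusion of the angles detected under each augmentation filter.

    fused = sum(lambda_n * theta_n) / (sum(lambda_n) + epsilon) with lambda_n
    the viscosity weight of theta_n against the previous final angle. When
    every weight falls below ``lambda_floor`` the previous final angle is kept
    (status ``fallback``). With no history the plain mean is returned.
    Returns (fused_deg, status).
    """
    angles = [float(a) for a in per_filter_angles]
    if not angles:
        raise ValueError("fuse_filters needs at least one angle")
    if prev_final_deg is None:
        return float(np.mean(angles)), "ok"
    lams = np.array(
        [viscosity_weight(a - prev_final_deg, fp.viscosity) for a in angles]
    )
    if (lams < fp.lambda_floor).all():
        return float(prev_final_deg), "fallback"
    fused = float((lams * np.asarray(angles)).sum() / (lams.sum() + fp.epsilon))
    return fused, "ok"
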