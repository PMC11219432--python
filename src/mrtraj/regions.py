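"""Confidence regions for the joint (intercept, slope) causal effect.

Separate Wald intervals, the joint confidence rectangle (Cartesian product of
the two marginal intervals, joint coverage ~ 0.95^2), the Wald confidence
ellipse {theta : (theta - a)' V^-1 (theta - a) <= chi2_2(level)} with either
the full estimated covariance or the off-diagonal zeroed ("naive" ellipse),
and the exposure-effect-over-time band effect(t) = a_int + a_slope * t with
pointwise variance v11 + 2 t v12 + t^2 v22.

Regions are closed: boundary points count as contained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mr_estimators import MrEstimate

__all__ = [
    "ConfidenceRegion",
    "TrajectoryBand",
    "confidence_interval",
    "joint_rectangle",
    "joint_ellipse",
    "ellipse_area",
    "region_contains",
    "trajectory_band",
    "DEFAULT_BAND_TIMES",
]

#: Default evaluation grid for the trajectory band: the simulated follow-up
#: window 0..6 years in 0.1-year steps.
DEFAULT_BAND_TIMES = np.round(np.arange(0.0, 6.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class ConfidenceRegion:
    """A joint confidence region, rectangular or elliptic.

    For a rectangle, ``shape`` holds the two half-widths; for an ellipse, the
    2x2 covariance used, with the chi-square quantile in ``chi2_q``.
    """

    kind: str  # "rectangle" | "ellipse"
    level: float
    center: np.ndarray
    shape: np.ndarray
    chi2_q: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "ellipse"):
            raise ValueError("kind must be 'rectangle' or 'ellipse'")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")
        center = np.asarray(self.center, dtype=float)
        shape = np.asarray(self.shape, dtype=float)
        if self.kind == "rectangle":
            if shape.shape != (2,) or np.any(shape <= 0):
                raise ValueError("rectangle half-widths must be two positive numbers")
        else:
            if shape.shape != (2, 2) or np.any(np.linalg.eigvalsh(shape) <= 0):
                raise ValueError("ellipse shape must be positive-definite 2x2")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "shape", shape)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "level": self.level,
            "center": self.center.tolist(),
            "shape": self.shape.ravel().tolist(),
        }
        if self.chi2_q is not None:
            d["chi2_q"] = self.chi2_q
        return d


@dataclass(frozen=True)
class TrajectoryBand:
    """Pointwise confidence band for the exposure effect across time."""

    times: np.ndarray
    effect: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    method: str = "multivariate"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "effect": self.effect,
                "lower": self.lower,
                "upper": self.upper,
                "method": self.method,
            }
        )


def confidence_interval(
    estimate: float, se: float, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided Wald interval estimate +/- z(level) * se."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (estimate - z * se, estimate + z * se)


def joint_rectangle(est: MrEstimate, level: float = 0.95) -> ConfidenceRegion:
    """Cartesian product of the two separate marginal intervals.

    A point is contained only if both coordinates lie inside their margins;
    for independent estimates the joint coverage is approximately level^2.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    return ConfidenceRegion(
        kind="rectangle",
        level=level,
        center=est.point,
        shape=z * np.array([est.se_int, est.se_slope]),
    )


def joint_ellipse(
    est: MrEstimate, level: float = 0.95, zero_covariance: bool = False
) -> ConfidenceRegion:
    """Wald confidence ellipse from the estimate's 2x2 covariance.

    ``zero_covariance`` zeroes the off-diagonal before building the region
    (the naive ellipse, assuming the two estimates are independent).
    """
    V = est.vcov.copy()
    if zero_covariance:
        V[0, 1] = V[1, 0] = 0.0
    if np.any(np.linalg.eigvalsh(V) <= 0):
        raise np.linalg.LinAlgError("covariance matrix is singular")
    q = float(stats.chi2.ppf(level, df=2))
    return ConfidenceRegion(
        kind="ellipse", level=level, center=est.point, shape=V, chi2_q=q
    )


def ellipse_area(region: ConfidenceRegion) -> float:
    """Area of a confidence ellipse: pi * q * sqrt(det V)."""
    if region.kind != "ellipse":
        raise ValueError("area is defined for ellipse regions only")
    return float(np.pi * region.chi2_q * np.sqrt(np.linalg.det(region.shape)))


def region_contains(region: ConfidenceRegion, point: np.ndarray) -> bool:
    """Closed containment test (boundary counts as inside)."""
    d = np.asarray(point, dtype=float) - region.center
    if region.kind == "rectangle":
        return bool(np.all(np.abs(d) <= region.shape))
    return bool(d @ np.linalg.solve(region.shape, d) <= region.chi2_q)


def trajectory_band(
    est: MrEstimate,
    times: np.ndarray = DEFAULT_BAND_TIMES,
    level: float = 0.95,
    zero_covariance: bool = False,
) -> TrajectoryBand:
    """Pointwise band for the exposure's effect on the outcome across time.

    effect(t) = a_int + a_slope * t with variance v11 + 2 t v12 + t^2 v22;
    ``zero_covariance`` drops the cross-term (naive band).
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    V = est.vcov.copy()
    if zero_covariance:
        V[0, 1] = V[1, 0] = 0.0
    effect = est.a_int + est.a_slope * t
    var = V[0, 0] + 2.0 * t * V[0, 1] + t**2 * V[1, 1]
    if np.any(var < 0):
        raise ArithmeticError("negative band variance: vcov is not PSD")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return TrajectoryBand(
        times=t,
        effect=effect,
        lower=effect - half,
        upper=effect + half,
        method="naive" if zero_covariance else est.method,
    )
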