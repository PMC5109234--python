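"""Stability-related sway parameters.

Six parameters quantify the amplitude of COP motion:

* ``sp`` — sway path, the total 2-D length of the trajectory,
  sum of distances between consecutive points (mm);
* ``sp_ap`` / ``sp_ml`` — the same excursion projected on one axis (mm);
* ``area`` — area of the 95% confidence ellipse of the point cloud (mm²);
* ``rms_ap`` / ``rms_ml`` — standard deviation of each coordinate series
  about its mean (mm).

The confidence ellipse is the chi-square coverage region of the 2-D sample
covariance: semi-axes a = sqrt(k*lam1), b = sqrt(k*lam2) with k the
chi-square(2 df) quantile at the coverage level (k = 5.991 at 0.95) and
lam1 >= lam2 the covariance eigenvalues; area = pi*a*b.  At n = 10,000 the
small-sample F-based variant is numerically indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .forceplate import COPTrajectory

__all__ = [
    "ConfidenceEllipse",
    "StabilityMetrics",
    "sway_path_2d",
    "sway_path_axis",
    "rms_axis",
    "confidence_ellipse",
    "stability_set",
]


@dataclass(frozen=True)
class ConfidenceEllipse:
    a: float          # major semi-axis, mm
    b: float          # minor semi-axis, mm
    theta: float      # orientation of major axis, rad, in [0, pi)
    area: float       # mm^2
    coverage: float = 0.95

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValidationError("ellipse semi-axes must satisfy a >= b > 0")
        if not np.isclose(self.area, np.pi * self.a * self.b, rtol=1e-9):
            raise ValidationError("ellipse area inconsistent with pi*a*b")


@dataclass(frozen=True)
class StabilityMetrics:
    sp: float
    sp_ap: float
    sp_ml: float
    area: float
    rms_ap: float
    rms_ml: float


def sway_path_2d(traj: COPTrajectory) -> float:
    """Total 2-D path length (mm)."""
    return float(np.sum(np.hypot(np.diff(traj.ml), np.diff(traj.ap))))


def sway_path_axis(traj: COPTrajectory, axis: str) -> float:
    """Path length along one axis: sum of absolute first differences (mm)."""
    return float(np.sum(np.abs(np.diff(traj.axis(axis)))))


def rms_axis(traj: COPTrajectory, axis: str) -> float:
    """Standard deviation about the mean of one coordinate series (mm).

    Population divisor n; at trial length 10,000 the distinction from the
    n-1 form is negligible.
    """
    return float(np.std(traj.axis(axis)))


def confidence_ellipse(traj: COPTrajectory, coverage: float = 0.95) -> ConfidenceEllipse:
    """Coverage ellipse of the (ml, ap) point cloud.

    Raises on degenerate (collinear) clouds: the fractal dimension divides
    by the ellipse-derived planar extent, so a zero-area ellipse is an error
    rather than a value.
    """
    if len(traj) < 3:
        raise ValidationError("confidence ellipse needs at least 3 points")
    if not 0 < coverage < 1:
        raise ValidationError("coverage must lie in (0, 1)")
    cov = np.cov(traj.ml, traj.ap, ddof=1)
    lam, vec = np.linalg.eigh(cov)  # ascending eigenvalues
    if lam[0] <= 0 or lam[0] <= 1e-12 * lam[1]:
        raise ValidationError("degenerate COP covariance: ellipse undefined")
    k = stats.chi2.ppf(coverage, df=2)
    a = float(np.sqrt(k * lam[1]))
    b = float(np.sqrt(k * lam[0]))
    major = vec[:, 1]
    theta = float(np.arctan2(major[1], major[0]) % np.pi)
    return ConfidenceEllipse(a=a, b=b, theta=theta, area=float(np.pi * a * b),
                             coverage=coverage)


def stability_set(traj: COPTrajectory, coverage: float = 0.95) -> StabilityMetrics:
    """Bundle all six stability parameters for one trial."""
    ellipse = confidence_ellipse(traj, coverage)
    return StabilityMetrics(
        sp=sway_path_2d(traj),
        sp_ap=sway_path_axis(traj, "AP"),
        sp_ml=sway_path_axis(traj, "ML"),
        area=ellipse.area,
        rms_ap=rms_axis(traj, "AP"),
        rms_ml=rms_axis(traj, "ML"),
    )
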