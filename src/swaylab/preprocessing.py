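"""Zero-lag Butterworth filtering and trial windowing.

COP series are low-pass filtered with a zero-lag (forward-backward)
second-order Butterworth filter at 5 Hz before the spatial and nonlinear
parameters are computed; spectral parameters use the unfiltered series, so
the pipeline carries both versions of every trial.  "Second-order" is read
as the per-pass order: the forward-backward pass squares the magnitude
response (effective 4th-order attenuation) and cancels the phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ValidationError
from .forceplate import COPTrajectory

__all__ = ["FilterSpec", "butterworth_zero_lag", "window_trial", "filter_trajectory"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass specification: per-pass ``order`` and ``cutoff_hz`` at ``fs``."""

    order: int = 2
    cutoff_hz: float = 5.0
    fs: float = 200.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        if not 0 < self.cutoff_hz < self.fs / 2:
            raise ValidationError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, fs/2) = (0, {self.fs / 2})"
            )


def butterworth_zero_lag(series, spec: FilterSpec) -> np.ndarray:
    """Forward-backward Butterworth low-pass with reflective edge padding.

    The output has the same length as the input and zero phase shift.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("series must be 1-D")
    if len(x) <= 6 * spec.order:
        raise ValidationError(
            f"series too short for order-{spec.order} zero-lag filtering: "
            f"{len(x)} samples, need > {6 * spec.order}"
        )
    b, a = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=spec.fs)
    padlen = min(3 * (2 * spec.order + 1) * 3, len(x) - 1)
    return signal.filtfilt(b, a, x, padtype="even", padlen=padlen)


def window_trial(series, fs: float, duration_s: float = 50.0) -> np.ndarray:
    """Keep the first ``fs * duration_s`` samples of a trial (10,000 at
    200 Hz / 50 s)."""
    x = np.asarray(series, dtype=float)
    n_req = int(round(fs * duration_s))
    if len(x) < n_req:
        raise ValidationError(
            f"insufficient samples: need {n_req} ({duration_s} s at {fs} Hz), "
            f"got {len(x)}"
        )
    return x[:n_req].copy()


def filter_trajectory(traj: COPTrajectory, spec: FilterSpec | None = None) -> COPTrajectory:
    """Apply the zero-lag low-pass to both axes of a COP trajectory."""
    if spec is None:
        spec = FilterSpec(fs=traj.fs)
    elif spec.fs != traj.fs:
        spec = FilterSpec(order=spec.order, cutoff_hz=spec.cutoff_hz, fs=traj.fs)
    return COPTrajectory(
        ml=butterworth_zero_lag(traj.ml, spec),
        ap=butterworth_zero_lag(traj.ap, spec),
        fs=traj.fs,
    )
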