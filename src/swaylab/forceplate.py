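"""Force-plate channel tables, COP trajectories and trial metadata.

The center of pressure (COP) is the point of application of the resultant
ground reaction force on the plate surface.  With forces ``F`` in N, torques
``M`` in N·m about a reference located ``z0`` metres below the plate surface,
the standard plate mechanics give

    COP_x (ML) = (-My - Fx * z0) / Fz
    COP_y (AP) = ( Mx - Fy * z0) / Fz

with x the medial-lateral (rightward positive) and y the anterior-posterior
(forward positive) axis.  COP coordinates are stored in millimetres because
every downstream sway parameter is reported in mm or mm².
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "ForcePlateRecording",
    "COPTrajectory",
    "TrialRecord",
    "Group",
    "FootPosition",
    "Vision",
    "read_forceplate_table",
    "compute_cop",
    "write_cop",
    "read_cop",
]

_REQUIRED_COLUMNS = ("t", "fx", "fy", "fz", "mx", "my", "mz")
_GRID_RTOL = 1e-9


class Group(str, enum.Enum):
    PATIENT = "patient"
    CONTROL = "control"


class FootPosition(str, enum.Enum):
    """Stance configurations: heels 20 cm apart, 10 cm apart, or heels
    together with the feet opened at 30 degrees."""

    FP20 = "FP20"
    FP10 = "FP10"
    FP30 = "FP30"


class Vision(str, enum.Enum):
    EO = "EO"
    EC = "EC"


@dataclass
class ForcePlateRecording:
    """Raw per-trial force-plate channels on a uniform time grid.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, uniformly spaced at ``1/fs``.
    fs : float
        Sampling rate in Hz.
    fx, fy, fz : arrays of float
        Ground-reaction force components in N.  ``fz`` must be strictly
        positive throughout a valid stance trial (it divides the torques).
    mx, my, mz : arrays of float
        Plate torques in N·m.
    z0 : float
        Vertical distance (m) from the plate surface down to the torque
        reference point; 0 when torques are already expressed at the surface.
    """

    t: np.ndarray
    fs: float
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray
    mx: np.ndarray
    my: np.ndarray
    mz: np.ndarray
    z0: float = 0.0

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("t", "fx", "fy", "fz", "mx", "my", "mz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise ValidationError(f"channel {name!r} must be 1-D")
            arrays[name] = arr
            setattr(self, name, arr)
        n = len(arrays["t"])
        if n < 2:
            raise ValidationError("recording needs at least 2 samples")
        for name, arr in arrays.items():
            if len(arr) != n:
                raise ValidationError(
                    f"channel {name!r} has length {len(arr)}, expected {n}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"channel {name!r} contains non-finite values")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if np.any(arrays["fz"] <= 0):
            raise ValidationError("fz must be strictly positive at every sample")
        dt = np.diff(arrays["t"])
        if not np.allclose(dt, 1.0 / self.fs, rtol=_GRID_RTOL, atol=0):
            raise FormatError("time grid spacing is not uniform at 1/fs")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class COPTrajectory:
    """Paired medial-lateral / anterior-posterior COP series in mm."""

    ml: np.ndarray
    ap: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.ml = np.asarray(self.ml, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        if self.ml.ndim != 1 or self.ap.ndim != 1:
            raise ValidationError("ml and ap must be 1-D series")
        if len(self.ml) != len(self.ap):
            raise ValidationError(
                f"ml and ap lengths differ: {len(self.ml)} vs {len(self.ap)}"
            )
        if len(self.ml) < 2:
            raise ValidationError("trajectory needs at least 2 samples")
        if not (np.all(np.isfinite(self.ml)) and np.all(np.isfinite(self.ap))):
            raise ValidationError("trajectory contains non-finite values")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")

    def __len__(self) -> int:
        return len(self.ml)

    def axis(self, name: str) -> np.ndarray:
        key = str(name).upper()
        if key == "AP":
            return self.ap
        if key == "ML":
            return self.ml
        raise ValidationError(f"unknown axis {name!r}; expected 'AP' or 'ML'")


@dataclass
class TrialRecord:
    """One quiet-standing trial: a COP trajectory plus its design metadata."""

    subject_id: str
    group: Group
    foot_position: FootPosition
    vision: Vision
    cop: COPTrajectory

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.foot_position = FootPosition(self.foot_position)
        self.vision = Vision(self.vision)


def _read_delimited(source) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a header row."""
    try:
        df = pd.read_csv(source, sep=None, engine="python")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not parse delimited table: {exc}") from exc
    return df


def read_forceplate_table(
    source, schema: dict[str, str] | None = None, z0: float = 0.0
) -> ForcePlateRecording:
    """Read a delimited force-plate channel table.

    ``schema`` maps canonical channel names (``t``, ``fx`` ... ``mz``) to the
    column names actually present in the file; unknown columns are ignored.
    The sampling rate is inferred from the time column.
    """
    df = _read_delimited(source)
    schema = schema or {}
    cols = {}
    for name in _REQUIRED_COLUMNS:
        col = schema.get(name, name)
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} (channel {name!r})")
        cols[name] = df[col].to_numpy(dtype=float)
    t = cols["t"]
    if len(t) < 2:
        raise FormatError("table must contain at least 2 rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError("time column must be strictly increasing")
    step = np.mean(dt)
    if not np.allclose(dt, step, rtol=1e-6, atol=0):
        raise FormatError("non-uniform time grid in time column")
    fs = 1.0 / step
    return ForcePlateRecording(
        t=t, fs=fs, fx=cols["fx"], fy=cols["fy"], fz=cols["fz"],
        mx=cols["mx"], my=cols["my"], mz=cols["mz"], z0=z0,
    )


def compute_cop(rec: ForcePlateRecording) -> COPTrajectory:
    """Convert forces/torques to a COP trajectory (output in mm)."""
    ml = 1000.0 * (-rec.my - rec.fx * rec.z0) / rec.fz
    ap = 1000.0 * (rec.mx - rec.fy * rec.z0) / rec.fz
    return COPTrajectory(ml=ml, ap=ap, fs=rec.fs)


def write_cop(traj: COPTrajectory, path) -> None:
    """Write a COP trajectory as a CSV with columns t, ml_mm, ap_mm."""
    t = np.arange(len(traj)) / traj.fs
    df = pd.DataFrame({"t": t, "ml_mm": traj.ml, "ap_mm": traj.ap})
    try:
        df.to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise OSError(f"cannot write COP table to {path}: {exc}") from exc


def read_cop(source) -> COPTrajectory:
    """Read a COP trajectory written by :func:`write_cop`."""
    df = _read_delimited(source)
    for col in ("t", "ml_mm", "ap_mm"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValidationError("COP table must contain at least 2 rows")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, np.mean(dt), rtol=1e-6, atol=0):
        raise FormatError("non-uniform time grid in COP table")
    fs = 1.0 / float(np.mean(dt))
    ml = df["ml_mm"].to_numpy(dtype=float)
    ap = df["ap_mm"].to_numpy(dtype=float)
    return COPTrajectory(ml=ml, ap=ap, fs=fs)


def cop_from_path(path) -> COPTrajectory:
    return read_cop(Path(path))
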