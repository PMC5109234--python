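"""Seeded synthetic stand-in cohorts for quiet-standing COP recordings.

Each axis of a trial is a stationary Ornstein-Uhlenbeck (first-order
Gauss-Markov) process, discretised exactly:

    x[t+1] = x[t] * exp(-theta * dt) + sqrt(1 - exp(-2 theta dt)) * sigma * e[t]

initialised at its stationary law, so the target stationary SD ``sigma``
(mm) is hit in expectation from the first sample and the spectrum is a
low-pass Lorentzian with corner ``theta / 2 pi`` Hz — dominant sway power
sits well below 1.5 Hz for the default bandwidth.  An optional sinusoid on
the AP axis mimics the respiratory component of sway.

Group, vision and foot-position contrasts act multiplicatively
(log-additively) on the sigmas, with magnitudes patterned on the empirical
patient/control contrasts of the study population this generator stands in
for (controls RMS AP about 3-5 mm, patients about 5-8 mm, eyes-closed
inflation larger in patients).  Per-subject log-sigma intercepts create
between-subject variance.  All randomness flows from one master seed
through ``numpy.random.SeedSequence`` spawning, so cohorts are bit
reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import ValidationError
from .forceplate import (
    COPTrajectory,
    FootPosition,
    ForcePlateRecording,
    Group,
    TrialRecord,
    Vision,
)

__all__ = [
    "SwayParams",
    "CohortSpec",
    "generate_cop_trial",
    "generate_forceplate_from_cop",
    "generate_cohort",
]

#: condition order used for deterministic per-trial seed derivation
CONDITIONS = [
    (fp, vc) for fp in (FootPosition.FP20, FootPosition.FP10, FootPosition.FP30)
    for vc in (Vision.EO, Vision.EC)
]


@dataclass(frozen=True)
class SwayParams:
    """Per-trial generator parameters.

    ``sigma_*`` are target stationary SDs in mm; ``bandwidth_*`` the OU
    mean-reversion rates in 1/s (spectral corner = bandwidth / 2 pi Hz);
    ``resp_amp``/``resp_freq`` the optional respiratory sinusoid on AP.
    """

    sigma_ap: float = 4.0
    sigma_ml: float = 2.0
    bandwidth_ap: float = 1.5
    bandwidth_ml: float = 1.5
    resp_amp: float = 0.3
    resp_freq: float = 0.25
    duration_s: float = 50.0
    fs: float = 200.0

    def __post_init__(self) -> None:
        if self.sigma_ap <= 0 or self.sigma_ml <= 0:
            raise ValidationError("sigmas must be positive")
        if self.bandwidth_ap <= 0 or self.bandwidth_ml <= 0:
            raise ValidationError("bandwidths must be positive")
        if self.resp_amp < 0:
            raise ValidationError("respiratory amplitude must be >= 0")
        if not self.resp_freq < self.fs / 2:
            raise ValidationError("respiratory frequency must be below Nyquist")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValidationError("duration and fs must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: subjects per group, baseline sway, and multiplicative
    sigma contrasts.

    ``group_effect`` scales patients, ``vision_effect`` scales eyes-closed
    trials, ``fp_effects`` scales each foot position, and
    ``group_vision_interaction`` adds the extra eyes-closed inflation seen
    in patients.  ``subject_sd`` is the SD of per-subject intercepts on
    log-sigma.
    """

    n_per_group: int = 5
    baseline: SwayParams = field(default_factory=SwayParams)
    group_effect: float = 1.6
    vision_effect: float = 1.2
    fp_effects: dict = field(
        default_factory=lambda: {"FP20": 1.0, "FP10": 1.0, "FP30": 1.3}
    )
    group_vision_interaction: float = 1.25
    subject_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("need >= 2 subjects per group")
        for name, v in (
            ("group_effect", self.group_effect),
            ("vision_effect", self.vision_effect),
            ("group_vision_interaction", self.group_vision_interaction),
        ):
            if v <= 0:
                raise ValidationError(f"{name} must be positive")
        for fp in FootPosition:
            if self.fp_effects.get(fp.value, 0) <= 0:
                raise ValidationError(f"fp_effects[{fp.value!r}] must be positive")
        if self.subject_sd < 0:
            raise ValidationError("subject_sd must be >= 0")


def _ou_series(n: int, sigma: float, theta: float, fs: float,
               rng: np.random.Generator) -> np.ndarray:
    rho = np.exp(-theta / fs)
    innov_sd = sigma * np.sqrt(1.0 - rho ** 2)
    w = rng.standard_normal(n) * innov_sd
    w[0] = rng.standard_normal() * sigma  # stationary start
    return signal.lfilter([1.0], [1.0, -rho], w)


def generate_cop_trial(params: SwayParams, seed) -> COPTrajectory:
    """One synthetic COP trial; bit-deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    n = params.n_samples
    ap = _ou_series(n, params.sigma_ap, params.bandwidth_ap, params.fs, rng)
    ml = _ou_series(n, params.sigma_ml, params.bandwidth_ml, params.fs, rng)
    if params.resp_amp > 0:
        t = np.arange(n) / params.fs
        ap = ap + params.resp_amp * np.sin(2 * np.pi * params.resp_freq * t)
    return COPTrajectory(ml=ml, ap=ap, fs=params.fs)


def generate_forceplate_from_cop(
    traj: COPTrajectory,
    body_weight_n: float = 809.0,
    seed=None,
    jitter_n: float = 1.0,
) -> ForcePlateRecording:
    """Reconstruct plate channels that a COP conversion inverts exactly.

    The vertical load is the body weight (default 809 N, an 82.7 kg adult)
    plus small seeded jitter; torques are built from the jittered load so
    ``compute_cop`` recovers the trajectory to machine precision.
    """
    if body_weight_n <= 0:
        raise ValidationError("body weight must be positive")
    if jitter_n < 0:
        raise ValidationError("jitter must be >= 0")
    n = len(traj)
    fz = np.full(n, float(body_weight_n))
    if jitter_n > 0:
        rng = np.random.default_rng(seed)
        fz = fz + rng.standard_normal(n) * jitter_n
    if np.any(fz <= 0):
        raise ValidationError("jitter drove fz non-positive; reduce jitter_n")
    t = np.arange(n) / traj.fs
    zeros = np.zeros(n)
    return ForcePlateRecording(
        t=t, fs=traj.fs,
        fx=zeros, fy=zeros, fz=fz,
        mx=traj.ap * fz / 1000.0,
        my=-traj.ml * fz / 1000.0,
        mz=zeros,
        z0=0.0,
    )


def _trial_sigma(base: float, spec: CohortSpec, group: Group,
                 fp: FootPosition, vision: Vision, intercept: float) -> float:
    s = base * np.exp(intercept) * spec.fp_effects[fp.value]
    if group is Group.PATIENT:
        s *= spec.group_effect
    if vision is Vision.EC:
        s *= spec.vision_effect
        if group is Group.PATIENT:
            s *= spec.group_vision_interaction
    return float(s)


def generate_cohort(spec: CohortSpec) -> list[TrialRecord]:
    """Full balanced cohort: 2 groups x n subjects x 3 foot positions x
    2 vision conditions, one trial per cell (60 trials at defaults)."""
    ss = np.random.SeedSequence(spec.seed)
    n_subj = 2 * spec.n_per_group
    children = ss.spawn(1 + n_subj * len(CONDITIONS))
    rng_subj = np.random.default_rng(children[0])
    intercepts = rng_subj.standard_normal(n_subj) * spec.subject_sd

    trials: list[TrialRecord] = []
    idx = 1
    for si in range(n_subj):
        group = Group.PATIENT if si < spec.n_per_group else Group.CONTROL
        label = f"{'P' if group is Group.PATIENT else 'C'}{si % spec.n_per_group + 1:02d}"
        for fp, vc in CONDITIONS:
            params = replace(
                spec.baseline,
                sigma_ap=_trial_sigma(spec.baseline.sigma_ap, spec, group, fp, vc,
                                      intercepts[si]),
                sigma_ml=_trial_sigma(spec.baseline.sigma_ml, spec, group, fp, vc,
                                      intercepts[si]),
            )
            traj = generate_cop_trial(params, children[idx])
            idx += 1
            trials.append(
                TrialRecord(subject_id=label, group=group, foot_position=fp,
                            vision=vc, cop=traj)
            )
    return trials
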