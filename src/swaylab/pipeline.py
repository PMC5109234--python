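"""End-to-end orchestration: cohort -> per-trial metrics -> statistics.

The pipeline computes, for every trial, the six stability parameters from
the filtered COP trajectory and the five structure parameters (ApEn/FD
from the filtered, MPF from the unfiltered trajectory), then runs the
three-way mixed ANOVA (group x foot position x vision) on each of the 11
parameters, the four-way direction analysis on the axis-paired parameters
(SP, RMS, ApEn, MPF), Bonferroni post hoc foot-position comparisons where
the foot-position main effect is significant, and descriptive summaries
per group x condition cell.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, generate_cohort
from .errors import ValidationError
from .forceplate import COPTrajectory, FootPosition, TrialRecord, Vision, read_cop
from .preprocessing import FilterSpec, filter_trajectory, window_trial
from .stability import stability_set
from .stats import bonferroni_paired_t, descriptive_summary, rm_anova_mixed
from .structure import ApEnSpec, structure_set

__all__ = ["PipelineConfig", "run_pipeline", "compute_trial_metrics",
           "metrics_table", "analyze_metrics"]

log = logging.getLogger(__name__)

PARAMETERS = [
    "sp", "sp_ap", "sp_ml", "area", "rms_ap", "rms_ml",
    "fd", "apen_ap", "apen_ml", "mpf_ap", "mpf_ml",
]
#: axis-paired parameters entering the four-way direction analysis
DIRECTION_PAIRS = {
    "sp": ("sp_ap", "sp_ml"),
    "rms": ("rms_ap", "rms_ml"),
    "apen": ("apen_ap", "apen_ml"),
    "mpf": ("mpf_ap", "mpf_ml"),
}
TABLE_EFFECTS = ["group", "foot_position", "vision",
                 "group x foot_position", "group x vision"]
FP_PAIRS = [("FP10", "FP20"), ("FP10", "FP30"), ("FP20", "FP30")]


@dataclass
class PipelineConfig:
    """Everything a run needs; see the module docstring for the stages."""

    mode: str = "synthetic"            # synthetic | cop_dir | forceplate_dir
    input_dir: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    apen: ApEnSpec = field(default_factory=ApEnSpec)
    duration_s: float = 50.0
    psd_nw: float = 3.0
    psd_k: int = 5
    psd_bin_hz: float = 0.025
    psd_band: tuple[float, float] = (0.025, 1.5)
    include_first_bin: bool = False
    ellipse_coverage: float = 0.95
    d_convention: str = "semi_axes"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.mode not in ("synthetic", "cop_dir"):
            raise ValidationError(f"unknown input mode {self.mode!r}")
        if self.mode != "synthetic":
            if not self.input_dir or not Path(self.input_dir).is_dir():
                raise ValidationError(f"input directory not found: {self.input_dir}")


def compute_trial_metrics(trial: TrialRecord, config: PipelineConfig) -> dict:
    """All 11 parameters for one trial, as a tidy row."""
    fs = trial.cop.fs
    raw = COPTrajectory(
        ml=window_trial(trial.cop.ml, fs, config.duration_s),
        ap=window_trial(trial.cop.ap, fs, config.duration_s),
        fs=fs,
    )
    filt = filter_trajectory(raw, config.filter)
    stab = stability_set(filt, config.ellipse_coverage)
    struct = structure_set(
        filt, raw, apen_spec=config.apen, coverage=config.ellipse_coverage,
        d_convention=config.d_convention, nw=config.psd_nw, k=config.psd_k,
        bin_hz=config.psd_bin_hz, band=config.psd_band,
        include_first_bin=config.include_first_bin,
    )
    row = {
        "subject": trial.subject_id,
        "group": trial.group.value,
        "foot_position": trial.foot_position.value,
        "vision": trial.vision.value,
        **asdict(stab),
        **asdict(struct),
    }
    log.debug("trial metrics %s", row)
    return row


def _check_balance(trials: list[TrialRecord]) -> None:
    seen = {}
    for tr in trials:
        key = (tr.subject_id, tr.foot_position.value, tr.vision.value)
        if key in seen:
            raise ValidationError(f"duplicate trial for {key}")
        seen[key] = tr
    subjects = sorted({tr.subject_id for tr in trials})
    missing = [
        (s, fp.value, vc.value)
        for s in subjects
        for fp in FootPosition
        for vc in Vision
        if (s, fp.value, vc.value) not in seen
    ]
    if missing:
        raise ValidationError(f"incomplete cohort; missing cells: {missing}")


def metrics_table(trials: list[TrialRecord], config: PipelineConfig) -> pd.DataFrame:
    """Per-trial metric rows for a complete balanced cohort."""
    _check_balance(trials)
    rows = []
    for tr in trials:
        try:
            rows.append(compute_trial_metrics(tr, config))
        except ValidationError as exc:
            raise ValidationError(
                f"trial {tr.subject_id}/{tr.foot_position.value}/"
                f"{tr.vision.value}: {exc}"
            ) from exc
    return pd.DataFrame(rows)


def _load_cop_dir(input_dir: str) -> list[TrialRecord]:
    """Read a cohort from a directory of COP tables plus a manifest.

    The manifest (``manifest.csv``) columns: subject, group, foot_position,
    vision, file.
    """
    root = Path(input_dir)
    manifest = root / "manifest.csv"
    if not manifest.is_file():
        raise ValidationError(f"manifest not found: {manifest}")
    mf = pd.read_csv(manifest)
    required = {"subject", "group", "foot_position", "vision", "file"}
    if not required.issubset(mf.columns):
        raise ValidationError(
            f"manifest missing columns: {sorted(required - set(mf.columns))}"
        )
    trials = []
    for rec in mf.itertuples(index=False):
        path = root / str(rec.file)
        try:
            cop = read_cop(path)
        except ValidationError as exc:
            raise ValidationError(f"{path.name}: {exc}") from exc
        trials.append(
            TrialRecord(subject_id=str(rec.subject), group=rec.group,
                        foot_position=rec.foot_position, vision=rec.vision,
                        cop=cop)
        )
    return trials


def analyze_metrics(metrics: pd.DataFrame, config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Statistical layer: ANOVAs, direction analysis, post hocs, descriptives."""
    anova_rows = []
    posthoc_rows = []
    for param in PARAMETERS:
        effects = rm_anova_mixed(
            metrics, dv=param, between="group",
            within=["foot_position", "vision"],
        )
        by_name = {e.effect: e for e in effects}
        for eff_name in TABLE_EFFECTS:
            e = by_name[eff_name]
            anova_rows.append({"parameter": param, "analysis": "three_way",
                               **asdict(e)})
        fp_eff = by_name["foot_position"]
        if fp_eff.p_gg < config.alpha:
            for res in bonferroni_paired_t(metrics, dv=param,
                                           within="foot_position", pairs=FP_PAIRS):
                posthoc_rows.append({
                    "parameter": param,
                    "pair": f"{res.pair[0]} vs {res.pair[1]}",
                    "t": res.t, "p_raw": res.p_raw,
                    "p_bonferroni": res.p_bonferroni,
                    "g_av": res.g_av, "n": res.n,
                })

    # four-way direction analysis on axis-paired parameters
    for base, (ap_col, ml_col) in DIRECTION_PAIRS.items():
        ids = ["subject", "group", "foot_position", "vision"]
        long = metrics[ids + [ap_col, ml_col]].melt(
            id_vars=ids, value_vars=[ap_col, ml_col],
            var_name="direction", value_name=base,
        )
        long["direction"] = long["direction"].map({ap_col: "AP", ml_col: "ML"})
        effects = rm_anova_mixed(
            long, dv=base, between="group",
            within=["foot_position", "vision", "direction"],
        )
        for e in effects:
            if "direction" in e.effect:
                anova_rows.append({"parameter": base, "analysis": "four_way",
                                   **asdict(e)})

    desc = []
    for param in PARAMETERS:
        d = descriptive_summary(metrics, dv=param,
                                by=["group", "vision", "foot_position"])
        d.insert(0, "parameter", param)
        desc.append(d)

    return {
        "anova": pd.DataFrame(anova_rows),
        "posthoc": pd.DataFrame(
            posthoc_rows,
            columns=["parameter", "pair", "t", "p_raw", "p_bonferroni", "g_av", "n"],
        ),
        "descriptives": pd.concat(desc, ignore_index=True),
    }


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict[str, pd.DataFrame]:
    """Run the full analysis; optionally write all tables plus a run log."""
    if config.mode == "synthetic":
        trials = generate_cohort(config.cohort)
    else:
        trials = _load_cop_dir(config.input_dir)
    metrics = metrics_table(trials, config)
    tables = {"metrics": metrics, **analyze_metrics(metrics, config)}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        run_log = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.cohort.seed if config.mode == "synthetic" else None,
            "mode": config.mode,
            "alpha": config.alpha,
            "filter": asdict(config.filter),
            "apen": asdict(config.apen),
            "n_trials": len(metrics),
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return tables
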