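"""Published reference ANOVA statistics for late-onset Pompe disease standing.

The published study this pipeline models (five adults with late-onset
Pompe disease vs five matched controls, three foot positions, eyes
open/closed) reports, for each of the 11 sway parameters, the F statistic
and degrees of freedom of the three-way mixed ANOVA together with a
partial-eta-squared effect size for the significant effects, plus eight
effect sizes from the four-way direction analysis.  Those printed F and df
values are re-usable inputs: partial eta squared is a deterministic
function of them, so every published effect size can be recomputed and
checked.  This module stores the printed values as data.

``STABILITY_PARAMS``/``STRUCTURE_PARAMS`` split the 11 parameters into the
amplitude-related and organisation-related families used in the summary
statistics (mean effect size, per-family maxima).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "anova_table",
    "direction_effects",
    "STABILITY_PARAMS",
    "STRUCTURE_PARAMS",
]

STABILITY_PARAMS = ("SP", "SP AP", "SP ML", "AREA", "RMS AP", "RMS ML")
STRUCTURE_PARAMS = ("FD", "ApEn AP", "ApEn ML", "MPF AP", "MPF ML")

# (parameter, effect, F, df1, df2, reported partial eta squared)
# Effects: G = group (between), FP = foot position, VC = vision condition.
_TABLE_CELLS = [
    ("SP", "G", 10.76, 1, 8, 0.57),
    ("SP", "FP", 5.86, 2, 16, 0.42),
    ("SP", "VC", 44.15, 1, 8, 0.85),
    ("SP", "G x VC", 15.86, 1, 8, 0.66),
    ("SP AP", "G", 13.69, 1, 8, 0.63),
    ("SP AP", "VC", 34.95, 1, 8, 0.81),
    ("SP AP", "G x VC", 12.99, 1, 8, 0.62),
    ("SP ML", "FP", 9.32, 2, 16, 0.54),
    ("SP ML", "VC", 19.88, 1, 8, 0.71),
    ("SP ML", "G x VC", 6.03, 1, 8, 0.43),
    ("AREA", "G", 12.76, 1, 8, 0.61),
    ("AREA", "FP", 16.08, 2, 16, 0.67),
    ("AREA", "VC", 9.23, 1, 8, 0.54),
    ("AREA", "G x VC", 6.33, 1, 8, 0.44),
    ("RMS AP", "G", 5.45, 1, 8, 0.40),
    ("RMS AP", "VC", 7.26, 1, 8, 0.48),
    ("RMS AP", "G x VC", 14.74, 1, 8, 0.65),
    ("RMS ML", "G", 30.45, 1, 8, 0.79),
    ("RMS ML", "FP", 16.10, 2, 16, 0.67),
    ("FD", "VC", 56.31, 1, 8, 0.88),
    ("FD", "G x VC", 6.72, 1, 8, 0.46),
    ("ApEn AP", "VC", 17.88, 1, 8, 0.69),
    ("ApEn ML", "G x VC", 7.90, 1, 8, 0.50),
    ("MPF AP", "VC", 14.57, 1, 8, 0.65),
    ("MPF ML", "G x VC", 7.92, 1, 8, 0.50),
]

# Four-way direction analysis (Dir = sway direction, AP vs ML); all df (1, 8).
_DIRECTION_CELLS = [
    ("SP", "Dir", 23.19, 1, 8, 0.74),
    ("RMS", "Dir", 34.95, 1, 8, 0.81),
    ("SP", "G x Dir", 6.78, 1, 8, 0.46),
    ("SP", "G x VC x Dir", 6.46, 1, 8, 0.45),
    ("RMS", "G x VC x Dir", 13.88, 1, 8, 0.63),
    ("ApEn", "G x VC x Dir", 6.11, 1, 8, 0.43),
    ("MPF", "Dir", 5.47, 1, 8, 0.41),
    ("MPF", "G x VC x Dir", 6.37, 1, 8, 0.44),
]

_COLUMNS = ["parameter", "effect", "F", "df1", "df2", "eta_sq_p_reported"]


def anova_table() -> pd.DataFrame:
    """The 25 published three-way ANOVA cells that carry an effect size."""
    return pd.DataFrame(_TABLE_CELLS, columns=_COLUMNS)


def direction_effects() -> pd.DataFrame:
    """The 8 published direction-analysis effects with effect sizes."""
    return pd.DataFrame(_DIRECTION_CELLS, columns=_COLUMNS)
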