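"""Mixed repeated-measures statistics for balanced posturography designs.

The study design is one between-subjects factor (group: patients vs
controls) fully crossed with within-subjects factors (foot position,
vision, optionally sway direction), one observation per subject per cell.
For such balanced designs the classical univariate ANOVA decomposition is
exact and is computed here from inclusion-exclusion sums of squares:

* a between effect G tested against subjects-within-groups;
* every within effect w (and its interaction with G) tested against the
  w x subjects-within-groups interaction.

Sphericity is handled with the Greenhouse-Geisser epsilon estimated from
the pooled within-group covariance of the subject-level cell means; the
corrected p-value evaluates the same F at (eps*df1, eps*df2).  Effect sizes
are partial eta squared, recoverable from F and its degrees of freedom as
``F*df1 / (F*df1 + df2)``.  Post hoc paired t-tests are Bonferroni
corrected and accompanied by Hedges ``g_av``, the bias-corrected
standardized mean difference for paired designs based on the average of
the two conditions' standard deviations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "AnovaEffect",
    "PostHocResult",
    "rm_anova_mixed",
    "partial_eta_sq",
    "hedges_g_av",
    "bonferroni_paired_t",
    "descriptive_summary",
    "preliminary_checks",
]


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df1: float
    df2: float
    epsilon: float
    p_gg: float
    eta_sq_p: float
    ss: float
    ss_error: float


@dataclass(frozen=True)
class PostHocResult:
    pair: tuple[str, str]
    t: float
    p_raw: float
    p_bonferroni: float
    g_av: float
    n: int


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if df1 <= 0 or df2 <= 0:
        raise ValidationError("degrees of freedom must be positive")
    if F < 0:
        raise ValidationError("F must be non-negative")
    return float(F * df1 / (F * df1 + df2))


def hedges_g_av(x, y) -> float:
    """Hedges g for paired samples using the average of the two SDs.

    ``d_av = mean(x - y) / ((sd(x) + sd(y)) / 2)`` with sample SDs
    (divisor n-1), corrected by ``J = 1 - 3 / (4*(n-1) - 1)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired samples must be equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise ValidationError("paired samples need n >= 2")
    diff = float(np.mean(x - y))
    sd_av = (np.std(x, ddof=1) + np.std(y, ddof=1)) / 2.0
    if sd_av == 0:
        if diff == 0:
            return 0.0
        raise ValidationError("zero average SD: g_av undefined")
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return float(diff / sd_av * j)


# --- balanced mixed ANOVA --------------------------------------------------

def _pivot_design(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: list[str],
    subject: str,
) -> tuple[np.ndarray, list, list[list]]:
    """Arrange a tidy table into Y[group, subject, w1, ..., wk].

    Raises a validation error naming the missing/duplicated cells for any
    unbalanced design.
    """
    for col in [dv, between, subject, *within]:
        if col not in data.columns:
            raise ValidationError(f"column {col!r} not found in design table")
    df = data[[subject, between, *within, dv]].copy()
    if df[dv].isna().any():
        raise ValidationError("design table contains missing values")

    grp_of = df.groupby(subject)[between].nunique()
    if (grp_of > 1).any():
        bad = grp_of[grp_of > 1].index.tolist()
        raise ValidationError(f"subjects with inconsistent group label: {bad}")

    groups = sorted(df[between].unique())
    if len(groups) < 2:
        raise ValidationError("between factor needs >= 2 levels")
    wlevels = [sorted(df[w].unique()) for w in within]
    subj_by_group = {
        g: sorted(df.loc[df[between] == g, subject].unique()) for g in groups
    }
    ns = {g: len(s) for g, s in subj_by_group.items()}
    if len(set(ns.values())) > 1:
        raise ValidationError(f"unequal group sizes: {ns}")
    n = next(iter(ns.values()))
    if n < 2:
        raise ValidationError("need >= 2 subjects per group")

    shape = (len(groups), n, *[len(lv) for lv in wlevels])
    Y = np.full(shape, np.nan)
    index = df.set_index([between, subject, *within])[dv]
    if index.index.duplicated().any():
        dup = index.index[index.index.duplicated()].tolist()[:5]
        raise ValidationError(f"duplicated design cells: {dup}")
    for gi, g in enumerate(groups):
        for si, s in enumerate(subj_by_group[g]):
            for cell in itertools.product(*wlevels):
                key = (g, s, *cell)
                try:
                    Y[(gi, si, *[wlevels[j].index(cell[j]) for j in range(len(cell))])] = index[key]
                except KeyError:
                    raise ValidationError(
                        f"missing cell for subject {s!r}: {dict(zip(within, cell))}"
                    ) from None
    return Y, groups, wlevels


def _interaction_ss(Y: np.ndarray, axes: tuple[int, ...]) -> float:
    """Inclusion-exclusion SS for the crossed effect spanned by ``axes``.

    ``Y`` is the full data array; the effect estimate in each cell of the
    selected axes is the alternating sum of marginal means over subsets of
    ``axes``; the SS multiplies the squared estimates by the number of
    observations per cell.
    """
    all_axes = tuple(range(Y.ndim))
    est = np.zeros([Y.shape[a] if a in axes else 1 for a in all_axes])
    for sub in itertools.chain.from_iterable(
        itertools.combinations(axes, r) for r in range(len(axes) + 1)
    ):
        margin_over = tuple(a for a in all_axes if a not in sub)
        m = Y.mean(axis=margin_over, keepdims=True)
        est = est + (-1.0) ** (len(axes) - len(sub)) * m
    reps = Y.size / est.size
    return float(reps * np.sum(est ** 2))


def _gg_epsilon(Y: np.ndarray, w_axes: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon for the within effect on ``w_axes``.

    Collapses the data to subject x (cells of the effect), pools the
    covariance within groups, projects it on an orthonormal interaction
    contrast basis C (Kronecker product of per-factor Helmert contrasts)
    and returns ``tr(M)^2 / (d * tr(M^2))`` with ``M = C S C'``.
    """
    other_within = tuple(a for a in range(2, Y.ndim) if a not in w_axes)
    D = Y.mean(axis=other_within) if other_within else Y
    # D has shape (g, n, m_j for j in effect); flatten effect cells
    g, n = D.shape[0], D.shape[1]
    cells = int(np.prod(D.shape[2:]))
    D = D.reshape(g, n, cells)
    mats = []
    for a in w_axes:
        m = Y.shape[a]
        h = np.linalg.qr(
            np.column_stack([np.ones(m), np.eye(m)[:, : m - 1]])
        )[0][:, 1:]
        mats.append(h.T)  # (m-1, m)
    C = mats[0]
    for h in mats[1:]:
        C = np.kron(C, h)
    d = C.shape[0]
    if d == 1:
        return 1.0
    centered = D - D.mean(axis=1, keepdims=True)
    flat = centered.reshape(g * n, cells)
    dof = g * (n - 1)
    if dof < 1:
        raise ValidationError("not enough subjects to estimate covariance")
    S = flat.T @ flat / dof
    M = C @ S @ C.T
    tr2 = float(np.trace(M @ M))
    if tr2 <= 0:
        raise ValidationError("singular within-subject covariance")
    eps = float(np.trace(M)) ** 2 / (d * tr2)
    return float(min(1.0, max(eps, 1.0 / d)))


def rm_anova_mixed(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within: list[str],
    subject: str = "subject",
) -> list[AnovaEffect]:
    """Mixed repeated-measures ANOVA for a balanced, fully crossed design.

    Returns one :class:`AnovaEffect` per testable effect: the between
    factor, every within main effect and within-within interaction, and
    every between x within interaction.  Effect names join factor names
    with ``x`` (e.g. ``"group x vision"``).
    """
    if not within:
        raise ValidationError("at least one within factor is required")
    Y, groups, wlevels = _pivot_design(data, dv, between, within, subject)
    g = len(groups)
    n = Y.shape[1]
    k = len(within)
    w_axes_all = tuple(range(2, 2 + k))

    effects: list[AnovaEffect] = []

    # between effect: error = subjects within groups
    ss_g = _interaction_ss(Y, (0,))
    subj_means = Y.mean(axis=w_axes_all)  # (g, n)
    cells_per_subj = int(np.prod(Y.shape[2:]))
    grand = Y.mean()
    ss_between_total = cells_per_subj * float(
        np.sum((subj_means - grand) ** 2)
    )
    ss_s_in_g = ss_between_total - ss_g
    df_g = g - 1
    df_s = g * (n - 1)
    if ss_s_in_g <= 0 and df_s > 0:
        ss_s_in_g = max(ss_s_in_g, 0.0)
    ms_g = ss_g / df_g
    ms_s = ss_s_in_g / df_s
    if ms_s <= 0:
        raise ValidationError("zero between-subject error variance")
    F = ms_g / ms_s
    effects.append(
        AnovaEffect(
            effect=between, F=F, df1=df_g, df2=df_s, epsilon=1.0,
            p_gg=float(sps.f.sf(F, df_g, df_s)),
            eta_sq_p=partial_eta_sq(F, df_g, df_s),
            ss=ss_g, ss_error=ss_s_in_g,
        )
    )

    # within effects and their interactions with the between factor
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            w_axes = tuple(2 + j for j in combo)
            names = [within[j] for j in combo]
            df_w = int(np.prod([len(wlevels[j]) - 1 for j in combo]))
            ss_w = _interaction_ss(Y, w_axes)
            ss_gw = _interaction_ss(Y, (0, *w_axes))
            # w x subject-within-group error: the crossed interaction of the
            # subject identity with the effect contains G x w plus the error
            Yflat = Y.reshape(1, g * n, *Y.shape[2:])
            ss_uw = _interaction_ss(Yflat, (1, *w_axes))
            ss_err = ss_uw - ss_gw
            df_err = g * (n - 1) * df_w
            ss_err = max(ss_err, 0.0)
            ms_err = ss_err / df_err
            if ms_err <= 0:
                raise ValidationError(
                    f"zero within-subject error variance for effect {' x '.join(names)}"
                )
            eps = _gg_epsilon(Y, w_axes)
            for label, ss_eff, df_eff in (
                (" x ".join(names), ss_w, df_w),
                (" x ".join([between, *names]), ss_gw, df_g * df_w),
            ):
                F = (ss_eff / df_eff) / ms_err
                p = float(sps.f.sf(F, eps * df_eff, eps * df_err))
                effects.append(
                    AnovaEffect(
                        effect=label, F=F, df1=df_eff, df2=df_err,
                        epsilon=eps, p_gg=p,
                        eta_sq_p=partial_eta_sq(F, df_eff, df_err),
                        ss=ss_eff, ss_error=ss_err,
                    )
                )
    return effects


def bonferroni_paired_t(
    data: pd.DataFrame,
    dv: str,
    within: str,
    pairs: list[tuple[str, str]],
    subject: str = "subject",
) -> list[PostHocResult]:
    """Two-tailed paired t-tests with Bonferroni correction and g_av.

    Observations are collapsed to one value per subject per level of the
    ``within`` factor (averaging over any other design cells) before
    pairing; the correction multiplies each raw p by the number of pairs.
    """
    if len(pairs) < 1:
        raise ValidationError("at least one pair is required")
    cellmeans = data.groupby([subject, within], observed=True)[dv].mean().unstack(within)
    m = len(pairs)
    results = []
    for lv1, lv2 in pairs:
        for lv in (lv1, lv2):
            if lv not in cellmeans.columns:
                raise ValidationError(f"unknown level {lv!r} of factor {within!r}")
        x = cellmeans[lv1].to_numpy(dtype=float)
        y = cellmeans[lv2].to_numpy(dtype=float)
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValidationError(f"incomplete pairs for {lv1} vs {lv2}")
        if len(x) < 2:
            raise ValidationError("paired t-test needs >= 2 subjects")
        if np.allclose(x, y):
            t_stat, p_raw, g = 0.0, 1.0, 0.0
        else:
            t_stat, p_raw = sps.ttest_rel(x, y)
            g = hedges_g_av(x, y)
        results.append(
            PostHocResult(
                pair=(lv1, lv2), t=float(t_stat), p_raw=float(p_raw),
                p_bonferroni=float(min(1.0, m * p_raw)), g_av=g, n=len(x),
            )
        )
    return results


def descriptive_summary(
    data: pd.DataFrame,
    dv: str,
    by: list[str],
) -> pd.DataFrame:
    """Per-cell mean, SD, SE and range.

    Single-value cells report sd = se = 0 (flagged by n = 1); empty cells
    are impossible after groupby but an empty input is rejected.
    """
    if data.empty:
        raise ValidationError("empty design table")
    for col in [dv, *by]:
        if col not in data.columns:
            raise ValidationError(f"column {col!r} not found")

    def _cell(s: pd.Series) -> pd.Series:
        n = len(s)
        sd = float(s.std(ddof=1)) if n > 1 else 0.0
        return pd.Series(
            {
                "n": n,
                "mean": float(s.mean()),
                "sd": sd,
                "se": sd / np.sqrt(n),
                "min": float(s.min()),
                "max": float(s.max()),
            }
        )

    out = data.groupby(by, observed=True)[dv].apply(_cell).unstack()
    return out.reset_index()


def preliminary_checks(
    data: pd.DataFrame,
    dv: str,
    between: str,
    cell_factors: list[str],
) -> pd.DataFrame:
    """Shapiro-Wilk normality per group x condition cell and Levene
    variance-equality between groups per condition cell.

    Diagnostics only: results never alter the analysis path.
    """
    rows = []
    for cell, sub in data.groupby(cell_factors, observed=True):
        cell = cell if isinstance(cell, tuple) else (cell,)
        levene_groups = [
            grp[dv].to_numpy(dtype=float) for _, grp in sub.groupby(between, observed=True)
        ]
        if len(levene_groups) >= 2 and all(len(v) >= 2 for v in levene_groups):
            w, p_lev = sps.levene(*levene_groups)
        else:
            raise ValidationError("Levene test needs >= 2 values in >= 2 groups")
        for g, grp in sub.groupby(between, observed=True):
            vals = grp[dv].to_numpy(dtype=float)
            if len(vals) < 3:
                raise ValidationError(
                    f"Shapiro-Wilk needs n >= 3 per cell (got {len(vals)})"
                )
            sw, p_sw = sps.shapiro(vals)
            rows.append(
                {
                    **dict(zip(cell_factors, cell)),
                    between: g,
                    "shapiro_w": float(sw),
                    "shapiro_p": float(p_sw),
                    "levene_w": float(w),
                    "levene_p": float(p_lev),
                }
            )
    return pd.DataFrame(rows)
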