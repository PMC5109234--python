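import numpy as np
import pandas as pd
import pytest

from oracles import design_to_frame, mixed_anova_2within
from swaylab import (
    ValidationError,
    bonferroni_paired_t,
    descriptive_summary,
    hedges_g_av,
    partial_eta_sq,
    preliminary_checks,
    rm_anova_mixed,
)


def random_design(rng, g=2, n=5, a=3, b=2):
    return rng.standard_normal((g, n, a, b))


class TestPartialEtaSq:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [(23.19, 1, 8, 0.74), (34.95, 1, 8, 0.81), (0.0, 2, 16, 0.0)],
    )
    def test_known_values(self, F, df1, df2, expected):
        assert round(partial_eta_sq(F, df1, df2), 2) == expected

    def test_invalid_df(self):
        with pytest.raises(ValidationError):
            partial_eta_sq(1.0, 0, 8)


class TestHedgesGav:
    def test_identity_gives_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert hedges_g_av(x, x) == 0.0

    def test_mean_diff_equal_to_average_sd(self):
        # n = 5: J = 1 - 3/15 = 0.8
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        sd = np.std(x, ddof=1)
        assert hedges_g_av(x + sd, x) == pytest.approx(0.8)

    def test_antisymmetry(self, rng):
        x, y = rng.standard_normal((2, 12))
        assert hedges_g_av(x, y) == pytest.approx(-hedges_g_av(y, x))


class TestMixedAnova:
    def test_pure_group_offset_loads_on_group_effect(self, rng):
        Y = 1e-3 * rng.standard_normal((2, 5, 3, 2))
        Y[0] += 10.0
        eff = {e.effect: e for e in rm_anova_mixed(
            design_to_frame(Y), "value", "group", ["A", "B"])}
        assert eff["group"].F > 1e6
        assert eff["A"].F < 10
        assert eff["B"].F < 10

    def test_two_level_within_factor_has_epsilon_one(self, rng):
        Y = random_design(rng)
        eff = {e.effect: e for e in rm_anova_mixed(
            design_to_frame(Y), "value", "group", ["A", "B"])}
        assert eff["B"].epsilon == 1.0
        assert eff["group x B"].epsilon == 1.0
        assert 0 < eff["A"].epsilon <= 1.0

    def test_matches_first_principles_oracle(self, rng):
        mapping = {
            "G": "group", "A": "A", "B": "B", "GxA": "group x A",
            "GxB": "group x B", "AxB": "A x B", "GxAxB": "group x A x B",
        }
        for _ in range(20):
            g = 2
            n = int(rng.integers(3, 7))
            a = int(rng.integers(2, 5))
            b = int(rng.integers(2, 4))
            Y = rng.standard_normal((g, n, a, b)) + rng.standard_normal((g, 1, a, b))
            eff = {e.effect: e for e in rm_anova_mixed(
                design_to_frame(Y), "value", "group", ["A", "B"])}
            want = mixed_anova_2within(Y)
            for key, name in mapping.items():
                assert eff[name].F == pytest.approx(want[key], abs=1e-8), key

    def test_gg_correction_never_less_conservative(self, rng):
        from scipy import stats as sps

        # the correction is conservative wherever the test can reject;
        # for F deep inside the null region (F < ~1.4) shrinking the df
        # can lower p slightly, so assert on F >= 1.5
        checked = 0
        for _ in range(40):
            Y = random_design(rng, a=4)
            for e in rm_anova_mixed(design_to_frame(Y), "value", "group", ["A", "B"]):
                if e.df1 >= 2 and e.F >= 1.5:
                    p_unc = sps.f.sf(e.F, e.df1, e.df2)
                    assert e.p_gg >= p_unc - 1e-12
                    checked += 1
        assert checked > 10

    def test_epsilon_matches_pingouin_on_duplicated_groups(self, rng):
        # with both groups holding identical data, the pooled within-group
        # covariance equals the grand-centered one pingouin uses
        pg = pytest.importorskip("pingouin")
        mix = rng.standard_normal((4, 4))  # induce non-sphericity
        one = np.einsum("sab,ac->scb", rng.standard_normal((6, 4, 2)), mix)
        Y = np.stack([one, one])
        eff = {e.effect: e for e in rm_anova_mixed(
            design_to_frame(Y), "value", "group", ["A", "B"])}
        wide = pd.DataFrame(Y.mean(axis=3).reshape(12, 4))
        eps_pg = pg.epsilon(wide, correction="gg")
        assert eff["A"].epsilon == pytest.approx(float(eps_pg), abs=1e-10)

    def test_missing_cell_reported(self, rng):
        df = design_to_frame(random_design(rng))
        df = df[~((df.subject == "g0s1") & (df.A == "a2") & (df.B == "b0"))]
        with pytest.raises(ValidationError, match="g0s1"):
            rm_anova_mixed(df, "value", "group", ["A", "B"])


class TestPostHoc:
    def _frame(self, rng, shift=0.0):
        rows = []
        for s in range(8):
            base = rng.standard_normal()
            for i, lv in enumerate(["FP10", "FP20", "FP30"]):
                rows.append({"subject": f"s{s}", "cond": lv,
                             "value": base + rng.standard_normal() * 0.3
                             + shift * i})
        return pd.DataFrame(rows)

    def test_identical_pairs_report_null_result(self):
        df = pd.DataFrame({
            "subject": list("aabb"), "cond": ["x", "y"] * 2,
            "value": [1.0, 1.0, 2.0, 2.0],
        })
        res = bonferroni_paired_t(df, "value", "cond", [("x", "y")])[0]
        assert res.p_bonferroni == 1.0
        assert res.g_av == 0.0

    def test_bonferroni_multiplies_and_caps(self, rng):
        df = self._frame(rng, shift=0.5)
        pairs = [("FP10", "FP20"), ("FP10", "FP30"), ("FP20", "FP30")]
        for res in bonferroni_paired_t(df, "value", "cond", pairs):
            assert res.p_bonferroni == pytest.approx(min(1.0, 3 * res.p_raw))

    def test_unknown_level_rejected(self, rng):
        with pytest.raises(ValidationError):
            bonferroni_paired_t(self._frame(rng), "value", "cond", [("FP10", "zz")])


class TestDescriptives:
    def test_cell_summaries(self):
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"], "v": [1.0, 2.0, 3.0, 7.0]})
        out = descriptive_summary(df, "v", ["g"]).set_index("g")
        cell = out.loc["a"]
        assert cell["mean"] == 2.0
        assert (cell["min"], cell["max"]) == (1.0, 3.0)
        assert cell["se"] == pytest.approx(cell["sd"] / np.sqrt(3))
        single = out.loc["b"]
        assert single["sd"] == 0.0 and single["n"] == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            descriptive_summary(pd.DataFrame(columns=["g", "v"]), "v", ["g"])


class TestPreliminaryChecks:
    def _frame(self, rng, n=50, var_ratio=1.0):
        rows = []
        for g, scale in (("patient", np.sqrt(var_ratio)), ("control", 1.0)):
            for v in rng.standard_normal(n) * scale:
                rows.append({"group": g, "cond": "c1", "value": v})
        return pd.DataFrame(rows)

    def test_shapiro_p_uniform_under_gaussian_null(self, rng):
        from scipy import stats as sps

        ps = []
        for _ in range(300):
            out = preliminary_checks(self._frame(rng), "value", "group", ["cond"])
            ps.extend(out["shapiro_p"].tolist())
        d = sps.kstest(ps, "uniform").statistic
        assert d < 0.1

    def test_levene_calibration_and_power(self, rng):
        null_rej = np.mean([
            preliminary_checks(self._frame(rng), "value", "group", ["cond"])
            ["levene_p"].iloc[0] < 0.05
            for _ in range(200)
        ])
        assert null_rej == pytest.approx(0.05, abs=0.04)
        power = np.mean([
            preliminary_checks(self._frame(rng, var_ratio=10.0), "value",
                               "group", ["cond"])["levene_p"].iloc[0] < 0.05
            for _ in range(100)
        ])
        assert power > 0.95

    def test_small_cell_rejected(self, rng):
        df = self._frame(rng, n=2)
        with pytest.raises(ValidationError):
            preliminary_checks(df, "value", "group", ["cond"])
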