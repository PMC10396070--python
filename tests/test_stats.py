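"""Statistical harness against independent general-linear-model oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cutext.stats import (
    DesignError,
    ancova_one_covariate,
    cohens_d,
    mixed_anova,
    one_way_anova,
    pearson_corr,
    tukey_hsd,
)

TOY_GROUPS = [
    [12.1, 14.3, 11.8, 13.0, 12.6],
    [15.2, 16.1, 14.8, 15.9, 16.4],
    [11.0, 10.2, 12.4, 11.7, 10.9],
]


def textbook_f(groups):
    """Independent sums-of-squares oracle (textbook formulas, no reuse)."""
    allv = [x for g in groups for x in g]
    grand = sum(allv) / len(allv)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((x - sum(g) / len(g)) ** 2 for g in groups for x in g)
    df1, df2 = len(groups) - 1, len(allv) - len(groups)
    return (ssb / df1) / (ssw / df2), df1, df2


class TestOneWayAnova:
    def test_matches_textbook_oracle_to_1e9(self):
        res = one_way_anova(TOY_GROUPS)
        F, df1, df2 = textbook_f(TOY_GROUPS)
        assert res.F == pytest.approx(F, abs=1e-9)
        assert (res.df_between, res.df_within) == (df1, df2)
        assert res.p == pytest.approx(sps.f.sf(F, df1, df2), abs=1e-12)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(i * 0.5, 1, size=n) for i, n in enumerate([8, 12, 9, 7])]
        res = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_two_groups_equal_pooled_t_squared(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        res = one_way_anova([a, b])
        t = sps.ttest_ind(a, b).statistic
        assert res.F == pytest.approx(t**2, abs=1e-9)

    def test_identical_constants_degenerate(self):
        res = one_way_anova([[3.0, 3.0, 3.0], [3.0, 3.0]])
        assert res.degenerate and math.isnan(res.F) and math.isnan(res.p)

    def test_small_group_rejected(self):
        with pytest.raises(DesignError, match="n >= 2"):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestTukey:
    def test_matches_scipy_tukey_hsd(self, rng):
        groups = [rng.normal(i, 1, size=n) for i, n in enumerate([9, 11, 8])]
        mine = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        ci = ref.confidence_interval()
        for pw, (i, j) in zip(mine, [(0, 1), (0, 2), (1, 2)]):
            assert pw.p_tukey == pytest.approx(ref.pvalue[i, j], abs=1e-9)
            assert pw.ci95[0] == pytest.approx(ci.low[i, j], abs=1e-9)
            assert pw.ci95[1] == pytest.approx(ci.high[i, j], abs=1e-9)

    def test_identical_groups_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        pw = tukey_hsd([g, list(g), [5.0, 6.0, 7.0, 8.0]])[0]
        assert pw.p_tukey == pytest.approx(1.0, abs=1e-9)

    def test_huge_separation_tiny_p(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(15, 1, 20)
        pw = tukey_hsd([a, b])[0]
        assert pw.p_tukey < 1e-6

    def test_ci_contains_mean_diff(self, rng):
        groups = [rng.normal(i, 1, 10) for i in range(3)]
        for pw in tukey_hsd(groups):
            assert pw.ci95[0] <= pw.mean_diff <= pw.ci95[1]

    def test_p_at_least_unadjusted_t(self, rng):
        """Multiplicity monotonicity: Tukey never claims more than the
        unadjusted pairwise t sharing the same pooled error term (LSD)."""
        for _ in range(25):
            groups = [
                rng.normal(rng.normal(0, 0.5), 1, size=int(rng.integers(5, 15)))
                for _ in range(int(rng.integers(3, 6)))
            ]
            k = len(groups)
            n_total = sum(len(g) for g in groups)
            df_err = n_total - k
            msw = sum(
                ((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups
            ) / df_err
            pws = tukey_hsd(groups)
            idx = 0
            for i in range(k):
                for j in range(i + 1, k):
                    se = math.sqrt(msw * (1 / len(groups[i]) + 1 / len(groups[j])))
                    t = abs(np.mean(groups[i]) - np.mean(groups[j])) / se
                    t_p = 2 * sps.t.sf(t, df_err)
                    assert pws[idx].p_tukey >= t_p - 1e-12
                    idx += 1


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3], [2, 1, 3]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0, abs=1e-12)

    def test_one_pooled_sd_apart(self, rng):
        a = rng.normal(0, 1, 5000)
        b = a + 1.0  # identical spread, shifted by exactly one SD-ish
        d = cohens_d(b, a)
        assert d == pytest.approx(1.0 / np.std(a, ddof=1), rel=1e-9)

    def test_zero_spread_undefined(self):
        assert math.isnan(cohens_d([2.0, 2.0], [2.0, 2.0]))


class TestMixedAnova:
    @staticmethod
    def _balanced(rng, g=3, n=8, group_eff=1.0, mod_eff=2.0, inter=0.0):
        triples, rows = [], []
        for gi in range(g):
            for s in range(n):
                base = rng.normal(gi * group_eff, 1)
                w = base + rng.normal(0, 0.5)
                sp = base + mod_eff + gi * inter + rng.normal(0, 0.5)
                triples.append((f"g{gi}", w, sp))
                rows += [
                    {"subj": f"g{gi}s{s}", "group": f"g{gi}", "mod": "w", "y": w},
                    {"subj": f"g{gi}s{s}", "group": f"g{gi}", "mod": "s", "y": sp},
                ]
        return triples, pd.DataFrame(rows)

    def test_matches_pingouin_glm_oracle_to_1e9(self, rng):
        pg = pytest.importorskip("pingouin")
        triples, df = self._balanced(rng)
        res = mixed_anova(triples)
        aov = pg.mixed_anova(
            data=df, dv="y", within="mod", subject="subj", between="group"
        ).set_index("Source")
        assert res.between.F == pytest.approx(aov.loc["group", "F"], abs=1e-9)
        assert res.within.F == pytest.approx(aov.loc["mod", "F"], abs=1e-9)
        assert res.interaction.F == pytest.approx(aov.loc["Interaction", "F"], abs=1e-9)
        assert res.within.p == pytest.approx(aov.loc["mod", "p_unc"], abs=1e-9)

    def test_identical_modalities_give_zero_within_f(self, rng):
        triples = [("a", v, v) for v in rng.normal(0, 1, 6)] + [
            ("b", v, v) for v in rng.normal(1, 1, 6)
        ]
        res = mixed_anova(triples)
        assert res.within.F == pytest.approx(0.0)

    def test_planted_modality_shift_detected_without_group_effect(self, rng):
        triples, _ = self._balanced(rng, group_eff=0.0, mod_eff=3.0)
        res = mixed_anova(triples)
        assert res.within.p < 1e-6
        assert res.between.p > 0.01

    def test_single_group_reduces_to_paired_t_squared(self, rng):
        pairs = [(float(rng.normal(10, 2)), float(rng.normal(11, 2))) for _ in range(9)]
        res = mixed_anova([("only", w, s) for w, s in pairs])
        t = sps.ttest_rel([w for w, _ in pairs], [s for _, s in pairs])
        assert res.within.F == pytest.approx(t.statistic**2, abs=1e-9)
        assert math.isnan(res.between.F)

    def test_modality_contrast_ci_contains_diff(self, rng):
        triples, _ = self._balanced(rng)
        for pw in mixed_anova(triples).modality_contrasts:
            assert pw.ci95[0] <= pw.mean_diff <= pw.ci95[1]


class TestPearson:
    def test_perfect_lines(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_corr(x, x)[0] == pytest.approx(1.0)
        assert pearson_corr(x, [-2 * v + 3 for v in x])[0] == pytest.approx(-1.0)

    def test_five_point_closed_form(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        # closed-form Pearson on centered sums
        sx = sum((a - 3.0) ** 2 for a in x)
        sy = sum((b - 3.0) ** 2 for b in y)
        sxy = sum((a - 3.0) * (b - 3.0) for a, b in zip(x, y))
        r_ref = sxy / math.sqrt(sx * sy)
        r, p = pearson_corr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        t = r_ref * math.sqrt(3 / (1 - r_ref**2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), 3), abs=1e-12)

    def test_zero_variance_undefined(self):
        r, p = pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(r) and math.isnan(p)


class TestAncova:
    def test_matches_statsmodels_glm_oracle_to_1e9(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        y = np.concatenate([rng.normal(i, 1, 9) for i in range(3)])
        labels = ["a"] * 9 + ["b"] * 9 + ["c"] * 9
        cov = rng.normal(0, 1, 27) + 0.4 * y
        F, p, p_cov = ancova_one_covariate(y, labels, cov)
        fit = smf.ols(
            "y ~ x + C(g)", data=pd.DataFrame({"y": y, "g": labels, "x": cov})
        ).fit()
        tab = anova_lm(fit, typ=2)
        assert F == pytest.approx(tab.loc["C(g)", "F"], abs=1e-9)
        assert p == pytest.approx(tab.loc["C(g)", "PR(>F)"], abs=1e-9)
        assert p_cov == pytest.approx(tab.loc["x", "PR(>F)"], abs=1e-9)

    def test_constant_covariate_reduces_to_anova(self, rng):
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        y = np.concatenate(groups)
        labels = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        F, p, p_cov = ancova_one_covariate(y, labels, np.ones_like(y))
        ref = one_way_anova(groups)
        assert F == pytest.approx(ref.F, abs=1e-12)
        assert math.isnan(p_cov)

    def test_uncorrelated_covariate_barely_changes_f(self, rng):
        groups = [rng.normal(i * 2, 1, 40) for i in range(3)]
        y = np.concatenate(groups)
        labels = ["a"] * 40 + ["b"] * 40 + ["c"] * 40
        F, _, _ = ancova_one_covariate(y, labels, rng.normal(0, 1, 120))
        assert F == pytest.approx(one_way_anova(groups).F, rel=0.1)

    def test_outcome_explained_by_covariate_gives_group_p_one(self, rng):
        x = rng.normal(0, 1, 24)
        y = 2.0 * x + 0.5
        labels = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        F, p, p_cov = ancova_one_covariate(y, labels, x)
        assert p == pytest.approx(1.0)
        assert p_cov == pytest.approx(0.0, abs=1e-12)
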