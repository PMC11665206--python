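"""Cohen kappa, ICC, ANOVA/Bonferroni and group summaries."""

import numpy as np
import pytest

from svef3d.agreement import (
    ConfusionMatrix,
    cohen_kappa,
    group_summary,
    icc,
    oneway_anova_bonferroni,
)
from svef3d.io import fixture_confusion_matrix


def _kappa_oracle(counts):
    """Independent Po/Pe computation in plain float arithmetic."""
    c = np.asarray(counts, float)
    n = c.sum()
    po = np.trace(c) / n
    pe = (c.sum(1) * c.sum(0)).sum() / n**2
    return (po - pe) / (1 - pe), 100 * po


class TestCohenKappa:
    def test_culprit_confusion_table(self):
        res = cohen_kappa(fixture_confusion_matrix())
        assert round(res.kappa, 3) == 0.672
        assert round(res.percent_agreement, 1) == 81.8

    def test_perfect_agreement(self):
        res = cohen_kappa(ConfusionMatrix(np.eye(4, dtype=int) * 7))
        assert res.kappa == 1.0
        assert res.percent_agreement == 100.0

    def test_chance_only_agreement_is_zero(self):
        # rank-one table: counts proportional to row x column marginals
        res = cohen_kappa(ConfusionMatrix(np.outer([10, 20, 30], [6, 3, 1]) // 1))
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_invariance_under_category_permutation(self):
        rng = np.random.default_rng(1)
        c = rng.integers(0, 20, (4, 4))
        perm = rng.permutation(4)
        a = cohen_kappa(ConfusionMatrix(c))
        b = cohen_kappa(ConfusionMatrix(c[np.ix_(perm, perm)]))
        assert a.kappa == pytest.approx(b.kappa, abs=1e-14)
        assert a.se == pytest.approx(b.se, abs=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels(self, seed):
        sm = pytest.importorskip("statsmodels.stats.inter_rater")
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 15, (3, 3)) + np.diag(rng.integers(5, 20, 3))
        mine = cohen_kappa(ConfusionMatrix(c))
        ref = sm.cohens_kappa(c)
        assert mine.kappa == pytest.approx(ref.kappa, abs=1e-12)
        assert mine.se == pytest.approx(np.sqrt(ref.var_kappa), abs=2e-3)

    def test_degenerate_single_category_rejected(self):
        with pytest.raises(ValueError, match="single category"):
            cohen_kappa(ConfusionMatrix(np.array([[5, 0], [0, 0]])))

    def test_from_pairs(self):
        m = ConfusionMatrix.from_pairs(["LAD", "LAD", "RCA"], ["LAD", "RCA", "RCA"])
        assert m.n == 3
        assert m.counts[0, 0] == 1 and m.counts[0, 1] == 1 and m.counts[1, 1] == 1


def _icc21_oracle(x):
    """Direct two-way ANOVA mean-squares decomposition."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(1)[:, None] - x.mean(0)[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_duplicated_rater_columns_give_unity(self):
        rng = np.random.default_rng(0)
        col = rng.normal(50, 12, 17)
        res = icc(np.column_stack([col, col]))
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_independent_columns_give_near_zero(self):
        rng = np.random.default_rng(3)
        res = icc(rng.normal(0, 1, (5000, 2)))
        assert res.icc == pytest.approx(0.0, abs=0.05)

    def test_matches_mean_squares_oracle_on_a_small_table(self):
        x = np.array([[9., 2.], [45., 12.], [8., 13.], [15., 20.], [45., 42.], [10., 7.]])
        res = icc(x)
        assert res.icc == pytest.approx(_icc21_oracle(x), abs=1e-10)

    @pytest.mark.parametrize("form", ["ICC(2,1)", "ICC(3,1)", "ICC(1,1)"])
    def test_matches_pingouin(self, form):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        x = rng.normal(50, 10, (17, 1)) + rng.normal(0, 3, (17, 3))
        df = pd.DataFrame({
            "item": np.repeat(np.arange(17), 3),
            "rater": np.tile(np.arange(3), 17),
            "y": x.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="item", raters="rater", ratings="y")
        key = {"ICC(2,1)": "ICC(A,1)", "ICC(3,1)": "ICC(C,1)", "ICC(1,1)": "ICC(1,1)"}[form]
        row = ref[ref.Type == ("ICC1" if key == "ICC(1,1)" else key)]
        if row.empty:  # pingouin labels vary between releases
            row = ref.iloc[[{"ICC(1,1)": 0, "ICC(A,1)": 1, "ICC(C,1)": 2}[key]]]
        mine = icc(x, form=form)
        assert mine.icc == pytest.approx(float(row.ICC.iloc[0]), abs=1e-10)
        lo, hi = row.CI95.iloc[0]
        assert mine.ci[0] == pytest.approx(lo, abs=0.01)
        assert mine.ci[1] == pytest.approx(hi, abs=0.01)

    def test_listwise_deletion_of_incomplete_items(self):
        rng = np.random.default_rng(5)
        x = rng.normal(50, 10, (20, 2))
        x_nan = x.copy()
        x_nan[3, 1] = np.nan
        assert icc(x_nan).icc == pytest.approx(icc(np.delete(x, 3, axis=0)).icc)

    def test_zero_between_item_variance_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            icc(np.full((6, 2), 5.0))


class TestAnova:
    def test_constant_identical_groups_give_zero_f(self):
        res = oneway_anova_bonferroni({"a": [5.0, 5, 5], "b": [5.0, 5, 5]})
        assert res["F"] == pytest.approx(0.0)

    def test_two_groups_f_equals_squared_t(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(50, 10, 30), rng.normal(45, 10, 25)
        res = oneway_anova_bonferroni({"a": a, "b": b})
        t = res["pairwise"][("a", "b")]["t"]
        assert res["F"] == pytest.approx(t**2, rel=1e-10)
        assert res["pairwise"][("a", "b")]["p_adj"] == pytest.approx(
            res["pairwise"][("a", "b")]["p_raw"])  # one comparison, no inflation

    def test_wall_motion_grade_contrast_pattern(self):
        # normal clearly separates from the reduced-contraction grades, but
        # the small akinetic group rarely separates from hypokinetic
        rng = np.random.default_rng(42)
        groups = {
            "normal": rng.normal(52.7, 15.0, 320),
            "hypokinesis": rng.normal(38.0, 14.0, 227),
            "akinesis": rng.normal(30.0, 14.0, 14),
        }
        res = oneway_anova_bonferroni(groups)
        assert res["F"] > 30 and res["p"] < 0.001
        assert res["pairwise"][("normal", "hypokinesis")]["p_adj"] < 0.001
        assert res["pairwise"][("hypokinesis", "akinesis")]["p_adj"] > 0.05

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(50, 10, 20) for k in "abcd"}
        res = oneway_anova_bonferroni(groups)
        assert all(v["p_adj"] <= 1.0 for v in res["pairwise"].values())

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            oneway_anova_bonferroni({"a": [1.0, 2.0], "b": [3.0]})


class TestGroupSummary:
    def test_identical_classes(self):
        res = group_summary(np.r_[1.0, 2, 3, 1, 2, 3], np.r_[0, 0, 0, 1, 1, 1])
        assert res["normal"]["mean"] == res["abnormal"]["mean"]
        assert res["p"] == pytest.approx(1.0)

    def test_constant_classes(self):
        res = group_summary(np.r_[0.0, 0, 1, 1], np.r_[0, 0, 1, 1])
        assert res["normal"] == {"n": 2, "mean": 0.0, "sd": 0.0}
        assert res["abnormal"]["mean"] == 1.0

    def test_recovers_binormal_generator_moments(self):
        from svef3d.phantom import SvefPopulationSpec, sample_svef_population

        data = sample_svef_population(SvefPopulationSpec(seed=14))
        res = group_summary(data.scores, data.labels.astype(bool))
        assert res["normal"]["mean"] == pytest.approx(52.7, abs=3 * 15.0 / np.sqrt(320))
        assert res["abnormal"]["mean"] == pytest.approx(35.5, abs=3 * 14.4 / np.sqrt(241))
        assert res["p"] < 0.001

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            group_summary(np.r_[1.0, 2, 3], np.r_[0, 0, 1])
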