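"""ROC analysis: Mann-Whitney AUC, Youden cutoff, models 1 and 2."""

import numpy as np
import pytest

from svef3d.phantom import SvefPopulationSpec, sample_svef_population
from svef3d.roc import LabeledScores, model2_scores, roc_analysis, stratified_cutoffs
from svef3d.svef import SvefTable


def _brute_force_auc(scores, labels):
    """Pairwise-comparison Mann-Whitney oracle: P(abnormal < normal), ties 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] < neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def _brute_force_youden(scores, labels):
    """Exhaustive scan over all midpoint cutoffs, maximising J."""
    pos, neg = scores[labels == 1], scores[labels == 0]
    distinct = np.unique(scores)
    cands = np.concatenate([[distinct[0] - 1], (distinct[:-1] + distinct[1:]) / 2, [distinct[-1] + 1]])
    best_j, best_c, best_spec = -np.inf, None, -1.0
    for c in cands:
        sens = (pos < c).mean()
        spec = (neg >= c).mean()
        j = sens + spec - 1
        if j > best_j or (j == best_j and spec > best_spec):
            best_j, best_c, best_spec = j, c, spec
    return best_c, best_j


class TestAuc:
    def test_perfect_separation(self):
        data = LabeledScores(np.r_[10.0, 12, 15, 50, 55, 60], np.r_[1, 1, 1, 0, 0, 0])
        res = roc_analysis(data)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(50, 10, 5000)
        labels = rng.integers(0, 2, 5000)
        assert roc_analysis(LabeledScores(scores, labels)).auc == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        scores = rng.integers(0, 30, n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        res = roc_analysis(LabeledScores(scores, labels))
        assert res.auc == pytest.approx(_brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn_direction_convention(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        data = sample_svef_population(SvefPopulationSpec(seed=9))
        res = roc_analysis(data)
        # lower score = abnormal, so sklearn sees the negated scores
        assert res.auc == pytest.approx(
            sklearn.roc_auc_score(data.labels, -data.scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis(LabeledScores(np.r_[1.0, 2.0], np.r_[1, 1]))

    def test_curve_monotone_and_anchored(self):
        data = sample_svef_population(SvefPopulationSpec(seed=1))
        c = roc_analysis(data).curve
        assert tuple(c[0]) == (0.0, 0.0) and tuple(c[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c[:, 0]) >= 0) and np.all(np.diff(c[:, 1]) >= 0)

    def test_hanley_mcneil_interval_brackets_auc(self):
        res = roc_analysis(sample_svef_population(SvefPopulationSpec(seed=3)))
        assert res.ci_auc[0] < res.auc < res.ci_auc[1]
        assert res.ci_auc[1] - res.ci_auc[0] < 0.2


class TestYoudenCutoff:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = np.round(rng.normal(45, 12, 150), 1)
        labels = (rng.random(150) < 0.4).astype(int)
        labels[:2] = [0, 1]
        res = roc_analysis(LabeledScores(scores, labels))
        c, j = _brute_force_youden(scores, labels)
        assert res.cutoff == pytest.approx(c)
        assert res.youden_j == pytest.approx(j)

    def test_binormal_simulation_recovers_the_density_crossing(self):
        # the two printed group distributions cross near 44%; over seeds the
        # Youden cutoff concentrates there and the AUC near the closed form
        aucs, cuts = [], []
        for seed in range(20):
            res = roc_analysis(sample_svef_population(SvefPopulationSpec(seed=seed)))
            aucs.append(res.auc)
            cuts.append(res.cutoff)
        assert np.mean(cuts) == pytest.approx(44.0, abs=2.0)
        assert np.mean(aucs) == pytest.approx(0.796, abs=0.02)

    def test_alternative_closest_corner_criterion(self):
        data = sample_svef_population(SvefPopulationSpec(seed=0))
        youden = roc_analysis(data, criterion="youden")
        closest = roc_analysis(data, criterion="closest")
        assert closest.auc == youden.auc
        assert abs(closest.cutoff - youden.cutoff) < 10.0
        with pytest.raises(ValueError, match="criterion"):
            roc_analysis(data, criterion="best")


def _table(subject, svefs, global_ef):
    return SvefTable(subject_id=subject, svef=dict(zip(range(1, 18), svefs)),
                     global_ef=global_ef)


class TestModel2:
    def test_ratio_scores(self):
        t = _table("a", [44.0] * 8 + [22.0] + [44.0] * 8, 44.0)
        labels = {"a": {s: int(s == 9) for s in range(1, 18)}}
        data = model2_scores([t], labels)
        assert data.model == "model2"
        ratios = dict(zip(range(1, 18), data.scores))
        assert ratios[9] == pytest.approx(0.5)
        assert ratios[1] == pytest.approx(1.0)

    def test_uniform_subject_has_unit_ratios(self):
        t = _table("u", [51.0] * 17, 51.0)
        data = model2_scores([t], {"u": {s: 0 for s in range(1, 18)}})
        assert np.allclose(data.scores, 1.0)

    def test_zero_global_ef_rejected(self):
        t = _table("z", [10.0] * 17, 0.0)
        with pytest.raises(ValueError, match="global EF"):
            model2_scores([t], {"z": {s: 0 for s in range(1, 18)}})


class TestStratifiedCutoffs:
    def test_single_stratum_equals_plain_analysis(self):
        data = sample_svef_population(SvefPopulationSpec(seed=6))
        whole = roc_analysis(data)
        strat = stratified_cutoffs(data, np.zeros(len(data.scores)))
        assert strat[0.0].auc == whole.auc
        assert strat[0.0].cutoff == whole.cutoff

    def test_shifted_strata_yield_ordered_cutoffs(self):
        # emulate low-EF vs preserved-EF subjects: both groups shifted down
        # in the low stratum, so its optimal cutoff must come out lower
        rng = np.random.default_rng(12)
        lo = LabeledScores(
            np.r_[rng.normal(42, 10, 400), rng.normal(26, 10, 300)],
            np.r_[np.zeros(400, int), np.ones(300, int)])
        hi = LabeledScores(
            np.r_[rng.normal(55, 10, 400), rng.normal(38, 10, 300)],
            np.r_[np.zeros(400, int), np.ones(300, int)])
        data = LabeledScores(np.r_[lo.scores, hi.scores], np.r_[lo.labels, hi.labels])
        strata = np.r_[np.full(700, "low"), np.full(700, "high")]
        res = stratified_cutoffs(data, strata)
        assert res["low"].cutoff < res["high"].cutoff

    def test_stratum_with_one_class_rejected(self):
        data = LabeledScores(np.r_[1.0, 2, 3, 4], np.r_[0, 0, 1, 1])
        with pytest.raises(ValueError, match="lacks"):
            stratified_cutoffs(data, np.r_[0, 0, 1, 1])
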