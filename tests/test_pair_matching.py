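import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats
from sklearn.base import clone
from sklearn.metrics import roc_auc_score

from toothpair.pair_matching import (
    HausdorffPairClassifier,
    PairComparison,
    classify,
    cohens_kappa,
    compute_roc,
    enumerate_pairs,
    jitter_export,
    one_way_anova,
    threshold_full_sensitivity,
    threshold_full_specificity,
)


def make_comparisons(sym_values, nonsym_values, tooth_type="central", kind="crown"):
    comps = [
        PairComparison(f"i{k}", f"i{k}", tooth_type, kind, v)
        for k, v in enumerate(sym_values)
    ]
    comps += [
        PairComparison(f"a{k}", f"b{k}", tooth_type, kind, v)
        for k, v in enumerate(nonsym_values)
    ]
    return comps


class TestEnumeratePairs:
    @pytest.mark.parametrize("n,sym,nonsym", [(1, 1, 0), (5, 5, 20), (12, 12, 132)])
    def test_counts(self, n, sym, nonsym):
        pairs = enumerate_pairs([f"p{i}" for i in range(n)], "central")
        got_sym = sum(p.is_symmetric for p in pairs)
        assert got_sym == sym
        assert len(pairs) - got_sym == nonsym

    def test_one_direction_per_ordered_pair(self):
        pairs = enumerate_pairs(["a", "b", "c"], "canine")
        keys = {(p.right_individual, p.left_individual) for p in pairs}
        assert len(keys) == len(pairs) == 9


class TestRoc:
    def test_perfectly_separated(self):
        roc = compute_roc(make_comparisons([1.0, 1.2], [2.0, 3.0]))
        assert roc.auc == pytest.approx(1.0)

    def test_no_signal(self):
        roc = compute_roc(make_comparisons([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert roc.auc == pytest.approx(0.5)

    def test_sensitivity_at_largest_threshold_is_one(self):
        rng = np.random.default_rng(0)
        roc = compute_roc(
            make_comparisons(rng.random(10).tolist(), rng.random(30).tolist())
        )
        assert roc.sensitivity[-1] == 1.0

    def test_matches_sklearn_auc(self):
        rng = np.random.default_rng(5)
        sym = rng.normal(1.0, 0.3, 40)
        nonsym = rng.normal(2.0, 0.5, 120)
        roc = compute_roc(make_comparisons(sym, nonsym))
        y = np.r_[np.ones(40), np.zeros(120)]
        # lower HD means positive, so score is the negated HD
        assert roc.auc == pytest.approx(
            roc_auc_score(y, -np.r_[sym, nonsym]), abs=1e-12
        )

    def test_brute_force_reclassification(self):
        rng = np.random.default_rng(9)
        sym = rng.normal(1, 0.4, 15)
        nonsym = rng.normal(2, 0.4, 35)
        roc = compute_roc(make_comparisons(sym, nonsym))
        for t, se, sp in zip(roc.thresholds, roc.sensitivity, roc.specificity):
            assert se == pytest.approx((sym <= t).mean())
            assert sp == pytest.approx((nonsym > t).mean())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_roc(make_comparisons([1.0], []))


class TestThresholds:
    def test_full_specificity_examples(self):
        roc = compute_roc(make_comparisons([1.0, 1.2], [2.0, 3.0]))
        assert threshold_full_specificity(roc).value == pytest.approx(1.2)
        roc = compute_roc(make_comparisons([1.0, 2.5], [2.0, 3.0]))
        t = threshold_full_specificity(roc)
        assert t.value == pytest.approx(1.0)
        assert classify(make_comparisons([1.0, 2.5], [2.0, 3.0]), t).sensitivity_pct == 50.0

    def test_degenerate_when_negative_is_smallest(self):
        roc = compute_roc(make_comparisons([1.5, 2.0], [1.0, 3.0]))
        t = threshold_full_specificity(roc)
        assert t.degenerate
        assert t.value < 1.0

    def test_full_sensitivity_is_max_symmetric(self):
        roc = compute_roc(make_comparisons([1.0, 2.5], [2.0, 3.0]))
        assert threshold_full_sensitivity(roc).value == 2.5
        roc = compute_roc(make_comparisons([1.7], [2.0]))
        assert threshold_full_sensitivity(roc).value == 1.7

    def test_separable_implies_full_sensitivity_at_threshold(self):
        comps = make_comparisons([0.5, 0.8, 0.9], [1.5, 2.0, 4.0])
        roc = compute_roc(comps)
        cls = classify(comps, threshold_full_specificity(roc))
        assert cls.sensitivity_pct == 100.0
        assert cls.fp == 0


class TestClassify:
    def test_hand_counts(self):
        comps = make_comparisons([1.0, 1.2], [2.0, 3.0])
        c = classify(comps, 1.2)
        assert (c.tp, c.fn, c.fp, c.tn) == (2, 0, 0, 2)
        assert c.sensitivity_pct == 100.0 and c.accuracy_pct == 100.0

    def test_study_scale_arithmetic(self):
        """98/100 matches found, 0/9900 false positives -> 98% sens, 99.98% acc."""
        sym = [1.0] * 98 + [5.0] * 2
        nonsym = [3.0] * 9900
        c = classify(make_comparisons(sym, nonsym), 2.0)
        assert c.sensitivity_pct == pytest.approx(98.0)
        assert c.accuracy_pct == pytest.approx(100 * (98 + 9900) / 10000)
        assert c.accuracy_pct > 99.0

    def test_threshold_below_everything(self):
        c = classify(make_comparisons([1.0, 2.0], [3.0]), 0.5)
        assert c.sensitivity_pct == 0.0 and c.specificity_pct == 100.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        """Counts are unchanged by strictly monotone rescaling of all HDs."""
        rng = np.random.default_rng(seed)
        sym = rng.random(8)
        nonsym = rng.random(20) + 0.2
        comps = make_comparisons(sym, nonsym)
        t = threshold_full_specificity(compute_roc(comps))
        c1 = classify(comps, t)
        f = lambda x: np.log1p(3 * np.asarray(x))
        comps2 = make_comparisons(f(sym), f(nonsym))
        c2 = classify(comps2, float(f([t.value])[0]))
        assert (c1.tp, c1.fn, c1.tn, c1.fp) == (c2.tp, c2.fn, c2.tn, c2.fp)


class TestKappa:
    def test_hand_example(self):
        r = cohens_kappa([[20, 5], [10, 15]])
        assert r.kappa == pytest.approx(0.4)
        assert r.ci_low < 0.4 < r.ci_high

    def test_perfect_and_chance(self):
        assert cohens_kappa([[10, 0], [0, 10]]).kappa == 1.0
        assert cohens_kappa([[9, 3], [3, 1]]).kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        table = np.array([[37, 8], [5, 50]], dtype=float)
        ours = cohens_kappa(table)
        theirs = sm_kappa(table, return_results=True)
        assert ours.kappa == pytest.approx(float(theirs.kappa), abs=1e-12)


class TestAnova:
    def test_equal_means_f_zero(self):
        r = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert r.f == pytest.approx(0.0)

    def test_hand_example(self):
        """SSB = 4, SSW = 1, df (1, 2) -> F = 8."""
        r = one_way_anova([[1, 2], [3, 4]])
        assert r.f == pytest.approx(8.0)
        assert (r.df_between, r.df_within) == (1, 2)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 12) for m in (0.0, 0.4, 1.1)]
        ours = one_way_anova(groups)
        f, p = stats.f_oneway(*groups)
        assert ours.f == pytest.approx(f, rel=1e-12)
        assert ours.p == pytest.approx(p, rel=1e-12)

    def test_p_matches_quadrature(self):
        r = one_way_anova([[1, 2], [3, 4]])
        tail, _ = integrate.quad(
            lambda x: stats.f.pdf(x, r.df_between, r.df_within), r.f, np.inf
        )
        assert r.p == pytest.approx(tail, abs=1e-6)

    def test_degenerate_zero_within(self):
        r = one_way_anova([[1, 1], [2, 2]])
        assert r.degenerate and r.p == 0.0


class TestJitterExport:
    def test_min_rule_and_order_statistics(self):
        rng = np.random.default_rng(4)
        nonsym = rng.random(250) + 2.0
        comps = make_comparisons([0.5, 0.7], nonsym.tolist())
        df = jitter_export(comps, 1.0)
        tn = df[df.label == "TN"].hd.to_numpy()
        assert len(tn) == 100
        assert np.array_equal(tn, np.sort(nonsym)[:100])
        assert (df.label == "TP").sum() == 2

    def test_fewer_negatives_than_cap(self):
        comps = make_comparisons([0.5], (np.arange(50) + 2.0).tolist())
        df = jitter_export(comps, 1.0)
        assert (df.label == "TN").sum() == 50


class TestEstimator:
    def test_sklearn_contract(self):
        est = HausdorffPairClassifier(rule="full_specificity")
        assert clone(est).get_params() == est.get_params()

    def test_fit_predict(self):
        X = np.array([0.5, 0.8, 2.0, 3.0, 4.0])
        y = np.array([1, 1, 0, 0, 0])
        est = HausdorffPairClassifier().fit(X, y)
        assert est.threshold_ == pytest.approx(0.8)
        assert np.array_equal(est.predict(X), y)
        assert est.score(X, y) == 1.0

    def test_fixed_threshold_rule(self):
        est = HausdorffPairClassifier(rule=1.5).fit([1.0, 2.0], [1, 0])
        assert np.array_equal(est.predict([1.4, 1.6]), [1, 0])
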