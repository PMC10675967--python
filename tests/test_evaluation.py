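"""Subsampling splits, performance metrics, importance, experiment loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from clusterlasso.evaluation import (
    ConfusionCounts,
    MetricError,
    SubsampleSplit,
    bernoulli_likelihood,
    brier,
    make_subsamples,
    pr_auc,
    rmse,
    roc_auc,
    run_experiment,
    score_predictions,
    variable_importance,
)
from clusterlasso.lasso import FitResult
from clusterlasso.preprocess import prepare_global
from clusterlasso.synthetic import ScenarioConfig, generate
from tests.conftest import make_dataset


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_scenario(seed=0, H=10):
    cfg = ScenarioConfig(
        n_hospitals=H,
        hospital_size_range=(8, 30),
        n_comorbidity_vars=4,
        tau=0.2,
        seed=seed,
    )
    return generate(cfg)


class TestSubsamples:
    def test_sizes_and_disjointness(self):
        data = split_scenario(seed=1)
        splits = make_subsamples(data, R=20, seed=3)
        assert len(splits) == 20
        n_test = int(round(data.n / 20))
        for s in splits:
            assert len(s.test_idx) == n_test
            assert len(s.train_idx) == data.n - n_test
            assert len(np.intersect1d(s.train_idx, s.test_idx)) == 0

    def test_hospital_coverage_in_train(self):
        data = split_scenario(seed=2)
        labels = set(data.cluster_labels)
        for s in make_subsamples(data, R=20, seed=5):
            assert set(data.cluster[s.train_idx]) == labels

    def test_repair_with_single_patient_hospital(self):
        rng = np.random.default_rng(6)
        # hospital "z" has exactly one patient: it must always stay in train
        cluster = np.array(["a"] * 30 + ["b"] * 30 + ["z"])
        X = rng.integers(0, 2, (61, 3)).astype(float)
        y = rng.exponential(2.0, 61) + 0.1
        data = make_dataset(X, y, cluster=cluster, standardized=False)
        for s in make_subsamples(data, R=20, seed=7):
            assert "z" in set(data.cluster[s.train_idx])

    def test_deterministic_given_seed(self):
        data = split_scenario(seed=3)
        a = make_subsamples(data, R=5, seed=11)
        b = make_subsamples(data, R=5, seed=11)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.test_idx, t.test_idx)
            assert s.checksum() == t.checksum()

    def test_different_replicates_differ(self):
        data = split_scenario(seed=4)
        splits = make_subsamples(data, R=10, seed=13)
        checksums = {s.checksum() for s in splits}
        assert len(checksums) > 1

    def test_too_small_dataset_raises(self):
        data = make_dataset(np.ones((5, 1)), np.arange(5.0) + 1,
                            standardized=False)
        with pytest.raises(ValueError):
            make_subsamples(data, R=1, seed=0)


# ---------------------------------------------------------------------------
# metrics: hand-computed values
# ---------------------------------------------------------------------------

class TestMetricHandValues:
    def test_rmse(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 3.0, 2.0]) == pytest.approx(
            np.sqrt(2.0 / 3.0)
        )

    def test_roc_auc_hand_case(self):
        y = [1, 1, 0, 0]
        p = [0.9, 0.4, 0.6, 0.2]
        # pairs: (.9>.6), (.9>.2), (.4<.6), (.4>.2) -> 3/4
        assert roc_auc(y, p) == pytest.approx(0.75)

    def test_roc_auc_ties_count_half(self):
        assert roc_auc([1, 0], [0.5, 0.5]) == pytest.approx(0.5)

    def test_pr_auc_hand_case(self):
        y = [1, 0, 1, 0]
        p = [0.9, 0.8, 0.7, 0.1]
        # thresholds .9, .8, .7, .1: recall steps 1/2 at P=1 and 1/2 at P=2/3
        assert pr_auc(y, p) == pytest.approx(0.5 * 1.0 + 0.5 * (2.0 / 3.0))

    def test_brier(self):
        y = [1, 0, 1, 0]
        p = [0.9, 0.1, 0.6, 0.4]
        assert brier(y, p) == pytest.approx(
            np.mean([0.01, 0.01, 0.16, 0.16])
        )

    def test_bernoulli_likelihood(self):
        y = [1, 0]
        p = [0.8, 0.4]
        assert bernoulli_likelihood(y, p) == pytest.approx((0.8 + 0.6) / 2)

    def test_bernoulli_likelihood_clips(self):
        assert bernoulli_likelihood([1.0], [0.0]) > 0.0

    def test_confusion_counts(self):
        cc = ConfusionCounts.at_threshold(
            np.array([1, 1, 0, 0]), np.array([0.9, 0.2, 0.8, 0.1]), 0.5
        )
        assert (cc.TP, cc.FP, cc.TN, cc.FN) == (1, 1, 1, 1)

    def test_metric_errors(self):
        with pytest.raises(MetricError):
            roc_auc([1, 1], [0.5, 0.6])
        with pytest.raises(MetricError):
            pr_auc([0, 0], [0.5, 0.6])
        with pytest.raises(MetricError):
            rmse([], [])

    def test_score_predictions_keys(self):
        g = score_predictions(np.array([1.0, 2.0]), np.array([1.5, 1.5]),
                              "gaussian")
        assert set(g) == {"rmse"}
        b = score_predictions(
            np.array([1.0, 0.0, 1.0]), np.array([0.8, 0.2, 0.7]), "binomial"
        )
        assert set(b) == {"auc", "auprc", "brier", "bernoulli_lik"}


# ---------------------------------------------------------------------------
# metrics: property tests against brute force / scikit-learn
# ---------------------------------------------------------------------------

@st.composite
def labelled_scores(draw, max_n=200):
    n = draw(st.integers(4, max_n))
    # coarse score grid so ties actually occur
    p = draw(
        st.lists(st.integers(0, 20), min_size=n, max_size=n).map(
            lambda v: np.array(v) / 20.0
        )
    )
    y = np.array(draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    if y.sum() == 0:
        y[0] = 1
    if y.sum() == len(y):
        y[-1] = 0
    return y, p


class TestMetricProperties:
    @settings(max_examples=250, deadline=None)
    @given(labelled_scores())
    def test_roc_auc_equals_pairwise_brute_force(self, case):
        y, p = case
        pos = p[y == 1][:, None]
        neg = p[y == 0][None, :]
        brute = (np.sum(pos > neg) + 0.5 * np.sum(pos == neg)) / (
            pos.shape[0] * neg.shape[1]
        )
        assert roc_auc(y, p) == pytest.approx(brute, abs=1e-12)
        assert roc_auc(y, p) == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    @settings(max_examples=250, deadline=None)
    @given(labelled_scores())
    def test_pr_auc_equals_threshold_enumeration(self, case):
        y, p = case
        n_pos = y.sum()
        brute = 0.0
        prev_recall = 0.0
        for t in sorted(set(p), reverse=True):
            sel = p >= t
            tp = int(np.sum(y[sel]))
            precision = tp / int(np.sum(sel))
            recall = tp / n_pos
            brute += (recall - prev_recall) * precision
            prev_recall = recall
        assert pr_auc(y, p) == pytest.approx(brute, abs=1e-12)
        # same step-interpolation convention as scikit-learn
        assert pr_auc(y, p) == pytest.approx(
            average_precision_score(y, p), abs=1e-12
        )


# ---------------------------------------------------------------------------
# importance
# ---------------------------------------------------------------------------

def fake_fit(names, coefs):
    return FitResult(
        intercept=0.0,
        beta=np.asarray(coefs, dtype=float),
        var_names=list(names),
        family="gaussian",
        lam=0.1,
        alpha=1.0,
    )


class TestImportance:
    def test_topk_rates_and_mean_coefs(self):
        names = ["a", "b", "c", "d"]
        fits = [
            fake_fit(names, [0.5, 0.0, -0.4, 0.1]),
            fake_fit(names, [0.3, 0.2, 0.0, 0.0]),
        ]
        table = variable_importance(fits, names, k=2).table
        assert table.loc["a", "top5_rate"] == 1.0
        assert table.loc["c", "top5_rate"] == 0.5
        assert table.loc["d", "top5_rate"] == 0.0
        assert table.loc["a", "mean_coef"] == pytest.approx(0.4)
        assert table.loc["c", "mean_coef"] == pytest.approx(-0.4)
        assert np.isnan(table.loc["d", "mean_coef"])

    def test_tie_broken_by_variable_order(self):
        names = ["a", "b", "c"]
        fits = [fake_fit(names, [0.5, -0.5, 0.5])]
        table = variable_importance(fits, names, k=2).table
        assert table.loc["a", "top5_rate"] == 1.0
        assert table.loc["b", "top5_rate"] == 1.0
        assert table.loc["c", "top5_rate"] == 0.0

    def test_shortfall_counted(self):
        names = ["a", "b", "c"]
        imp = variable_importance([fake_fit(names, [0.5, 0.0, 0.0])], names,
                                  k=2)
        assert imp.shortfalls == 1

    def test_formatted_style(self):
        names = ["a", "b"]
        fits = [fake_fit(names, [0.16, 0.0]), fake_fit(names, [0.16, 0.0])]
        out = variable_importance(fits, names, k=1).formatted()
        assert out["a"] == "100% (.16)"
        assert out["b"] == "0% (-)"

    def test_subfit_names_map_into_universe(self):
        # fits from folds that dropped a column still aggregate correctly
        names = ["a", "b", "c"]
        fits = [fake_fit(["a", "c"], [0.5, -0.2])]
        table = variable_importance(fits, names, k=2).table
        assert table.loc["b", "top5_rate"] == 0.0
        assert table.loc["c", "mean_coef"] == pytest.approx(-0.2)


# ---------------------------------------------------------------------------
# experiment loop (small end-to-end smoke)
# ---------------------------------------------------------------------------

class TestRunExperiment:
    def test_small_gaussian_experiment(self):
        cfg = ScenarioConfig(
            n_hospitals=8,
            hospital_size_range=(25, 40),
            n_comorbidity_vars=6,
            beta_true=(0.2, 0.5, -0.5, 0.0, 0.0, 0.0, 0.0),
            tau=0.3,
            seed=31,
        )
        data, _ = prepare_global(generate(cfg))
        splits = make_subsamples(data, R=3, seed=1)
        res = run_experiment(
            data,
            variants=["no_hosps", "hosps_random"],
            criteria=["cv_min", "bic"],
            splits=splits,
            cv_seed=2,
        )
        assert res.failures == []
        agg = res.aggregate
        combos = set(zip(agg.variant, agg.criterion))
        assert ("no_hosps", "cv_min") in combos
        assert ("hosps_random", "bic") in combos
        r = agg[agg.metric == "rmse"]
        assert (r["n"] == 3).all()
        assert np.allclose(r["se"], r["sd"] / np.sqrt(3))
        # importance built from the cv_min fits of both variants
        assert set(res.importance) == {"no_hosps", "hosps_random"}
        for table in res.importance.values():
            assert table.n_replicates == 3

    def test_cv_1se_not_offered_for_mixed(self):
        cfg = ScenarioConfig(
            n_hospitals=6,
            hospital_size_range=(25, 35),
            n_comorbidity_vars=4,
            beta_true=(0.2, 0.5, -0.4, 0.0, 0.0),
            tau=0.2,
            seed=33,
        )
        data, _ = prepare_global(generate(cfg))
        splits = make_subsamples(data, R=2, seed=1)
        res = run_experiment(
            data,
            variants=["hosps_random"],
            criteria=["cv_1se", "bic"],
            splits=splits,
            cv_seed=2,
        )
        assert set(res.metrics.criterion.unique()) == {"bic"}
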