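import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxprofiler import (
    BalancedForestProtocol,
    FEATURE_SUBSETS,
    ablation_compare,
    balanced_subsample,
    roc_auc,
    run_protocol,
)

from oracles import pairwise_auc


class TestBalancedSubsample:
    def test_minority_fully_included(self):
        toxic = [f"t{i}" for i in range(3)]
        nontoxic = [f"n{i}" for i in range(10)]
        chosen = balanced_subsample(toxic, nontoxic, seed=0)
        assert len(chosen) == 6
        assert set(toxic) <= set(chosen)
        assert len(set(chosen)) == 6

    def test_already_balanced_keeps_everything(self):
        toxic = ["t0", "t1"]
        nontoxic = ["n0", "n1"]
        assert sorted(balanced_subsample(toxic, nontoxic, seed=5)) == sorted(
            toxic + nontoxic
        )

    def test_roles_swap_when_toxic_is_majority(self):
        toxic = [f"t{i}" for i in range(10)]
        nontoxic = ["n0", "n1"]
        chosen = balanced_subsample(toxic, nontoxic, seed=1)
        assert len(chosen) == 4 and set(nontoxic) <= set(chosen)

    def test_deterministic_given_seed(self):
        toxic = [f"t{i}" for i in range(5)]
        nontoxic = [f"n{i}" for i in range(50)]
        assert balanced_subsample(toxic, nontoxic, 7) == balanced_subsample(
            toxic, nontoxic, 7
        )
        assert balanced_subsample(toxic, nontoxic, 7) != balanced_subsample(
            toxic, nontoxic, 8
        )

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            balanced_subsample([], ["n0"], seed=0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_half_concordant_pairs(self):
        assert roc_auc([0.9, 0.2, 0.8, 0.3], [1, 1, 0, 0]) == 0.5

    def test_all_tied_scores(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(4, 201))
            labels = np.zeros(n, bool)
            labels[: int(rng.integers(1, n))] = True
            rng.shuffle(labels)
            scores = np.round(rng.random(n), 2)  # rounding induces ties
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )

    @given(
        st.lists(
            st.floats(0, 1).map(lambda x: round(x, 6)), min_size=4, max_size=40
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_complement_and_monotone_invariance(self, raw):
        n = len(raw)
        labels = np.array([i % 2 == 0 for i in range(n)])
        scores = np.asarray(raw)
        if len(np.unique(scores)) == n:  # complement identity needs no ties
            assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)
        assert roc_auc(np.exp(3 * scores), labels) == pytest.approx(
            roc_auc(scores, labels)
        )


def make_features(n, seed, oracle=False):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "positive_count": rng.integers(0, 60, n),
            "pI": rng.uniform(4, 11, n),
            "length": rng.integers(30, 900, n),
            "is_tf": rng.random(n) < 0.05,
            "is_regulatory": rng.random(n) < 0.15,
            "is_catalytic": rng.random(n) < 0.5,
        },
        index=[f"p{i}" for i in range(n)],
    )
    y = rng.random(n) < 0.3
    if oracle:
        X["oracle"] = y.astype(float)
    return X, y


class TestRunProtocol:
    def test_report_shape_and_mean(self):
        X, y = make_features(300, seed=1)
        rep = run_protocol(X, y, "SEQUENCE", n_repetitions=3, seed=2, n_estimators=30)
        assert rep.feature_subset_name == "SEQUENCE"
        assert rep.feature_names == FEATURE_SUBSETS["SEQUENCE"]
        assert len(rep.per_rep_auc) == 3
        assert rep.mean_auc == pytest.approx(np.mean(rep.per_rep_auc))

    def test_bit_reproducible_given_seed(self):
        X, y = make_features(300, seed=3)
        r1 = run_protocol(X, y, "COMBINED", n_repetitions=3, seed=9, n_estimators=40)
        r2 = run_protocol(X, y, "COMBINED", n_repetitions=3, seed=9, n_estimators=40)
        assert r1.per_rep_auc == r2.per_rep_auc

    def test_chance_level_on_label_independent_features(self):
        X, y = make_features(2000, seed=4)
        rep = run_protocol(X, y, "COMBINED", n_repetitions=3, seed=0, n_estimators=100)
        assert 0.45 <= rep.mean_auc <= 0.55

    def test_oracle_feature_saturates_auc(self):
        X, y = make_features(400, seed=5, oracle=True)
        rep = run_protocol(X, y, ["oracle"], n_repetitions=3, seed=0, n_estimators=50)
        assert rep.mean_auc >= 0.99

    def test_constant_feature_warns_but_runs(self):
        X, y = make_features(200, seed=6)
        X["flat"] = 1.0
        with pytest.warns(UserWarning, match="flat"):
            rep = run_protocol(X, y, ["positive_count", "flat"],
                               n_repetitions=2, seed=0, n_estimators=20)
        assert len(rep.per_rep_auc) == 2

    def test_split_holdout_route(self):
        X, y = make_features(500, seed=7, oracle=True)
        rep = run_protocol(X, y, ["oracle"], n_repetitions=2, seed=0,
                           n_estimators=30, holdout="split")
        assert rep.mean_auc >= 0.99

    def test_single_class_cohort_raises(self):
        X, _ = make_features(50, seed=8)
        with pytest.raises(ValueError):
            run_protocol(X, np.ones(50, bool), "SEQUENCE", n_repetitions=1, seed=0)


class TestEstimatorInterface:
    def test_fitted_attributes_and_predict(self):
        X, y = make_features(300, seed=10, oracle=True)
        est = BalancedForestProtocol(
            feature_names=["oracle"], n_repetitions=2, n_estimators=30, random_state=0
        )
        est.fit(X, y)
        assert hasattr(est, "report_") and len(est.estimators_) == 2
        proba = est.predict_proba(X)
        assert proba.shape == (300, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        acc = (est.predict(X) == y).mean()
        assert acc > 0.95

    def test_get_params_round_trip(self):
        est = BalancedForestProtocol(n_repetitions=4, holdout="split", random_state=3)
        clone = BalancedForestProtocol(**est.get_params())
        assert clone.get_params() == est.get_params()

    def test_bad_holdout_rejected(self):
        X, y = make_features(60, seed=11)
        with pytest.raises(ValueError):
            BalancedForestProtocol(holdout="loocv").fit(X, y)


class TestAblationCompare:
    def test_three_named_reports_with_same_seed_schedule(self):
        X, y = make_features(300, seed=12)
        reports = ablation_compare(X, y, seed=1, n_repetitions=2, n_estimators=20)
        assert [r.feature_subset_name for r in reports] == [
            "SEQUENCE", "FUNCTION", "COMBINED",
        ]
        assert all(len(r.per_rep_auc) == 2 for r in reports)
        assert all(r.seed == 1 for r in reports)

    def test_custom_extra_subset(self):
        X, y = make_features(300, seed=13)
        X["in_complex"] = np.random.default_rng(0).random(300) < 0.25
        reports = ablation_compare(
            X, y, seed=1, n_repetitions=2, n_estimators=20,
            extra_subsets={"COMBINED_plus_complex": FEATURE_SUBSETS["COMBINED"] + ["in_complex"]},
        )
        assert reports[-1].feature_subset_name == "COMBINED_plus_complex"
        assert "in_complex" in reports[-1].feature_names
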