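import math
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxprofiler import (
    LabeledCohort,
    bin_toxicity_trend,
    class_minus_class,
    enrichment_scan,
    equal_freq_bins,
    fisher_2x2,
    rank_sum_test,
    two_sample_t,
)
from toxprofiler.data_io import FluorescenceClass, GrowthClass, ProteinRecord

from oracles import fisher_oracle, rank_sum_oracle


def make_cohort(flags, go_sets=None, name="ALL"):
    records = [
        ProteinRecord(
            f"p{i}", "MKR", GrowthClass.SLOW_GROWTH, FluorescenceClass.FLUORESCENCE,
            go_classes=frozenset(go_sets[i]) if go_sets else frozenset(),
        )
        for i in range(len(flags))
    ]
    return LabeledCohort(records, np.asarray(flags, dtype=bool), name)


class TestRankSum:
    def test_exact_small_sample(self):
        r = rank_sum_test([1, 2], [3, 4])
        assert r.p_value == pytest.approx(1 / 3)
        assert r.effect_direction == -1

    def test_identical_groups_null_center(self):
        r = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert r.p_value == 1.0
        assert r.effect_direction == 0

    def test_extreme_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1000, 1, 50)
        b = rng.normal(0, 1, 50)
        r = rank_sum_test(a, b)
        assert r.p_value < 1e-10
        assert r.effect_direction == 1

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_matches_enumeration_for_small_pooled_n(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n1 = int(rng.integers(1, 7))
            n2 = int(rng.integers(1, 13 - n1))
            pool = rng.permutation(1000)[: n1 + n2].astype(float)
            a, b = pool[:n1], pool[n1:]
            assert rank_sum_test(a, b).p_value == pytest.approx(
                rank_sum_oracle(a, b), abs=1e-12
            )

    @given(
        st.lists(st.integers(0, 1000), min_size=2, max_size=30, unique=True),
        st.integers(1, 29),
    )
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_monotone_transform(self, pool, split):
        split = min(split, len(pool) - 1)
        a = np.array(pool[:split], dtype=float)
        b = np.array(pool[split:], dtype=float)
        r1 = rank_sum_test(a, b)
        r2 = rank_sum_test(np.exp(a / 100), np.exp(b / 100))
        assert r1.p_value == pytest.approx(r2.p_value)


class TestFisher:
    def test_diagonal_table(self):
        r = fisher_2x2([[2, 0], [0, 2]])
        assert r.p_value == pytest.approx(1 / 3)

    def test_no_association(self):
        r = fisher_2x2([[5, 5], [5, 5]])
        assert r.p_value == 1.0
        assert r.statistic == pytest.approx(1.0)

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            fisher_2x2([[1, -1], [0, 2]])

    def test_zero_cell_odds_ratio_infinite(self):
        assert math.isinf(fisher_2x2([[3, 1], [0, 4]]).statistic)

    def test_matches_enumeration_on_random_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 9, size=4))
            if a + b + c + d == 0:
                continue
            assert fisher_2x2([[a, b], [c, d]]).p_value == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            )

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    @settings(deadline=None, max_examples=100)
    def test_invariant_under_transpose_and_double_swap(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_2x2([[a, b], [c, d]]).p_value
        assert fisher_2x2([[a, c], [b, d]]).p_value == pytest.approx(p, abs=1e-12)
        assert fisher_2x2([[d, c], [b, a]]).p_value == pytest.approx(p, abs=1e-12)


class TestTwoSampleT:
    def test_clear_separation(self):
        r = two_sample_t([0.0, 0.0], [1.0, 1.0])
        assert r.group_summaries == ((2, 0.0), (2, 1.0))
        assert r.effect_direction == -1

    def test_identical_degenerate_groups(self):
        r = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_matches_closed_form_welch(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.000, 1, 2000)
        b = rng.normal(0.003, 1, 2000)
        r = two_sample_t(a, b)
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert r.statistic == pytest.approx((a.mean() - b.mean()) / se)


class TestEqualFreqBins:
    def test_distinct_values_exact_split(self):
        assignment = equal_freq_bins(np.arange(100.0), k=20, seed=0)
        sizes = np.bincount(assignment)
        assert (sizes == 5).all()
        # contiguity: bin index must be sorted along sorted values
        assert (np.diff(assignment[np.argsort(np.arange(100.0))]) >= 0).all()

    def test_all_ties_split_evenly(self):
        sizes = np.bincount(equal_freq_bins([1.0, 1.0, 1.0, 1.0], k=2, seed=1))
        assert sorted(sizes) == [2, 2]

    def test_uneven_split_pigeonhole(self):
        sizes = np.bincount(equal_freq_bins(np.arange(101.0), k=20, seed=0))
        assert sizes.sum() == 101
        assert sizes.max() - sizes.min() == 1
        assert sorted(sizes)[-1] == 6 and (sizes == 5).sum() == 19

    def test_deterministic_given_seed(self):
        vals = np.random.default_rng(2).integers(0, 5, 60).astype(float)
        a1 = equal_freq_bins(vals, k=6, seed=9)
        a2 = equal_freq_bins(vals, k=6, seed=9)
        assert (a1 == a2).all()

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            equal_freq_bins([1.0, 2.0], k=3)


class TestBinToxicityTrend:
    def test_step_function_gives_positive_slope(self):
        vals = np.arange(40.0)
        flags = vals > np.median(vals)
        prof = bin_toxicity_trend(vals, flags, k=4, fit_kind="LINEAR")
        assert prof.bin_percent_toxic.tolist() == [0.0, 0.0, 100.0, 100.0]
        assert prof.fit_coefficients[0] > 0

    def test_all_nontoxic_flat(self):
        prof = bin_toxicity_trend(np.arange(40.0), np.zeros(40, bool), k=4)
        assert (prof.bin_percent_toxic == 0).all()
        assert prof.fit_coefficients[0] == pytest.approx(0.0, abs=1e-9)

    def test_u_shape_recovered_by_quadratic(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(3, 11, 400)
        flags = rng.random(400) < 1 / (1 + np.exp(-((vals - 7) ** 2 - 4)))
        prof = bin_toxicity_trend(vals, flags, k=20, fit_kind="QUADRATIC")
        assert prof.fit_coefficients[0] > 0

    def test_weighted_bin_average_equals_cohort_rate(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=203)
        flags = rng.random(203) < 0.3
        prof = bin_toxicity_trend(vals, flags, k=20)
        weighted = (prof.bin_percent_toxic * prof.bin_n).sum() / prof.bin_n.sum()
        assert weighted == pytest.approx(100 * flags.mean())

    def test_unknown_fit_kind_raises(self):
        with pytest.raises(ValueError):
            bin_toxicity_trend([1.0, 2.0], [True, False], k=2, fit_kind="CUBIC")


class TestEnrichmentScan:
    def test_fully_toxic_class_tops_ranking(self):
        flags = [True] * 10 + [False] * 30
        go = [{"hot"} if f else set() for f in flags]
        cohort = make_cohort(flags, go)
        results = enrichment_scan(cohort, {"hot": {f"p{i}" for i in range(10)}},
                                  min_size=5)
        assert results[0].class_id == "hot"
        assert results[0].percent_toxic_in_class == 100.0
        assert results[0].p_value < 1e-6

    def test_class_covering_cohort_degenerate(self):
        cohort = make_cohort([True] * 5 + [False] * 5)
        results = enrichment_scan(
            cohort, {"all": {f"p{i}" for i in range(10)}}, min_size=2
        )
        assert results[0].p_value == 1.0
        assert math.isnan(results[0].odds_ratio)

    def test_min_size_floor_applied(self):
        cohort = make_cohort([True, False, False, False])
        results = enrichment_scan(cohort, {"tiny": {"p0"}}, min_size=2)
        assert results == []

    def test_disjoint_cover_sums_to_cohort_toxics(self):
        rng = np.random.default_rng(12)
        flags = rng.random(60) < 0.4
        half_a = {f"p{i}" for i in range(30)}
        half_b = {f"p{i}" for i in range(30, 60)}
        cohort = make_cohort(flags)
        results = enrichment_scan(cohort, {"a": half_a, "b": half_b}, min_size=1)
        assert sum(r.n_toxic_in_class for r in results) == int(flags.sum())

    def test_q_values_monotone_with_p(self):
        rng = np.random.default_rng(13)
        flags = rng.random(100) < 0.3
        classes = {
            f"c{j}": {f"p{i}" for i in rng.choice(100, 40, replace=False)}
            for j in range(5)
        }
        results = enrichment_scan(make_cohort(flags), classes, min_size=10)
        ps = [r.p_value for r in results]
        qs = [r.q_value for r in results]
        assert ps == sorted(ps)
        assert all(q >= p for p, q in zip(ps, qs))


def test_class_minus_class():
    assert class_minus_class({"1", "2", "3"}, {"2"}) == {"1", "3"}
    assert class_minus_class({"1"}, {"1"}) == set()
    assert class_minus_class({"1", "2"}, {"3"}) == {"1", "2"}
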