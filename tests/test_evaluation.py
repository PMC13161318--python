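"""Cluster scoring: matching, ranking metrics, concordance, KM, bootstrap."""

from itertools import permutations

import numpy as np
import pytest

from survclust import SurvivalCohort
from survclust.evaluation import (
    apply_permutation,
    bootstrap_cindex,
    cluster_c_index,
    derive_risk_order,
    evaluate_clustering,
    km_curve,
    match_clusters,
    paired_bootstrap_pvalue,
    per_class_auroc_auprc,
)


class TestMatching:
    def test_identity_and_swap(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        np.testing.assert_array_equal(match_clusters(truth, truth, 3), [0, 1, 2])
        swapped = truth.copy()
        swapped[truth == 0], swapped[truth == 1] = 1, 0
        perm = match_clusters(swapped, truth, 3)
        np.testing.assert_array_equal(perm, [1, 0, 2])

    def test_matches_brute_force_on_random_confusions(self, rng):
        def agreement(pred, truth, perm):
            return (np.asarray(perm)[pred] == truth).sum()

        for _ in range(10):
            truth = rng.integers(0, 3, 60)
            pred = rng.integers(0, 3, 60)
            perm = match_clusters(pred, truth, 3)
            best = max(
                agreement(pred, truth, p) for p in permutations(range(3))
            )
            assert agreement(pred, truth, perm) == best

    def test_large_k_uses_optimal_assignment(self, rng):
        truth = rng.integers(0, 9, 400)
        noisy = truth.copy()
        flip = rng.random(400) < 0.2
        noisy[flip] = rng.integers(0, 9, flip.sum())
        shuffled = (noisy + 4) % 9  # relabel by a known permutation
        perm = match_clusters(shuffled, truth, 9)
        np.testing.assert_array_equal(perm[(np.arange(9) + 4) % 9], np.arange(9))


class TestRankingMetrics:
    def test_perfect_and_constant_scores(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        perfect = np.eye(3)[truth]
        out = per_class_auroc_auprc(perfect, truth, np.arange(3))
        np.testing.assert_allclose(out["auroc"], 1.0)
        np.testing.assert_allclose(out["auprc"], 1.0)
        constant = np.full((6, 3), 1 / 3)
        out = per_class_auroc_auprc(constant, truth, np.arange(3))
        np.testing.assert_allclose(out["auroc"], 0.5)

    def test_single_inversion_matches_pair_counting(self):
        # 6 subjects, binary-as-2-class fixture with one inverted pair:
        # positives {3,4,5}; scores give one pos below one neg
        truth = np.array([0, 0, 0, 1, 1, 1])
        score1 = np.array([0.1, 0.2, 0.55, 0.5, 0.7, 0.9])
        probs = np.column_stack([1 - score1, score1])
        out = per_class_auroc_auprc(probs, truth, np.arange(2))
        # exhaustive counting: 9 pos/neg pairs, 1 discordant -> 8/9
        assert out["auroc"][1] == pytest.approx(8 / 9)

    def test_absent_class_reported_as_nan(self):
        truth = np.array([0, 0, 1, 1])
        probs = np.full((4, 3), 1 / 3)
        out = per_class_auroc_auprc(probs, truth, np.arange(3))
        assert np.isnan(out["auroc"][2]) and np.isnan(out["auprc"][2])

    def test_invariance_under_monotone_score_transform(self, rng):
        truth = rng.integers(0, 2, 50)
        score = rng.random(50)
        probs = np.column_stack([1 - score, score])
        warped = np.column_stack([1 - score, np.exp(3 * score)])  # monotone
        a = per_class_auroc_auprc(probs, truth, np.arange(2))
        b = per_class_auroc_auprc(warped, truth, np.arange(2))
        assert a["auroc"][1] == pytest.approx(b["auroc"][1])
        assert a["auprc"][1] == pytest.approx(b["auprc"][1])


def brute_force_cindex(times, events, risk):
    conc = ties = usable = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ti, tj = times[i], times[j]
            if events[i] == 1 and (ti < tj or (ti == tj and events[j] == 0)):
                usable += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    ties += 1
    return (conc + 0.5 * ties) / usable


class TestConcordance:
    def test_perfectly_ordered_clusters(self):
        # singleton clusters: no risk ties, perfect ordering -> exactly 1
        cohort = SurvivalCohort(np.array([1.0, 9.0]), np.ones(2, int))
        labels = np.array([1, 0])  # cluster 0 lives longest
        assert cluster_c_index(labels, cohort, risk_order=[0, 1]) == 1.0
        # with multi-subject clusters, within-cluster ties keep c below 1
        cohort4 = SurvivalCohort(np.array([1.0, 2.0, 8.0, 9.0]), np.ones(4, int))
        labels4 = np.array([1, 1, 0, 0])
        assert cluster_c_index(labels4, cohort4, [0, 1]) == pytest.approx(5 / 6)

    def test_single_cluster_is_chance(self):
        cohort = SurvivalCohort(np.array([1.0, 2.0, 3.0]), np.ones(3, int))
        assert cluster_c_index(np.zeros(3, int), cohort, [0]) == 0.5

    def test_matches_brute_force_with_censoring(self, rng):
        times = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 0, 1, 1, 0])
        labels = np.array([0, 1, 1, 0, 2, 2, 1, 0])
        order = [2, 1, 0]
        got = cluster_c_index(labels, SurvivalCohort(times, events), order)
        rank = np.empty(3)
        rank[np.asarray(order)] = np.arange(3)
        assert got == pytest.approx(brute_force_cindex(times, events, rank[labels]))

    def test_reverse_order_complements(self, rng):
        times = rng.exponential(1, 40) + 0.01  # continuous: no time ties
        events = (rng.random(40) > 0.3).astype(int)
        events[0] = 1
        labels = rng.integers(0, 3, 40)
        labels[:3] = [0, 1, 2]
        cohort = SurvivalCohort(times, events)
        c1 = cluster_c_index(labels, cohort, [0, 1, 2])
        c2 = cluster_c_index(labels, cohort, [2, 1, 0])
        # risk ties keep 0.5 on both sides; non-tied pairs flip
        assert c1 + c2 == pytest.approx(1.0)

    def test_no_events_raises(self):
        cohort = SurvivalCohort(np.array([1.0, 2.0]), np.array([0, 0]))
        with pytest.raises(ValueError, match="usable"):
            cluster_c_index(np.array([0, 1]), cohort, [0, 1])

    def test_agrees_with_compiled_reference_on_continuous_times(self, rng):
        # with continuous (tie-free) times our pair convention coincides
        # with the standard compiled implementation
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        from survclust.evaluation import _harrell

        times = rng.exponential(1, 80) + 0.001
        events = (rng.random(80) > 0.3).astype(int)
        events[0] = 1
        risk = rng.normal(size=80)
        ours = _harrell(times, events, risk)
        y = np.array(
            [(bool(e), t) for e, t in zip(events, times)],
            dtype=[("event", bool), ("time", float)],
        )
        ref = sksurv_metrics.concordance_index_censored(
            y["event"], y["time"], risk
        )[0]
        assert ours == pytest.approx(ref, abs=1e-12)


class TestRiskOrder:
    def test_disjoint_time_ranges(self):
        cohort = SurvivalCohort(
            np.array([1.0, 2.0, 10.0, 11.0]), np.ones(4, int)
        )
        labels = np.array([0, 0, 1, 1])
        order = derive_risk_order(labels, cohort, k=2)
        np.testing.assert_array_equal(order, [1, 0])  # cluster 1 survives longest

    def test_identical_clusters_tie_break_by_id(self):
        cohort = SurvivalCohort(np.array([1.0, 2.0, 1.0, 2.0]), np.ones(4, int))
        labels = np.array([0, 0, 1, 1])
        np.testing.assert_array_equal(derive_risk_order(labels, cohort, k=2), [0, 1])

    def test_three_cluster_km_medians_hand_computed(self):
        # medians: cluster0 = 2, cluster1 = 5, cluster2 = 3 -> order [1, 2, 0]
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 2.0, 3.0, 4.0])
        events = np.ones(9, int)
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        order = derive_risk_order(labels, SurvivalCohort(times, events), k=3)
        np.testing.assert_array_equal(order, [1, 2, 0])

    def test_empty_cluster_raises_when_strict(self):
        cohort = SurvivalCohort(np.array([1.0, 2.0]), np.ones(2, int))
        with pytest.raises(ValueError, match="empty"):
            derive_risk_order(np.array([0, 0]), cohort, k=2)


class TestKaplanMeier:
    def test_all_events_distinct_times(self):
        cohort = SurvivalCohort(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4, int))
        curve = km_curve(cohort)
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert curve.median == 2.0

    def test_all_censored_flat_curve(self):
        cohort = SurvivalCohort(np.array([1.0, 2.0]), np.zeros(2, int))
        curve = km_curve(cohort)
        np.testing.assert_allclose(curve.survival, 1.0)
        assert np.isinf(curve.median)

    def test_mixed_fixture_hand_product_limit(self):
        # times 1(e) 2(c) 3(e) 4(e) 5(c) 6(e); risk sets 6,_,4,3,_,1
        cohort = SurvivalCohort(
            np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
            np.array([1, 0, 1, 1, 0, 1]),
        )
        curve = km_curve(cohort)
        s1 = 5 / 6
        s3 = s1 * 3 / 4
        s4 = s3 * 2 / 3
        s6 = 0.0
        np.testing.assert_allclose(curve.survival, [s1, s1, s3, s4, s4, s6],
                                   atol=1e-10)

    def test_equals_empirical_survival_without_censoring(self, rng):
        times = np.sort(rng.exponential(1, 30)) + 0.01
        cohort = SurvivalCohort(times, np.ones(30, int))
        curve = km_curve(cohort)
        for t in times[[5, 15, 25]]:
            emp = (times > t).mean()
            assert curve.at(t)[0] == pytest.approx(emp, abs=1e-12)


class TestBootstrap:
    def test_constant_cindex_zero_width_ci(self):
        cohort = SurvivalCohort(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4, int))
        risk = np.array([3.0, 2.0, 1.0, 0.0])  # perfect ordering resists resampling
        out = bootstrap_cindex(risk, cohort, n_boot=200, seed=0)
        assert out.ci_a == (1.0, 1.0)

    def test_seeded_repeatability_and_coverage(self, rng):
        times = rng.exponential(1, 60) + 0.01
        events = (rng.random(60) > 0.3).astype(int)
        events[0] = 1
        cohort = SurvivalCohort(times, events)
        risk = rng.integers(0, 3, 60).astype(float)
        a = bootstrap_cindex(risk, cohort, n_boot=300, seed=42)
        b = bootstrap_cindex(risk, cohort, n_boot=300, seed=42)
        assert a == b
        from survclust.evaluation import _harrell

        point = _harrell(times, events, risk)
        assert a.ci_a[0] - 1e-9 <= point <= a.ci_a[1] + 1e-9

    def test_self_comparison_p_half(self, rng):
        times = rng.exponential(1, 40) + 0.01
        cohort = SurvivalCohort(times, np.ones(40, int))
        risk = rng.random(40)
        out = paired_bootstrap_pvalue(risk, risk, cohort, n_boot=200, seed=1)
        assert out.p_one_sided == pytest.approx(0.5)
        assert out.delta_median == 0.0

    def test_dominant_model_floors_at_one_over_nboot(self, rng):
        times = np.sort(rng.exponential(1, 80)) + 0.01
        cohort = SurvivalCohort(times, np.ones(80, int))
        good = -times  # oracle risk: exactly reversed survival
        bad = rng.random(80)
        out = paired_bootstrap_pvalue(good, bad, cohort, n_boot=200, seed=2)
        assert out.p_one_sided == pytest.approx(1 / 200)

    def test_mismatched_subjects_rejected(self, rng):
        cohort = SurvivalCohort(np.array([1.0, 2.0]), np.ones(2, int))
        with pytest.raises(ValueError, match="same subjects"):
            paired_bootstrap_pvalue([1.0], [1.0, 2.0], cohort, n_boot=100)


def test_evaluate_clustering_report_fields(rng):
    times = rng.exponential(1, 90) + 0.01
    events = (rng.random(90) > 0.3).astype(int)
    events[0] = 1
    cohort = SurvivalCohort(times, events)
    truth = rng.integers(0, 3, 90)
    probs = rng.dirichlet(np.ones(3), 90)
    report = evaluate_clustering(
        probs, cohort, true_labels=truth, n_boot=200, seed=0
    )
    assert report.k == 3
    assert sorted(report.permutation.tolist()) == [0, 1, 2]
    assert 0 <= report.c_index <= 1
    assert report.c_index_ci[0] <= report.c_index_ci[1]
    assert 0 < report.logrank_p <= 1
    assert len(report.km_summaries) == 3
    payload = report.to_dict()
    assert isinstance(payload["auroc_per_class"], list)
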