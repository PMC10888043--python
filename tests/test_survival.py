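"""Survival losses and evaluation statistics against hand and brute-force oracles."""

import numpy as np
import pytest
from scipy.special import expit

from petsurv_oracles import brute_force_concordance, hand_log_rank
from petctsurv.autodiff import Tensor
from petctsurv.survival import (CIndexResult, KMCurve, LossConfig, RiskOutput,
                                SurvivalTable, bootstrap_ci, combined_loss,
                                cox_loss, cox_loss_grad, focal_loss,
                                focal_loss_grad, harrell_c, km_curve,
                                l2_event_distance, log_rank, proposed_loss,
                                proposed_loss_grad, risk_set, stratify)
from conftest import random_survival_fixture


class TestRiskSet:
    def test_definition(self):
        t = SurvivalTable(list("abc"), [5.0, 3.0, 8.0], [1, 1, 1])
        assert set(risk_set(t, 0)) == {0, 2}

    def test_earliest_event_includes_everyone(self):
        t = SurvivalTable(list("abc"), [5.0, 3.0, 8.0], [1, 1, 0])
        assert set(risk_set(t, 1)) == {0, 1, 2}

    def test_all_ties_share_full_risk_set(self):
        t = SurvivalTable(list("abcd"), [2.0] * 4, [1, 1, 1, 1])
        for i in range(4):
            assert set(risk_set(t, i)) == {0, 1, 2, 3}

    def test_censored_index_rejected(self):
        t = SurvivalTable(list("ab"), [1.0, 2.0], [1, 0])
        with pytest.raises(ValueError):
            risk_set(t, 1)


class TestProposedLoss:
    def test_two_subject_fixture_equals_half_log_two(self, two_subject_table):
        loss = proposed_loss(np.zeros((2, 2)), two_subject_table)
        assert loss == pytest.approx(np.log(2) / 2, abs=1e-10)

    def test_single_event_singleton_risk_set_is_zero(self):
        t = SurvivalTable(["a"], [3.0], [1])
        assert proposed_loss(np.zeros((1, 1)), t) == pytest.approx(0.0, abs=1e-12)

    def test_loss_is_nonnegative(self, rng):
        for _ in range(25):
            t = random_survival_fixture(rng, int(rng.integers(2, 15)))
            m = np.unique(t.time[t.event == 1]).size
            s = rng.normal(size=(len(t), m)) * 3
            assert proposed_loss(s, t) >= -1e-12

    def test_sigmoid_link_is_not_shift_invariant(self, rng):
        t = random_survival_fixture(rng, 8)
        m = np.unique(t.time[t.event == 1]).size
        s = rng.normal(size=(8, m))
        assert proposed_loss(s + 1.0, t) != pytest.approx(proposed_loss(s, t),
                                                          abs=1e-6)

    def test_raising_an_event_subjects_score_lowers_the_loss(self, rng):
        # gradient-sign property at the subject's own event time
        t = random_survival_fixture(rng, 10)
        ev = int(np.flatnonzero(t.event == 1)[0])
        grid = np.unique(t.time[t.event == 1])
        col = int(np.searchsorted(grid, t.time[ev]))
        s = rng.normal(size=(10, grid.size))
        g = proposed_loss_grad(s, t)
        assert g[ev, col] < 0

    def test_no_events_rejected(self):
        t = SurvivalTable(list("ab"), [1.0, 2.0], [0, 0])
        with pytest.raises(ValueError):
            proposed_loss(np.zeros((2, 0)), t)

    def test_accepts_risk_output_grid_superset(self, rng):
        t = SurvivalTable(list("abc"), [1.0, 2.0, 3.0], [1, 0, 1])
        grid = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        risk = RiskOutput(rng.normal(size=(3, 5)), grid)
        cols = np.searchsorted(grid, [1.0, 3.0])
        assert proposed_loss(risk, t) == pytest.approx(
            proposed_loss(risk.scores[:, cols], t))


class TestCoxLoss:
    def test_two_subject_fixture_equals_half_log_two(self, two_subject_table):
        assert cox_loss(np.zeros(2), two_subject_table) == pytest.approx(
            np.log(2) / 2, abs=1e-10)

    def test_exponential_link_is_shift_invariant(self, rng):
        t = random_survival_fixture(rng, 9)
        s = rng.normal(size=9)
        assert cox_loss(s + 5.0, t) == pytest.approx(cox_loss(s, t), abs=1e-10)

    def test_link_equivalence_with_time_invariant_scores(self, rng):
        # with the exponential link, the time-indexed partial likelihood
        # reduces exactly to the Breslow/Cox partial likelihood
        for _ in range(100):
            t = random_survival_fixture(rng, int(rng.integers(2, 21)))
            s = rng.normal(size=len(t))
            m = np.unique(t.time[t.event == 1]).size
            tiled = np.tile(s[:, None], (1, m))
            assert proposed_loss(tiled, t, link="exp") == pytest.approx(
                cox_loss(s, t), abs=1e-10)


class TestFocalLoss:
    def test_gamma_zero_is_binary_cross_entropy(self, rng):
        p = rng.uniform(0.05, 0.95, size=12)
        e = rng.integers(0, 2, size=12)
        bce = -np.mean(e * np.log(p) + (1 - e) * np.log(1 - p))
        assert focal_loss(p, e, gamma=0.0) == pytest.approx(bce, abs=1e-12)

    def test_half_probability_event_closed_form(self):
        # -(1-0.5)^2 ln 0.5 = 0.25 ln 2
        assert focal_loss(np.array([0.5]), np.array([1]),
                          gamma=2.0) == pytest.approx(0.25 * np.log(2))

    def test_confident_correct_predictions_vanish(self):
        p = np.array([1 - 1e-9, 1e-9])
        e = np.array([1, 0])
        assert focal_loss(p, e) == pytest.approx(0.0, abs=1e-12)

    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([1.0]), np.array([1]))


class TestGradients:
    def test_loss_gradients_match_central_finite_differences(self, rng):
        eps = 1e-6
        for _ in range(5):
            t = random_survival_fixture(rng, 7)
            m = np.unique(t.time[t.event == 1]).size
            s = rng.normal(size=(7, m))
            g = proposed_loss_grad(s, t)
            for i, c in [(0, 0), (3, m - 1), (6, m // 2)]:
                sp, sm = s.copy(), s.copy()
                sp[i, c] += eps
                sm[i, c] -= eps
                num = (proposed_loss(sp, t) - proposed_loss(sm, t)) / (2 * eps)
                assert g[i, c] == pytest.approx(num, rel=1e-5, abs=1e-9)

    def test_cox_gradient_at_zero_scores(self, two_subject_table):
        g = cox_loss_grad(np.zeros(2), two_subject_table)
        eps = 1e-6
        for i in range(2):
            s = np.zeros(2)
            s[i] += eps
            fp = cox_loss(s, two_subject_table)
            s[i] -= 2 * eps
            fm = cox_loss(s, two_subject_table)
            assert g[i] == pytest.approx((fp - fm) / (2 * eps), abs=1e-5)


class TestCombinedLoss:
    def test_single_component_reduces_to_that_loss(self, rng):
        t = random_survival_fixture(rng, 6)
        grid = np.unique(t.time)
        risk = RiskOutput(rng.normal(size=(6, grid.size)), grid)
        cfg = LossConfig(use_cox=False, use_proposed=True, use_focal=False)
        assert combined_loss(risk, t, cfg) == pytest.approx(proposed_loss(risk, t))

    def test_components_add_linearly(self, rng):
        t = random_survival_fixture(rng, 6)
        grid = np.unique(t.time)
        risk = RiskOutput(rng.normal(size=(6, grid.size)), grid)
        own = risk.at_own_time(t)
        both = combined_loss(risk, t, LossConfig(use_proposed=True,
                                                 use_focal=True))
        expected = (proposed_loss(risk, t)
                    + focal_loss(expit(own), t.event, gamma=2.0))
        assert both == pytest.approx(expected)

    def test_cox_plus_focal_on_two_subject_fixture(self, two_subject_table):
        grid = np.array([1.0, 2.0])
        risk = RiskOutput(np.zeros((2, 2)), grid)
        cfg = LossConfig(use_cox=True, use_proposed=False, use_focal=True)
        expected = np.log(2) / 2 + focal_loss(np.array([0.5, 0.5]),
                                              two_subject_table.event)
        assert combined_loss(risk, two_subject_table, cfg) == pytest.approx(expected)

    def test_all_disabled_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(use_cox=False, use_proposed=False, use_focal=False)


class TestHarrellC:
    def test_perfect_and_reversed_rankings(self):
        t = SurvivalTable(list("abc"), [1.0, 2.0, 3.0], [1, 1, 1])
        assert harrell_c(t, np.array([3.0, 2.0, 1.0])) == 1.0
        assert harrell_c(t, np.array([1.0, 2.0, 3.0])) == 0.0

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 9))
            times = rng.integers(1, 6, size=n).astype(float)  # force ties
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                events[0] = 1
            risks = rng.integers(0, 4, size=n).astype(float)
            t = SurvivalTable([str(i) for i in range(n)], times, events)
            expected = brute_force_concordance(times, events, risks)
            if expected is None:
                continue
            assert harrell_c(t, risks) == pytest.approx(expected, abs=1e-12)

    def test_complement_symmetry_on_tie_free_data(self, rng):
        t = random_survival_fixture(rng, 12)
        r = rng.normal(size=12)
        assert harrell_c(t, r) + harrell_c(t, -r) == pytest.approx(1.0)

    def test_subject_permutation_invariance(self, rng):
        t = random_survival_fixture(rng, 15)
        r = rng.normal(size=15)
        perm = rng.permutation(15)
        assert harrell_c(t.subset(perm), r[perm]) == pytest.approx(harrell_c(t, r))


class TestBootstrap:
    def test_degenerate_statistic_gives_zero_width(self, rng):
        t = random_survival_fixture(rng, 20)
        res = bootstrap_ci(lambda tab, r: 0.42, t, np.zeros(20), B=50, seed=0)
        assert res.ci_lower == res.ci_upper == pytest.approx(0.42)

    def test_same_seed_identical_intervals(self, rng):
        t = random_survival_fixture(rng, 30)
        r = rng.normal(size=30)
        a = bootstrap_ci(harrell_c, t, r, B=200, seed=3)
        b = bootstrap_ci(harrell_c, t, r, B=200, seed=3)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)

    def test_interval_contains_estimate(self, rng):
        t = random_survival_fixture(rng, 25)
        r = rng.normal(size=25)
        res = bootstrap_ci(harrell_c, t, r, B=300, seed=1)
        assert res.ci_lower <= res.estimate <= res.ci_upper


class TestKaplanMeier:
    def test_three_subject_product_limit(self):
        t = SurvivalTable(list("abc"), [1.0, 2.0, 3.0], [1, 1, 0])
        c = km_curve(t)
        s = dict(zip(c.times, c.survival))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[2.0] == pytest.approx(1 / 3)
        assert s[3.0] == pytest.approx(1 / 3)
        assert dict(zip(c.times, c.at_risk)) == {1.0: 3, 2.0: 2, 3.0: 1}

    def test_no_events_curve_stays_at_one(self):
        t = SurvivalTable(list("abc"), [1.0, 2.0, 3.0], [0, 0, 0])
        assert np.allclose(km_curve(t).survival, 1.0)

    def test_all_events_reduces_to_empirical_survivor_fraction(self, rng):
        times = np.sort(rng.exponential(10, size=20)) + 1
        t = SurvivalTable([str(i) for i in range(20)], times, np.ones(20, int))
        c = km_curve(t)
        for tk, sk in zip(c.times, c.survival):
            assert sk == pytest.approx(np.mean(times > tk))


class TestLogRank:
    def test_identical_groups_give_null(self, rng):
        t = random_survival_fixture(rng, 10)
        stat, p = log_rank(t, t)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_four_subject_case_matches_textbook_computation(self):
        a = SurvivalTable(["a1", "a2"], [1.0, 3.0], [1, 1])
        b = SurvivalTable(["b1", "b2"], [2.0, 4.0], [1, 0])
        stat, p = log_rank(a, b)
        exp_stat, exp_p = hand_log_rank(a.time, a.event, b.time, b.event)
        assert stat == pytest.approx(exp_stat, abs=1e-10)
        assert p == pytest.approx(exp_p, abs=1e-10)

    def test_separated_exponential_groups_detected(self, rng):
        hits = 0
        for s in range(100):
            r = np.random.default_rng(s)
            a_t = r.exponential(100, 200) + 1e-3
            b_t = r.exponential(25, 200) + 1e-3
            a = SurvivalTable([f"a{i}" for i in range(200)], a_t, np.ones(200, int))
            b = SurvivalTable([f"b{i}" for i in range(200)], b_t, np.ones(200, int))
            _, p = log_rank(a, b)
            hits += p < 0.001
        assert hits >= 95


class TestStratify:
    def test_median_split(self):
        labels, cutoff = stratify(np.array([1.0, 2.0, 3.0, 4.0]))
        assert list(labels) == ["low", "low", "high", "high"]
        assert cutoff == 2.5

    def test_ties_at_median_go_low(self):
        labels, cutoff = stratify(np.array([1.0, 2.0, 3.0, 3.0, 5.0]))
        assert cutoff == 3.0
        assert list(labels) == ["low", "low", "low", "low", "high"]

    def test_monotone_transform_preserves_labels(self, rng):
        r = rng.normal(size=11)
        a, _ = stratify(r)
        b, _ = stratify(np.exp(r))
        assert list(a) == list(b)

    def test_constant_risks_rejected(self):
        with pytest.raises(ValueError):
            stratify(np.ones(5))


class TestL2EventDistance:
    def test_constant_half_probability_gives_half_everywhere(self):
        t = SurvivalTable(list("abc"), [1.0, 2.0, 3.0], [1, 0, 1])
        risk = RiskOutput(np.zeros((3, 3)), np.array([1.0, 2.0, 3.0]))
        d, mean = l2_event_distance(risk, t)
        assert np.allclose(d, 0.5)
        assert mean == pytest.approx(0.5)

    def test_sharp_predictions_vanish(self):
        t = SurvivalTable(list("ab"), [1.0, 2.0], [1, 0])
        scores = np.array([[30.0, 30.0], [-30.0, -30.0]])
        _, mean = l2_event_distance(RiskOutput(scores, np.array([1.0, 2.0])), t)
        assert mean == pytest.approx(0.0, abs=1e-10)

    def test_mixed_fixture_matches_hand_computation(self, rng):
        t = SurvivalTable(list("abcd"), [1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        scores = rng.normal(size=(4, 4))
        grid = np.array([1.0, 2.0, 3.0, 4.0])
        d, _ = l2_event_distance(RiskOutput(scores, grid), t)
        for i in range(4):
            assert d[i] == pytest.approx(abs(expit(scores[i, i]) - t.event[i]))

    def test_missing_time_column_rejected(self):
        t = SurvivalTable(list("ab"), [1.0, 2.5], [1, 0])
        risk = RiskOutput(np.zeros((2, 1)), np.array([1.0]))
        with pytest.raises(ValueError, match="no score column"):
            l2_event_distance(risk, t)


def test_survival_table_csv_roundtrip(tmp_path, rng):
    t = random_survival_fixture(rng, 9)
    path = tmp_path / "surv.csv"
    t.to_csv(path)
    back = SurvivalTable.from_csv(path)
    assert back.subject_ids == t.subject_ids
    assert np.allclose(back.time, t.time)
    assert np.array_equal(back.event, t.event)
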