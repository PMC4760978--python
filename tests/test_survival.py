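import numpy as np
import pytest
from hypothesis import given, strategies as st
from lifelines import CoxPHFitter
import pandas as pd

from sigcord.survival import (
    cox_binary_hr,
    dichotomize,
    km_estimate,
    logrank,
    roc_auc,
)


def km_oracle(times, events, t):
    """Hand product-limit: multiply (1 - d/n) over event times <= t."""
    s = 1.0
    for u in sorted(set(times[events == 1])):
        if u > t:
            break
        n = np.sum(times >= u)
        d = np.sum((times == u) & (events == 1))
        s *= 1 - d / n
    return s


def logrank_oracle(times, events, group):
    """Brute-force two-group log-rank sums."""
    o_minus_e, var = 0.0, 0.0
    for u in sorted(set(times[events == 1])):
        at_risk = times >= u
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == u) & (events == 1)).sum()
        d1 = ((times == u) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def auc_oracle(scores, labels):
    """Pair counting: concordant poor/good pairs, ties half."""
    poor = scores[labels == "poor"]
    good = scores[labels == "good"]
    wins = sum((p > g) + 0.5 * (p == g) for p in poor for g in good)
    return wins / (len(poor) * len(good))


class TestKm:
    def test_no_censoring_reduces_to_empirical_survival(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.ones(4, dtype=int)
        curve = km_estimate(times, events)
        assert curve.survival_at(2.5) == pytest.approx(0.5)

    def test_all_censored_stays_at_one(self):
        curve = km_estimate(np.array([1.0, 5.0, 9.0]), np.zeros(3, dtype=int))
        assert curve.survival_at(100.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([1, 0, 1])
        curve = km_estimate(times, events)
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(3.0) == pytest.approx(0.0)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            km_estimate(np.array([]), np.array([]))

    @given(st.integers(0, 1000))
    def test_matches_hand_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 25)
        times = rng.integers(1, 10, n).astype(float)  # ties likely
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        curve = km_estimate(times, events)
        for t in [0.5, 3.0, 7.0, 12.0]:
            assert curve.survival_at(t) == pytest.approx(
                km_oracle(times, events, t), abs=1e-10
            )


class TestLogrank:
    def test_identical_groups_score_zero(self):
        times = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        events = np.array([1, 0, 1, 1, 0, 1])
        group = np.array([0, 0, 0, 1, 1, 1])
        stat, p = logrank(times, events, group)
        assert stat == pytest.approx(0.0, abs=1e-10)

    def test_separated_groups_significant(self):
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.ones(6, dtype=int)
        group = np.array([0, 0, 0, 1, 1, 1])
        stat, p = logrank(times, events, group)
        assert p < 0.05
        assert stat == pytest.approx(logrank_oracle(times, events, group))

    def test_three_identical_groups_score_zero(self):
        times = np.tile([1.0, 2.0, 3.0], 3)
        events = np.tile([1, 1, 0], 3)
        group = np.repeat(["a", "b", "c"], 3)
        stat, _ = logrank(times, events, group)
        assert stat == pytest.approx(0.0, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank(np.array([1.0, 2.0]), np.array([1, 1]), np.array([0, 0]))

    @given(st.integers(0, 500))
    def test_matches_brute_force_sums(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        times = rng.integers(1, 12, n).astype(float)
        events = rng.integers(0, 2, n)
        group = rng.integers(0, 2, n)
        if group.min() == group.max() or events.sum() == 0:
            return
        stat, _ = logrank(times, events, group)
        assert stat == pytest.approx(logrank_oracle(times, events, group), rel=1e-6)

    def test_p_value_invariant_to_relabeling(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        group = rng.integers(0, 2, 40)
        _, p1 = logrank(times, events, group)
        _, p2 = logrank(times, events, 1 - group)
        assert p1 == pytest.approx(p2)


class TestCox:
    def test_duplicated_data_gives_unit_hr(self):
        times = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        events = np.tile([1, 1, 0, 1], 2)
        indicator = np.repeat([0, 1], 4)
        est = cox_binary_hr(times, events, indicator)
        assert est.hr == pytest.approx(1.0, abs=1e-6)

    def test_recovers_exponential_rate_ratio(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = np.repeat([0, 1], n // 2)
        times = rng.exponential(np.where(x == 1, 0.5, 1.0))
        events = np.ones(n, dtype=int)
        est = cox_binary_hr(times, events, x)
        assert 1.8 <= est.hr <= 2.2
        assert est.ci_low <= est.hr <= est.ci_high
        assert est.converged

    def test_constant_indicator_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_binary_hr(np.array([1.0, 2.0]), np.array([1, 1]), np.array([1, 1]))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_binary_hr(np.array([1.0, 2.0]), np.array([0, 0]), np.array([0, 1]))

    def test_monotone_likelihood_flagged(self):
        # all events in one group, complete separation in time
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1, 1, 1, 0, 0, 0])
        est = cox_binary_hr(times, events, x)
        assert not est.converged

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_lifelines_when_untied(self, seed):
        # continuous times -> no ties, so Breslow == Efron exactly
        rng = np.random.default_rng(seed)
        n = 150
        x = rng.integers(0, 2, n)
        times = rng.exponential(np.where(x == 1, 0.6, 1.0))
        events = rng.integers(0, 2, n)
        if events.sum() < 5 or len(np.unique(x)) < 2:
            return
        est = cox_binary_hr(times, events, x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": times, "e": events, "x": x}),
            duration_col="t",
            event_col="e",
        )
        assert np.log(est.hr) == pytest.approx(cph.params_["x"], abs=1e-5)
        assert est.log_hr_se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    @pytest.mark.parametrize("true_hr", [1.0, 2.0, 4.5])
    def test_log_hr_within_three_se_of_truth(self, true_hr):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 600
            x = rng.integers(0, 2, n)
            times = rng.exponential(1.0 / np.where(x == 1, true_hr, 1.0))
            events = (times < rng.exponential(2.0, n)).astype(int)
            times = np.minimum(times, 8.0)
            if events.sum() == 0:
                continue
            est = cox_binary_hr(times, events, x)
            if abs(np.log(est.hr) - np.log(true_hr)) <= 3 * est.log_hr_se:
                hits += 1
        assert hits >= int(0.9 * n_seeds)


class TestDichotomize:
    @pytest.mark.parametrize(
        "time, event, label",
        [
            (30.0, 1, "poor"),
            (60.0, 1, "poor"),  # event at the horizon counts within 5 years
            (40.0, 0, "excluded"),
            (80.0, 0, "good"),
            (61.0, 1, "good"),  # event after horizon, adequate follow-up
            (60.0, 0, "good"),
        ],
    )
    def test_label_rules(self, time, event, label):
        out = dichotomize(np.array([time]), np.array([event]))
        assert out[0] == label


class TestAuc:
    def test_perfect_ranking(self):
        scores = np.array([5.0, 4.0, 1.0, 0.0])
        labels = np.array(["poor", "poor", "good", "good"])
        auc, lo, hi = roc_auc(scores, labels)
        assert auc == 1.0

    def test_all_ties_is_half(self):
        scores = np.ones(10)
        labels = np.array(["poor"] * 5 + ["good"] * 5)
        auc, _, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5)

    def test_pair_counting_example(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array(["poor", "good", "poor", "good"])
        auc, _, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.25)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array(["poor", "poor"]))

    @given(st.integers(0, 500))
    def test_matches_pair_counting_and_negation(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        scores = rng.integers(0, 6, n).astype(float)  # ties likely
        labels = np.where(rng.random(n) < 0.5, "poor", "good")
        if len(set(labels)) < 2:
            return
        auc, lo, hi = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_oracle(scores, labels), abs=1e-10)
        neg, _, _ = roc_auc(-scores, labels)
        assert auc == pytest.approx(1 - neg, abs=1e-10)
        assert 0 <= lo <= auc <= hi <= 1

    def test_point_estimate_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = rng.normal(size=200)
        labels = np.where(rng.random(200) < 0.3, "poor", "good")
        auc, _, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels == "poor", scores))
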