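"""Survival and classification metrics against hand calculations and
independent references (lifelines, brute-force enumeration)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from marginsig import (
    concordance_index,
    covariate_prognosis,
    hazard_ratio_from_logrank,
    km_estimate,
    logrank,
    logrank_hr,
    roc_auc,
    spearman_permutation,
    welch_t,
)


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([3, 5, 9], [0, 0, 0])
        assert curve.times.size == 0  # no drops: S(t) = 1 everywhere

    def test_two_events_halve_then_zero(self):
        curve = km_estimate([1, 2], [1, 1])
        assert curve.survival == pytest.approx([0.5, 0.0])

    def test_six_subject_hand_example(self):
        # times (1,2,3,4,5,6), events (1,1,0,1,0,1); hand product-limit:
        # S = 5/6, 2/3, 4/9, 0 at event times 1,2,4,6
        curve = km_estimate([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        assert curve.times == pytest.approx([1, 2, 4, 6])
        assert curve.survival == pytest.approx([5 / 6, 2 / 3, 4 / 9, 0.0])
        assert curve.n_at_risk.tolist() == [6, 5, 3, 1]
        # Greenwood: S^2 * cumsum d/(n(n-d))
        assert curve.variance[:3] == pytest.approx(
            [(5 / 6) ** 2 / 30, (2 / 3) ** 2 * (1 / 12), (4 / 9) ** 2 * 0.25]
        )
        # log-scale CI at t=2
        half = stats.norm.ppf(0.975) * np.sqrt(1 / 12)
        assert curve.ci_lower[1] == pytest.approx((2 / 3) * np.exp(-half))
        assert curve.ci_upper[1] == pytest.approx(min(1.0, (2 / 3) * np.exp(half)))
        assert curve.ci_lower[0] == pytest.approx(
            (5 / 6) * np.exp(-stats.norm.ppf(0.975) * np.sqrt(1 / 30)))
        assert (curve.ci_lower <= curve.survival + 1e-12).all()
        assert (curve.ci_upper >= curve.survival - 1e-12).all()

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        times = rng.exponential(10, 40).round(2) + 0.01
        events = rng.integers(0, 2, 40)
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        ref = kmf.survival_function_.loc[curve.times, "KM_estimate"].to_numpy()
        assert curve.survival == pytest.approx(ref, abs=1e-10)

    def test_no_censoring_equals_empirical_survivor(self):
        times = np.array([2.0, 4.0, 4.0, 7.0, 9.0])
        curve = km_estimate(times, np.ones(5, dtype=int))
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((times > t).mean())

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_chi_square(self):
        times = [1, 2, 3, 4] * 2
        events = [1, 0, 1, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        res = logrank(groups, times, events)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_four_subject_hand_enumeration(self):
        # A: {1,2} events, B: {3,4} events. Hypergeometric tables give
        # E_A = 1/2 + 1/3 = 5/6, V = 1/4 + 2/9 = 17/36, chi2 = (7/6)^2/(17/36)
        res = logrank(["A", "A", "B", "B"], [1, 2, 3, 4], [1, 1, 1, 1])
        assert res.observed.tolist() == [2.0, 2.0]
        assert res.expected["A"] == pytest.approx(5 / 6)
        assert res.expected["B"] == pytest.approx(19 / 6)
        assert res.chi_square == pytest.approx(49 / 17)
        assert res.p_value == pytest.approx(stats.chi2.sf(49 / 17, 1))

    def test_matches_lifelines_with_ties(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(12)
        times = rng.integers(1, 15, 60).astype(float)  # heavy ties
        events = rng.integers(0, 2, 60)
        groups = rng.choice(["a", "b", "c"], 60)
        res = logrank(groups, times, events)
        ref = multivariate_logrank_test(times, groups, events)
        assert res.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.df == 2

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        times = rng.exponential(5, 30) + 0.1
        events = rng.integers(0, 2, 30)
        groups = rng.choice(["a", "b"], 30)
        flipped = np.where(groups == "a", "z", "a")
        assert logrank(groups, times, events).chi_square == pytest.approx(
            logrank(flipped, times, events).chi_square
        )

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(14)
        times = rng.exponential(5, 30) + 0.1
        events = rng.integers(0, 2, 30)
        groups = rng.choice(["a", "b"], 30)
        a = logrank(groups, times, events)
        b = logrank(groups, np.exp(times / 10), events)
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank(["a", "a"], [1, 2], [1, 1])


class TestHazardRatio:
    def test_identical_groups_hr_one(self):
        o = pd.Series({"high": 3.0, "low": 3.0})
        e = pd.Series({"high": 3.0, "low": 3.0})
        assert hazard_ratio_from_logrank(o, e, "high") == pytest.approx(1.0)

    def test_printed_arithmetic_example(self):
        o = pd.Series({"high": 8.0, "low": 2.0})
        e = pd.Series({"high": 5.0, "low": 5.0})
        assert hazard_ratio_from_logrank(o, e, "high") == pytest.approx(4.0)

    def test_zero_event_groups_flagged(self):
        e = pd.Series({"high": 2.0, "low": 2.0})
        assert hazard_ratio_from_logrank(
            pd.Series({"high": 4.0, "low": 0.0}), e, "high") == np.inf
        assert hazard_ratio_from_logrank(
            pd.Series({"high": 0.0, "low": 4.0}), e, "high") == 0.0

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            hazard_ratio_from_logrank(pd.Series({"high": 1.0, "low": 1.0}),
                                      pd.Series({"high": 0.0, "low": 2.0}), "high")

    def test_oe_ratio_tracks_cox_fit(self):
        """Proportional-hazards cohorts, true HR=3: the O/E-ratio estimator's
        median lands in [2.4, 3.6] and its log agrees with the partial-
        likelihood fit within 15% in median relative difference."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(42)
        hrs, rel = [], []
        for _ in range(60):  # 60 cohorts of n=200 keeps runtime modest
            n = 200
            grp = rng.integers(0, 2, n)
            lam = np.where(grp == 1, 3.0, 1.0) * 0.05
            t = rng.exponential(1.0 / lam)
            c = rng.exponential(40.0, n)
            times = np.minimum(t, c)
            events = (t <= c).astype(int)
            groups = np.where(grp == 1, "high", "low")
            hr, _ = logrank_hr(groups, times, events)
            df = pd.DataFrame({"t": times, "e": events, "x": grp})
            cox = CoxPHFitter().fit(df, "t", "e")
            hr_cox = float(np.exp(cox.params_["x"]))
            hrs.append(hr)
            rel.append(abs(np.log(hr) - np.log(hr_cox)) / abs(np.log(hr_cox)))
        assert 2.4 <= np.median(hrs) <= 3.6
        assert np.median(rel) < 0.15


class TestConcordance:
    def test_perfect_anti_ordering_scores_one(self):
        # higher risk with shorter time, no censoring
        assert concordance_index([4, 3, 2, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 1.0

    def test_perfect_ordering_scores_zero(self):
        assert concordance_index([1, 2, 3, 4], [1, 2, 3, 4], [1, 1, 1, 1]) == 0.0

    def test_eight_subject_pairwise_enumeration(self):
        rng = np.random.default_rng(19)
        risks = rng.normal(size=8)
        times = rng.exponential(10, 8) + 0.1
        events = np.array([1, 0, 1, 1, 0, 1, 0, 1])
        num = den = 0.0
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                shorter = (times[i] < times[j] and events[i] == 1) or (
                    times[i] == times[j] and events[i] == 1 and events[j] == 0)
                if not shorter:
                    continue
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
        assert concordance_index(risks, times, events) == pytest.approx(num / den)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(20)
        risks = rng.normal(size=30)
        times = rng.exponential(10, 30) + 0.1
        events = rng.integers(0, 2, 30)
        # lifelines orders by predicted survival time (higher = longer), so
        # pass -risks
        assert concordance_index(risks, times, events) == pytest.approx(
            ll_cindex(times, -risks, events)
        )

    def test_flip_symmetry_on_tie_free_data(self):
        rng = np.random.default_rng(21)
        risks = rng.normal(size=25)
        times = rng.exponential(10, 25) + 0.1
        events = rng.integers(0, 2, 25)
        c = concordance_index(risks, times, events)
        assert c + concordance_index(-risks, times, events) == pytest.approx(1.0)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1, 2], [3, 4], [0, 0])


class TestRocAuc:
    def test_all_equal_risks_auc_half(self):
        res = roc_auc([1.0] * 10, [0, 1] * 5, threshold=1.0)
        assert res.auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], threshold=5.0)
        assert res.auc == 1.0
        assert res.accuracy == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_auc_equals_pair_counting(self):
        rng = np.random.default_rng(23)
        risks = rng.integers(0, 6, 10).astype(float)  # ties on purpose
        y = rng.integers(0, 2, 10)
        if y.sum() in (0, 10):
            y[0] = 1 - y[0]
        pos, neg = risks[y == 1], risks[y == 0]
        u = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg)
        res = roc_auc(risks, y, threshold=np.median(risks))
        assert res.auc == pytest.approx(u / (len(pos) * len(neg)))

    def test_label_flip_complement(self):
        rng = np.random.default_rng(24)
        risks = rng.normal(size=20)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        a = roc_auc(risks, y, 0.0).auc
        b = roc_auc(risks, 1 - y, 0.0).auc
        assert a + b == pytest.approx(1.0)

    def test_roc_points_match_sklearn(self):
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(25)
        risks = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        res = roc_auc(risks, y, 0.0)
        fpr, tpr, _ = roc_curve(y, risks, drop_intermediate=False)
        assert res.fpr == pytest.approx(fpr)
        assert res.tpr == pytest.approx(tpr)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_auc([1, 2, 3], [1, 1, 1], 1.0)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_example(self):
        # A={1,2,3}, B={2,3,4}: t = -sqrt(3/2), Welch df = 4
        t, df, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-np.sqrt(1.5), abs=1e-9)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.2878641, abs=1e-4)

    def test_degenerate_variances(self):
        t, _, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, _, p = welch_t([2.0, 2.0], [3.0, 3.0])
        assert np.isinf(t) and t < 0 and p == 0.0

    def test_large_n_agrees_with_student(self):
        rng = np.random.default_rng(31)
        a = rng.normal(0.0, 1.0, 400)
        b = rng.normal(0.15, 1.0, 400)
        _, _, p_welch = welch_t(a, b)
        p_student = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert abs(p_welch - p_student) < 1e-3


class TestSpearmanPermutation:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        rho, p = spearman_permutation(x, x**3, n_perm=200, seed=0)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_permutation(x, -x, n_perm=200, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(33)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert spearman_permutation(x, y, 500, seed=5) == spearman_permutation(
            x, y, 500, seed=5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_permutation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_p_roughly_uniform(self):
        """Independent pairs (n=62): over 200 reps, 4-16% of p < 0.10."""
        rng = np.random.default_rng(34)
        hits = 0
        for rep in range(200):
            x, y = rng.normal(size=62), rng.normal(size=62)
            _, p = spearman_permutation(x, y, n_perm=300, seed=rep)
            hits += p < 0.10
        assert 0.04 <= hits / 200 <= 0.16


class TestCovariatePrognosis:
    @staticmethod
    def _outcomes(n, rng):
        events = rng.integers(0, 2, n)
        times = np.where(events == 1, rng.exponential(10, n), rng.exponential(60, n)) + 0.5
        return pd.DataFrame({
            "event": events,
            "time_months": times,
            "age": rng.normal(64, 10, n).round(1),
            "sex": rng.choice(["F", "M"], n),
            "stage": rng.choice(["I", "II", "III", "IV"], n),
        }, index=[f"p{i}" for i in range(n)])

    def test_table_shape_and_missing_handling(self):
        rng = np.random.default_rng(40)
        outcomes = self._outcomes(62, rng)
        outcomes.loc[outcomes.index[:4], "sex"] = np.nan
        table = covariate_prognosis(outcomes, {"age": "continuous",
                                               "sex": "categorical",
                                               "stage": "categorical"})
        assert table.loc["sex", "N"] == 58
        assert table.loc["age", "N"] == 62
        assert table.loc["stage", "n_groups"] == 4
        assert np.isnan(table.loc["stage", "HR"])  # HR only for 2 groups
        assert np.isfinite(table.loc["age", "HR"])

    def test_single_level_covariate_rejected(self):
        rng = np.random.default_rng(41)
        outcomes = self._outcomes(20, rng)
        outcomes["site"] = "tongue"
        with pytest.raises(ValueError, match="single level"):
            covariate_prognosis(outcomes, {"site": "categorical"})

    def test_null_binary_covariate_type_I(self):
        """Binary covariate independent of outcome: p < 0.05 in 3-8% of reps."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            outcomes = self._outcomes(62, rng)
            table = covariate_prognosis(outcomes, {"sex": "categorical"})
            hits += table.loc["sex", "p_value"] < 0.05
        assert 0.03 <= hits / n_rep <= 0.08

    def test_true_risk_covariate_is_prognostic(self):
        """A continuous covariate equal to the hazard driver comes out with
        HR > 1 and p < 0.05 in >= 80% of strong-effect reps."""
        rng = np.random.default_rng(43)
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            n = 62
            x = rng.normal(size=n)
            lam = 0.03 * np.exp(1.2 * x)
            t = rng.exponential(1.0 / lam)
            c = rng.exponential(60.0, n)
            outcomes = pd.DataFrame({
                "event": (t <= c).astype(int),
                "time_months": np.minimum(t, c) + 0.01,
                "risk": x,
            }, index=[f"p{i}" for i in range(n)])
            table = covariate_prognosis(outcomes, {"risk": "continuous"})
            wins += (table.loc["risk", "HR"] > 1) and (table.loc["risk", "p_value"] < 0.05)
        assert wins / n_rep >= 0.80
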