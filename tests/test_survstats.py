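"""Survival statistics against brute-force and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_clinical
from netprog.survstats import (
    SeparationError,
    concordance_index,
    cox_fit,
    cox_loglik,
    ctx_benefit_analysis,
    kaplan_meier,
    logrank_test,
)


def brute_force_cindex(scores, time, event):
    """Double-loop Harrell C-index: the independent oracle."""
    num = den = 0.0
    n = len(scores)
    for i, j in itertools.permutations(range(n), 2):
        if event[i] == 1 and time[i] < time[j]:
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_ranking(self):
        assert concordance_index([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_constant_scores_half(self):
        assert concordance_index([5, 5, 5], [1, 2, 3], [1, 1, 1]) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_censored_data(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        time = rng.exponential(10, size=n).round(2)
        event = rng.integers(0, 2, size=n)
        if event.sum() == 0:
            event[0] = 1
        scores = rng.normal(size=n)
        if seed % 3 == 0:  # exercise score ties
            scores = np.round(scores, 0)
        assert concordance_index(scores, time, event) == pytest.approx(
            brute_force_cindex(scores, time, event), abs=1e-12
        )

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            concordance_index([1, 2], [5, 5], [0, 0])


class TestKaplanMeier:
    def test_all_events_hand_values(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(km.event_times, [1, 2, 3])

    def test_censoring_shrinks_risk_set(self):
        # times (1, 2+, 3): S(1) = 2/3, then risk set of 1 -> S(3) = 1/3...
        # product-limit: S(3) = 2/3 * (1 - 1/1) = 0? No: at t=3 risk set {3} -> 2/3 * 0
        km = kaplan_meier([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_censored_middle_preserves_step(self):
        # times (1, 2+, 3, 4): at t=3 risk set {3,4} -> S = 2/3 * 1/2 = 1/3
        km = kaplan_meier([1, 2, 3, 4], [1, 0, 1, 0])
        assert km.survival_at(1) == pytest.approx(3 / 4)
        assert km.survival_at(3) == pytest.approx(3 / 8)

    def test_no_events_flat_curve(self):
        km = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.survival_at(100) == 1.0

    def test_no_censoring_matches_empirical_survival(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, size=30)
        km = kaplan_meier(t, np.ones(30, dtype=int))
        for q in [np.quantile(t, 0.3), np.quantile(t, 0.7)]:
            assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)


class TestLogrank:
    def test_identical_groups_zero_statistic(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = ["a"] * 4 + ["b"] * 4
        res = logrank_test(g, t, e)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_separated_groups(self):
        # group a: events at 1,2,3; group b: events at 10,11,12.
        # 2x2 tables: O_a = 3, E_a = 3/6+2/5+1/4 = 1.15, V = sum of
        # hypergeometric variances.
        t = [1, 2, 3, 10, 11, 12]
        e = [1] * 6
        g = ["a"] * 3 + ["b"] * 3
        E = 3 / 6 + 2 / 5 + 1 / 4
        V = (3 * 3) / (6 * 6 * 5) * 5 + (2 * 3) / (5 * 5 * 4) * 4 + (1 * 3) / (4 * 4 * 3) * 3
        expected = (3 - E) ** 2 / V
        res = logrank_test(g, t, e)
        assert res["statistic"] == pytest.approx(expected, rel=1e-10)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(3, size=20)
        e = rng.integers(0, 2, size=20)
        e[:4] = 1
        g = np.array(["a", "b"] * 10)
        r1 = logrank_test(g, t, e)
        g2 = np.where(g == "a", "b", "a")
        r2 = logrank_test(g2, t, e)
        assert r1["statistic"] == pytest.approx(r2["statistic"])

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            logrank_test(["a", "a"], [1, 2], [1, 1])


class TestCox:
    def test_null_binary_covariate(self):
        rng = np.random.default_rng(6)
        n = 200
        t = rng.exponential(10, size=n)
        e = rng.integers(0, 2, size=n)
        x = pd.DataFrame({"g": np.tile([0.0, 1.0], n // 2)})
        # identical generating process in both levels -> log HR near 0
        fit = cox_fit(x, t, e)
        assert abs(fit.coef[0]) < 0.35  # ~2 SE at this n

    def test_newton_matches_grid_maximizer(self):
        # 10-sample fixture; brute-force grid over beta is the oracle
        t = np.array([2.0, 4.0, 1.0, 7.0, 3.0, 9.0, 5.0, 8.0, 6.0, 10.0])
        e = np.array([1, 1, 1, 0, 1, 1, 0, 1, 1, 1])
        x = np.array([1.2, -0.3, 0.8, 0.1, 0.5, -1.0, 0.0, -0.6, 0.9, -1.4])
        fit = cox_fit(pd.DataFrame({"x": x}), t, e)
        grid = np.linspace(fit.coef[0] - 0.5, fit.coef[0] + 0.5, 20001)
        lls = [cox_loglik(np.array([b]), x[:, None], t, e)[0] for b in grid]
        assert fit.coef[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)
        # gradient vanishes at the Newton solution: sharper 1e-6 check
        _, g, _ = cox_loglik(fit.coef, x[:, None], t, e)
        assert abs(g[0]) < 1e-6

    def test_separation_detected(self):
        # covariate equal to the exact event order -> monotone likelihood
        t = np.arange(1.0, 9.0)
        e = np.ones(8, dtype=int)
        x = pd.DataFrame({"x": -t})
        with pytest.raises(SeparationError):
            cox_fit(x, t, e)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), [1, 2, 3], [1, 1, 1])

    def test_hr_ci_brackets_hr(self):
        rng = np.random.default_rng(7)
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, dtype=int))
        assert fit.ci_lower[0] < fit.hazard_ratio[0] < fit.ci_upper[0]

    def test_logrank_equals_squared_cox_score_test(self):
        # classical identity: at distinct event times the two-sample
        # log-rank statistic is the Cox partial-likelihood score test for
        # the group indicator (the hypergeometric variance's tie factor
        # (n-d)/(n-1) is 1 when no event time repeats)
        rng = np.random.default_rng(8)
        n = 60
        t = rng.exponential(5, size=n)  # continuous: tie-free
        e = rng.integers(0, 2, size=n)
        e[:10] = 1
        g = rng.integers(0, 2, size=n)
        lr = logrank_test(np.where(g == 1, "a", "b"), t, e)
        fit = cox_fit(pd.DataFrame({"g": g.astype(float)}), t, e, ties="breslow")
        assert lr["statistic"] == pytest.approx(fit.score_chi2_null, abs=1e-6)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(9)
        n = 80
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, size=n).astype(float)
        t = rng.exponential(np.exp(-(0.6 * x1 - 0.4 * x2)))
        e = (rng.uniform(size=n) < 0.7).astype(int)
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        fit = cox_fit(pd.DataFrame({"x1": x1, "x2": x2}), t, e)
        assert np.allclose(fit.coef, cph.params_.to_numpy(), atol=1e-5)
        assert np.allclose(fit.se, cph.standard_errors_.to_numpy(), atol=1e-5)

    def test_parameter_recovery(self):
        # data simulated under PH with log-HR 0.7; estimates concentrate
        # around the truth
        hits = 0
        reps = 50
        for k in range(reps):
            rng = np.random.default_rng(1000 + k)
            n = 500
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.7 * x))
            cens = rng.exponential(np.quantile(t, 0.85), size=n)
            time = np.minimum(t, cens)
            event = (t <= cens).astype(int)
            fit = cox_fit(pd.DataFrame({"x": x}), time, event)
            hits += abs(fit.coef[0] - 0.7) < 0.15
        assert hits >= 0.9 * reps


class TestCtxAnalysis:
    def test_no_stage_three_errors(self):
        clin = make_clinical([5, 6, 7, 8], [1, 0, 1, 0], stage=["II"] * 4)
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=clin.index)
        with pytest.raises(ValueError, match="stage III"):
            ctx_benefit_analysis(scores, clin)

    def test_constant_ctx_stratum_skipped(self):
        rng = np.random.default_rng(10)
        n = 20
        clin = make_clinical(rng.exponential(5, n), rng.integers(0, 2, n),
                             ctx=[1] * n)
        scores = pd.Series(rng.normal(size=n), index=clin.index)
        with pytest.warns(UserWarning, match="skipped"):
            res = ctx_benefit_analysis(scores, clin)
        assert res["high-risk"]["skipped"] and res["low-risk"]["skipped"]

    def test_interaction_recovered_with_oracle_scores(self):
        # generative benchmark: treatment benefit only in the high-risk half
        from netprog.simulate import SyntheticConfig, generate_expression_survival

        cfg = SyntheticConfig(rng_seed=1, n_samples=300)
        cohort, _ = generate_expression_survival(cfg, [f"G{i:04d}" for i in range(80)])
        res = ctx_benefit_analysis(cohort["latent_risk"], cohort["clinical"])
        assert res["high-risk"]["hr_ctx"] < 1.0
        assert res["high-risk"]["cox_p"] < 0.05
        assert res["low-risk"]["cox_p"] > 0.05
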