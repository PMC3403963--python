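"""Conditional logistic likelihood, Newton fit, interaction tests,
subgroup odds ratios and weighted ARR."""

import numpy as np
import pandas as pd
import pytest

from sepsispgx.analysis import (
    AnalysisSpec,
    build_analysis_sets,
    conditional_loglik,
    fit_clogit,
    interaction_test,
    subgroup_or,
    weighted_arr,
)
from sepsispgx.errors import EstimationError


def mcnemar_pairs(n_treated_died, n_control_died, n_concordant=5):
    """1:1 pairs with a treatment-only covariate."""
    sets = []
    X = np.array([[1.0], [0.0]])
    for _ in range(n_treated_died):
        sets.append((X, np.array([1.0, 0.0])))
    for _ in range(n_control_died):
        sets.append((X, np.array([0.0, 1.0])))
    for _ in range(n_concordant):
        sets.append((X, np.array([1.0, 1.0])))
    return sets


class TestConditionalLoglik:
    def test_uniform_subset_distribution_at_zero(self):
        # one 1:2 set with a single death: log(1/3) at beta = 0
        X = np.array([[1.0], [0.0], [0.0]])
        y = np.array([1.0, 0.0, 0.0])
        ll, _, _ = conditional_loglik(np.zeros(1), [(X, y)])
        assert ll == pytest.approx(np.log(1 / 3))

    def test_concordant_sets_contribute_zero(self):
        X = np.array([[1.0], [0.0], [0.0]])
        ll, grad, hess = conditional_loglik(
            np.array([0.7]),
            [(X, np.array([1.0, 1.0, 1.0])), (X, np.array([0.0, 0.0, 0.0]))],
        )
        assert ll == 0.0
        assert grad[0] == 0.0
        assert hess[0, 0] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        sets = []
        for _ in range(12):
            n = rng.integers(2, 5)
            X = rng.normal(size=(n, 3))
            y = np.zeros(n)
            y[: rng.integers(1, n)] = 1.0
            rng.shuffle(y)
            sets.append((X, y))
        beta = rng.normal(scale=0.5, size=3)
        ll, grad, hess = conditional_loglik(beta, sets)
        eps = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            lp, _, _ = conditional_loglik(beta + e, sets)
            lm, _, _ = conditional_loglik(beta - e, sets)
            fd = (lp - lm) / (2 * eps)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)
            # Hessian column via gradient differences
            _, gp, _ = conditional_loglik(beta + e, sets)
            _, gm, _ = conditional_loglik(beta - e, sets)
            np.testing.assert_allclose(hess[:, j], (gp - gm) / (2 * eps),
                                       rtol=1e-4, atol=1e-6)


class TestFitClogit:
    def test_mcnemar_closed_form(self):
        fit = fit_clogit(mcnemar_pairs(10, 5))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(10 / 5), abs=1e-8)
        # classical McNemar SE: sqrt(1/b + 1/c)
        assert fit.se("x0") == pytest.approx(np.sqrt(1 / 10 + 1 / 5), rel=1e-6)

    def test_dropped_set_accounting(self):
        fit = fit_clogit(mcnemar_pairs(4, 3, n_concordant=7))
        assert fit.n_sets == 14
        assert fit.n_informative == 7
        assert fit.n_dropped == 7
        assert fit.n_informative + fit.n_dropped == fit.n_sets

    def test_one_directional_pairs_flag_separation(self):
        fit = fit_clogit(mcnemar_pairs(12, 0))
        assert not fit.estimable
        assert "separation" in fit.message or "monotone" in fit.message

    def test_no_informative_sets_is_estimation_error(self):
        X = np.array([[1.0], [0.0]])
        with pytest.raises(EstimationError):
            fit_clogit([(X, np.array([1.0, 1.0]))])

    def test_set_level_constant_shift_invariance(self):
        rng = np.random.default_rng(4)
        sets = []
        shifted = []
        for _ in range(40):
            X = rng.normal(size=(3, 2))
            y = np.array([1.0, 0.0, 0.0])
            rng.shuffle(y)
            sets.append((X, y))
            shifted.append((X + rng.normal() * np.ones((3, 1)), y))
        f1 = fit_clogit(sets)
        f2 = fit_clogit(shifted)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-8)

    def test_interaction_recovery_on_simulated_sets(self):
        from sepsispgx.power import PowerScenario, _draw_sets
        from scipy.special import logit

        sc = PowerScenario(n_treated=2000, seed=12)
        rng = np.random.default_rng(12)
        irp, treated, y = _draw_sets(sc, rng)
        sets = [
            (np.column_stack([treated[i], irp[i], treated[i] * irp[i]]), y[i])
            for i in range(len(y))
        ]
        fit = fit_clogit(sets, ["treated", "irp", "treated:irp"])
        truth = (logit(sc.p0_pos - sc.arr_pos) - logit(sc.p0_pos)) - (
            logit(sc.p0_neg - sc.arr_neg) - logit(sc.p0_neg)
        )
        assert fit.converged
        assert abs(fit.coef("treated:irp") - truth) < 3 * fit.se("treated:irp")

    def test_matches_statsmodels_conditional_logit(self):
        smc = pytest.importorskip("statsmodels.discrete.conditional_models")
        rng = np.random.default_rng(6)
        rows, groups = [], []
        sets = []
        for g in range(120):
            n = 3
            X = rng.normal(size=(n, 2))
            eta = X @ np.array([0.6, -0.4])
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.sum() in (0, n):
                y[rng.integers(0, n)] = 1 - y[rng.integers(0, n)]
            sets.append((X, y))
            for i in range(n):
                rows.append([y[i], X[i, 0], X[i, 1]])
                groups.append(g)
        fit = fit_clogit(sets)
        arr = np.array(rows)
        theirs = smc.ConditionalLogit(arr[:, 0], arr[:, 1:], groups=np.array(groups)).fit(disp=0)
        np.testing.assert_allclose(fit.beta, theirs.params, atol=1e-5)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov)), theirs.bse, rtol=1e-3)


class TestInteractionTest:
    def _fit(self, beta, se, names=("treated", "irp", "treated:irp")):
        from sepsispgx.analysis import ConditionalLogisticFit

        p = len(names)
        cov = np.eye(p) * se**2
        return ConditionalLogisticFit(list(names), np.array(beta), cov, 0.0, 5,
                                      True, True, 10, 10, 0)

    def test_zero_coefficient_gives_p_one(self):
        tests = interaction_test({"A": self._fit([0.1, 0.2, 0.0], 0.5)})
        assert tests["p"].iloc[0] == pytest.approx(1.0)
        assert not tests["significant"].iloc[0]

    def test_z_196_not_significant_at_bonferroni_level(self):
        tests = interaction_test({"A": self._fit([0.0, 0.0, 1.96], 1.0)})
        row = tests.iloc[0]
        assert row["p"] == pytest.approx(0.05, abs=1e-3)
        assert not row["significant"]  # 0.05 > 0.025

    def test_non_estimable_fit_reported_inconclusive(self):
        fit = self._fit([0.0, 0.0, 20.0], 0.1)
        fit.estimable = False
        fit.message = "separation"
        tests = interaction_test({"A": fit})
        assert not tests["conclusive"].iloc[0]
        assert not tests["significant"].iloc[0]

    def test_family_summary_covers_both_irps(self):
        tests = interaction_test(
            {"A": self._fit([0, 0, 3.0], 1.0), "B": self._fit([0, 0, 0.5], 1.0)}
        )
        assert list(tests["irp_id"]) == ["A", "B"]
        assert tests["significant"].tolist() == [True, False]


class TestSubgroupOR:
    def test_null_coefficients_give_unit_ors(self):
        fit = TestInteractionTest()._fit([0.0, 0.3, 0.0], 0.4)
        ors = subgroup_or(fit)
        assert ors["odds_ratio"].tolist() == pytest.approx([1.0, 1.0])

    def test_additive_log_odds(self):
        fit = TestInteractionTest()._fit([-0.5, 0.0, -0.3], 0.4)
        ors = subgroup_or(fit).set_index("irp_stratum")
        assert ors.loc["negative", "odds_ratio"] == pytest.approx(np.exp(-0.5))
        assert ors.loc["positive", "odds_ratio"] == pytest.approx(np.exp(-0.8))
        assert (ors["ci_lower"] < ors["odds_ratio"]).all()
        assert (ors["ci_upper"] > ors["odds_ratio"]).all()


def make_arr_table(n_sets=100, m=2, p_treated=0.2, p_control=0.4, seed=0,
                   irp="positive"):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sets):
        rows.append({"set_id": f"s{s}", "patient_id": f"T{s}", "treated": 1,
                     "outcome": float(rng.random() < p_treated), "irp": irp})
        for j in range(m):
            rows.append({"set_id": f"s{s}", "patient_id": f"C{s}_{j}", "treated": 0,
                         "outcome": float(rng.random() < p_control), "irp": irp})
    return pd.DataFrame(rows)


class TestWeightedARR:
    def test_point_estimate_arithmetic(self):
        # deterministic outcomes: treated mortality 0.2, control 0.4
        rows = []
        for s in range(10):
            rows.append({"set_id": s, "patient_id": f"T{s}", "treated": 1,
                         "outcome": float(s < 2), "irp": "positive"})
            rows.append({"set_id": s, "patient_id": f"C{s}", "treated": 0,
                         "outcome": float(s < 4), "irp": "positive"})
        est = weighted_arr(pd.DataFrame(rows), "irp", "positive", n_boot=200, seed=1)
        assert est.arr == pytest.approx(20.0)
        assert est.ci_lower <= est.arr <= est.ci_upper

    def test_one_to_one_weights_collapse_to_plain_mean(self):
        tbl = make_arr_table(m=1, seed=3)
        est = weighted_arr(tbl, "irp", "positive", n_boot=200, seed=1)
        controls = tbl[tbl["treated"] == 0]
        assert est.control_mortality == pytest.approx(controls["outcome"].mean())

    def test_empty_stratum_reported_undefined(self):
        tbl = make_arr_table(n_sets=10)
        est = weighted_arr(tbl, "irp", "negative", n_boot=100, seed=1)
        assert not est.defined

    def test_bootstrap_ci_coverage(self):
        # nominal 95% percentile CI over independent re-generations
        covered = 0
        n_outer = 120
        for k in range(n_outer):
            tbl = make_arr_table(n_sets=150, p_treated=0.25, p_control=0.40,
                                 seed=1000 + k)
            est = weighted_arr(tbl, "irp", "positive", n_boot=400, seed=k)
            covered += est.ci_lower <= 15.0 <= est.ci_upper
        # binomial(120, .95): 3-sigma lower bound ~ 0.89
        assert covered / n_outer > 0.88


class TestBuildAnalysisSets:
    def test_indeterminate_patients_excluded(self):
        tbl = make_arr_table(n_sets=5)
        tbl.loc[0, "irp"] = "indeterminate"
        sets, names = build_analysis_sets(tbl, "irp")
        assert names[:3] == ["treated", "irp", "treated:irp"]
        total_members = sum(len(y) for _, y in sets)
        assert total_members == len(tbl) - 1
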