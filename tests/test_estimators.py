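"""The five selection-adjusted estimators, against printed worked-example
values, closed forms and trivial limits."""

import numpy as np
import pytest
from scipy.stats import norm

from seamtte import (
    SelectionRule,
    ShrinkageConfig,
    StageSummaries,
    UmvcueBounds,
    apply_rule,
    estimate_report,
    multiple_iterations_estimate,
    naive_bias,
    shrinkage_estimate,
    single_iteration_estimate,
    umvcue_bounds,
    umvcue_estimate,
)
from seamtte.estimators import (
    DegenerateBranchError,
    estimate_nu2,
    stage1_shrinkage_vector,
)

from conftest import make_summaries_1arm


@pytest.fixture(scope="module")
def report(worked_example):
    summaries, _, outcome = worked_example
    cfg = ShrinkageConfig(w=0.5, theta1_all=-0.5809, nu2="estimate")
    return estimate_report(summaries, outcome, cfg, abseps=1e-9)


class TestWorkedExample:
    """Every bias-adjusted cell of the published worked-example table,
    reproduced from the printed stage summaries to +-0.001."""

    def test_umvcue(self, report):
        assert report.umvcue[1] == pytest.approx(-0.6146, abs=1e-3)
        assert report.umvcue[2] == pytest.approx(-0.5281, abs=1e-3)

    def test_single_iteration(self, report):
        assert report.si[1] == pytest.approx(-0.5922, abs=1e-3)
        assert report.si[2] == pytest.approx(-0.5110, abs=1e-3)

    def test_multiple_iterations(self, report):
        assert report.mi_converged
        assert report.mi[1] == pytest.approx(-0.5744, abs=1e-3)
        assert report.mi[2] == pytest.approx(-0.4890, abs=1e-3)

    def test_shrinkage(self, report):
        assert report.nu2 == 0.0
        assert report.shrinkage[1] == pytest.approx(-0.6754, abs=1e-3)
        assert report.shrinkage[2] == pytest.approx(-0.6057, abs=1e-3)

    def test_stage1_correlation(self, worked_example):
        summaries, _, _ = worked_example
        rho = summaries.Sigma1[0, 1] / np.sqrt(
            summaries.Sigma1[0, 0] * summaries.Sigma1[1, 1]
        )
        assert rho == pytest.approx(0.4377, abs=5e-4)


class TestNaiveBias:
    def test_zero_when_region_covers_space(self, worked_example):
        summaries, _, _ = worked_example
        out = apply_rule(
            SelectionRule("all_loghr_le_b", b=1e9),
            summaries.theta1, summaries.V1,
        )
        s = StageSummaries.build(
            summaries.theta1, summaries.V1, summaries.Sigma1,
            summaries.theta_full, summaries.V_full,
        )
        b = naive_bias(np.array([-0.3, -0.4]), s, out)
        np.testing.assert_allclose(b, 0.0, atol=1e-5)

    def test_univariate_truncation_closed_form(self):
        # K=1, threshold rule: conditional mean of a one-sided truncated
        # normal gives bias = t1 * (-sigma1 phi(a)/Phi(a))
        theta, V1, V = -0.25, 9.0, 20.0
        s = make_summaries_1arm(-0.30, V1, theta, V)
        rule = SelectionRule("all_loghr_le_b", b=-0.1)
        out = apply_rule(rule, np.array([-0.30]), np.array([V1]))
        b = naive_bias(np.array([theta]), s, out, abseps=1e-9)[0]
        sig1 = 1 / np.sqrt(V1)
        alpha = (-0.1 - theta) / sig1
        expected = (V1 / V) * (-sig1 * norm.pdf(alpha) / norm.cdf(alpha))
        assert b == pytest.approx(expected, abs=1e-7)

    def test_si_correction_direction(self, worked_example):
        # selecting for benefit biases the naive estimate downward, so the
        # SI estimate moves up
        summaries, _, outcome = worked_example
        si = single_iteration_estimate(summaries, outcome, abseps=1e-8)
        for j in outcome.selected:
            assert si[j] > summaries.theta_full[j]


class TestMultipleIterations:
    def test_fixed_point_residual(self, worked_example):
        summaries, _, outcome = worked_example
        mi, converged, _ = multiple_iterations_estimate(
            summaries, outcome, tol=1e-8, abseps=1e-9
        )
        assert converged
        theta_t = summaries.theta1.copy()
        for j in outcome.selected:
            theta_t[j - 1] = mi[j]
        b = naive_bias(theta_t, summaries, outcome, abseps=1e-9)
        theta_hat = np.array(
            [summaries.theta_full[j] for j in outcome.selected]
        )
        resid = np.abs(theta_hat - b[[j - 1 for j in outcome.selected]]
                       - np.array([mi[j] for j in outcome.selected]))
        assert np.max(resid) <= 1e-6

    def test_zero_bias_region_converges_to_naive(self, worked_example):
        summaries, _, _ = worked_example
        out = apply_rule(
            SelectionRule("all_loghr_le_b", b=1e9),
            summaries.theta1, summaries.V1,
        )
        mi, converged, iters = multiple_iterations_estimate(summaries, out)
        assert converged and iters <= 2
        for j in out.selected:
            assert mi[j] == pytest.approx(summaries.theta_full[j], abs=1e-4)


class TestShrinkage:
    def test_nu2_zero_full_shrinkage(self):
        v = stage1_shrinkage_vector(
            np.array([-0.5, -0.6]), 0.1 * np.eye(2), -0.55, 0.0
        )
        np.testing.assert_allclose(v, [-0.55, -0.55])

    def test_nu2_large_no_shrinkage(self):
        theta1 = np.array([-0.5, -0.6])
        v = stage1_shrinkage_vector(theta1, 0.1 * np.eye(2), -0.55, 1e9)
        np.testing.assert_allclose(v, theta1, atol=1e-6)

    def test_nu2_estimate_truncates_at_zero(self, worked_example):
        summaries, _, _ = worked_example
        nu2 = estimate_nu2(
            summaries.theta1, summaries.sigma1sq, -0.5809
        )
        assert nu2 == 0.0

    def test_nu2_estimate_positive_when_spread_large(self):
        nu2 = estimate_nu2(
            np.array([0.5, -1.5, 1.0, -1.0]), np.full(4, 0.01), 0.0
        )
        assert nu2 > 0.5

    def test_convex_combination(self, worked_example):
        summaries, _, outcome = worked_example
        cfg = ShrinkageConfig(w=0.5, theta1_all=-0.5809, nu2=0.0)
        sh, nu2 = shrinkage_estimate(summaries, outcome, cfg)
        for j in outcome.selected:
            lo = min(-0.5809, summaries.theta2[j])
            hi = max(-0.5809, summaries.theta2[j])
            assert lo <= sh[j] <= hi

    def test_event_count_weight(self):
        w = ShrinkageConfig.event_count_weight(717, 316, 1, 4)
        assert w == pytest.approx(717 * 2 / (717 * 2 + 316 * 5))


class TestUmvcue:
    def test_threshold_bound_backmaps_to_w(self, worked_example):
        # at theta2 = B_L the recombined stage-1 estimate equals W exactly
        summaries, rule, outcome = worked_example
        for j in outcome.selected:
            b = umvcue_bounds(rule, outcome, summaries, j)
            s1 = summaries.sigma1sq[j - 1]
            s2 = summaries.sigma2sq[j]
            theta_hat = summaries.theta_full[j]
            theta1_at_bound = ((s1 + s2) * theta_hat - s1 * b.BL) / s2
            assert theta1_at_bound == pytest.approx(
                outcome.bounds[j][1], abs=1e-10
            )

    def test_one_sided_specialization_identity(self, worked_example):
        # the threshold-rule closed form (Mills-ratio expression in g(W))
        # equals the general truncated-normal form at the mapped bounds
        summaries, rule, outcome = worked_example
        for j in outcome.selected:
            b = umvcue_bounds(rule, outcome, summaries, j)
            got = umvcue_estimate(summaries, b, j)
            s1 = summaries.sigma1sq[j - 1]
            s2 = summaries.sigma2sq[j]
            theta_hat = summaries.theta_full[j]
            W = outcome.bounds[j][1]
            g = np.sqrt(s1 + s2) / s1 * (theta_hat - W)
            direct = theta_hat + s2 / np.sqrt(s1 + s2) * norm.pdf(g) / (
                1.0 - norm.cdf(g)
            )
            assert got == pytest.approx(direct, abs=1e-12)

    def test_no_truncation_returns_naive(self, worked_example):
        summaries, _, _ = worked_example
        b = UmvcueBounds(-np.inf, np.inf, 0.2)
        assert umvcue_estimate(summaries, b, 1) == summaries.theta_full[1]

    def test_infinite_w_no_correction(self, worked_example):
        summaries, _, _ = worked_example
        rule = SelectionRule("best_loghr")
        out = apply_rule(rule, np.array([-0.5, -0.4]),
                         summaries.V1)
        # push the competitor bound far away: correction should vanish
        s = StageSummaries.build(
            summaries.theta1, summaries.V1, summaries.Sigma1,
            summaries.theta_full, summaries.V_full,
        )
        b = umvcue_bounds(rule, out, s, 1)
        assert b.BL < np.inf
        far = UmvcueBounds(summaries.theta_full[1] - 60 * b.eta, np.inf,
                           b.eta)
        assert umvcue_estimate(s, far, 1) == pytest.approx(
            s.theta_full[1], abs=1e-9
        )

    def test_deep_tail_is_stable(self, worked_example):
        # log-scale Mills ratio keeps the estimate finite far in the tail
        summaries, _, _ = worked_example
        eta = 0.24
        b = UmvcueBounds(summaries.theta_full[1] + 40 * eta, np.inf, eta)
        v = umvcue_estimate(summaries, b, 1)
        assert np.isfinite(v)
        # conditional mean of a lower-truncated normal sits just above B_L
        assert v > b.BL

    def test_degenerate_branch_raises(self):
        theta1 = np.array([-0.4, -0.2])
        V1 = np.array([10.0, 10.0])
        s1 = 1.0 / V1
        # q12 exactly equal to sigma1^2: branch undefined
        Sigma1 = np.array([[s1[0], s1[0]], [s1[0], s1[1]]])
        s = StageSummaries.build(
            theta1, V1, Sigma1, {1: -0.45}, {1: 25.0}
        )
        rule = SelectionRule("best_loghr")
        out = apply_rule(rule, theta1, V1)
        with pytest.raises(DegenerateBranchError):
            umvcue_bounds(rule, out, s, 1)


class TestCompetitorBoundBranch:
    """Best-type rules: the Table-2 bound against a brute-force
    re-derivation from the sufficient statistic."""

    @pytest.mark.parametrize("kind", ["best_loghr", "best_pval"])
    def test_bound_solves_constraint_equation(self, kind):
        rng = np.random.default_rng(17)
        for _ in range(20):
            V1 = rng.uniform(6.0, 14.0, 2)
            s1sq = 1.0 / V1
            q = rng.uniform(0.2, 0.8) * np.sqrt(s1sq[0] * s1sq[1])
            Sigma1 = np.array([[s1sq[0], q], [q, s1sq[1]]])
            theta1 = np.sort(rng.normal(-0.3, 0.3, 2))  # arm 1 smallest
            V_full = V1[0] + rng.uniform(4.0, 12.0)
            theta_full = rng.normal(theta1[0], 0.1)
            s = StageSummaries.build(
                theta1, V1, Sigma1, {1: theta_full}, {1: V_full}
            )
            rule = (SelectionRule(kind) if kind == "best_loghr"
                    else SelectionRule(kind))
            out = apply_rule(rule, theta1, V1)
            if out.selected != (1,):
                continue
            b = umvcue_bounds(rule, out, s, 1)
            B = b.BL if np.isfinite(b.BL) else b.BU
            # at theta2 = B, holding the sufficient statistic
            # theta*_i = theta1_i + (q_1i/s2) theta2 fixed, the selection
            # constraint theta1_1 <= theta1_l (on the rule's scale) binds
            s2 = s.sigma2sq[1]
            th2_obs = s.theta2[1]
            tstar1 = theta1[0] + (s1sq[0] / s2) * th2_obs
            tstar2 = theta1[1] + (q / s2) * th2_obs
            th1_at = tstar1 - (s1sq[0] / s2) * B
            th2_at = tstar2 - (q / s2) * B
            if kind == "best_loghr":
                assert th1_at == pytest.approx(th2_at, abs=1e-8)
            else:
                assert th1_at * np.sqrt(V1[0]) == pytest.approx(
                    th2_at * np.sqrt(V1[1]), abs=1e-8
                )
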