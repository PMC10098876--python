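"""Trial simulator: event-time law, design calculator, replication
mechanics and the normal-theory shortcut."""

import numpy as np
import pytest

from seamtte import (
    SelectionRule,
    StageSummaries,
    TrialDesign,
    apply_rule,
    normal_theory_replicate,
    replicate,
    required_events,
    simulate_trial,
    umvcue_bounds,
    umvcue_estimate,
    weibull_sample,
)


class TestWeibullSample:
    def test_gamma_one_is_exponential(self, rng):
        lam = 1.0 / 200.0
        x = weibull_sample(lam, 1.0, 100_000, rng)
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - 200.0) < 3 * se

    def test_median_identity_gamma_half(self, rng):
        med = 365.0
        lam = np.log(2) / med ** 0.5
        x = weibull_sample(lam, 0.5, 200_000, rng)
        assert np.median(x) == pytest.approx(365.0, rel=0.02)

    def test_proportional_hazards_recovery(self, rng):
        # a large two-arm fit recovers the log HR used to scale the hazard
        from seamtte import SurvivalDataset, pairwise_ph_fit

        theta = -0.4
        lam0 = np.log(2) / 365.0 ** 0.5
        n = 20_000
        t0 = weibull_sample(lam0, 0.5, n, rng)
        t1 = weibull_sample(lam0 * np.exp(theta), 0.5, n, rng)
        t = np.concatenate([t0, t1])
        c = np.full(2 * n, 2000.0)
        ds = SurvivalDataset(
            np.arange(2 * n), np.repeat([0, 1], n), np.zeros(2 * n),
            np.minimum(t, c), t <= c,
        )
        th, _ = pairwise_ph_fit(ds, 1)
        assert th == pytest.approx(theta, abs=0.03)


class TestRequiredEvents:
    def test_reference_design_632(self):
        assert required_events(0.80, 0.05, 0.8) == 632

    def test_direct_formula_hr_half(self):
        assert required_events(0.80, 0.05, 0.5) == 66

    def test_hr_one_rejected(self):
        with pytest.raises(ValueError):
            required_events(0.80, 0.05, 1.0)


class TestSimulateTrial:
    def test_selection_free_design_runs_stage2(self, rng):
        d = TrialDesign(
            K=1, theta=(0.0,), rule=SelectionRule("all_loghr_le_b", b=1e6),
            interim_events=80, stage2_events=40,
            carryover_extension=200.0,
        )
        res = simulate_trial(d, rng, estimators=("naive",))
        assert not res.futility and res.selected == (1,)
        assert res.stage2_end > res.interim_time
        assert res.error is None

    def test_futility_returns_no_estimates(self):
        d = TrialDesign(
            K=2, theta=(1.5, 1.5),
            rule=SelectionRule("best_loghr_le_b", b=-2.0),
            interim_events=60, stage2_events=30,
        )
        res = simulate_trial(d, np.random.default_rng(2),
                             estimators=("naive",))
        assert res.futility and res.estimates == {}

    def test_score_route_runs(self, rng):
        d = TrialDesign(
            K=2, theta=(0.0, 0.0),
            rule=SelectionRule("best_loghr_le_b", b=0.0),
            interim_events=80, stage2_events=40,
            estimation_route="score",
        )
        res = simulate_trial(d, rng, estimators=("naive", "umvcue"))
        if not res.futility:
            assert res.error is None
            assert set(res.estimates) == {"naive", "umvcue"}

    def test_all_estimators_on_one_trial(self, rng):
        d = TrialDesign(
            K=2, theta=(-0.2, -0.2),
            rule=SelectionRule("best_loghr_le_b", b=0.0),
            interim_events=120, stage2_events=60,
        )
        res = simulate_trial(
            d, rng,
            estimators=("naive", "umvcue", "si", "mi", "shrinkage"),
        )
        assert not res.futility
        assert res.error is None
        j = res.selected[0]
        for name in ("naive", "umvcue", "si", "mi", "shrinkage"):
            assert np.isfinite(res.estimates[name][j])


class TestReplicate:
    def test_single_rep_frequencies_are_binary(self):
        d = TrialDesign(
            K=2, theta=(0.0, 0.0),
            rule=SelectionRule("best_loghr_le_b", b=0.0),
            interim_events=60, stage2_events=30,
        )
        res = replicate(d, 1, seed=3, stage1_only=True)
        vals = set(res.selection_freq.values()) | {res.futility_freq}
        assert vals <= {0.0, 1.0}

    def test_rmse_at_least_abs_bias(self):
        d = TrialDesign(
            K=2, theta=(0.0, 0.0),
            rule=SelectionRule("best_loghr_le_b", b=0.0),
            interim_events=60, stage2_events=30,
        )
        res = replicate(d, 30, seed=4, estimators=("naive",))
        for j, b in res.conditional_bias["naive"].items():
            assert res.conditional_rmse["naive"][j] >= abs(b) - 1e-12

    def test_symmetric_arms_select_equally(self):
        d = TrialDesign(
            K=2, theta=(0.0, 0.0),
            rule=SelectionRule("best_loghr_le_b", b=0.0),
            interim_events=60, stage2_events=30,
        )
        res = replicate(d, 300, seed=5, stage1_only=True)
        f1 = res.selection_freq[1]
        f2 = res.selection_freq[2]
        n = 300 * (1 - res.futility_freq)
        se = np.sqrt(0.5 * 0.5 / n) * np.sqrt(2)
        assert abs(f1 - f2) < 4 * se

    def test_futility_monotone_in_boundary(self):
        d0 = TrialDesign(
            K=2, theta=(0.0, 0.0),
            rule=SelectionRule("best_loghr_le_b", b=0.3),
            interim_events=60, stage2_events=30,
        )
        fut = []
        for b in (0.3, 0.0, -0.3):
            d = TrialDesign(
                K=2, theta=(0.0, 0.0),
                rule=SelectionRule("best_loghr_le_b", b=b),
                interim_events=60, stage2_events=30,
            )
            fut.append(replicate(d, 120, seed=6,
                                 stage1_only=True).futility_freq)
        assert fut[0] <= fut[1] <= fut[2]
        assert d0.lambda0 == pytest.approx(np.log(2) / 365.0 ** 0.5)


class TestNormalTheoryShortcut:
    def test_matches_scalar_path(self, exchangeable_config):
        # the vectorized UMVCUE in the shortcut must agree with the scalar
        # API route, draw by draw
        theta, Sigma1, sigma2sq, V1 = exchangeable_config
        rule = SelectionRule("best_loghr_le_b", b=0.0)
        out = normal_theory_replicate(
            theta, Sigma1, sigma2sq, rule, 60, seed=12
        )
        for i in range(len(out["rep"])):
            j = int(out["arm"][i])
            th1 = np.asarray(
                # reconstruct the full stage-1 vector for this replicate
                _th1_for_rep(theta, Sigma1, 60, 12, out["rep"][i])
            )
            outcome = apply_rule(rule, th1, V1)
            assert outcome.selected == (j,)
            s2 = sigma2sq[j - 1]
            V2 = 1.0 / s2
            naive = out["naive"][i]
            summaries = StageSummaries.build(
                th1, V1, Sigma1,
                {j: naive}, {j: V1[j - 1] + V2},
            )
            b = umvcue_bounds(rule, outcome, summaries, j)
            got = umvcue_estimate(summaries, b, j)
            assert got == pytest.approx(out["umvcue"][i], abs=1e-10)

    @pytest.mark.parametrize(
        "kind,param",
        [
            ("all_loghr_le_b", {"b": 0.0}),
            ("best_loghr", {}),
        ],
    )
    def test_umvcue_conditionally_unbiased(self, kind, param,
                                           exchangeable_config):
        theta, Sigma1, sigma2sq, _ = exchangeable_config
        rule = SelectionRule(kind, **param)
        out = normal_theory_replicate(
            theta, Sigma1, sigma2sq, rule, 120_000, seed=13
        )
        m = out["arm"] == 1
        err = out["umvcue"][m] - theta[0]
        se = err.std(ddof=1) / np.sqrt(m.sum())
        assert abs(err.mean()) < 3 * se


def _th1_for_rep(theta, Sigma1, n_reps, seed, rep):
    """Regenerate the rep-th stage-1 draw of normal_theory_replicate."""
    rng = np.random.default_rng(seed)
    K = len(theta)
    L = np.linalg.cholesky(Sigma1)
    th1 = theta + rng.standard_normal((n_reps, K)) @ L.T
    return th1[rep]
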