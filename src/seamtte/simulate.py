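"""Two-stage multi-arm survival trial simulator and operating characteristics.

The generator emulates the standard seamless phase II/III design with a
time-to-event endpoint:

* proportional Weibull hazards, h_0(t) = lambda gamma t^{gamma-1} for the
  control and h_j(t) = exp(theta_j) h_0(t) for experimental arm j, with the
  control scale set from the control median survival
  (lambda_0 = ln 2 / median^gamma);
* deterministic recruitment of ``recruit_rate`` subjects per day with
  random blocked 1:...:1 allocation;
* an interim analysis triggered by a prefixed total event count (or a
  prefixed calendar time), at which a selection rule is applied to the
  stage-1 log HR estimates;
* stage-2 recruitment restricted to control plus the selected arm(s),
  stopped when a prefixed number of stage-2-patient events has accrued;
* continued follow-up of stage-1 patients without events, censored a
  prefixed number of days after the interim (the carry-over rule that keeps
  the information increments approximately independent).

``replicate`` runs many such trials and reports selection frequencies plus
conditional bias and RMSE of the requested estimators, conditioning on
which arm was selected, exactly as operating-characteristics tables for
these designs are laid out.  ``normal_theory_replicate`` bypasses the
survival layer and draws the stage-wise estimates directly from their joint
asymptotic normal law; it is the fast oracle for checking conditional
unbiasedness of the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from ._coxph import CoxFitError
from .estimators import (
    ShrinkageConfig,
    multiple_iterations_estimate,
    shrinkage_estimate,
    single_iteration_estimate,
    umvcue_bounds,
    umvcue_estimate,
)
from .mvnorm import NumericalSelectionError
from .selection import SelectionRule, apply_rule
from .stagewise import (
    NonEstimableError,
    StageSummaries,
    SurvivalDataset,
    fit_multiarm_ph,
    logrank_score,
    pairwise_ph_fit,
    pooled_loghr,
    stage1_covariance,
)

__all__ = [
    "TrialDesign",
    "TrialResult",
    "ReplicationResult",
    "weibull_sample",
    "simulate_trial",
    "replicate",
    "normal_theory_replicate",
    "required_events",
]

ALL_ESTIMATORS = ("naive", "umvcue", "si", "mi", "shrinkage")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialDesign:
    """Configuration of a simulated two-stage multi-arm survival trial.

    All triggers are prefixed (never data dependent): ``interim_events``
    (or ``interim_calendar``) sets the interim analysis, ``stage2_events``
    (or ``stage2_calendar``) ends stage 2, and ``carryover_extension`` is
    the number of days past the interim for which stage-1 patients without
    events remain under observation.
    """

    K: int
    theta: tuple[float, ...]
    rule: SelectionRule
    gamma: float = 0.5
    control_median: float = 365.0
    recruit_rate: float = 1.0
    interim_events: int | None = 717
    interim_calendar: float | None = None
    stage2_events: int | None = 316
    stage2_calendar: float | None = None
    carryover_extension: float = 365.0
    estimation_route: str = "ph"  # "ph" | "score"

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.theta) != self.K:
            raise ValueError("theta must have length K")
        if self.gamma <= 0 or self.control_median <= 0:
            raise ValueError("gamma and control_median must be positive")
        if self.recruit_rate <= 0:
            raise ValueError("recruit_rate must be positive")
        if (self.interim_events is None) == (self.interim_calendar is None):
            raise ValueError(
                "exactly one of interim_events / interim_calendar"
            )
        if (self.stage2_events is None) == (self.stage2_calendar is None):
            raise ValueError(
                "exactly one of stage2_events / stage2_calendar"
            )
        if self.estimation_route not in ("ph", "score"):
            raise ValueError("estimation_route must be 'ph' or 'score'")

    @property
    def lambda0(self) -> float:
        """Control Weibull scale giving the configured median survival."""
        return np.log(2.0) / self.control_median ** self.gamma

    def shrinkage_weight(self, n_selected: int) -> float:
        """Planned-event shrinkage weight E1(|S|+1)/(E1(|S|+1)+E2(K+1))."""
        E1 = self.interim_events
        E2 = self.stage2_events
        if E1 is None or E2 is None:
            return 0.5
        return ShrinkageConfig.event_count_weight(
            E1, E2, n_selected, self.K
        )

    @classmethod
    def scenario(cls, number: int, rule: SelectionRule | None = None,
                 **overrides) -> "TrialDesign":
        """Preset simulation-study scenarios (K = 4, best-arm rule with
        futility at 0, interim at 717 events, 316 stage-2 events, one-year
        carry-over, one recruit per day)."""
        thetas = {
            1: (0.0, 0.0, 0.0, 0.0),
            2: (-0.2231,) * 4,
            3: (0.0, -0.1393, -0.3011, -0.5108),
            4: (-0.9163, -0.9163, -0.9163, -1.0498),
        }
        if number not in thetas:
            raise ValueError("scenario must be 1..4")
        if rule is None:
            rule = SelectionRule("best_loghr_le_b", b=0.0)
        return cls(K=4, theta=thetas[number], rule=rule, **overrides)


# ---------------------------------------------------------------------------
# event-time generation
# ---------------------------------------------------------------------------

def weibull_sample(lam: float, gamma: float, n: int, rng) -> np.ndarray:
    """Event times with survival function exp(-lam * t^gamma)."""
    if lam <= 0 or gamma <= 0:
        raise ValueError("lam and gamma must be positive")
    rng = np.random.default_rng(rng)
    u = rng.random(n)
    return (-np.log(u) / lam) ** (1.0 / gamma)


def _blocked_allocation(n: int, arms: np.ndarray, rng) -> np.ndarray:
    """Random permuted-block 1:...:1 allocation to ``arms``."""
    b = len(arms)
    n_blocks = -(-n // b)
    out = np.empty(n_blocks * b, dtype=arms.dtype)
    for i in range(n_blocks):
        out[i * b:(i + 1) * b] = rng.permutation(arms)
    return out[:n]


def _recruit_cohort(
    design: TrialDesign,
    arms: np.ndarray,
    start_day: float,
    n: int,
    rng,
    id_offset: int,
):
    """Arrival times, arm labels and latent event times for n recruits."""
    arrivals = start_day + np.arange(n) / design.recruit_rate
    alloc = _blocked_allocation(n, arms, rng)
    lam = design.lambda0 * np.exp(
        np.concatenate([[0.0], np.asarray(design.theta)])
    )
    tau = weibull_sample(1.0, design.gamma, n, rng)  # unit-scale draws
    # rescale per-arm: S(t) = exp(-lam t^g) <=> t = (E / lam)^{1/g}, with
    # E standard exponential; unit draws are (E)^{1/g}
    tau = tau / lam[alloc] ** (1.0 / design.gamma)
    ids = id_offset + np.arange(n)
    return ids, alloc, arrivals, tau


def _event_count_time(
    arrivals: np.ndarray, tau: np.ndarray, count: int
) -> float:
    """Calendar time at which the count-th event occurs.

    Valid whenever every subject recruited before the returned time is in
    the supplied arrays (subjects recruited later die later than their own
    arrival, so they cannot enter the first ``count`` deaths).
    """
    deaths = arrivals + tau
    if len(deaths) < count:
        raise ValueError("not enough subjects generated for event trigger")
    return float(np.partition(deaths, count - 1)[count - 1])


# ---------------------------------------------------------------------------
# one trial
# ---------------------------------------------------------------------------

@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    selected: tuple[int, ...]
    futility: bool
    interim_time: float
    stage2_end: float | None
    theta1: np.ndarray | None
    V1: np.ndarray | None
    estimates: dict[str, dict[int, float]] = field(default_factory=dict)
    mi_converged: bool = True
    error: str | None = None


def _stage1_trial_data(design: TrialDesign, rng):
    """Generate stage-1 recruits out to the interim time."""
    arms = np.arange(design.K + 1)
    n0 = int(
        3.0 * (design.interim_events or 0) * (design.K + 1) / 2
    ) + 2000
    ids, alloc, arrivals, tau = _recruit_cohort(design, arms, 0.0, n0, rng, 0)
    if design.interim_events is not None:
        T1 = _event_count_time(arrivals, tau, design.interim_events)
        while T1 > arrivals[-1]:
            more = _recruit_cohort(
                design, arms, arrivals[-1] + 1.0 / design.recruit_rate,
                2000, rng, ids[-1] + 1,
            )
            ids = np.concatenate([ids, more[0]])
            alloc = np.concatenate([alloc, more[1]])
            arrivals = np.concatenate([arrivals, more[2]])
            tau = np.concatenate([tau, more[3]])
            T1 = _event_count_time(arrivals, tau, design.interim_events)
    else:
        T1 = float(design.interim_calendar)
    keep = arrivals < T1
    return ids[keep], alloc[keep], arrivals[keep], tau[keep], T1


def simulate_trial(
    design: TrialDesign,
    rng,
    estimators: tuple[str, ...] = ALL_ESTIMATORS,
    stage1_only: bool = False,
) -> TrialResult:
    """Simulate one two-stage trial and compute the requested estimators.

    ``stage1_only=True`` stops after applying the selection rule, which is
    sufficient (and much faster) when only selection frequencies are
    needed.  Estimation failures inside a trial are recorded on the result
    rather than raised, so that replication runs are robust.
    """
    rng = np.random.default_rng(rng)
    unknown = set(estimators) - set(ALL_ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimators: {sorted(unknown)}")

    ids, alloc, arrivals, tau, T1 = _stage1_trial_data(design, rng)

    obs1 = np.minimum(tau, T1 - arrivals)
    ev1 = tau <= T1 - arrivals
    stage1 = SurvivalDataset(ids, alloc, arrivals, obs1, ev1)

    try:
        if design.estimation_route == "ph":
            theta1, Sigma1 = fit_multiarm_ph(stage1)
            V1 = 1.0 / np.diag(Sigma1)
        else:
            theta1 = np.empty(design.K)
            for j in range(1, design.K + 1):
                S, V = logrank_score(stage1, j)
                theta1[j - 1] = S / V
            Sigma1 = stage1_covariance(stage1)
            V1 = 1.0 / np.diag(Sigma1)
    except (CoxFitError, NonEstimableError) as exc:
        return TrialResult((), True, T1, None, None, None,
                           error=f"stage1: {exc}")

    outcome = apply_rule(design.rule, theta1, V1)
    result = TrialResult(
        outcome.selected, outcome.futility, T1, None, theta1, V1
    )
    if outcome.futility or stage1_only:
        return result

    # ---- stage 2 ----------------------------------------------------------
    arms2 = np.array([0] + list(outcome.selected))
    start2 = T1 + 1.0 / design.recruit_rate
    n2 = int(3.0 * (design.stage2_events or 0) * len(arms2) / 2) + 1500
    ids2, alloc2, arrivals2, tau2 = _recruit_cohort(
        design, arms2, start2, n2, rng, ids[-1] + 1
    )
    if design.stage2_events is not None:
        T2 = _event_count_time(arrivals2, tau2, design.stage2_events)
        while T2 > arrivals2[-1]:
            more = _recruit_cohort(
                design, arms2, arrivals2[-1] + 1.0 / design.recruit_rate,
                1500, rng, ids2[-1] + 1,
            )
            ids2 = np.concatenate([ids2, more[0]])
            alloc2 = np.concatenate([alloc2, more[1]])
            arrivals2 = np.concatenate([arrivals2, more[2]])
            tau2 = np.concatenate([tau2, more[3]])
            T2 = _event_count_time(arrivals2, tau2, design.stage2_events)
    else:
        T2 = float(design.stage2_calendar)
    keep2 = arrivals2 < T2
    obs2 = np.minimum(tau2[keep2], T2 - arrivals2[keep2])
    ev2 = tau2[keep2] <= T2 - arrivals2[keep2]
    stage2 = SurvivalDataset(
        ids2[keep2], alloc2[keep2], arrivals2[keep2], obs2, ev2
    )
    result.stage2_end = T2

    # carry-over: stage-1 patients followed to the prefixed horizon
    horizon = T1 + design.carryover_extension
    obs1x = np.minimum(tau, horizon - arrivals)
    ev1x = tau <= horizon - arrivals
    stage1_extended = SurvivalDataset(ids, alloc, arrivals, obs1x, ev1x)
    combined = SurvivalDataset.concat([stage1_extended, stage2])

    theta_full: dict[int, float] = {}
    V_full: dict[int, float] = {}
    try:
        for j in outcome.selected:
            if design.estimation_route == "ph":
                th, V = pairwise_ph_fit(combined, j)
            else:
                S, V = logrank_score(combined, j)
                th = S / V
            theta_full[j] = th
            V_full[j] = V
        theta1_all = (
            pooled_loghr(stage1) if "shrinkage" in estimators else None
        )
        summaries = StageSummaries.build(
            theta1, V1, Sigma1, theta_full, V_full, theta1_all=theta1_all
        )
    except (CoxFitError, NonEstimableError) as exc:
        result.error = f"stage2: {exc}"
        return result

    est: dict[str, dict[int, float]] = {}
    try:
        if "naive" in estimators:
            est["naive"] = dict(theta_full)
        if "umvcue" in estimators:
            est["umvcue"] = {
                j: umvcue_estimate(
                    summaries,
                    umvcue_bounds(design.rule, outcome, summaries, j),
                    j,
                )
                for j in outcome.selected
            }
        if "si" in estimators:
            est["si"] = single_iteration_estimate(summaries, outcome)
        if "mi" in estimators:
            mi, conv, _ = multiple_iterations_estimate(summaries, outcome)
            est["mi"] = mi
            result.mi_converged = conv
        if "shrinkage" in estimators:
            cfg = ShrinkageConfig(
                w=design.shrinkage_weight(len(outcome.selected)),
                theta1_all=summaries.theta1_all,
                nu2="estimate",
            )
            sh, _ = shrinkage_estimate(summaries, outcome, cfg)
            est["shrinkage"] = sh
    except (NumericalSelectionError, FloatingPointError,
            NonEstimableError) as exc:
        result.error = f"estimation: {exc}"
    result.estimates = est
    return result


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicationResult:
    """Operating characteristics over replicated trials.

    Conditional metrics for arm j average only over replicates in which
    arm j was selected (and the trial continued); MI metrics additionally
    exclude non-converged replicates, which are counted separately.
    """

    design: TrialDesign
    n_reps: int
    seed: int
    estimators: tuple[str, ...]
    futility_freq: float
    selection_freq: dict[int, float]
    conditional_bias: dict[str, dict[int, float]]
    conditional_rmse: dict[str, dict[int, float]]
    conditional_se: dict[str, dict[int, float]]
    n_selected: dict[int, int]
    mi_nonconverged: int
    n_errors: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for j in sorted(self.selection_freq):
            row = {
                "arm": j,
                "selection_prob": self.selection_freq[j],
                "n_selected": self.n_selected[j],
            }
            for name in self.estimators:
                row[f"bias_{name}"] = self.conditional_bias[name].get(j)
                row[f"rmse_{name}"] = self.conditional_rmse[name].get(j)
            rows.append(row)
        return pd.DataFrame(rows).set_index("arm")


def replicate(
    design: TrialDesign,
    n_reps: int,
    seed: int,
    estimators: tuple[str, ...] = ("naive", "umvcue"),
    stage1_only: bool = False,
) -> ReplicationResult:
    """Replicate the design and summarize conditional operating
    characteristics.

    Each replicate gets an independent substream of the master seed, so
    results do not depend on evaluation order.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    theta = np.asarray(design.theta)

    sel_count = {j: 0 for j in range(1, design.K + 1)}
    futility = 0
    errors = 0
    mi_nonconv = 0
    values: dict[str, dict[int, list[float]]] = {
        name: {j: [] for j in range(1, design.K + 1)} for name in estimators
    }

    for child in children:
        res = simulate_trial(
            design, np.random.default_rng(child),
            estimators=() if stage1_only else estimators,
            stage1_only=stage1_only,
        )
        if res.error is not None and not res.futility:
            errors += 1
            continue
        if res.futility:
            futility += 1
            continue
        for j in res.selected:
            sel_count[j] += 1
        if stage1_only:
            continue
        if not res.mi_converged:
            mi_nonconv += 1
        for name in estimators:
            if name == "mi" and not res.mi_converged:
                continue
            for j, v in res.estimates.get(name, {}).items():
                values[name][j].append(v)

    n_eff = n_reps - errors
    bias: dict[str, dict[int, float]] = {}
    rmse: dict[str, dict[int, float]] = {}
    se: dict[str, dict[int, float]] = {}
    for name in estimators:
        bias[name], rmse[name], se[name] = {}, {}, {}
        for j in range(1, design.K + 1):
            v = np.asarray(values[name][j])
            if len(v) == 0:
                continue
            err = v - theta[j - 1]
            bias[name][j] = float(err.mean())
            rmse[name][j] = float(np.sqrt(np.mean(err ** 2)))
            se[name][j] = float(err.std(ddof=1) / np.sqrt(len(err))
                                if len(err) > 1 else np.nan)
    return ReplicationResult(
        design=design,
        n_reps=n_reps,
        seed=seed,
        estimators=tuple(estimators),
        futility_freq=futility / n_eff if n_eff else np.nan,
        selection_freq={
            j: sel_count[j] / n_eff if n_eff else np.nan for j in sel_count
        },
        conditional_bias=bias,
        conditional_rmse=rmse,
        conditional_se=se,
        n_selected=sel_count,
        mi_nonconverged=mi_nonconv,
        n_errors=errors,
    )


# ---------------------------------------------------------------------------
# normal-theory shortcut
# ---------------------------------------------------------------------------

def normal_theory_replicate(
    theta,
    Sigma1,
    sigma2sq,
    rule: SelectionRule,
    n_reps: int,
    seed: int,
):
    """Draw stage-wise estimates directly from their joint normal law.

    For each replicate, theta1 ~ MVN(theta, Sigma1) and, for every arm
    selected by ``rule``, an independent stage-2 increment
    theta2_j ~ N(theta_j, sigma2sq_j); the naive estimate recombines the
    two stages by inverse-variance weighting and the UMVCUE is evaluated
    from its closed form.  Returns a dict of flat arrays

        rep, arm, theta1_sel, theta2, naive, umvcue, W, w_src

    with one row per (replicate, selected arm).  This is the fast oracle
    for conditional-unbiasedness checks: it isolates the estimator algebra
    from the survival-sampling layer.
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta, dtype=float)
    Sigma1 = np.asarray(Sigma1, dtype=float)
    sigma2sq = np.asarray(sigma2sq, dtype=float)
    K = len(theta)
    V1 = 1.0 / np.diag(Sigma1)
    s1sq = np.diag(Sigma1)

    L = np.linalg.cholesky(Sigma1)
    th1 = theta + rng.standard_normal((n_reps, K)) @ L.T

    thr = rule.own_threshold(V1)
    if rule.is_best_type:
        score = th1 * np.sqrt(V1) if rule.is_pval_type else th1
        jstar = np.argmin(score, axis=1)
        cont = th1[np.arange(n_reps), jstar] <= thr[jstar]
        rep_idx = np.nonzero(cont)[0]
        arm_idx = jstar[cont]
        # competitor minimum on the selected arm's scale
        if rule.is_pval_type:
            scaled = th1[rep_idx] * np.sqrt(V1)[None, :]
            scaled = scaled / np.sqrt(V1[arm_idx])[:, None]
        else:
            scaled = th1[rep_idx].copy()
        scaled[np.arange(len(rep_idx)), arm_idx] = np.inf
        lmin = np.argmin(scaled, axis=1)
        comp = scaled[np.arange(len(rep_idx)), lmin]
        own = thr[arm_idx]
        use_comp = comp <= own
        W = np.where(use_comp, comp, own)
        w_src = np.where(use_comp, lmin, -1)
    else:
        sel = th1 <= thr[None, :]
        rep_idx, arm_idx = np.nonzero(sel)
        W = thr[arm_idx]
        w_src = np.full(len(rep_idx), -1)

    th1_sel = th1[rep_idx, arm_idx]
    s1 = s1sq[arm_idx]
    s2 = sigma2sq[arm_idx]
    th2 = theta[arm_idx] + np.sqrt(s2) * rng.standard_normal(len(rep_idx))
    naive = (s2 * th1_sel + s1 * th2) / (s1 + s2)
    eta = s2 / np.sqrt(s1 + s2)

    # truncation bounds on theta2 (vectorized umvcue_bounds)
    BL = np.full(len(rep_idx), -np.inf)
    BU = np.full(len(rep_idx), np.inf)
    own_mask = w_src < 0
    fin = own_mask & np.isfinite(W)
    BL[fin] = ((s1[fin] + s2[fin]) * naive[fin] - s2[fin] * W[fin]) / s1[fin]
    if (~own_mask).any():
        m = ~own_mask
        q = Sigma1[arm_idx[m], w_src[m]]
        if rule.is_pval_type:
            s1j = np.sqrt(s1[m])
            s1l = np.sqrt(s1sq[w_src[m]])
            qS = s1j * s1l
            num = (s2[m] * s1l * W[m] + s1j * q * th2[m]
                   - s1l * (s1[m] + s2[m]) * naive[m])
            den = s1j * q - s1[m] * s1l
        else:
            qS = s1[m]
            num = (s2[m] * W[m] + q * th2[m]
                   - (s1[m] + s2[m]) * naive[m])
            den = q - s1[m]
        B = num / den
        hi_side = q > qS
        BU[np.nonzero(m)[0][hi_side]] = B[hi_side]
        BL[np.nonzero(m)[0][~hi_side]] = B[~hi_side]

    lo = (BL - naive) / eta
    hi = (BU - naive) / eta
    ratio = np.zeros(len(rep_idx))
    only_lo = np.isfinite(lo) & ~np.isfinite(hi)
    only_hi = np.isfinite(hi) & ~np.isfinite(lo)
    both = np.isfinite(lo) & np.isfinite(hi)
    ratio[only_lo] = -np.exp(
        norm.logpdf(lo[only_lo]) - norm.logsf(lo[only_lo])
    )
    ratio[only_hi] = np.exp(
        norm.logpdf(hi[only_hi]) - norm.logcdf(hi[only_hi])
    )
    if both.any():
        denom = norm.cdf(hi[both]) - norm.cdf(lo[both])
        ratio[both] = (norm.pdf(hi[both]) - norm.pdf(lo[both])) / denom
    umv = naive - eta * ratio

    return {
        "rep": rep_idx,
        "arm": arm_idx + 1,
        "theta1_sel": th1_sel,
        "theta2": th2,
        "naive": naive,
        "umvcue": umv,
        "W": W,
        "w_src": np.where(w_src < 0, 0, w_src + 1),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# design calculator
# ---------------------------------------------------------------------------

def required_events(
    power: float, alpha_two_sided: float, hr: float,
    allocation_ratio: float = 1.0,
) -> int:
    """Schoenfeld event count for a two-arm logrank comparison.

    d = (1 + r)^2 / r * (z_{1-alpha/2} + z_{power})^2 / (ln hr)^2 for
    allocation ratio r, rounded up to the next even integer (r = 1 gives
    the familiar factor 4).
    """
    if not 0.0 < power < 1.0:
        raise ValueError("power must be in (0, 1)")
    if not 0.0 < alpha_two_sided < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if hr <= 0 or hr == 1.0:
        raise ValueError("hazard ratio must be positive and != 1")
    r = allocation_ratio
    z = norm.ppf(1.0 - alpha_two_sided / 2.0) + norm.ppf(power)
    d = (1.0 + r) ** 2 / r * z ** 2 / np.log(hr) ** 2
    n = int(np.ceil(d))
    return n if n % 2 == 0 else n + 1
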