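"""Selection-adjusted point estimators for the selected treatment arms.

Five estimators of the log hazard ratio theta_j of a selected arm are
provided, all operating on the stage-wise summaries (stage-1 estimates and
covariance, combined-data estimates, independent stage-2 increments):

naive
    theta_hat_j, the combined-data estimate; biased because the same
    stage-1 data drove selection.

single-iteration bias-subtracted (SI)
    theta_hat_j - b_j(theta_hat): the analytic conditional bias of the
    naive estimator, evaluated at the naive estimates themselves, is
    subtracted once.

multiple-iterations bias-subtracted (MI)
    the bias is evaluated at the fixed point of theta~ = theta_hat -
    b(theta~), solved by functional iteration.

shrinkage (SH)
    an empirical-Bayes posterior-mean shrinkage of the stage-1 estimates
    toward the pooled all-experimental-arms estimate, weighted with the
    unbiased stage-2 increment.

UMVCUE
    the Rao-Blackwell estimator E[theta2_j | sufficient statistic,
    selection event]: the unbiased stage-2 increment conditioned on a
    complete sufficient statistic, which reduces to a truncated-normal mean
    of theta2_j between selection-induced bounds (B_L, B_U).

The conditional bias of the naive estimator for arm j in the selected set S
is t_j * (E[theta1_j 1_S] / Prob(S) - theta_j) with t_j = V1_j / V_j the
information fraction; for unselected arms the naive estimator is the
stage-1 estimate with bias E[theta1_j' 1_S] / Prob(S) - theta_j'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .mvnorm import selection_moments
from .selection import SelectionOutcome, SelectionRule
from .stagewise import StageSummaries

__all__ = [
    "UmvcueBounds",
    "ShrinkageConfig",
    "EstimateReport",
    "DegenerateBranchError",
    "naive_bias",
    "single_iteration_estimate",
    "multiple_iterations_estimate",
    "estimate_nu2",
    "shrinkage_estimate",
    "stage1_shrinkage_vector",
    "umvcue_bounds",
    "umvcue_estimate",
    "estimate_report",
]

_PROB_FLOOR = 1e-12


class DegenerateBranchError(RuntimeError):
    """q_jl equals q(S) exactly; the truncation branch is undefined."""


# ---------------------------------------------------------------------------
# bias of the naive estimator, and the bias-subtracted estimators
# ---------------------------------------------------------------------------

def naive_bias(
    theta,
    summaries: StageSummaries,
    outcome: SelectionOutcome,
    abseps: float = 1e-6,
) -> np.ndarray:
    """Conditional bias of the naive estimators under working effects theta.

    Returns a K-vector: for j in the selected set the bias of the
    combined-data estimate, t_j * (E[theta1_j 1_S]/Prob(S) - theta_j); for
    unselected arms the bias of the stage-1 estimate.
    """
    theta = np.asarray(theta, dtype=float)
    P, mom = selection_moments(
        theta, summaries.Sigma1, outcome, abseps=abseps,
        prob_floor=_PROB_FLOOR,
    )
    cond_mean = mom / P
    bias = cond_mean - theta
    for j in outcome.selected:
        bias[j - 1] *= summaries.t_frac(j)
    return bias


def _naive_vector(
    summaries: StageSummaries, outcome: SelectionOutcome
) -> np.ndarray:
    """The K-vector of naive estimates: combined-data estimates for
    selected arms, stage-1 estimates elsewhere."""
    v = summaries.theta1.copy()
    for j in outcome.selected:
        v[j - 1] = summaries.theta_full[j]
    return v


def single_iteration_estimate(
    summaries: StageSummaries,
    outcome: SelectionOutcome,
    abseps: float = 1e-6,
) -> dict[int, float]:
    """Single-iteration bias-subtracted estimates for the selected arms."""
    theta_hat = _naive_vector(summaries, outcome)
    b = naive_bias(theta_hat, summaries, outcome, abseps=abseps)
    return {j: float(theta_hat[j - 1] - b[j - 1]) for j in outcome.selected}


def multiple_iterations_estimate(
    summaries: StageSummaries,
    outcome: SelectionOutcome,
    tol: float = 1e-6,
    max_iter: int = 100,
    abseps: float = 1e-6,
) -> tuple[dict[int, float], bool, int]:
    """Multiple-iterations bias-subtracted estimates.

    Solves theta~ = theta_hat - b(theta~) by functional iteration started
    at the naive vector; convergence is declared when the sup-norm step
    drops to ``tol``.  Divergence (step norm doubling over 10 consecutive
    iterations) or exhaustion of ``max_iter`` returns the last iterate with
    ``converged=False`` rather than raising, so that a prespecified
    fallback estimator can be used.
    """
    theta_hat = _naive_vector(summaries, outcome)
    theta_t = theta_hat.copy()
    converged = False
    growth_run = 0
    prev_step = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        b = naive_bias(theta_t, summaries, outcome, abseps=abseps)
        nxt = theta_hat - b
        step = float(np.max(np.abs(nxt - theta_t)))
        theta_t = nxt
        if step <= tol:
            converged = True
            break
        growth_run = growth_run + 1 if step > 2.0 * prev_step else 0
        if growth_run >= 10:
            break
        prev_step = step
    est = {j: float(theta_t[j - 1]) for j in outcome.selected}
    return est, converged, it


# ---------------------------------------------------------------------------
# shrinkage estimator
# ---------------------------------------------------------------------------

@dataclass
class ShrinkageConfig:
    """Configuration of the two-stage shrinkage estimator.

    ``w`` weights the stage-1 shrinkage value against the stage-2
    increment; ``nu2`` is the prior variance of the exchangeable normal
    prior on the K true effects, either a fixed value or ``"estimate"`` for
    the method-of-moments fixed point; ``theta1_all`` is the pooled stage-1
    estimate used as the shrinkage target (all experimental arms versus
    control).
    """

    w: float
    theta1_all: float
    nu2: float | str = "estimate"

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("weight w must lie in [0, 1]")
        if isinstance(self.nu2, str):
            if self.nu2 != "estimate":
                raise ValueError("nu2 must be a number or 'estimate'")
        elif self.nu2 < 0:
            raise ValueError("nu2 must be >= 0")

    @staticmethod
    def event_count_weight(E1: int, E2: int, n_selected: int, K: int) -> float:
        """Planned-event weight w = E1(|S|+1) / (E1(|S|+1) + E2(K+1))."""
        return E1 * (n_selected + 1) / (E1 * (n_selected + 1) + E2 * (K + 1))


def estimate_nu2(
    theta1,
    sigma1sq,
    theta1_all: float,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> float:
    """Method-of-moments prior variance for the shrinkage estimator.

    Iterates nu2 <- max{0, sum_j w_j [(theta1_j - theta1_all)^2 -
    sigma1_j^2] / sum_j w_j} with precision weights
    w_j = 1 / (nu2 + sigma1_j^2) until stable.  Truncation at zero gives
    complete shrinkage to the pooled estimate when the observed spread is
    within sampling noise.
    """
    theta1 = np.asarray(theta1, dtype=float)
    sigma1sq = np.asarray(sigma1sq, dtype=float)
    resid2 = (theta1 - theta1_all) ** 2
    nu2 = max(0.0, float(np.mean(resid2 - sigma1sq)))
    for _ in range(max_iter):
        w = 1.0 / (nu2 + sigma1sq)
        nxt = max(0.0, float(np.sum(w * (resid2 - sigma1sq)) / np.sum(w)))
        if abs(nxt - nu2) <= tol:
            return nxt
        nu2 = nxt
    return nu2


def stage1_shrinkage_vector(
    theta1, Sigma1, theta1_all: float, nu2: float
) -> np.ndarray:
    """Posterior-mean stage-1 shrinkage values for all K arms.

    C = I - Sigma1 (nu2 I + Sigma1)^{-1}; the vector is
    C theta1 + (I - C) theta1_all.
    """
    theta1 = np.asarray(theta1, dtype=float)
    Sigma1 = np.asarray(Sigma1, dtype=float)
    K = len(theta1)
    if nu2 == 0.0:
        # full shrinkage: C = 0
        return np.full(K, float(theta1_all))
    M = np.linalg.solve(nu2 * np.eye(K) + Sigma1, np.eye(K))
    C = np.eye(K) - Sigma1 @ M
    return C @ theta1 + (np.eye(K) - C) @ np.full(K, float(theta1_all))


def shrinkage_estimate(
    summaries: StageSummaries,
    outcome: SelectionOutcome,
    cfg: ShrinkageConfig,
) -> tuple[dict[int, float], float]:
    """Two-stage shrinkage estimates for the selected arms.

    Returns the per-arm estimates w * SH1_j + (1 - w) * theta2_j together
    with the prior variance nu2 actually used.
    """
    if cfg.nu2 == "estimate":
        nu2 = estimate_nu2(
            summaries.theta1, summaries.sigma1sq, cfg.theta1_all
        )
    else:
        nu2 = float(cfg.nu2)
    sh1 = stage1_shrinkage_vector(
        summaries.theta1, summaries.Sigma1, cfg.theta1_all, nu2
    )
    est = {
        j: float(cfg.w * sh1[j - 1] + (1.0 - cfg.w) * summaries.theta2[j])
        for j in outcome.selected
    }
    return est, nu2


# ---------------------------------------------------------------------------
# the approximate UMVCUE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UmvcueBounds:
    """Selection-induced truncation bounds on the stage-2 increment.

    ``eta = sigma2^2 / sqrt(sigma1^2 + sigma2^2)`` is the conditional
    standard deviation of theta2_j given the sufficient statistic.
    """

    BL: float
    BU: float
    eta: float

    def __post_init__(self):
        if not self.BL < self.BU:
            raise ValueError("need BL < BU")
        if not self.eta > 0:
            raise ValueError("eta must be positive")


def umvcue_bounds(
    rule: SelectionRule,
    outcome: SelectionOutcome,
    summaries: StageSummaries,
    j: int,
) -> UmvcueBounds:
    """Map the stage-1 selection constraint to bounds on theta2_j.

    Holding the sufficient statistic fixed, the selection constraint
    theta1_j <= W_j becomes a one-sided interval for theta2_j.  When W_j is
    the rule's own threshold (pure threshold rules, or a best-type rule
    whose binding constraint is the futility boundary) the bound is

        B_L = ((sigma1^2 + sigma2^2) theta_hat_j - sigma2^2 W_j) / sigma1^2,
        B_U = +inf.

    When W_j is achieved by a competitor arm l the bound additionally
    involves the covariance q_jl; the side of the truncation flips with the
    sign of q_jl - q(S), where q(S) = sigma1_j^2 for log-HR based rules and
    q(S) = sigma1_j sigma1_l for P-value based rules.
    """
    if j not in outcome.selected:
        raise ValueError(f"arm {j} is not in the selected set")
    s1 = float(summaries.sigma1sq[j - 1])
    s2 = float(summaries.sigma2sq[j])
    theta_hat = float(summaries.theta_full[j])
    eta = s2 / math.sqrt(s1 + s2)
    _, W = outcome.bounds[j]
    src = outcome.w_source[j]

    if src is None:
        if not np.isfinite(W):
            return UmvcueBounds(-np.inf, np.inf, eta)
        BL = ((s1 + s2) * theta_hat - s2 * W) / s1
        return UmvcueBounds(BL, np.inf, eta)

    # competitor-achieved bound: W = theta1_l (log-HR scale) or the
    # rescaled theta1_l on arm j's P-value scale
    l = src
    q = float(summaries.Sigma1[j - 1, l - 1])
    theta2 = float(summaries.theta2[j])
    if rule.is_pval_type:
        s1_j = math.sqrt(s1)
        s1_l = math.sqrt(float(summaries.sigma1sq[l - 1]))
        qS = s1_j * s1_l
        num = (s2 * s1_l * W + s1_j * q * theta2
               - s1_l * (s1 + s2) * theta_hat)
        den = s1_j * q - s1 * s1_l
    else:
        qS = s1
        num = s2 * W + q * theta2 - (s1 + s2) * theta_hat
        den = q - s1
    if den == 0.0 or q == qS:
        raise DegenerateBranchError(
            f"arm {j}: q_jl = q(S) = {qS}; truncation branch undefined"
        )
    B = num / den
    if q > qS:
        return UmvcueBounds(-np.inf, B, eta)
    return UmvcueBounds(B, np.inf, eta)


def umvcue_estimate(
    summaries: StageSummaries, bounds: UmvcueBounds, j: int
) -> float:
    """Evaluate the UMVCUE for a selected arm from its truncation bounds.

        theta_UMV = theta_hat_j - eta * [phi(u) - phi(l)] / [Phi(u) - Phi(l)]

    with u = (B_U - theta_hat_j)/eta, l = (B_L - theta_hat_j)/eta.  One-sided
    truncations are evaluated through log-scale Mills ratios, which stay
    accurate arbitrarily far into the tails.
    """
    theta_hat = float(summaries.theta_full[j])
    eta = bounds.eta
    lo = (bounds.BL - theta_hat) / eta
    hi = (bounds.BU - theta_hat) / eta

    if not np.isfinite(lo) and not np.isfinite(hi):
        return theta_hat
    if not np.isfinite(hi):
        # [B_L, inf): ratio = -phi(lo) / (1 - Phi(lo))
        ratio = -math.exp(norm.logpdf(lo) - norm.logsf(lo))
    elif not np.isfinite(lo):
        # (-inf, B_U]: ratio = phi(hi) / Phi(hi)
        ratio = math.exp(norm.logpdf(hi) - norm.logcdf(hi))
    else:
        denom = norm.cdf(hi) - norm.cdf(lo)
        if denom < _PROB_FLOOR:
            raise FloatingPointError(
                f"arm {j}: truncation mass underflow on "
                f"[{bounds.BL}, {bounds.BU}]"
            )
        ratio = (norm.pdf(hi) - norm.pdf(lo)) / denom
    return theta_hat - eta * ratio


# ---------------------------------------------------------------------------
# combined report
# ---------------------------------------------------------------------------

@dataclass
class EstimateReport:
    """All five estimators per selected arm, with diagnostics."""

    selected: tuple[int, ...]
    naive: dict[int, float]
    si: dict[int, float]
    mi: dict[int, float]
    mi_converged: bool
    mi_iterations: int
    shrinkage: dict[int, float]
    nu2: float
    w: float
    umvcue: dict[int, float]
    umvcue_bounds: dict[int, tuple[float, float]] = field(
        default_factory=dict
    )

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "naive": {str(k): v for k, v in self.naive.items()},
            "si": {str(k): v for k, v in self.si.items()},
            "mi": {str(k): v for k, v in self.mi.items()},
            "mi_converged": self.mi_converged,
            "mi_iterations": self.mi_iterations,
            "shrinkage": {str(k): v for k, v in self.shrinkage.items()},
            "nu2": self.nu2,
            "w": self.w,
            "umvcue": {str(k): v for k, v in self.umvcue.items()},
            "umvcue_bounds": {
                str(k): list(v) for k, v in self.umvcue_bounds.items()
            },
        }

    def to_frame(self):
        import pandas as pd

        rows = []
        for j in self.selected:
            rows.append(
                {
                    "arm": j,
                    "naive": self.naive[j],
                    "umvcue": self.umvcue[j],
                    "si": self.si[j],
                    "mi": self.mi[j],
                    "shrinkage": self.shrinkage[j],
                }
            )
        return pd.DataFrame(rows).set_index("arm")


def estimate_report(
    summaries: StageSummaries,
    outcome: SelectionOutcome,
    shrink: ShrinkageConfig,
    mi_tol: float = 1e-6,
    mi_max_iter: int = 100,
    abseps: float = 1e-6,
) -> EstimateReport:
    """Compute all five estimators for every selected arm."""
    rule = outcome.rule
    naive = {j: float(summaries.theta_full[j]) for j in outcome.selected}
    si = single_iteration_estimate(summaries, outcome, abseps=abseps)
    mi, conv, iters = multiple_iterations_estimate(
        summaries, outcome, tol=mi_tol, max_iter=mi_max_iter, abseps=abseps
    )
    sh, nu2 = shrinkage_estimate(summaries, outcome, shrink)
    umv = {}
    ubounds = {}
    for j in outcome.selected:
        b = umvcue_bounds(rule, outcome, summaries, j)
        umv[j] = float(umvcue_estimate(summaries, b, j))
        ubounds[j] = (b.BL, b.BU)
    return EstimateReport(
        selected=outcome.selected,
        naive=naive,
        si=si,
        mi=mi,
        mi_converged=conv,
        mi_iterations=iters,
        shrinkage=sh,
        nu2=nu2,
        w=shrink.w,
        umvcue=umv,
        umvcue_bounds=ubounds,
    )
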