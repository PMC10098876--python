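"""Newton solver for the Cox proportional-hazards partial likelihood.

The trial analyses only ever fit treatment-indicator models (at most K
binary covariates), but each simulated trial refits the model thousands of
times, so the solver is written directly on sorted arrays with reverse
cumulative sums rather than through a general-purpose survival package.
Tied event times are handled with the Breslow convention.
"""

from __future__ import annotations

import numpy as np


class CoxFitError(RuntimeError):
    """Partial-likelihood maximization failed (no events, separation,
    monotone likelihood or singular information)."""


def cox_newton(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximize the Breslow partial likelihood by Newton-Raphson.

    Parameters
    ----------
    times : observed times on study (> 0).
    events : event indicators (True = event, False = censored).
    X : (n, p) covariate matrix.
    tol : convergence tolerance on the sup-norm of the score vector.
    max_iter : maximum Newton iterations.

    Returns
    -------
    beta : (p,) estimated log hazard ratios.
    cov : (p, p) inverse observed information.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != times.shape[0]:
        X = X.T
    n, p = X.shape
    if not events.any():
        raise CoxFitError("no events: partial likelihood is flat")

    order = np.argsort(times, kind="stable")
    ts = times[order]
    ev = events[order]
    Xs = np.ascontiguousarray(X[order])
    # risk set of an event at t is the suffix starting at the first
    # index of its tie group
    grp_start = np.searchsorted(ts, ts, side="left")
    d_idx = np.nonzero(ev)[0]
    d_grp = grp_start[d_idx]
    Xd_sum = Xs[d_idx].sum(axis=0)

    XX = Xs[:, :, None] * Xs[:, None, :]
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = Xs @ beta
        eta -= eta.max()  # guards exp overflow; cancels in all ratios
        w = np.exp(eta)
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum((Xs * w[:, None])[::-1], axis=0)[::-1]
        new_loglik = eta[d_idx].sum() - np.log(S0[d_grp]).sum()
        u = S1[d_grp] / S0[d_grp, None]
        grad = Xd_sum - u.sum(axis=0)
        # S2 contribution: sum_d E_d[x x'] where E_d is wrt risk-set weights
        S2 = np.cumsum((XX * w[:, None, None])[::-1], axis=0)[::-1]
        info = (S2[d_grp] / S0[d_grp, None, None]).sum(axis=0) - np.einsum(
            "dj,dk->jk", u, u
        )
        if np.max(np.abs(grad)) <= tol:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise CoxFitError(f"singular information matrix: {exc}") from exc
        # step-halving keeps the likelihood monotone; the tolerance is
        # relative to |loglik| so float noise in large sums cannot stall it
        ll_slack = 1e-10 * (abs(new_loglik) + 1.0)
        halvings = 0
        while halvings < 30:
            cand = beta + step
            eta_c = Xs @ cand
            eta_c -= eta_c.max()
            w_c = np.exp(eta_c)
            S0_c = np.cumsum(w_c[::-1])[::-1]
            ll_c = eta_c[d_idx].sum() - np.log(S0_c[d_grp]).sum()
            if ll_c >= new_loglik - ll_slack:
                break
            step = step / 2.0
            halvings += 1
        beta = beta + step
        if np.max(np.abs(beta)) > 50.0:
            raise CoxFitError(
                "monotone likelihood / separation: estimate diverging "
                f"(|beta| > 50 at beta={beta})"
            )
    else:
        raise CoxFitError(f"no convergence in {max_iter} Newton iterations")

    if np.max(np.abs(beta)) > 15.0:
        # a |log HR| beyond 15 means some arm contributed (almost) no
        # events inside shared risk sets: the likelihood is monotone
        raise CoxFitError(
            "monotone likelihood / separation: an arm has no events in "
            f"shared risk sets (beta={beta})"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise CoxFitError(f"singular information at optimum: {exc}") from exc
    return beta, cov
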