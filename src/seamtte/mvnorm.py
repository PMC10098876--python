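"""Rectangle probabilities and first truncated moments of MVN vectors.

These are the computational kernels behind the selection probability
Prob(S), the truncated means E[theta1_j 1_S] appearing in the bias of the
naive estimator, and the fixed point solved by the multiple-iterations
bias-subtracted estimator.

Rectangle probabilities in dimension >= 2 are computed with scipy's
quasi-Monte-Carlo integrator; a fixed internal randomization seed makes the
returned values deterministic across calls and runs.  First moments use the
standard decomposition

    E[X 1_R] = mu * P(R) + Sigma @ c,
    c_k = phi_k(l_k) P(R_{-k} | X_k = l_k) - phi_k(u_k) P(R_{-k} | X_k = u_k),

where phi_k is the marginal density of X_k and the conditional factors are
(m-1)-dimensional rectangle probabilities of the conditional normal law.
Infinite limits are represented as +/-inf and contribute nothing at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal, norm

__all__ = [
    "MvnRectangle",
    "NumericalSelectionError",
    "rect_prob",
    "rect_first_moments",
    "selection_moments",
]

# randomization seed for the QMC lattice; fixed so that outputs are
# reproducible to within the integration tolerance
_QMC_SEED = 186283


class NumericalSelectionError(RuntimeError):
    """Selection probability below the numerical floor for the supplied
    working mean."""


@dataclass(frozen=True)
class MvnRectangle:
    """A rectangle event {lower <= X <= upper} for X ~ MVN(mean, cov)."""

    mean: np.ndarray
    cov: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        for name in ("mean", "cov", "lower", "upper"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        m = len(self.mean)
        if self.cov.shape != (m, m):
            raise ValueError("cov shape inconsistent with mean")
        if self.lower.shape != (m,) or self.upper.shape != (m,):
            raise ValueError("limit shapes inconsistent with mean")
        if not np.all(self.lower < self.upper):
            raise ValueError("need lower < upper componentwise")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("cov must be symmetric")
        w = np.linalg.eigvalsh(self.cov)
        if w.min() < -1e-10 * max(w.max(), 1.0):
            raise ValueError("cov must be positive semi-definite")

    @property
    def dim(self) -> int:
        return len(self.mean)


def rect_prob(r: MvnRectangle, abseps: float = 1e-6) -> float:
    """P(lower <= X <= upper) for X ~ MVN(mean, cov).

    Univariate rectangles use the exact normal cdf; higher dimensions use
    the QMC integrator with absolute accuracy ``abseps`` and a fixed
    internal randomization seed.
    """
    if r.dim == 1:
        s = np.sqrt(r.cov[0, 0])
        if s == 0.0:
            return float(r.lower[0] <= r.mean[0] <= r.upper[0])
        return float(
            norm.cdf((r.upper[0] - r.mean[0]) / s)
            - norm.cdf((r.lower[0] - r.mean[0]) / s)
        )
    p = multivariate_normal.cdf(
        r.upper,
        mean=r.mean,
        cov=r.cov,
        lower_limit=r.lower,
        abseps=abseps,
        releps=0.0,
        rng=np.random.default_rng(_QMC_SEED),
    )
    return float(min(max(p, 0.0), 1.0))


def _conditional_rect(r: MvnRectangle, k: int, x_k: float) -> MvnRectangle:
    """The (m-1)-dimensional conditional rectangle given X_k = x_k."""
    idx = [i for i in range(r.dim) if i != k]
    s_kk = r.cov[k, k]
    s_rk = r.cov[idx, k]
    mean_c = r.mean[idx] + s_rk * (x_k - r.mean[k]) / s_kk
    cov_c = r.cov[np.ix_(idx, idx)] - np.outer(s_rk, s_rk) / s_kk
    # symmetrize and clip tiny negative variances from cancellation
    cov_c = (cov_c + cov_c.T) / 2.0
    d = np.diag(cov_c).copy()
    bad = d < 0
    if bad.any():
        cov_c[np.diag_indices_from(cov_c)] = np.where(bad, 0.0, d)
    return MvnRectangle(mean_c, cov_c, r.lower[idx], r.upper[idx])


def rect_first_moments(r: MvnRectangle, abseps: float = 1e-6) -> np.ndarray:
    """E[X_j 1{lower <= X <= upper}] for each component j."""
    P = rect_prob(r, abseps=abseps)
    c = np.zeros(r.dim)
    for k in range(r.dim):
        s_k = np.sqrt(r.cov[k, k])
        for bound, sign in ((r.lower[k], 1.0), (r.upper[k], -1.0)):
            if not np.isfinite(bound):
                continue
            dens = norm.pdf(bound, loc=r.mean[k], scale=s_k)
            if dens == 0.0:
                continue
            if r.dim == 1:
                cond_p = 1.0
            else:
                cond_p = rect_prob(
                    _conditional_rect(r, k, bound), abseps=abseps
                )
            c[k] += sign * dens * cond_p
    return r.mean * P + r.cov @ c


def selection_moments(
    theta,
    Sigma1,
    outcome,
    abseps: float = 1e-6,
    prob_floor: float = 1e-12,
) -> tuple[float, np.ndarray]:
    """Selection probability and truncated first moments of theta1.

    Maps the stage-1 estimator vector into the rectangle coordinates of the
    selection region (delta1 = A theta1 ~ MVN(A theta, A Sigma1 A')),
    evaluates the rectangle probability and first moments there, and maps
    the moments back, returning

        (Prob(S), E[theta1_j 1_S] for j = 1..K)

    under working true effects ``theta``.
    """
    theta = np.asarray(theta, dtype=float)
    Sigma1 = np.asarray(Sigma1, dtype=float)
    A = outcome.region.A
    rect = MvnRectangle(
        A @ theta, A @ Sigma1 @ A.T, outcome.region.lower,
        outcome.region.upper,
    )
    P = rect_prob(rect, abseps=abseps)
    if P < prob_floor:
        raise NumericalSelectionError(
            f"selection probability {P:.3e} below floor {prob_floor:.1e} "
            f"under working mean {theta}"
        )
    m_delta = rect_first_moments(rect, abseps=abseps)
    m_theta = np.linalg.solve(A, m_delta)
    return P, m_theta
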