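"""Stage-wise log hazard ratio estimation for two-stage multi-arm trials.

A two-stage seamless phase II/III trial compares K experimental arms with a
shared control.  At the interim analysis every pairwise comparison j yields
a stage-1 log hazard ratio estimate theta1_j with Fisher information V1_j;
after stage 2 each selected arm has a combined-data estimate theta_j with
information V_j.  This module provides both estimation routes discussed for
such designs:

* the logrank score route: theta1_j = S1_j / V1_j from the logrank score
  statistic and its hypergeometric variance, with the cross-arm covariance
  q_ij induced by the shared control computed from risk-set fractions at
  control event times; and
* the proportional-hazards regression route: a single Cox model with K
  treatment indicators at the interim, and pairwise Cox models on the
  combined data.

Either way the stage-2 contribution is isolated through the independent
increment construction theta2_j = (S_j - S1_j) / (V_j - V1_j), which is the
quantity the selection-adjusted estimators treat as untouched by selection.

Sign convention throughout: a negative log hazard ratio means the
experimental arm is superior to control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from ._coxph import CoxFitError, cox_newton

__all__ = [
    "SurvivalDataset",
    "StageSummaries",
    "CarryoverFollowUp",
    "NonEstimableError",
    "CoxFitError",
    "logrank_score",
    "stage1_covariance",
    "fit_multiarm_ph",
    "pairwise_ph_fit",
    "pooled_loghr",
    "increment_decompose",
    "combine_stages",
]


class NonEstimableError(RuntimeError):
    """A log hazard ratio is not estimable (zero information)."""


@dataclass(frozen=True)
class SurvivalDataset:
    """Per-subject survival records for a multi-arm trial.

    Attributes
    ----------
    subject_id : integer identifiers, one per record.
    arm : arm codes with 0 = control and 1..K the experimental arms.
    recruit_time : calendar time of recruitment, days >= 0.
    time : observed time on study, days > 0.
    event : True for an observed event, False for censoring.
    """

    subject_id: np.ndarray
    arm: np.ndarray
    recruit_time: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        for name in ("subject_id", "arm", "recruit_time", "time", "event"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = len(self.subject_id)
        if not all(
            len(getattr(self, f)) == n
            for f in ("arm", "recruit_time", "time", "event")
        ):
            raise ValueError("field lengths differ")
        if n and self.time.min() <= 0:
            raise ValueError("observed_time must be > 0")
        if n and self.recruit_time.min() < 0:
            raise ValueError("recruit_time must be >= 0")
        if n and self.arm.min() < 0:
            raise ValueError("arm codes must be >= 0 (0 = control)")

    @property
    def n(self) -> int:
        return len(self.subject_id)

    @property
    def n_arms(self) -> int:
        """Number of experimental arms (max arm code)."""
        return int(self.arm.max()) if self.n else 0

    @property
    def calendar_end(self) -> np.ndarray:
        """Calendar time of event or censoring."""
        return self.recruit_time + self.time

    def restrict_arms(self, arms) -> "SurvivalDataset":
        mask = np.isin(self.arm, np.asarray(list(arms)))
        return self._mask(mask)

    def administrative_censor(self, analysis_time: float) -> "SurvivalDataset":
        """Freeze the data at a calendar analysis time.

        Subjects recruited at or after ``analysis_time`` are dropped; the
        rest are censored at ``analysis_time`` on the calendar scale.
        """
        keep = self.recruit_time < analysis_time
        ds = self._mask(keep)
        cutoff = analysis_time - ds.recruit_time
        new_time = np.minimum(ds.time, cutoff)
        new_event = ds.event & (ds.time <= cutoff)
        return replace(ds, time=new_time, event=new_event)

    def _mask(self, mask: np.ndarray) -> "SurvivalDataset":
        return SurvivalDataset(
            self.subject_id[mask],
            self.arm[mask],
            self.recruit_time[mask],
            self.time[mask],
            self.event[mask],
        )

    @staticmethod
    def concat(parts) -> "SurvivalDataset":
        return SurvivalDataset(
            np.concatenate([p.subject_id for p in parts]),
            np.concatenate([p.arm for p in parts]),
            np.concatenate([p.recruit_time for p in parts]),
            np.concatenate([p.time for p in parts]),
            np.concatenate([p.event for p in parts]),
        )


@dataclass(frozen=True)
class CarryoverFollowUp:
    """Prefixed stage-2 follow-up rule for stage-1 patients.

    Stage-1 patients without an event at the interim analysis continue to be
    followed in stage 2, censored ``extension`` days after the interim.
    Fixing the extension in advance (rather than data-dependently) is what
    keeps the stage-2 information increment approximately independent of the
    stage-1 data.
    """

    interim_time: float
    extension: float

    def apply(self, stage1_full: SurvivalDataset) -> SurvivalDataset:
        """Censor stage-1 records at ``interim_time + extension``.

        ``stage1_full`` must carry the *uncensored* stage-1 follow-up (i.e.
        events whenever they occur); the rule truncates it on the calendar
        scale.
        """
        return stage1_full.administrative_censor(
            self.interim_time + self.extension
        )


# ---------------------------------------------------------------------------
# logrank score route
# ---------------------------------------------------------------------------

def _at_risk(sorted_times: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Number of subjects with observed time >= each t."""
    return len(sorted_times) - np.searchsorted(sorted_times, t, side="left")


def logrank_score(
    data: SurvivalDataset, arm: int, analysis_time: float | None = None
) -> tuple[float, float]:
    """Logrank score statistic and Fisher information for one comparison.

    Restricts the data to the control and experimental arm ``arm`` and
    computes S = sum over event times of (observed events on the
    experimental arm minus the expected count under equal hazards) and V =
    the matching hypergeometric variance sum.  Asymptotically
    S ~ N(theta * V, V) so theta_hat = S / V.

    Ties are handled by the standard hypergeometric correction
    d (r - d) / (r - 1).
    """
    if arm < 1:
        raise ValueError("arm must be an experimental arm (>= 1)")
    ds = data.restrict_arms((0, arm))
    if analysis_time is not None:
        ds = ds.administrative_censor(analysis_time)
    if ds.n == 0 or not ds.event.any():
        raise NonEstimableError(f"arm {arm}: no events, information is zero")

    is_exp = ds.arm == arm
    all_sorted = np.sort(ds.time)
    exp_sorted = np.sort(ds.time[is_exp])

    ev_times = ds.time[ds.event]
    ev_exp = is_exp[ds.event]
    uniq, inv = np.unique(ev_times, return_inverse=True)
    d_tot = np.bincount(inv, minlength=len(uniq)).astype(float)
    d_exp = np.bincount(inv, weights=ev_exp.astype(float), minlength=len(uniq))

    r_all = _at_risk(all_sorted, uniq).astype(float)
    r_exp = _at_risk(exp_sorted, uniq).astype(float)
    frac = r_exp / r_all
    S = float(np.sum(d_exp - d_tot * frac))
    with np.errstate(divide="ignore", invalid="ignore"):
        tie = np.where(r_all > 1, (r_all - d_tot) / (r_all - 1), 0.0)
    V = float(np.sum(d_tot * frac * (1.0 - frac) * tie))
    if V <= 0:
        raise NonEstimableError(
            f"arm {arm}: zero variance (no at-risk overlap at event times)"
        )
    return S, V


def stage1_covariance(
    data: SurvivalDataset, analysis_time: float | None = None
) -> np.ndarray:
    """Covariance matrix of the K stage-1 logrank log HR estimators.

    The diagonal is 1 / V1_j.  The off-diagonal covariance induced by the
    shared control arm is

        q_ij = sigma1_i^2 sigma1_j^2 * sum_d p_{d,i} p_{d,j},

    where the sum runs over stage-1 event times, p_{d,i} =
    r_{d,i} / (r_{d,c} + r_{d,i}) when the event at t_d occurred on the
    control or arm i, and p_{d,i} = 0 when it occurred on another
    experimental arm.  Only control events contribute off-diagonally, since
    an event on arm i zeroes p_{d,j} for every j != i.  Tied times are
    processed as simultaneous events with risk sets fixed at the tie time.
    """
    ds = data
    if analysis_time is not None:
        ds = ds.administrative_censor(analysis_time)
    K = ds.n_arms
    if K < 1:
        raise ValueError("need at least one experimental arm")

    V1 = np.empty(K)
    for j in range(1, K + 1):
        _, V1[j - 1] = logrank_score(ds, j)  # raises if not estimable
    sig2 = 1.0 / V1

    Sigma = np.diag(sig2.copy())
    if K == 1:
        return Sigma

    ctrl_ev_times = ds.time[(ds.arm == 0) & ds.event]
    if len(ctrl_ev_times):
        ctrl_sorted = np.sort(ds.time[ds.arm == 0])
        r_c = _at_risk(ctrl_sorted, ctrl_ev_times).astype(float)
        P = np.empty((len(ctrl_ev_times), K))
        for j in range(1, K + 1):
            arm_sorted = np.sort(ds.time[ds.arm == j])
            r_j = _at_risk(arm_sorted, ctrl_ev_times).astype(float)
            P[:, j - 1] = r_j / (r_c + r_j)
        M = P.T @ P  # sum_d p_{d,i} p_{d,j}
        for i in range(K):
            for j in range(i + 1, K):
                q = sig2[i] * sig2[j] * M[i, j]
                Sigma[i, j] = Sigma[j, i] = q
    return Sigma


# ---------------------------------------------------------------------------
# proportional-hazards regression route
# ---------------------------------------------------------------------------

def fit_multiarm_ph(
    data: SurvivalDataset, analysis_time: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the interim Cox model with K treatment-indicator covariates.

    Returns the K-vector of stage-1 log HR estimates and the full K x K
    covariance matrix (inverse observed information), whose off-diagonal
    entries play the role of q_ij in the joint stage-1 distribution.
    """
    ds = data
    if analysis_time is not None:
        ds = ds.administrative_censor(analysis_time)
    K = ds.n_arms
    if K < 1:
        raise ValueError("need at least one experimental arm")
    X = np.empty((ds.n, K))
    for j in range(1, K + 1):
        X[:, j - 1] = ds.arm == j
    beta, cov = cox_newton(ds.time, ds.event, X)
    return beta, cov


def pairwise_ph_fit(
    data: SurvivalDataset,
    arm: int,
    analysis_time: float | None = None,
    follow_up: CarryoverFollowUp | None = None,
) -> tuple[float, float]:
    """Combined-data Cox fit for the control versus one selected arm.

    ``data`` holds all stage-1 and stage-2 records.  If ``follow_up`` is
    given it is applied first (the prefixed censoring of stage-1 carry-over
    patients is then the caller's responsibility to encode in the record
    times; see :class:`CarryoverFollowUp`).  Returns (theta_full, V_full)
    with V_full the Fisher information 1 / var(theta_full).
    """
    ds = data
    if follow_up is not None:
        ds = follow_up.apply(ds)
    ds = ds.restrict_arms((0, arm))
    if analysis_time is not None:
        ds = ds.administrative_censor(analysis_time)
    X = (ds.arm == arm).astype(float)[:, None]
    beta, cov = cox_newton(ds.time, ds.event, X)
    return float(beta[0]), float(1.0 / cov[0, 0])


def pooled_loghr(
    data: SurvivalDataset, analysis_time: float | None = None
) -> float:
    """Stage-1 log HR of all experimental arms pooled versus control.

    This is the pooled estimate used as the shrinkage target: the K
    experimental arms are treated as a single treatment group.
    """
    ds = data
    if analysis_time is not None:
        ds = ds.administrative_censor(analysis_time)
    X = (ds.arm > 0).astype(float)[:, None]
    beta, _ = cox_newton(ds.time, ds.event, X)
    return float(beta[0])


# ---------------------------------------------------------------------------
# independent-increment algebra
# ---------------------------------------------------------------------------

def increment_decompose(
    theta1_j: float, V1_j: float, theta_full_j: float, V_full_j: float
) -> tuple[float, float]:
    """Stage-2 independent increment from stage-1 and combined summaries.

    With S1 = theta1 * V1 and S = theta * V, the stage-2 estimate is
    theta2 = (S - S1) / (V - V1) with variance sigma2^2 = 1 / (V - V1).
    """
    if V1_j <= 0:
        raise NonEstimableError("stage-1 information must be positive")
    if V_full_j <= V1_j:
        raise NonEstimableError(
            f"no stage-2 information: V_full={V_full_j} <= V1={V1_j}"
        )
    S1 = theta1_j * V1_j
    S = theta_full_j * V_full_j
    dV = V_full_j - V1_j
    return (S - S1) / dV, 1.0 / dV


def combine_stages(
    theta1_j: float, sigma1sq_j: float, theta2_j: float, sigma2sq_j: float
) -> float:
    """Inverse-variance recombination of the stage-wise estimates.

    theta = (sigma2^2 * theta1 + sigma1^2 * theta2) / (sigma1^2 + sigma2^2);
    exact algebraic inverse of :func:`increment_decompose`.
    """
    return (sigma2sq_j * theta1_j + sigma1sq_j * theta2_j) / (
        sigma1sq_j + sigma2sq_j
    )


@dataclass
class StageSummaries:
    """Sufficient numerical state for the selection-adjusted estimators.

    Attributes
    ----------
    theta1 : (K,) stage-1 log HR estimates.
    V1 : (K,) stage-1 Fisher informations.
    Sigma1 : (K, K) stage-1 covariance matrix (diagonal 1/V1_j, off-diagonal
        the shared-control covariances q_ij).
    theta_full, V_full : combined-data estimate and information per selected
        arm (1-based keys).
    theta2, sigma2sq : stage-2 increment estimate and variance per selected
        arm, derived via :func:`increment_decompose`.
    theta1_all : pooled stage-1 estimate (all experimental arms vs control),
        needed by the shrinkage estimator; may be None when unavailable.
    """

    theta1: np.ndarray
    V1: np.ndarray
    Sigma1: np.ndarray
    theta_full: dict[int, float] = field(default_factory=dict)
    V_full: dict[int, float] = field(default_factory=dict)
    theta2: dict[int, float] = field(default_factory=dict)
    sigma2sq: dict[int, float] = field(default_factory=dict)
    theta1_all: float | None = None

    def __post_init__(self):
        self.theta1 = np.asarray(self.theta1, dtype=float)
        self.V1 = np.asarray(self.V1, dtype=float)
        self.Sigma1 = np.asarray(self.Sigma1, dtype=float)
        K = len(self.theta1)
        if self.V1.shape != (K,) or self.Sigma1.shape != (K, K):
            raise ValueError("inconsistent shapes in stage summaries")
        if np.any(self.V1 <= 0):
            raise ValueError("stage-1 informations must be positive")
        if not np.allclose(self.Sigma1, self.Sigma1.T):
            raise ValueError("Sigma1 must be symmetric")

    @property
    def K(self) -> int:
        return len(self.theta1)

    @property
    def sigma1sq(self) -> np.ndarray:
        return 1.0 / self.V1

    def t_frac(self, j: int) -> float:
        """Information fraction t_j = V1_j / V_j for a selected arm."""
        return float(self.V1[j - 1] / self.V_full[j])

    @classmethod
    def build(
        cls,
        theta1,
        V1,
        Sigma1,
        theta_full: dict[int, float],
        V_full: dict[int, float],
        theta1_all: float | None = None,
    ) -> "StageSummaries":
        """Assemble summaries, deriving the stage-2 increments."""
        s = cls(theta1, V1, Sigma1, dict(theta_full), dict(V_full),
                theta1_all=theta1_all)
        for j in s.theta_full:
            t2, s2 = increment_decompose(
                s.theta1[j - 1], s.V1[j - 1], s.theta_full[j], s.V_full[j]
            )
            s.theta2[j] = t2
            s.sigma2sq[j] = s2
        return s

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "theta1": self.theta1.tolist(),
            "V1": self.V1.tolist(),
            "Sigma1": self.Sigma1.tolist(),
            "theta_full": {str(k): v for k, v in self.theta_full.items()},
            "V_full": {str(k): v for k, v in self.V_full.items()},
            "theta1_all": self.theta1_all,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageSummaries":
        return cls.build(
            np.asarray(d["theta1"], dtype=float),
            np.asarray(d["V1"], dtype=float),
            np.asarray(d["Sigma1"], dtype=float),
            {int(k): float(v) for k, v in d.get("theta_full", {}).items()},
            {int(k): float(v) for k, v in d.get("V_full", {}).items()},
            theta1_all=d.get("theta1_all"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StageSummaries":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
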