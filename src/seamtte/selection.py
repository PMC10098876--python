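"""Interim treatment-selection rules and their acceptance regions.

Six standard rules are supported, identified by ``SelectionRule.kind``:

========================  ====================================================
``all_loghr_le_b``        keep every arm with stage-1 log HR <= b
``all_pval_le_a``         keep every arm with one-sided pairwise P-value <= a
``best_loghr``            keep the arm with the smallest stage-1 log HR
``best_pval``             keep the arm with the smallest pairwise P-value
``best_loghr_le_b``       smallest log HR, but only if it is <= b (else stop
                          for futility)
``best_pval_le_a``        smallest P-value, but only if its P <= a
========================  ====================================================

P-values are one-sided lower-tail: p_j = Phi(theta1_j * sqrt(V1_j)), so
p_j <= a is equivalent to theta1_j <= Phi^{-1}(a) / sqrt(V1_j) and small
p means benefit.

Every rule yields, for a selected arm j, a conditional upper bound W_j on
theta1_j (holding the co-arms fixed) and the lower bound L_j = -inf; these
bounds drive the truncation in the selection-adjusted estimators.  The full
selection event is additionally described as a rectangle
{lower <= A theta1 <= upper} in linearly transformed coordinates, which is
the form needed for multivariate-normal rectangle probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "RULE_KINDS",
    "SelectionRule",
    "Region",
    "SelectionOutcome",
    "apply_rule",
    "selection_region",
]

RULE_KINDS = (
    "all_loghr_le_b",
    "all_pval_le_a",
    "best_loghr",
    "best_pval",
    "best_loghr_le_b",
    "best_pval_le_a",
)

_NEEDS_A = {"all_pval_le_a", "best_pval_le_a"}
_NEEDS_B = {"all_loghr_le_b", "best_loghr_le_b"}
_BEST = {"best_loghr", "best_pval", "best_loghr_le_b", "best_pval_le_a"}
_PVAL = {"all_pval_le_a", "best_pval", "best_pval_le_a"}


@dataclass(frozen=True)
class SelectionRule:
    """A Table-style selection rule with its threshold parameter(s)."""

    kind: str
    a: float | None = None
    b: float | None = None

    def __post_init__(self):
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind in _NEEDS_A:
            if self.a is None or not (0.0 < self.a < 1.0):
                raise ValueError(f"rule {self.kind} needs a in (0, 1)")
            if self.b is not None:
                raise ValueError(f"rule {self.kind} does not take b")
        elif self.kind in _NEEDS_B:
            if self.b is None or not np.isfinite(self.b):
                raise ValueError(f"rule {self.kind} needs a finite b")
            if self.a is not None:
                raise ValueError(f"rule {self.kind} does not take a")
        else:
            if self.a is not None or self.b is not None:
                raise ValueError(f"rule {self.kind} takes no parameters")

    @property
    def is_best_type(self) -> bool:
        return self.kind in _BEST

    @property
    def is_pval_type(self) -> bool:
        return self.kind in _PVAL

    def own_threshold(self, V1: np.ndarray) -> np.ndarray:
        """Per-arm upper threshold on theta1_j from the rule's own-arm
        constraint; +inf for the pure 'best' rules."""
        V1 = np.asarray(V1, dtype=float)
        if self.kind in _NEEDS_B:
            return np.full(len(V1), float(self.b))
        if self.kind in _NEEDS_A:
            return norm.ppf(self.a) / np.sqrt(V1)
        return np.full(len(V1), np.inf)


@dataclass(frozen=True)
class Region:
    """Rectangle {lower <= A x <= upper} describing a selection event."""

    A: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


@dataclass(frozen=True)
class SelectionOutcome:
    """Result of applying a selection rule to the stage-1 estimates.

    ``bounds[j] = (L_j, W_j)`` for each selected arm; ``w_source[j]`` names
    the competitor arm whose estimate achieves W_j, or None when W_j is the
    rule's own threshold (b or the P-value bound).
    """

    rule: SelectionRule
    selected: tuple[int, ...]
    futility: bool
    bounds: dict[int, tuple[float, float]]
    w_source: dict[int, int | None]
    region: Region


def apply_rule(
    rule: SelectionRule, theta1, V1
) -> SelectionOutcome:
    """Apply a selection rule to the stage-1 estimates.

    Ties between arms in best-type rules are broken toward the lowest arm
    index (a measure-zero event under the continuous model).
    """
    theta1 = np.asarray(theta1, dtype=float)
    V1 = np.asarray(V1, dtype=float)
    K = len(theta1)
    if V1.shape != (K,):
        raise ValueError("theta1 and V1 must have equal length")
    if not (np.all(np.isfinite(theta1)) and np.all(V1 > 0)):
        raise ValueError("theta1 must be finite and V1 positive")

    thr = rule.own_threshold(V1)
    bounds: dict[int, tuple[float, float]] = {}
    w_source: dict[int, int | None] = {}

    if rule.is_best_type:
        score = theta1 * np.sqrt(V1) if rule.is_pval_type else theta1
        jstar = int(np.argmin(score))  # argmin takes lowest index on ties
        if theta1[jstar] <= thr[jstar]:
            selected = (jstar + 1,)
            # competitor estimates on arm-jstar's scale
            if rule.is_pval_type:
                comp = theta1 * np.sqrt(V1 / V1[jstar])
            else:
                comp = theta1.copy()
            comp[jstar] = np.inf
            lmin = int(np.argmin(comp))
            if comp[lmin] <= thr[jstar]:
                W, src = float(comp[lmin]), lmin + 1
            else:
                W, src = float(thr[jstar]), None
            if not np.isfinite(thr[jstar]) and K == 1:
                # single arm, no threshold: selection is certain and W = +inf
                W, src = np.inf, None
            bounds[jstar + 1] = (-np.inf, W)
            w_source[jstar + 1] = src
        else:
            selected = ()
    else:
        sel_mask = theta1 <= thr
        selected = tuple(int(j) + 1 for j in np.nonzero(sel_mask)[0])
        for j in selected:
            bounds[j] = (-np.inf, float(thr[j - 1]))
            w_source[j] = None

    futility = len(selected) == 0
    region = selection_region(rule, selected, V1)
    return SelectionOutcome(rule, selected, futility, bounds, w_source, region)


def selection_region(
    rule: SelectionRule, selected, V1
) -> Region:
    """Rectangle representation of the event {selection outcome = selected}.

    For threshold ('all'-type) rules A is the identity and the rectangle
    constrains each arm to its own side of the threshold.  For best-type
    rules with selected arm j the coordinates are theta1_j itself plus the
    contrasts competitor - selected (competitors rescaled by
    sqrt(V1_i / V1_j) for P-value rules), with the contrasts positive and
    theta1_j below the rule threshold.  An empty ``selected`` encodes the
    futility event, which exists only for rules with a threshold.
    """
    V1 = np.asarray(V1, dtype=float)
    K = len(V1)
    selected = tuple(int(j) for j in selected)
    thr = rule.own_threshold(V1)

    if rule.is_best_type:
        if not selected:
            if np.all(np.isinf(thr)):
                raise ValueError(
                    f"rule {rule.kind} cannot stop for futility"
                )
            # futility: every arm above its own threshold
            return Region(
                np.eye(K), thr.copy(), np.full(K, np.inf)
            )
        if len(selected) != 1:
            raise ValueError("best-type rules select exactly one arm")
        j = selected[0] - 1
        A = np.zeros((K, K))
        lower = np.empty(K)
        upper = np.empty(K)
        for i in range(K):
            if i == j:
                A[i, j] = 1.0
                lower[i], upper[i] = -np.inf, thr[j]
            else:
                scale = np.sqrt(V1[i] / V1[j]) if rule.is_pval_type else 1.0
                A[i, i] = scale
                A[i, j] = -1.0
                lower[i], upper[i] = 0.0, np.inf
        return Region(A, lower, upper)

    # threshold rules: componentwise region for an arbitrary selected set
    sel = np.zeros(K, dtype=bool)
    for j in selected:
        sel[j - 1] = True
    lower = np.where(sel, -np.inf, thr)
    upper = np.where(sel, thr, np.inf)
    return Region(np.eye(K), lower, upper)
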