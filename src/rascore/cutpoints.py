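"""Empirical ROC curves, AUC and Youden-index optimal cut-points.

A continuous covariate is dichotomized at the observed value maximizing the
Youden index J = sensitivity + specificity - 1.  Candidate thresholds are the
distinct observed data values (so a reported cut-off is always attainable
from the data); ties in J are broken by the smallest cut-off.  The risk
direction may be fixed by the caller (``ge_is_risk``: values >= cut-off are
test-positive; ``lt_is_risk``: values < cut-off are) or chosen automatically
as the direction with AUC >= 0.5.
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError

GE_IS_RISK = "ge_is_risk"
LT_IS_RISK = "lt_is_risk"


@dataclass(frozen=True)
class RocCurve:
    """Operating points of an empirical ROC curve.

    ``thresholds`` are the distinct observed values bracketed by -inf/+inf so
    the curve always contains the (sens=1, spec=0) and (sens=0, spec=1)
    endpoints; the decision rule is "positive if value >= threshold".
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


@dataclass(frozen=True)
class CutpointResult:
    variable: str
    cutoff: float
    direction: str          # GE_IS_RISK or LT_IS_RISK
    youden_j: float
    auc: float
    p_value: float


def _split(values, outcome):
    values = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if values.shape != y.shape:
        raise ValueError("values and outcome must have the same length")
    if y.min() == y.max():
        raise DegenerateDataError("outcome contains a single class")
    return values, y


def roc_curve(values, outcome) -> RocCurve:
    """Empirical ROC of ``values`` against a binary ``outcome`` (rule: value
    >= threshold is test-positive)."""
    values, y = _split(values, outcome)
    cases = np.sort(values[y == 1])
    controls = np.sort(values[y == 0])
    thr = np.unique(values)
    sens = 1.0 - np.searchsorted(cases, thr, side="left") / cases.size
    spec = np.searchsorted(controls, thr, side="left") / controls.size
    return RocCurve(
        thresholds=np.concatenate(([-np.inf], thr, [np.inf])),
        sensitivity=np.concatenate(([1.0], sens, [0.0])),
        specificity=np.concatenate(([0.0], spec, [1.0])),
    )


def auc_trapezoid(roc: RocCurve) -> float:
    """Area under an empirical ROC curve by the trapezoidal rule.

    For the empirical curve this equals the tie-corrected Mann-Whitney
    statistic (wins + half-ties over all case-control pairs).
    """
    # traverse in curve order (descending threshold -> non-decreasing FPR) so
    # diagonal tie segments contribute their half-credit correctly
    fpr = (1.0 - roc.specificity)[::-1]
    return float(np.trapezoid(roc.sensitivity[::-1], fpr))


def mann_whitney_auc(values, outcome) -> float:
    """Tie-corrected Mann-Whitney AUC, P(case > control) + 0.5 P(tie)."""
    values, y = _split(values, outcome)
    ranks = stats.rankdata(values)
    n1 = int(y.sum())
    n0 = y.size - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_pvalue(auc: float, n_pos: int, n_neg: int) -> float:
    """Two-sided p-value for H0: AUC = 0.5.

    Continuity-corrected normal approximation to the Mann-Whitney U statistic
    under the no-tie null: U = AUC * n_pos * n_neg, E[U] = n_pos*n_neg/2,
    Var[U] = n_pos*n_neg*(n_pos+n_neg+1)/12.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one case and one control")
    sd_u = math.sqrt(n_pos * n_neg * (n_pos + n_neg + 1) / 12.0)
    z = max(0.0, abs(auc - 0.5) * n_pos * n_neg - 0.5) / sd_u
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def youden_cutpoint(
    values,
    outcome,
    direction: str | None = None,
    variable: str = "",
) -> CutpointResult:
    """Optimal cut-point by the Youden index over observed thresholds.

    With ``direction=GE_IS_RISK`` the rule is "value >= cutoff"; with
    ``LT_IS_RISK`` it is "value < cutoff".  If unset, the direction giving
    AUC >= 0.5 is used.  Equal-J ties resolve to the smallest cutoff.
    """
    values, y = _split(values, outcome)
    auc_ge = mann_whitney_auc(values, y)
    if direction is None:
        direction = GE_IS_RISK if auc_ge >= 0.5 else LT_IS_RISK
    if direction not in (GE_IS_RISK, LT_IS_RISK):
        raise ValueError(f"unknown direction {direction!r}")

    cases = np.sort(values[y == 1])
    controls = np.sort(values[y == 0])
    n1, n0 = cases.size, controls.size
    thr = np.unique(values)
    cases_below = np.searchsorted(cases, thr, side="left")
    controls_below = np.searchsorted(controls, thr, side="left")
    # integer-scaled J = (sens + spec - 1) * n1 * n0, so ties are exact
    if direction == GE_IS_RISK:
        # sens = P(v >= c | case), spec = P(v < c | control)
        j_scaled = controls_below * n1 - cases_below * n0
        auc = auc_ge
    else:
        # sens = P(v < c | case), spec = P(v >= c | control)
        j_scaled = cases_below * n0 - controls_below * n1
        auc = 1.0 - auc_ge
    best = int(np.argmax(j_scaled))  # first (smallest) maximizer breaks ties
    return CutpointResult(
        variable=variable,
        cutoff=float(thr[best]),
        direction=direction,
        youden_j=float(j_scaled[best] / (n1 * n0)),
        auc=auc,
        p_value=auc_pvalue(auc, int(y.sum()), int(y.size - y.sum())),
    )
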