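"""Integer risk score derivation, calibration and evaluation.

Points: each retained coefficient beta_k is divided by the smallest retained
coefficient beta_min and rounded to the nearest integer (half away from
zero), so the weakest predictor scores 1 point.  A patient's risk score is
the sum of points over the indicators present; mutually exclusive categorical
levels (e.g. unilateral vs bilateral carotid plaque) contribute at most one
level's points, so the maximum score is the sum over variables of each
variable's largest point value.

Score -> probability calibration fits the one-predictor logistic model
logit P = alpha_s + beta_s * score by maximum likelihood, either to
patient-level scores or to a grouped score table (expanded to subjects —
identical likelihood).  Evaluation on grouped data covers the tie-corrected
Mann-Whitney AUC with a DeLong confidence interval, sensitivity/specificity/
predictive values at a score cut-off, the Hosmer-Lemeshow chi-square over the
observed score groups, a paired DeLong comparison of two predictors, and the
coefficient of determination between predicted and observed per-score event
frequencies.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .cohort import DerivedRecord, GroupedScoreTable
from .errors import DegenerateDataError, ScoringError
from .model import FittedLogisticModel, fit_logistic_matrix

logger = logging.getLogger(__name__)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ScoreSystem:
    """Integer points per indicator plus the score->probability calibration."""

    points: dict[str, int]
    max_score: int
    #: indicators that are mutually exclusive levels of one variable
    exclusive_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    calibration: tuple[float, float] | None = None  # (alpha_s, beta_s)

    def probability(self, score: float) -> float:
        """Calibrated outcome probability at a given score."""
        if self.calibration is None:
            raise ScoringError("score system has not been calibrated")
        alpha, beta = self.calibration
        return float(expit(alpha + beta * score))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "points": self.points,
                "max_score": self.max_score,
                "exclusive_groups": {k: list(v) for k, v in self.exclusive_groups.items()},
                "calibration": self.calibration,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ScoreSystem":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            points={k: int(v) for k, v in d["points"].items()},
            max_score=int(d["max_score"]),
            exclusive_groups={
                k: tuple(v) for k, v in d.get("exclusive_groups", {}).items()
            },
            calibration=tuple(d["calibration"]) if d.get("calibration") else None,
        )


def derive_scores(
    coefficients: Mapping[str, float] | FittedLogisticModel,
    exclusive_groups: Mapping[str, Sequence[str]] | None = None,
) -> ScoreSystem:
    """Integer points from logistic coefficients: round(beta_k / beta_min).

    All retained coefficients must be positive (risk-coded indicators);
    otherwise the caller is instructed to recode the offending indicator in
    its risk direction.  ``exclusive_groups`` marks sets of indicators that
    are levels of one categorical variable, so the maximum attainable score
    counts only the largest level.
    """
    groups: dict[str, tuple[str, ...]] = {}
    if isinstance(coefficients, FittedLogisticModel):
        model = coefficients
        coefficients = model.coefficients
        if model.design is not None:
            for cat in model.design.categorical:
                groups[cat.name] = tuple(cat.column_names())
    if exclusive_groups:
        groups.update({k: tuple(v) for k, v in exclusive_groups.items()})

    if not coefficients:
        raise ScoringError("no coefficients to score")
    bad = {k: b for k, b in coefficients.items() if b <= 0}
    if bad:
        raise ScoringError(
            f"coefficients must be positive (risk-coded); recode {sorted(bad)} "
            "so that indicator = 1 marks the risk direction"
        )
    beta_min = min(coefficients.values())
    points = {k: _round_half_away(b / beta_min) for k, b in coefficients.items()}

    grouped_terms = {t for terms in groups.values() for t in terms}
    max_score = sum(p for k, p in points.items() if k not in grouped_terms)
    for terms in groups.values():
        levels = [points[t] for t in terms if t in points]
        if levels:
            max_score += max(levels)
    return ScoreSystem(points=points, max_score=max_score, exclusive_groups=groups)


def total_score(
    record: DerivedRecord | Mapping[str, int],
    system: ScoreSystem,
) -> int:
    """Sum of points over the indicators present in the record."""
    indicators = (
        record.indicator_values() if isinstance(record, DerivedRecord) else dict(record)
    )
    score = 0
    for term, pts in system.points.items():
        if term not in indicators:
            raise ScoringError(f"record lacks required indicator {term!r}")
        score += pts * int(bool(indicators[term]))
    return score


@dataclass
class CalibrationFit:
    system: ScoreSystem
    alpha: float
    beta: float
    #: per-score (score, n, predicted event frequency n_s * p(score))
    predicted_frequencies: list[tuple[int, int, float]]
    model: FittedLogisticModel

    def predicted_events_at(self, score: int) -> float:
        for s, _, e in self.predicted_frequencies:
            if s == score:
                return e
        raise KeyError(f"score {score} not present in the table")


def calibrate_score(
    data: GroupedScoreTable | tuple[np.ndarray, np.ndarray],
    system: ScoreSystem | None = None,
) -> CalibrationFit:
    """Fit the score-only logistic model and attach it to the score system.

    ``data`` is a grouped score table or a (scores, outcome) pair of
    per-subject arrays.  Grouped counts are expanded to subjects; the
    likelihood is identical to a weighted fit.  Requires at least two
    distinct score values and both outcome classes overall.
    """
    if isinstance(data, GroupedScoreTable):
        score, y = data.expand()
        table = data
    else:
        score = np.asarray(data[0], dtype=float)
        y = np.asarray(data[1], dtype=int)
        uniq = np.unique(score).astype(int)
        table = GroupedScoreTable(
            scores=tuple(int(s) for s in uniq),
            n=tuple(int((score == s).sum()) for s in uniq),
            events=tuple(int(y[score == s].sum()) for s in uniq),
        )
    X = np.column_stack([np.ones_like(score), score])
    model = fit_logistic_matrix(X, y, ["(intercept)", "score"], {"score": [1]})
    alpha, beta = float(model.params[0]), float(model.params[1])
    predicted = [
        (s, n_s, n_s * float(expit(alpha + beta * s)))
        for s, n_s in zip(table.scores, table.n)
    ]
    system = system or ScoreSystem(points={}, max_score=max(table.scores))
    system.calibration = (alpha, beta)
    return CalibrationFit(
        system=system, alpha=alpha, beta=beta,
        predicted_frequencies=predicted, model=model,
    )


# ---------------------------------------------------------------------------
# Grouped-data discrimination and classification
# ---------------------------------------------------------------------------

def _grouped_arrays(table: GroupedScoreTable):
    n = np.asarray(table.n, dtype=float)
    e = np.asarray(table.events, dtype=float)
    return n, e, n - e


def grouped_auc(
    table: GroupedScoreTable, ci_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Tie-corrected Mann-Whitney AUC from grouped counts, with a DeLong
    (placement-value) Wald confidence interval.

    AUC = sum over event rows of events_s * (controls below + half controls
    at score s), divided by E*(N-E).
    """
    n, e, c = _grouped_arrays(table)
    E, C = e.sum(), c.sum()
    if E == 0 or C == 0:
        raise DegenerateDataError("grouped table has a single outcome class")
    controls_below = np.concatenate(([0.0], np.cumsum(c)[:-1]))
    events_above = (np.cumsum(e[::-1])[::-1] - e)
    # placements: v10 = per-case fraction of controls beaten (+ half ties),
    # v01 = per-control fraction of cases above; both average to the AUC
    v10 = (controls_below + 0.5 * c) / C
    v01 = (events_above + 0.5 * e) / E
    auc = float(np.sum(e * v10) / E)
    # weighted variances of the placement values
    s10 = np.sum(e * (v10 - auc) ** 2) / max(E - 1, 1)
    s01 = np.sum(c * (v01 - auc) ** 2) / max(C - 1, 1)
    se = math.sqrt(s10 / E + s01 / C)
    z = stats.norm.ppf(0.5 + ci_level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return auc, (lo, hi)


@dataclass(frozen=True)
class ClassificationMetrics:
    cutoff: int
    sensitivity: float
    specificity: float
    ppv_raw: float
    npv_raw: float
    ppv_adjusted: float | None
    npv_adjusted: float | None


def classification_metrics(
    table: GroupedScoreTable,
    cutoff: int,
    prevalence: float | None = None,
) -> ClassificationMetrics:
    """Confusion-matrix metrics for the rule "score >= cutoff is positive".

    Raw PPV/NPV come from the table's own counts; when ``prevalence`` is
    given, Bayes-adjusted PPV/NPV at that prevalence are reported as well.
    """
    scores = np.asarray(table.scores)
    n, e, c = _grouped_arrays(table)
    pos = scores >= cutoff
    tp = float(e[pos].sum())
    fn = float(e[~pos].sum())
    fp = float(c[pos].sum())
    tn = float(c[~pos].sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv_raw = tp / (tp + fp) if tp + fp else float("nan")
    npv_raw = tn / (tn + fn) if tn + fn else float("nan")
    ppv_adj = npv_adj = None
    if prevalence is not None:
        p = prevalence
        ppv_adj = sens * p / (sens * p + (1 - spec) * (1 - p))
        npv_adj = spec * (1 - p) / (spec * (1 - p) + (1 - sens) * p)
    return ClassificationMetrics(
        cutoff=cutoff, sensitivity=sens, specificity=spec,
        ppv_raw=ppv_raw, npv_raw=npv_raw,
        ppv_adjusted=ppv_adj, npv_adjusted=npv_adj,
    )


def hosmer_lemeshow(
    table: GroupedScoreTable,
    calibration: tuple[float, float],
    df_adjust: int = 2,
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness of fit over the observed score groups.

    chi2 = sum over groups of (O-E)^2/E + ((n-O)-(n-E))^2/(n-E) with expected
    counts from the calibrated score->probability model; df = groups -
    ``df_adjust``.  Empty score rows are removed, and a group whose expected
    event (or non-event) count is zero is merged with its neighbour.
    """
    alpha, beta = calibration
    rows = [
        (s, n_s, o_s, n_s * float(expit(alpha + beta * s)))
        for s, n_s, o_s in zip(table.scores, table.n, table.events)
        if n_s > 0
    ]
    if len(rows) < 3:
        raise DegenerateDataError("need at least 3 non-empty score groups")
    merged: list[list[float]] = []
    for s, n_s, o_s, e_s in rows:
        if merged and (merged[-1][3] <= 1e-12 or merged[-1][3] >= merged[-1][1] - 1e-12):
            logger.info("merging degenerate score group into score %s", s)
            merged[-1][1] += n_s
            merged[-1][2] += o_s
            merged[-1][3] += e_s
        else:
            merged.append([s, n_s, o_s, e_s])
    if len(merged) >= 2 and (
        merged[-1][3] <= 1e-12 or merged[-1][3] >= merged[-1][1] - 1e-12
    ):
        last = merged.pop()
        merged[-1][1] += last[1]
        merged[-1][2] += last[2]
        merged[-1][3] += last[3]
    chi2 = 0.0
    for _, n_s, o_s, e_s in merged:
        chi2 += (o_s - e_s) ** 2 / e_s
        chi2 += ((n_s - o_s) - (n_s - e_s)) ** 2 / (n_s - e_s)
    df = len(merged) - df_adjust
    if df < 1:
        raise DegenerateDataError("not enough groups for the requested df adjustment")
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def delong_compare(
    predictions_a: np.ndarray,
    predictions_b: np.ndarray,
    outcome: np.ndarray,
) -> tuple[float, float]:
    """Paired DeLong comparison of two predictors on the same subjects.

    Returns (AUC_a - AUC_b, two-sided p).  Rank-invariant: a strictly
    monotone transform of a predictor leaves its placements unchanged.
    """
    a = np.asarray(predictions_a, dtype=float)
    b = np.asarray(predictions_b, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("prediction vectors and outcome must share a length")
    if y.min() == y.max():
        raise DegenerateDataError("outcome contains a single class")

    def placements(x):
        cases = np.sort(x[y == 1])
        controls = np.sort(x[y == 0])
        n1, n0 = cases.size, controls.size
        v10 = (
            np.searchsorted(controls, x[y == 1], side="left")
            + 0.5 * (
                np.searchsorted(controls, x[y == 1], side="right")
                - np.searchsorted(controls, x[y == 1], side="left")
            )
        ) / n0
        v01 = (
            (n1 - np.searchsorted(cases, x[y == 0], side="right"))
            + 0.5 * (
                np.searchsorted(cases, x[y == 0], side="right")
                - np.searchsorted(cases, x[y == 0], side="left")
            )
        ) / n1
        return v10, v01

    v10a, v01a = placements(a)
    v10b, v01b = placements(b)
    n1, n0 = v10a.size, v01a.size
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    delta = auc_a - auc_b
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (np.var(d10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(d01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    if var <= 0:
        return delta, 1.0 if delta == 0 else 0.0
    z = delta / math.sqrt(var)
    return delta, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def fit_goodness_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination of an OLS regression of observed on
    predicted per-score frequencies; NaN when the predictor has no variance."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.var(pred) == 0.0:
        logger.warning("predicted frequencies have zero variance; R^2 undefined")
        return float("nan")
    X = np.column_stack([np.ones_like(pred), pred])
    coef, _, _, _ = np.linalg.lstsq(X, obs, rcond=None)
    resid = obs - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    return 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
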