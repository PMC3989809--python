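"""Maximum-likelihood logistic regression, Wald inference and backward
elimination.

The fitter is iteratively reweighted least squares (Fisher scoring) with
step-halving.  Convergence requires the score vector X'(y - p) to vanish
(max-norm below 1e-8) or the relative log-likelihood change to fall below
1e-10, within 50 iterations.  Complete or quasi-complete separation is
reported as an error naming the offending term (a coefficient diverging past
|beta| = 15 while the score has not vanished); during backward-selection or
bootstrap paths the caller drops that term and continues.

Categorical covariates use reference (dummy) coding and are tested, retained
and eliminated as whole blocks via multi-degree-of-freedom Wald tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cutpoints import mann_whitney_auc
from .errors import CollinearityError, DegenerateDataError, SeparationError

logger = logging.getLogger(__name__)

MAX_ITER = 50
SCORE_TOL = 1e-8
LL_RELTOL = 1e-10
BETA_BOUND = 15.0


@dataclass(frozen=True)
class CategoricalTerm:
    """A categorical covariate with a reference level; each non-reference
    level becomes one dummy column, and the levels form one selection block."""

    name: str
    reference: str
    levels: tuple[str, ...]  # non-reference levels, in display order

    def column_names(self) -> list[str]:
        return [f"{self.name}[{lv}]" for lv in self.levels]


@dataclass(frozen=True)
class DesignSpec:
    """Model terms: binary 0/1 columns plus optional categorical blocks."""

    binary: tuple[str, ...]
    categorical: tuple[CategoricalTerm, ...] = ()
    outcome: str = "ras_significant"

    def __post_init__(self):
        names = list(self.binary) + [c.name for c in self.categorical]
        if len(names) != len(set(names)):
            raise ValueError("duplicate terms in design")

    @property
    def terms(self) -> list[str]:
        return list(self.binary) + [c.name for c in self.categorical]

    def drop(self, term: str) -> "DesignSpec":
        return DesignSpec(
            binary=tuple(b for b in self.binary if b != term),
            categorical=tuple(c for c in self.categorical if c.name != term),
            outcome=self.outcome,
        )

    def build(self, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str], dict]:
        """Design matrix with leading intercept, outcome vector, column names
        and the term -> column-index-list blocks."""
        cols: list[np.ndarray] = [np.ones(len(data))]
        names = ["(intercept)"]
        blocks: dict[str, list[int]] = {}
        for b in self.binary:
            blocks[b] = [len(names)]
            cols.append(data[b].to_numpy(dtype=float))
            names.append(b)
        for cat in self.categorical:
            idx = []
            for lv, cname in zip(cat.levels, cat.column_names()):
                idx.append(len(names))
                if cname in data.columns:
                    cols.append(data[cname].to_numpy(dtype=float))
                else:
                    cols.append((data[cat.name] == lv).to_numpy(dtype=float))
                names.append(cname)
            blocks[cat.name] = idx
        X = np.column_stack(cols)
        y = data[self.outcome].to_numpy(dtype=float)
        return X, y, names, blocks


@dataclass
class FittedLogisticModel:
    """A converged maximum-likelihood logistic fit."""

    param_names: list[str]
    params: np.ndarray                  # (intercept, betas...)
    cov: np.ndarray                     # inverse observed Fisher information
    term_blocks: dict[str, list[int]]   # term -> parameter indices
    log_likelihood: float
    apparent_auc: float
    converged: bool
    n_used: int
    n_iter: int
    design: DesignSpec | None = None

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> dict[str, float]:
        """Per-column coefficients, excluding the intercept."""
        return {n: float(b) for n, b in zip(self.param_names[1:], self.params[1:])}

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def wald_p(self, term: str) -> float:
        return wald_test(self, term)

    def or_ci(self, column: str, level: float = 0.95) -> tuple[float, float, float]:
        """(odds ratio, lower, upper) for one design column at the given
        confidence level; OR = exp(beta)."""
        i = self.param_names.index(column)
        z = stats.norm.ppf(0.5 + level / 2.0)
        b, s = self.params[i], self.se()[i]
        return float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s))

    def predict_linear(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params

    def predict_frame(self, data: pd.DataFrame) -> np.ndarray:
        """Fitted probabilities for rows of a derived-covariate frame."""
        if self.design is None:
            raise ValueError("model was fitted without a DesignSpec")
        X, _, _, _ = self.design.build(data)
        return expit(X @ self.params)

    def summary_frame(self) -> pd.DataFrame:
        """Coefficients, SEs, ORs with 90% and 95% CIs, per design column."""
        rows = []
        se = self.se()
        for i, name in enumerate(self.param_names):
            if i == 0:
                continue
            or95 = self.or_ci(name, 0.95)
            or90 = self.or_ci(name, 0.90)
            rows.append(
                {
                    "term": name,
                    "coef": self.params[i],
                    "se": se[i],
                    "or": or95[0],
                    "or_l95": or95[1],
                    "or_u95": or95[2],
                    "or_l90": or90[1],
                    "or_u90": or90[2],
                }
            )
        return pd.DataFrame(rows)


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_matrix(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    term_blocks: Mapping[str, list[int]] | None = None,
    max_iter: int = MAX_ITER,
) -> FittedLogisticModel:
    """IRLS fit of a logistic model to an explicit design matrix (first
    column is expected to be the intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    names = list(names or [f"x{i}" for i in range(k)])
    if y.sum() == 0 or y.sum() == n:
        raise DegenerateDataError("outcome contains a single class")
    if np.linalg.matrix_rank(X) < k:
        raise CollinearityError(_rank_deficiency_message(X, names))

    beta = np.zeros(k)
    ll = _log_likelihood(X @ beta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        g = X.T @ (y - p)
        if np.max(np.abs(g)) < SCORE_TOL:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError("singular information matrix") from exc
        # step-halving keeps the likelihood non-decreasing
        step = 1.0
        for _ in range(30):
            ll_new = _log_likelihood(X @ (beta + step * delta), y)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        _check_separation(beta, g, names)
        if abs(ll_new - ll) < LL_RELTOL * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    p = expit(X @ beta)
    g = X.T @ (y - p)
    if not converged and np.max(np.abs(g)) < 1e-6:
        converged = True
    _check_separation(beta, g, names, final=not converged)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    H = X.T @ (X * w[:, None])
    cov = np.linalg.inv(H)
    try:
        auc = mann_whitney_auc(p, y.astype(int))
    except DegenerateDataError:  # pragma: no cover - excluded above
        auc = 0.5
    return FittedLogisticModel(
        param_names=names,
        params=beta,
        cov=cov,
        term_blocks=dict(term_blocks or {}),
        log_likelihood=_log_likelihood(X @ beta, y),
        apparent_auc=auc,
        converged=converged,
        n_used=n,
        n_iter=it,
    )


def _check_separation(beta, score, names, final: bool = False) -> None:
    big = np.abs(beta[1:]) > BETA_BOUND
    if big.any() and (final or np.max(np.abs(score)) > 1e-6):
        j = 1 + int(np.argmax(np.abs(beta[1:])))
        raise SeparationError(names[j])


def _rank_deficiency_message(X, names) -> str:
    # point at columns whose removal restores full rank
    r = np.linalg.matrix_rank(X)
    culprits = []
    for j in range(1, X.shape[1]):
        keep = [c for c in range(X.shape[1]) if c != j]
        if np.linalg.matrix_rank(X[:, keep]) == r:
            culprits.append(names[j])
    return f"design matrix is rank deficient (rank {r} < {X.shape[1]}); " \
           f"linearly dependent columns include {culprits or names[1:]}"


def fit_logistic(design: DesignSpec, data: pd.DataFrame) -> FittedLogisticModel:
    """Fit the design to a derived-covariate frame."""
    X, y, names, blocks = design.build(data)
    model = fit_logistic_matrix(X, y, names, blocks)
    model.design = design
    return model


def wald_test(model: FittedLogisticModel, term: str) -> float:
    """Wald p-value of one term: (beta/se)^2 against chi2(1) for single
    columns, the quadratic form beta' Sigma^-1 beta against chi2(df) for
    categorical blocks."""
    if term not in model.term_blocks:
        raise KeyError(f"term {term!r} not in model")
    idx = model.term_blocks[term]
    b = model.params[idx]
    sigma = model.cov[np.ix_(idx, idx)]
    try:
        w = float(b @ np.linalg.solve(sigma, b))
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(f"singular covariance block for term {term!r}") from exc
    return float(stats.chi2.sf(w, df=len(idx)))


def backward_select(
    design: DesignSpec,
    data: pd.DataFrame,
    p_exit: float = 0.10,
) -> tuple[FittedLogisticModel, list[dict]]:
    """Backward elimination by Wald statistics.

    Repeatedly removes the term with the largest Wald p among those with
    p >= ``p_exit`` (categorical blocks as a whole), refitting after each
    removal, until every remaining term has p < ``p_exit``.  A term whose
    presence causes separation is dropped with a logged warning.  Returns the
    final model and the elimination trace.
    """
    if not 0 < p_exit <= 1:
        raise ValueError("p_exit must be in (0, 1]")
    trace: list[dict] = []
    current = design
    while True:
        try:
            model = fit_logistic(current, data)
        except SeparationError as exc:
            term = _column_term(current, exc.term)
            logger.warning("dropping term %r: %s", term, exc)
            trace.append({"removed": term, "p": None, "reason": "separation"})
            current = current.drop(term)
            if not current.terms:
                raise
            continue
        pvals = {t: wald_test(model, t) for t in current.terms}
        removable = {t: p for t, p in pvals.items() if p >= p_exit}
        if not removable:
            return model, trace
        worst = max(removable, key=removable.get)
        trace.append({"removed": worst, "p": removable[worst], "reason": "p_exit"})
        current = current.drop(worst)
        if not current.terms:
            # intercept-only model
            X = np.ones((len(data), 1))
            y = data[design.outcome].to_numpy(dtype=float)
            model = fit_logistic_matrix(X, y, ["(intercept)"], {})
            model.design = current
            return model, trace


def _column_term(design: DesignSpec, column: str) -> str:
    for cat in design.categorical:
        if column in cat.column_names() or column == cat.name:
            return cat.name
    return column


def vif(design: DesignSpec, data: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor of every design column: 1/(1 - R^2) from an
    OLS regression of the column on all other columns (with intercept).
    Exactly collinear columns report ``inf``."""
    X, _, names, _ = design.build(data)
    out: dict[str, float] = {}
    for j in range(1, X.shape[1]):
        target = X[:, j]
        others = np.delete(X, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((target - target.mean()) ** 2).sum())
        if ss_tot == 0.0:
            out[names[j]] = np.inf
        else:
            r2 = 1.0 - ss_res / ss_tot
            out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out
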