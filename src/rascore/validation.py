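"""Bootstrap internal validation and calibration assessment.

The optimism of a modelling pipeline is estimated by re-running the ENTIRE
pipeline (cut-point re-derivation, dichotomization, backward selection, fit)
on bootstrap resamples of the original cohort.  Each resample's model is
evaluated twice: on the resample it was built from (C_boot) and on the
original data (C_orig).  Optimism is the mean of C_boot - C_orig over
convergent resamples — the standard Harrell convention — and the
bias-corrected AUC is the apparent AUC minus that optimism.  An Efron-style
0.632 estimator (0.632 * out-of-bag + 0.368 * apparent) is available as an
optional alternative.

Calibration is assessed with a tricube-weighted local linear smoother
(lowess) of the observed outcome against the predicted probability; the mean
and 0.9-quantile absolute differences between the smoothed observed and
predicted probabilities summarize calibration error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cutpoints import mann_whitney_auc
from .errors import DegenerateDataError

logger = logging.getLogger(__name__)


class PredictivePipeline(Protocol):
    """A model-development procedure: frame in, predictive model out."""

    def __call__(self, data: pd.DataFrame) -> "PredictiveModel": ...


class PredictiveModel(Protocol):
    def predict(self, data: pd.DataFrame) -> np.ndarray: ...


@dataclass
class CalibrationResult:
    predicted: np.ndarray       # sorted predicted probabilities
    smoothed: np.ndarray        # lowess-smoothed observed frequencies
    mean_abs_error: float
    q90_abs_error: float


@dataclass
class ValidationReport:
    m_requested: int
    m_converged: int
    apparent_auc: float
    optimism: float
    bias_corrected_auc: float
    optimism_632: float | None
    auc_632: float | None
    calibration: CalibrationResult | None
    resample_log: list[dict] = field(default_factory=list)
    validity_warning: str | None = None


def calibration_curve(
    predicted: np.ndarray,
    observed: np.ndarray,
    span: float = 0.75,
) -> CalibrationResult:
    """Smoothed calibration curve and absolute-error summaries.

    ``span`` is the lowess bandwidth fraction; robustness iterations are
    disabled because the response is binary.  Errors are |smoothed observed -
    predicted| over subjects.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have the same length")
    if predicted.min() < 0 or predicted.max() > 1:
        raise ValueError("predicted values must be probabilities")
    order = np.argsort(predicted, kind="stable")
    p_sorted = predicted[order]
    smoothed = sm.nonparametric.lowess(
        observed[order], p_sorted, frac=span, it=0, return_sorted=False
    )
    err = np.abs(smoothed - p_sorted)
    return CalibrationResult(
        predicted=p_sorted,
        smoothed=smoothed,
        mean_abs_error=float(err.mean()),
        q90_abs_error=float(np.quantile(err, 0.9)),
    )


def bootstrap_validate(
    data: pd.DataFrame,
    pipeline: Callable[[pd.DataFrame], PredictiveModel],
    m: int = 1000,
    seed: int = 0,
    outcome: str = "ras_significant",
    span: float = 0.75,
    compute_632: bool = False,
) -> ValidationReport:
    """Optimism-corrected bootstrap validation of a full pipeline.

    Draws ``m`` resamples of size n with replacement (seeded), re-runs the
    pipeline on each, and averages C_boot - C_orig over resamples that
    converge; resamples where the pipeline raises are skipped and counted,
    with a validity warning when more than 20% fail.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    y = data[outcome].to_numpy(dtype=int)
    n = len(data)

    original_model = pipeline(data)
    p_orig = np.asarray(original_model.predict(data), dtype=float)
    apparent = mann_whitney_auc(p_orig, y)

    rng = np.random.default_rng(seed)
    indices = rng.integers(0, n, size=(m, n))

    diffs: list[float] = []
    oob_aucs: list[float] = []
    log: list[dict] = []
    for b in range(m):
        idx = indices[b]
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            boot_model = pipeline(sample)
            p_boot = np.asarray(boot_model.predict(sample), dtype=float)
            c_boot = mann_whitney_auc(p_boot, y[idx])
            c_orig = mann_whitney_auc(
                np.asarray(boot_model.predict(data), dtype=float), y
            )
        except Exception as exc:  # noqa: BLE001 - any pipeline failure is a skip
            log.append({"resample": b, "status": "failed", "error": str(exc)})
            continue
        entry = {"resample": b, "status": "ok",
                 "c_boot": c_boot, "c_orig": c_orig}
        diffs.append(c_boot - c_orig)
        if compute_632:
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size and len(np.unique(y[oob])) == 2:
                c_oob = mann_whitney_auc(
                    np.asarray(boot_model.predict(data.iloc[oob]), dtype=float),
                    y[oob],
                )
                oob_aucs.append(c_oob)
                entry["c_oob"] = c_oob
        log.append(entry)

    m_conv = len(diffs)
    if m_conv == 0:
        raise DegenerateDataError("no bootstrap resample converged")
    optimism = float(np.mean(diffs))
    warning = None
    if m_conv < 0.8 * m:
        warning = (
            f"only {m_conv}/{m} resamples converged (> 20% failures); "
            "optimism estimate may be unreliable"
        )
        logger.warning(warning)

    optimism_632 = auc_632 = None
    if compute_632 and oob_aucs:
        auc_632 = float(0.632 * np.mean(oob_aucs) + 0.368 * apparent)
        optimism_632 = apparent - auc_632

    calibration = calibration_curve(p_orig, y.astype(float), span=span)
    return ValidationReport(
        m_requested=m,
        m_converged=m_conv,
        apparent_auc=float(apparent),
        optimism=optimism,
        bias_corrected_auc=float(apparent - optimism),
        optimism_632=optimism_632,
        auc_632=auc_632,
        calibration=calibration,
        resample_log=log,
        validity_warning=warning,
    )
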