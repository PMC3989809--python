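"""End-to-end model development: Youden cut-points -> dichotomization ->
backward-Wald logistic selection.

This is the procedure that internal validation must re-run in full on every
bootstrap resample, so it is packaged as a single callable taking a raw
patient-level frame and returning a fitted object that can predict on the
original data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort as ch
from . import cutpoints as cp
from .errors import DegenerateDataError
from .model import (
    CategoricalTerm,
    DesignSpec,
    FittedLogisticModel,
    backward_select,
    fit_logistic,
    vif,
)

logger = logging.getLogger(__name__)

#: Binary covariates entered as-is (the AHM >= 4 category is a fixed clinical
#: threshold, not Youden-derived).
DEFAULT_BINARY_TERMS = (
    "male",
    "hypertension",
    "diabetes",
    "smoking",
    "proteinuria",
    "ckd_stage_ge3",
    "ahm_ge4",
    "cad_significant",
)

#: Continuous covariates dichotomized at their Youden-optimal cut-points.
DEFAULT_CONTINUOUS_TERMS = (
    "age", "bmi", "cimt", "total_chol", "hdl_chol", "triglyceride",
)

CAP_TERM = CategoricalTerm(
    name="cap_extent", reference="none", levels=("unilateral", "bilateral")
)


@dataclass
class DevelopedModel:
    """Output of one run of the full development pipeline."""

    cutpoints: dict[str, cp.CutpointResult]
    model: FittedLogisticModel
    elimination_trace: list[dict]
    dropped_constant: list[str]
    n_used: int
    vifs: dict[str, float] = field(default_factory=dict)

    @property
    def cutoffs(self) -> dict[str, float]:
        return {v: r.cutoff for v, r in self.cutpoints.items()}

    def predict(self, raw: pd.DataFrame) -> np.ndarray:
        """Predicted outcome probability for raw patient-level rows, applying
        this model's own cut-points before the logistic formula."""
        derived = ch.derive_frame(raw, self.cutoffs)
        return self.model.predict_frame(derived)


def develop(
    raw: pd.DataFrame,
    p_exit: float = 0.10,
    continuous: Sequence[str] = DEFAULT_CONTINUOUS_TERMS,
    binary: Sequence[str] = DEFAULT_BINARY_TERMS,
    fixed_cutoffs: Mapping[str, float] | None = None,
    compute_vif: bool = False,
) -> DevelopedModel:
    """Run the full development pipeline on a raw patient-level frame.

    Steps: exclude incomplete rows; find the Youden cut-point of each
    continuous covariate (risk directions per
    :data:`rascore.cohort.CUTOFF_DIRECTIONS`); dichotomize; fit the full
    logistic model (CAP as a 3-level categorical against "none") and run
    backward elimination at ``p_exit``.  Covariates that are constant in the
    data (possible in bootstrap resamples) are dropped and recorded.
    ``fixed_cutoffs`` pins selected cut-offs instead of re-deriving them.
    """
    raw = ch.exclude_incomplete(raw)
    y = raw["ras_significant"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("outcome contains a single class")

    fixed_cutoffs = dict(fixed_cutoffs or {})
    cut_results: dict[str, cp.CutpointResult] = {}
    dropped: list[str] = []
    for var in continuous:
        direction = (
            cp.GE_IS_RISK if ch.CUTOFF_DIRECTIONS[var] == "ge" else cp.LT_IS_RISK
        )
        values = raw[var].to_numpy(dtype=float)
        if np.unique(values).size < 2:
            dropped.append(var)
            continue
        if var in fixed_cutoffs:
            cut_results[var] = cp.CutpointResult(
                variable=var, cutoff=float(fixed_cutoffs[var]),
                direction=direction, youden_j=np.nan,
                auc=np.nan, p_value=np.nan,
            )
        else:
            cut_results[var] = cp.youden_cutpoint(
                values, y, direction=direction, variable=var
            )

    derived = ch.derive_frame(raw, {v: r.cutoff for v, r in cut_results.items()})

    binary_terms = []
    for var in continuous:
        name = ch.INDICATOR_NAMES[var]
        if var in dropped:
            continue
        binary_terms.append(name)
    for term in binary:
        if derived[term].nunique() < 2:
            dropped.append(term)
            logger.info("dropping constant covariate %r", term)
            continue
        binary_terms.append(term)
    # a Youden indicator can still be constant (cutoff at the extreme)
    binary_terms = [t for t in binary_terms if derived[t].nunique() >= 2]

    categorical = ()
    cap_levels = tuple(
        lv for lv in CAP_TERM.levels if (derived["cap_extent"] == lv).any()
    )
    if cap_levels and (derived["cap_extent"] == CAP_TERM.reference).any():
        categorical = (
            CategoricalTerm("cap_extent", CAP_TERM.reference, cap_levels),
        )
    else:
        dropped.append("cap_extent")

    design = DesignSpec(
        binary=tuple(binary_terms), categorical=categorical,
        outcome="ras_significant",
    )
    vifs = vif(design, derived) if compute_vif else {}
    model, trace = backward_select(design, derived, p_exit=p_exit)
    return DevelopedModel(
        cutpoints=cut_results,
        model=model,
        elimination_trace=trace,
        dropped_constant=dropped,
        n_used=len(derived),
        vifs=vifs,
    )


def full_model(raw: pd.DataFrame, **kwargs) -> DevelopedModel:
    """The pre-selection model: same pipeline but no elimination
    (p_exit > 1 keeps every term)."""
    return develop(raw, p_exit=1.0, **kwargs)
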