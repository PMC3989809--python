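"""Reference data from the published renal-artery-stenosis risk model.

These are the printed results of the original single-centre study (641
patients undergoing simultaneous coronary and renal angiography, 60 with
significant RAS): the final multivariable coefficients, the integer points of
the published scoring system, and the grouped per-score outcome counts.  They
serve as in-package inputs for the score-derivation and grouped-evaluation
machinery and as fixtures for cross-checking the implementation.
"""

from __future__ import annotations

from .cohort import GroupedScoreTable

#: Final-model logistic coefficients (risk-coded indicators; carotid-plaque
#: levels against a "none" reference).
REFERENCE_COEFFICIENTS: dict[str, float] = {
    "cad_significant": 1.724,
    "cap_unilateral": 0.958,
    "cap_bilateral": 1.584,
    "ckd_stage_ge3": 1.566,
    "ahm_ge4": 1.563,
    "cimt_ge_cut": 0.849,
    "age_ge_cut": 0.831,
    "bmi_lt_cut": 0.872,
}

#: Mutually exclusive indicator groups (levels of one categorical variable).
REFERENCE_EXCLUSIVE_GROUPS: dict[str, tuple[str, ...]] = {
    "cap_extent": ("cap_unilateral", "cap_bilateral"),
}

#: Published integer points of the scoring system.
REFERENCE_POINTS: dict[str, int] = {
    "cad_significant": 2,
    "cap_unilateral": 1,
    "cap_bilateral": 2,
    "ckd_stage_ge3": 2,
    "ahm_ge4": 2,
    "cimt_ge_cut": 1,
    "age_ge_cut": 1,
    "bmi_lt_cut": 1,
}

#: Published odds ratios (95% CI) alongside the coefficients, one decimal.
REFERENCE_ODDS_RATIOS: dict[str, float] = {
    "cad_significant": 5.6,
    "cap_unilateral": 2.6,
    "cap_bilateral": 4.9,
    "ckd_stage_ge3": 4.8,
    "ahm_ge4": 4.8,
    "cimt_ge_cut": 2.3,
    "age_ge_cut": 2.3,
    "bmi_lt_cut": 2.4,
}


def reference_score_table(include_empty: bool = False) -> GroupedScoreTable:
    """Observed per-score outcome counts of the original cohort.

    Scores 9-11 were attainable but observed in no patient; they are included
    only when ``include_empty`` is set.
    """
    rows = [
        # (score, n, events)
        (0, 156, 1),
        (1, 145, 1),
        (2, 106, 2),
        (3, 77, 6),
        (4, 56, 8),
        (5, 45, 11),
        (6, 28, 14),
        (7, 21, 12),
        (8, 7, 5),
    ]
    if include_empty:
        rows += [(9, 0, 0), (10, 0, 0), (11, 0, 0)]
    return GroupedScoreTable(
        scores=tuple(r[0] for r in rows),
        n=tuple(r[1] for r in rows),
        events=tuple(r[2] for r in rows),
    )
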