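"""Score derivation, calibration, grouped evaluation and AUC comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from rascore import datasets as ds
from rascore import scoring as sc
from rascore.cohort import GroupedScoreTable
from rascore.cutpoints import mann_whitney_auc
from rascore.errors import CollinearityError, DegenerateDataError, ScoringError


def random_table(rng, max_rows=6):
    rows = rng.integers(2, max_rows + 1)
    scores = np.sort(rng.choice(np.arange(12), size=rows, replace=False))
    n = rng.integers(1, 30, size=rows)
    events = np.array([rng.integers(0, n_s + 1) for n_s in n])
    if events.sum() == 0:
        events[rng.integers(rows)] = 1
    if events.sum() == n.sum():
        grow = rng.integers(rows)
        n[grow] += 1
    return GroupedScoreTable(
        scores=tuple(int(s) for s in scores),
        n=tuple(int(v) for v in n),
        events=tuple(int(v) for v in events),
    )


# -- derive_scores ----------------------------------------------------------

def test_published_coefficients_yield_published_points():
    system = sc.derive_scores(ds.REFERENCE_COEFFICIENTS, ds.REFERENCE_EXCLUSIVE_GROUPS)
    assert system.points == ds.REFERENCE_POINTS
    assert system.max_score == 11


def test_equal_coefficients_all_score_one():
    system = sc.derive_scores({"a": 0.7, "b": 0.7, "c": 0.7})
    assert system.points == {"a": 1, "b": 1, "c": 1}
    assert system.max_score == 3


def test_ratio_rounding_half_away_from_zero():
    assert sc.derive_scores({"a": 0.5, "b": 1.26}).points == {"a": 1, "b": 3}
    # exact .5 ratios round away from zero
    assert sc.derive_scores({"a": 1.0, "b": 1.5}).points == {"a": 1, "b": 2}


def test_non_risk_coded_coefficients_rejected():
    with pytest.raises(ScoringError, match="recode"):
        sc.derive_scores({"a": 1.2, "b": -0.4})
    with pytest.raises(ScoringError):
        sc.derive_scores({})


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0.1, 3.0), min_size=1, max_size=6),
    st.floats(0.01, 50.0),
)
def test_scores_scale_invariant(betas, c):
    coeffs = {f"x{i}": b for i, b in enumerate(betas)}
    scaled = {k: v * c for k, v in coeffs.items()}
    assert sc.derive_scores(coeffs).points == sc.derive_scores(scaled).points


# -- total_score ------------------------------------------------------------

def reference_system():
    return sc.derive_scores(ds.REFERENCE_COEFFICIENTS, ds.REFERENCE_EXCLUSIVE_GROUPS)


def test_total_score_extremes_and_examples():
    system = reference_system()
    absent = {k: 0 for k in system.points}
    assert sc.total_score(absent, system) == 0
    maximal = {k: 1 for k in system.points}
    maximal["cap_unilateral"] = 0  # bilateral supersedes unilateral
    assert sc.total_score(maximal, system) == 11
    cad_and_bilateral = dict(absent, cad_significant=1, cap_bilateral=1)
    assert sc.total_score(cad_and_bilateral, system) == 4


def test_total_score_missing_indicator_named():
    system = reference_system()
    with pytest.raises(ScoringError, match="ahm_ge4"):
        sc.total_score({k: 0 for k in system.points if k != "ahm_ge4"}, system)


def test_total_score_monotone_in_indicators():
    system = reference_system()
    base = {k: 0 for k in system.points}
    s0 = sc.total_score(base, system)
    for k in system.points:
        bumped = dict(base, **{k: 1})
        assert sc.total_score(bumped, system) >= s0


def test_score_system_json_round_trip(tmp_path):
    system = reference_system()
    system.calibration = (-5.17, 0.82)
    path = tmp_path / "system.json"
    system.to_json(path)
    back = sc.ScoreSystem.from_json(path)
    assert back.points == system.points
    assert back.max_score == system.max_score
    assert back.calibration == pytest.approx(system.calibration)


# -- calibrate_score --------------------------------------------------------

def test_calibration_reproduces_published_predicted_frequency(reference_table):
    fit = sc.calibrate_score(reference_table)
    assert fit.predicted_events_at(5) == pytest.approx(11.32, abs=0.05)
    total = sum(e for _, _, e in fit.predicted_frequencies)
    assert total == pytest.approx(reference_table.total_events, abs=0.1)
    assert fit.beta > 0
    # probability increases with score under positive slope
    probs = [fit.system.probability(s) for s in range(0, 9)]
    assert all(b > a for a, b in zip(probs, probs[1:]))


def test_calibration_degenerate_single_score():
    t = GroupedScoreTable(scores=(3,), n=(50,), events=(10,))
    with pytest.raises(CollinearityError):
        sc.calibrate_score(t)


def test_calibration_parameter_recovery():
    rng = np.random.default_rng(21)
    alpha, beta = -3.2, 0.75
    scores = rng.integers(0, 9, 20_000)
    y = (rng.uniform(size=20_000) < expit(alpha + beta * scores)).astype(int)
    fit = sc.calibrate_score((scores.astype(float), y))
    assert fit.alpha == pytest.approx(alpha, abs=0.05)
    assert fit.beta == pytest.approx(beta, abs=0.05)


# -- grouped_auc ------------------------------------------------------------

def test_grouped_auc_reproduces_published_value(reference_table):
    auc, ci = sc.grouped_auc(reference_table)
    assert auc == pytest.approx(0.896, abs=0.0005)
    assert ci[0] < auc < ci[1]


def test_grouped_auc_extremes_and_degenerate():
    perfect = GroupedScoreTable(scores=(0, 5), n=(10, 4), events=(0, 4))
    auc, _ = sc.grouped_auc(perfect)
    assert auc == 1.0
    with pytest.raises(DegenerateDataError):
        sc.grouped_auc(GroupedScoreTable(scores=(0, 1), n=(5, 5), events=(0, 0)))


def test_grouped_auc_equals_expansion_oracle():
    rng = np.random.default_rng(33)
    for _ in range(50):
        t = random_table(rng)
        score, y = t.expand()
        expected = mann_whitney_auc(score, y)
        auc, _ = sc.grouped_auc(t)
        assert auc == pytest.approx(expected, abs=1e-12)


# -- classification metrics -------------------------------------------------

def test_metrics_reproduce_published_operating_point(reference_table):
    m = sc.classification_metrics(reference_table, cutoff=4, prevalence=0.094)
    assert m.sensitivity * 100 == pytest.approx(83.3, abs=0.05)
    assert m.specificity * 100 == pytest.approx(81.6, abs=0.05)
    assert m.ppv_raw * 100 == pytest.approx(31.8, abs=0.05)
    # raw-count NPV; the prevalence-adjusted variant is also reported
    assert m.npv_raw * 100 == pytest.approx(97.9, abs=0.05)
    assert m.npv_adjusted is not None and m.ppv_adjusted is not None


def test_metrics_trivial_cutoffs(reference_table):
    low = sc.classification_metrics(reference_table, cutoff=0)
    assert low.sensitivity == 1.0 and low.specificity == 0.0


def test_metrics_match_bruteforce_confusion_matrices():
    rng = np.random.default_rng(44)
    t = random_table(rng, max_rows=6)
    score, y = t.expand()
    for cutoff in range(min(t.scores), max(t.scores) + 2):
        m = sc.classification_metrics(t, cutoff)
        pos = score >= cutoff
        tp, fp = (pos & (y == 1)).sum(), (pos & (y == 0)).sum()
        fn, tn = (~pos & (y == 1)).sum(), (~pos & (y == 0)).sum()
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))


def test_adjusted_ppv_at_table_prevalence_equals_raw(reference_table):
    prev = reference_table.total_events / reference_table.total_n
    m = sc.classification_metrics(reference_table, cutoff=4, prevalence=prev)
    assert m.ppv_adjusted == pytest.approx(m.ppv_raw, abs=1e-4)
    assert m.npv_adjusted == pytest.approx(m.npv_raw, abs=1e-4)


# -- Hosmer-Lemeshow --------------------------------------------------------

def test_hosmer_lemeshow_perfect_fit_is_chi2_zero():
    # choose calibration, then set observed = expected exactly
    alpha, beta = -2.0, 0.5
    scores = (0, 2, 4, 6)
    n = (100, 100, 100, 100)
    events = tuple(100 * expit(alpha + beta * s) for s in scores)
    # build chi2 by hand with fractional "observed" counts
    chi2 = 0.0
    for s, n_s, o_s in zip(scores, n, events):
        e_s = n_s * expit(alpha + beta * s)
        chi2 += (o_s - e_s) ** 2 / e_s + ((n_s - o_s) - (n_s - e_s)) ** 2 / (n_s - e_s)
    assert chi2 == pytest.approx(0.0, abs=1e-12)


def test_hosmer_lemeshow_matches_hand_computation():
    t = GroupedScoreTable(scores=(0, 1, 2, 3), n=(50, 40, 30, 20), events=(2, 5, 9, 11))
    alpha, beta = -2.5, 0.9
    chi2, df, p = sc.hosmer_lemeshow(t, (alpha, beta))
    expected = 0.0
    for s, n_s, o_s in zip(t.scores, t.n, t.events):
        e_s = n_s * expit(alpha + beta * s)
        expected += (o_s - e_s) ** 2 / e_s
        expected += ((n_s - o_s) - (n_s - e_s)) ** 2 / (n_s - e_s)
    assert chi2 == pytest.approx(expected, rel=1e-12)
    assert df == 2
    from scipy import stats
    assert p == pytest.approx(stats.chi2.sf(expected, 2), rel=1e-12)


def test_hosmer_lemeshow_on_published_table_brackets_published_p(reference_table):
    fit = sc.calibrate_score(reference_table)
    chi2, df, p = sc.hosmer_lemeshow(reference_table, (fit.alpha, fit.beta))
    assert 0.8 < p < 0.95
    assert df == len(reference_table.scores) - 2


def test_hosmer_lemeshow_needs_three_groups():
    t = GroupedScoreTable(scores=(0, 1), n=(10, 10), events=(2, 3))
    with pytest.raises(DegenerateDataError):
        sc.hosmer_lemeshow(t, (-1.0, 0.5))


# -- DeLong comparison ------------------------------------------------------

def test_delong_self_comparison_and_rank_invariance():
    rng = np.random.default_rng(55)
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    a = rng.normal(size=100) + y
    delta, p = sc.delong_compare(a, a, y)
    assert delta == 0.0 and p == 1.0
    delta2, p2 = sc.delong_compare(a, np.exp(a / 3.0), y)  # monotone transform
    assert delta2 == 0.0
    assert p2 == 1.0


def test_delong_type_one_error_rate():
    rng = np.random.default_rng(66)
    rejections = 0
    n_sims = 200
    for _ in range(n_sims):
        y = np.r_[np.ones(40, int), np.zeros(160, int)]
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        _, p = sc.delong_compare(a, b, y)
        rejections += p < 0.05
    assert 0.02 <= rejections / n_sims <= 0.09


def test_delong_degenerate_outcome():
    with pytest.raises(DegenerateDataError):
        sc.delong_compare(np.r_[1.0, 2.0], np.r_[2.0, 1.0], np.r_[1, 1])


# -- goodness of fit --------------------------------------------------------

def test_fit_r2_identity_and_published_bound(reference_table):
    obs = np.array(reference_table.events, float)
    assert sc.fit_goodness_r2(obs, obs) == pytest.approx(1.0)
    fit = sc.calibrate_score(reference_table)
    pred = np.array([e for _, _, e in fit.predicted_frequencies])
    assert sc.fit_goodness_r2(obs, pred) >= 0.95


def test_fit_r2_matches_hand_computation():
    obs = np.array([1.0, 4.0, 2.0, 8.0])
    pred = np.array([1.5, 3.0, 2.5, 7.0])
    X = np.column_stack([np.ones(4), pred])
    coef, *_ = np.linalg.lstsq(X, obs, rcond=None)
    ss_res = float(((obs - X @ coef) ** 2).sum())
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    assert sc.fit_goodness_r2(obs, pred) == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)


def test_fit_r2_zero_variance_predictor_is_nan():
    assert math.isnan(sc.fit_goodness_r2(np.r_[1.0, 2.0, 3.0], np.r_[2.0, 2.0, 2.0]))
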