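"""Logistic fits, ROC, univariate screen and three-model comparison."""

import warnings

import numpy as np
import pytest

from neoeit.errors import (
    CollinearityError,
    DegenerateOutcomeError,
    SchemaError,
    SmallSampleWarning,
)
from neoeit.models import (
    WaldLogisticRegression,
    compare_models,
    fit_logistic,
    roc_auc,
    univariate_screen,
)
from neoeit.simulate import CohortScenario, make_cohort


def bruteforce_auc(scores, labels):
    """Concordant-pair counting over all positive-negative pairs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_or_equals_crossproduct_on_2x2():
    x = np.array([1] * 15 + [0] * 15, float)
    y = np.array([1] * 10 + [0] * 5 + [1] * 5 + [0] * 10, float)
    fit = fit_logistic(x[:, None], y, ["exposure"])
    t = fit.term("exposure")
    assert t["or"] == pytest.approx(4.0, abs=1e-8)  # (10*10)/(5*5)
    assert t["ci_low"] < 4.0 < t["ci_high"]
    assert fit.converged


def test_perfect_separation_flagged_not_reported():
    x = np.arange(6, dtype=float)
    y = np.array([0, 0, 0, 1, 1, 1], float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_logistic(x[:, None], y)
    assert fit.separation
    assert not fit.converged
    assert np.isnan(fit.term("x0")["or"])


def test_constant_outcome_rejected():
    with pytest.raises(DegenerateOutcomeError):
        fit_logistic(np.random.default_rng(0).normal(size=(20, 1)), np.ones(20))


def test_collinear_design_rejected():
    rng = np.random.default_rng(1)
    x = rng.normal(size=20)
    design = np.column_stack([x, 2 * x])
    y = (rng.random(20) < 0.5).astype(float)
    with pytest.raises(CollinearityError):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_logistic(design, y)


def test_null_predictor_or_near_one_at_large_n():
    rng = np.random.default_rng(2)
    x = rng.normal(size=10_000)
    y = (rng.random(10_000) < 0.5).astype(float)
    fit = fit_logistic(x[:, None], y, ["x"])
    i = fit.names.index("x")
    # OR within Monte-Carlo error of 1: |log OR| < 3 SE
    assert abs(fit.coef[i]) < 3 * fit.se[i]


def test_null_rejection_rate_near_alpha():
    rng = np.random.default_rng(3)
    rejections = 0
    reps = 400
    for _ in range(reps):
        x = rng.normal(size=200)
        y = (rng.random(200) < 0.4).astype(float)
        fit = fit_logistic(x[:, None], y, ["x"])
        if fit.term("x")["p"] < 0.05:
            rejections += 1
    assert 0.02 <= rejections / reps <= 0.09


def test_standardize_gives_per_sd_odds_ratios():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 2.5, size=400)
    y = (rng.random(400) < 1 / (1 + np.exp(-0.4 * x))).astype(float)
    raw = fit_logistic(x[:, None], y, ["x"])
    std = fit_logistic(x[:, None], y, ["x"], standardize=True)
    sd = x.std()
    assert std.term("x")["coef"] == pytest.approx(raw.term("x")["coef"] * sd, rel=1e-6)


# --- ROC --------------------------------------------------------------------


def test_roc_examples():
    assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]).auc == 1.0
    assert roc_auc([5.0] * 8, [0, 1] * 4).auc == 0.5
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]).auc == 0.75


def test_roc_requires_both_classes():
    with pytest.raises(DegenerateOutcomeError):
        roc_auc([1.0, 2.0], [1, 1])


def test_roc_label_reversal():
    rng = np.random.default_rng(5)
    scores = np.round(rng.normal(size=80), 1)  # rounded -> plenty of ties
    labels = (rng.random(80) < 0.4).astype(int)
    a = roc_auc(scores, labels).auc
    b = roc_auc(scores, 1 - labels).auc
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_roc_matches_bruteforce_pairs():
    rng = np.random.default_rng(6)
    for _ in range(15):
        n = int(rng.integers(10, 200))
        scores = np.round(rng.normal(size=n), 1)
        labels = (rng.random(n) < 0.5).astype(int)
        if labels.min() == labels.max():
            continue
        assert roc_auc(scores, labels).auc == pytest.approx(
            bruteforce_auc(scores, labels), abs=1e-12
        )


# --- screen and model comparison --------------------------------------------


def test_univariate_screen_is_table2_shaped():
    table, _ = make_cohort(CohortScenario(n_subjects=200, seed=7))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        screen = univariate_screen(table)
    assert len(screen) == 15  # 5 predictors x 3 outcomes
    assert set(screen.columns) >= {"predictor", "outcome", "or", "ci_low",
                                   "ci_high", "p", "significant"}


def test_screen_missing_column_is_schema_error():
    table, _ = make_cohort(CohortScenario(n_subjects=20, seed=7))
    with pytest.raises(SchemaError):
        univariate_screen(table.drop(columns=["ahr"]))


def test_rare_outcome_flagged_unreliable():
    table, _ = make_cohort(CohortScenario(n_subjects=40, seed=8))
    table["outcome_bpd_mod_severe"] = 0
    table.loc[0, "outcome_bpd_mod_severe"] = 1  # a single event
    with pytest.warns(SmallSampleWarning):
        screen = univariate_screen(table, outcomes="outcome_bpd_mod_severe")
    assert not screen["reliable"].any()


def test_nested_models_never_increase_deviance():
    table, _ = make_cohort(CohortScenario(n_subjects=300, seed=9))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = compare_models(table, "outcome_oxygen_28d")
    combined = rep["models"]["combined"]["deviance"]
    for sub in ("clinical", "eit"):
        assert combined <= rep["models"][sub]["deviance"] + 1e-9


@pytest.mark.parametrize(
    "driver,winner,loser",
    [("clinical", "clinical", "eit"), ("eit", "eit", "clinical")],
)
def test_auc_favors_the_generating_model(driver, winner, loser):
    if driver == "clinical":
        coeffs = {"outcome_oxygen_28d": {
            "intercept": 0.9 * 29.6 + 0.002 * 1140.0,
            "gestational_age_weeks": -0.9, "birth_weight_g": -0.002,
        }}
    else:
        coeffs = {"outcome_oxygen_28d": {
            "intercept": 0.15 * 60.0 - 2.0, "aer_pct": -0.15, "ahr": 2.0,
        }}
    wins = 0
    for rep_i in range(7):
        table, _ = make_cohort(
            CohortScenario(n_subjects=250, coefficients=coeffs, seed=100 + rep_i)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = compare_models(table, "outcome_oxygen_28d")
        if rep["models"][winner]["auc"] > rep["models"][loser]["auc"]:
            wins += 1
    assert wins >= 5  # majority of seeded replicates


def test_estimator_sklearn_interface():
    est = WaldLogisticRegression(standardize=True)
    assert est.get_params()["standardize"] is True
    est.set_params(standardize=False)
    rng = np.random.default_rng(10)
    X = rng.normal(size=(120, 2))
    y = (rng.random(120) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
    est.fit(X, y)
    proba = est.predict_proba(X)
    assert proba.shape == (120, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert est.predict(X).min() >= 0
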