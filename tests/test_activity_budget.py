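"""Budget tallies and Dirichlet regression: likelihood, recovery, Wald."""

import numpy as np
import pandas as pd
import pytest

from felacc.activity_budget import (
    budgets_frame,
    compare_budgets,
    design_matrix,
    dirichlet_loglik,
    fit_dirichlet_regression,
    predict_budgets,
    zero_adjust,
    _loglik_and_grad,
    _moment_start,
)
from felacc.models import RFParams, train_random_forest
from felacc.synthetic_data import SimConfig, generate_study


def budget_frame_from_matrix(Y, groups, n_epochs=1000):
    """Long-format budget frame for a composition matrix and group dummy."""
    rows = []
    for i, (y, g) in enumerate(zip(Y, groups)):
        for k, p in enumerate(y):
            rows.append({
                "cat_id": f"obs{i}", "day": 0,
                "technique": "SOM" if g else "RF", "mount": "collar",
                "round": 4, "behaviour": f"b{k}", "proportion": p,
                "n_epochs": n_epochs,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# zero adjustment and likelihood


def test_zero_adjust_direct_substitution():
    out = zero_adjust(np.array([1.0, 0.0]), 100)
    np.testing.assert_allclose(out, [0.995, 0.005])


def test_zero_adjust_limit_and_interiority():
    y = np.array([0.6, 0.4])
    np.testing.assert_allclose(zero_adjust(y, 10**9), y, atol=1e-8)
    for n in (1, 2, 10, 1000):
        out = zero_adjust(np.array([1.0, 0.0, 0.0]), n)
        assert (out > 0).all() and (out < 1).all()
        assert out.sum() == pytest.approx(1.0)


def test_dirichlet_loglik_uniform_density():
    # alpha = (1,1,1): density is the constant (K-1)! = 2 on the simplex
    y = np.array([[0.2, 0.5, 0.3]])
    alpha = np.ones((1, 3))
    assert dirichlet_loglik(y, alpha) == pytest.approx(np.log(2.0))


def test_dirichlet_loglik_hand_computation():
    # alpha = (2,1,1), y = (1/2,1/4,1/4):
    # logGamma(4) - logGamma(2) + 1 * log(1/2) = log 6 - log 2 = log 3
    y = np.array([[0.5, 0.25, 0.25]])
    alpha = np.array([[2.0, 1.0, 1.0]])
    assert dirichlet_loglik(y, alpha) == pytest.approx(np.log(3.0))


def test_dirichlet_loglik_additive_and_boundary():
    rng = np.random.default_rng(0)
    y = rng.dirichlet([2, 3, 4], size=10)
    alpha = np.full((10, 3), 2.5)
    total = dirichlet_loglik(y, alpha)
    parts = sum(dirichlet_loglik(y[i:i + 1], alpha[i:i + 1])
                for i in range(10))
    assert total == pytest.approx(parts)
    with pytest.raises(ValueError, match="interior"):
        dirichlet_loglik(np.array([[1.0, 0.0, 0.0]]), alpha[:1])


def test_gradient_matches_finite_differences():
    rng = np.random.default_rng(1)
    Y = rng.dirichlet([2, 2, 2], size=40)
    X = np.column_stack([np.ones(40), rng.integers(0, 2, 40)])
    logY = np.log(Y)
    theta = rng.normal(0, 0.3, size=3 * 2)
    _, grad = _loglik_and_grad(theta, X, logY, 3, 2)
    eps = 1e-6
    for j in range(len(theta)):
        up, dn = theta.copy(), theta.copy()
        up[j] += eps
        dn[j] -= eps
        fd = (_loglik_and_grad(up, X, logY, 3, 2)[0]
              - _loglik_and_grad(dn, X, logY, 3, 2)[0]) / (2 * eps)
        assert grad[j] == pytest.approx(fd, rel=1e-4, abs=1e-6)


# ---------------------------------------------------------------------------
# fitting


def test_intercept_only_recovers_symmetric_alpha():
    rng = np.random.default_rng(2)
    Y = rng.dirichlet([2.0, 2.0, 2.0], size=500)
    frame = budget_frame_from_matrix(Y, np.zeros(500, dtype=int))
    fit = fit_dirichlet_regression(frame, covariates=())
    alpha_hat = np.exp(fit.beta[:, 0])
    assert fit.converged
    # components mutually within 10%
    assert alpha_hat.max() / alpha_hat.min() < 1.10
    assert np.median(alpha_hat) == pytest.approx(2.0, rel=0.15)


def test_loglik_at_optimum_beats_moment_start():
    rng = np.random.default_rng(3)
    Y = rng.dirichlet([3.0, 1.0, 2.0], size=120)
    frame = budget_frame_from_matrix(Y, np.zeros(120, dtype=int))
    fit = fit_dirichlet_regression(frame, covariates=())
    theta0 = _moment_start(Y, 3, 1)
    start_ll, _ = _loglik_and_grad(theta0, np.ones((120, 1)), np.log(Y), 3, 1)
    assert fit.loglik >= start_ll


def test_duplicated_dataset_same_beta_double_loglik():
    rng = np.random.default_rng(4)
    Y = rng.dirichlet([2.0, 3.0, 4.0], size=80)
    frame = budget_frame_from_matrix(Y, np.zeros(80, dtype=int))
    doubled = budget_frame_from_matrix(np.vstack([Y, Y]),
                                       np.zeros(160, dtype=int))
    f1 = fit_dirichlet_regression(frame, covariates=())
    f2 = fit_dirichlet_regression(doubled, covariates=())
    np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-4)
    assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-4)


def test_wald_power_under_strong_effect():
    hits = []
    for rep in range(30):
        rng = np.random.default_rng(1000 + rep)
        n = 200
        g = np.repeat([0, 1], n // 2)
        alpha = np.tile([2.0, 2.0, 2.0], (n, 1))
        alpha[g == 1, 0] *= np.exp(1.0)
        Y = np.vstack([rng.dirichlet(a) for a in alpha])
        frame = budget_frame_from_matrix(Y, g)
        fit = fit_dirichlet_regression(frame, covariates=("technique",))
        table = compare_budgets(fit, "technique[SOM]")
        hits.append(table.loc[table.behaviour == "b0", "p"].iloc[0] < 0.05)
    assert np.mean(hits) > 0.9


def test_self_contrast_is_null():
    rng = np.random.default_rng(5)
    Y = rng.dirichlet([2, 2], size=40)
    frame = budget_frame_from_matrix(Y, np.zeros(40, dtype=int))
    fit = fit_dirichlet_regression(frame, covariates=())
    out = compare_budgets(fit, "self")
    assert (out["effect"] == 0).all() and (out["p"] == 1).all()
    with pytest.raises(KeyError, match="unknown contrast"):
        compare_budgets(fit, "mount[harness]")


# ---------------------------------------------------------------------------
# budget prediction


@pytest.fixture(scope="module")
def tiny_budget_setup():
    config = SimConfig(n_cats=2, n_days=2, annotated_window=(0, 600), seed=21)
    study = generate_study(config)
    from felacc.pipeline import annotated_dataset, preprocess_dataset
    data, _ = preprocess_dataset(annotated_dataset(study, "harness"),
                                 min_count_s=5)
    model = train_random_forest(data, RFParams(n_trees=50, seed=21))
    return study, model


def test_budgets_sum_to_one_and_conserve_epochs(tiny_budget_setup):
    study, model = tiny_budget_setup
    budgets = predict_budgets(model, study, days=[1], round_index=4)
    assert len(budgets) == 2  # one per cat-day
    for b in budgets:
        assert b.proportions.sum() == pytest.approx(1.0)
        assert b.n_epochs == 86400  # every epoch of the day is classified
    frame = budgets_frame(budgets)
    assert set(frame.behaviour) <= set(model.classes)


def test_budget_matches_ground_truth_occupancy(tiny_budget_setup):
    """With a strong classifier the predicted budget tracks the
    generator's true occupancy for the dominant behaviour."""
    study, model = tiny_budget_setup
    budgets = predict_budgets(model, study, days=[1])
    cat = study.cats[0]
    truth = pd.Series(cat.true_labels(86400, 2 * 86400)).value_counts(
        normalize=True)
    b = next(x for x in budgets if x.cat_id == cat.cat_id)
    est = dict(zip(b.classes, b.proportions))
    top = truth.index[0]
    assert abs(est.get(top, 0.0) - truth[top]) < 0.15


def test_empty_day_selection_rejected(tiny_budget_setup):
    study, model = tiny_budget_setup
    with pytest.raises(ValueError, match="day"):
        predict_budgets(model, study, days=[])


def test_design_matrix_treatment_coding():
    frame = pd.DataFrame({
        "mount": ["collar", "harness", "collar", "harness"],
        "technique": ["RF", "RF", "SOM", "SOM"],
        "day": [0, 0, 1, 1],
    })
    X, names = design_matrix(frame)
    assert names[0] == "intercept"
    assert "mount[harness]" in names and "technique[SOM]" in names
    assert X.shape == (4, 4)
    np.testing.assert_array_equal(X[:, 0], 1.0)
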