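"""Logistic MLE, fit metrics, and VIF against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from acescope import (
    SeparationError,
    c_statistic,
    compute_metrics,
    fit_logistic,
    vif,
)
from acescope.fitting import FitError
from acescope.predictors import DesignMatrix


def design_from(X, y, ace_columns=None):
    cols = ["intercept"] + [f"x{i}" for i in range(1, X.shape[1])]
    return DesignMatrix(
        X=np.asarray(X, float), y=np.asarray(y, float), columns=cols,
        spec="baseline", ace_columns=ace_columns or [],
    )


def random_design(rng, n, k, binary=False):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
    if binary:
        X[:, 1:] = (X[:, 1:] > 0).astype(float)
    beta = rng.normal(scale=0.7, size=k)
    y = (rng.random(n) < expit(X @ beta)).astype(float)
    if y.min() == y.max():  # pragma: no cover - reroll degenerate outcomes
        y[0] = 1 - y[0]
    return design_from(X, y)


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

def test_intercept_only_closed_form():
    y = np.array([1.0] * 30 + [0.0] * 70)
    fit = fit_logistic(design_from(np.ones((100, 1)), y))
    assert fit.beta[0] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)
    assert fit.fitted.mean() == pytest.approx(0.3, abs=1e-10)


def test_two_by_two_log_odds_ratio():
    """20 exposed cases, 10 exposed controls, 10 unexposed cases, 20
    unexposed controls: the slope is the log cross-product ratio ln 4."""
    x = np.array([1.0] * 30 + [0.0] * 30)
    y = np.array([1.0] * 20 + [0.0] * 10 + [1.0] * 10 + [0.0] * 20)
    fit = fit_logistic(design_from(np.column_stack([np.ones(60), x]), y))
    assert fit.beta[1] == pytest.approx(np.log(4.0), abs=1e-6)


def test_constant_outcome_raises():
    with pytest.raises(SeparationError):
        fit_logistic(design_from(np.ones((20, 1)), np.zeros(20)))


def test_perfect_separation_raises():
    x = np.array([0.0] * 10 + [1.0] * 10)
    y = x.copy()
    with pytest.raises(FitError):
        fit_logistic(design_from(np.column_stack([np.ones(20), x]), y))


def test_per_observation_quantities_consistent():
    rng = np.random.default_rng(1)
    fit = fit_logistic(random_design(rng, 400, 4))
    assert fit.loglik_i.sum() == pytest.approx(fit.loglik_total, abs=1e-8)
    # score equation: columns of the summed score vanish at the MLE
    assert np.abs(fit.score_i.sum(axis=0)).max() < 1e-8
    # observed information equals -hessian and matches X'WX
    w = fit.fitted * (1 - fit.fitted)
    X = fit.design.X
    np.testing.assert_allclose(-fit.hessian, X.T @ (X * w[:, None]), rtol=1e-10)


def test_mean_fitted_probability_equals_prevalence():
    rng = np.random.default_rng(2)
    for _ in range(5):
        fit = fit_logistic(random_design(rng, 300, 3))
        assert fit.fitted.mean() == pytest.approx(fit.design.y.mean(), abs=1e-9)


def test_matches_generic_numerical_optimizer():
    """MLE agrees with a generic BFGS minimizer of the negative
    log-likelihood on 20 random small datasets."""
    rng = np.random.default_rng(3)
    for rep in range(20):
        n = int(rng.integers(50, 201))
        k = int(rng.integers(2, 7))
        design = random_design(rng, n, k)
        fit = fit_logistic(design)

        def nll(beta, X=design.X, y=design.y):
            eta = X @ beta
            return -(y @ eta - np.logaddexp(0.0, eta).sum())

        res = minimize(nll, np.zeros(k), method="BFGS", options={"gtol": 1e-10})
        np.testing.assert_allclose(fit.beta, res.x, atol=1e-6)


def test_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(4)
    design = random_design(rng, 500, 5)
    fit = fit_logistic(design)
    ref = sm.Logit(design.y, design.X).fit(disp=0)
    np.testing.assert_allclose(fit.beta, ref.params, atol=1e-7)
    np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-6)
    np.testing.assert_allclose(fit.loglik_i, ref.model.loglikeobs(ref.params), atol=1e-10)


def test_adding_column_never_decreases_loglik():
    rng = np.random.default_rng(5)
    for _ in range(5):
        design = random_design(rng, 300, 4)
        reduced = design_from(design.X[:, :3], design.y)
        assert fit_logistic(design).loglik_total >= fit_logistic(reduced).loglik_total - 1e-9


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def c_stat_bruteforce(p, y):
    pairs = [
        (pi, pj)
        for (pi, yi), (pj, yj) in itertools.product(zip(p, y), zip(p, y))
        if yi == 1 and yj == 0
    ]
    return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs) / len(pairs)


def test_c_stat_worked_example():
    p = np.array([0.9, 0.8, 0.7, 0.4, 0.2])
    y = np.array([1, 1, 0, 1, 0])
    assert c_statistic(p, y) == pytest.approx(5 / 6, abs=1e-12)


def test_c_stat_constant_predictions():
    assert c_statistic(np.full(10, 0.3), np.array([1] * 4 + [0] * 6)) == 0.5


@settings(max_examples=60)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 4), st.integers(0, 1)), min_size=4, max_size=30
    ).filter(lambda d: 0 < sum(y for _, y in d) < len(d))
)
def test_c_stat_matches_exhaustive_enumeration(data):
    """Rank-based c-statistic equals the exhaustive pair count (ties 1/2)
    on small datasets, including heavy ties."""
    p = np.array([v / 4 for v, _ in data])
    y = np.array([y for _, y in data])
    assert c_statistic(p, y) == pytest.approx(c_stat_bruteforce(p, y), abs=1e-12)


def test_c_stat_invariant_to_monotone_transform():
    rng = np.random.default_rng(6)
    p = rng.random(200)
    y = (rng.random(200) < 0.4).astype(int)
    assert c_statistic(p, y) == pytest.approx(c_statistic(np.exp(3 * p), y), abs=1e-12)


def test_metrics_identities():
    rng = np.random.default_rng(7)
    design = random_design(rng, 400, 4)
    null = design_from(design.X[:, :1], design.y)
    fit, null_fit = fit_logistic(design), fit_logistic(null)
    met = compute_metrics(fit, null_fit)
    assert met.aic == pytest.approx(-2 * fit.loglik_total + 2 * fit.k, abs=1e-8)
    cs = 1 - np.exp(2 * (null_fit.loglik_total - fit.loglik_total) / fit.n)
    nk = cs / (1 - np.exp(2 * null_fit.loglik_total / fit.n))
    assert met.r2_nagelkerke == pytest.approx(nk, abs=1e-8)
    assert 0 <= met.r2_nagelkerke <= 1


def test_metrics_null_vs_null_is_zero():
    y = np.array([1.0] * 40 + [0.0] * 60)
    null = fit_logistic(design_from(np.ones((100, 1)), y))
    met = compute_metrics(null, null)
    assert met.r2_nagelkerke == pytest.approx(0.0, abs=1e-12)


def test_metrics_row_mismatch_rejected():
    y = np.array([1.0] * 10 + [0.0] * 10)
    f1 = fit_logistic(design_from(np.ones((20, 1)), y))
    f2 = fit_logistic(design_from(np.ones((20, 1)), y[::-1]))
    with pytest.raises(ValueError):
        compute_metrics(f1, f2)


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def test_vif_orthogonal_columns():
    n = 64
    X = np.ones((n, 3))
    X[:, 1] = np.tile([1, -1], n // 2)
    X[:, 2] = np.tile([1, 1, -1, -1], n // 4)
    d = design_from(X, np.tile([0.0, 1.0], n // 2), ace_columns=["x1", "x2"])
    vals = vif(d)
    assert vals["x1"] == pytest.approx(1.0, abs=1e-10)
    assert vals["x2"] == pytest.approx(1.0, abs=1e-10)


def test_vif_bivariate_closed_form():
    """Two correlated predictors and an intercept: VIF = 1/(1-r^2)."""
    rng = np.random.default_rng(8)
    a = rng.standard_normal(500)
    b = 0.6 * a + 0.8 * rng.standard_normal(500)
    X = np.column_stack([np.ones(500), a, b])
    y = (rng.random(500) < 0.5).astype(float)
    d = design_from(X, y, ace_columns=["x1", "x2"])
    r = np.corrcoef(a, b)[0, 1]
    expected = 1.0 / (1.0 - r**2)
    vals = vif(d)
    assert vals["x1"] == pytest.approx(expected, rel=1e-10)
    assert vals["x2"] == pytest.approx(expected, rel=1e-10)


def test_vif_duplicate_column_infinite():
    rng = np.random.default_rng(9)
    a = rng.standard_normal(100)
    X = np.column_stack([np.ones(100), a, a])
    d = design_from(X, (rng.random(100) < 0.5).astype(float), ace_columns=["x1", "x2"])
    vals = vif(d)
    assert vals["x1"] == np.inf and vals["x2"] == np.inf
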