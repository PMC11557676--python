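"""Penalised ordinal regression: objective, solver, tuning, stability."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from taigrade.elastic_net import (
    ElasticNetConfig,
    bootstrap_inclusion,
    fit_penalized,
    lambda_path,
    penalized_objective,
    select_tuning,
)
from taigrade.regression import fit_proportional_odds


def _ordinal_data(rng, n=200, p=6, signal=(1.2, -0.9), k=4):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{j}" for j in range(p)])
    beta = np.zeros(p)
    beta[:len(signal)] = signal
    eta = X.to_numpy() @ beta
    th = np.quantile(eta, np.linspace(0.2, 0.8, k - 1)) + np.linspace(0, 1e-3, k - 1)
    cum = 1 / (1 + np.exp(-(np.asarray(th)[None, :] - eta[:, None])))
    y = (rng.uniform(size=n)[:, None] > cum).sum(axis=1) + 1.0
    return X, pd.Series(y)


def test_objective_components(rng):
    X, y = _ordinal_data(rng, n=60)
    codes = np.searchsorted(np.sort(y.unique()), y)
    pen = np.array([True] * 4 + [False] * 2)
    beta = np.array([2.0, 0, 0, 0, 0.5, -0.5])
    theta = np.array([-1.0, 0.0, 1.0])
    A = X.to_numpy()
    base = penalized_objective(beta, theta, A, codes, pen, 0.0, 1.0)
    # lambda=0: objective is the bare mean negative log-likelihood
    # alpha=0, beta_j=2, lambda=1: ridge adds (1/2)*2^2 = 2 for that column
    ridge = penalized_objective(beta, theta, A, codes, pen, 1.0, 0.0)
    assert ridge == pytest.approx(base + 2.0)
    lasso = penalized_objective(beta, theta, A, codes, pen, 1.0, 1.0)
    assert lasso == pytest.approx(base + 2.0)   # |2| on the only nonzero pen column
    zero_pen = penalized_objective(np.array([0, 0, 0, 0, 0.5, -0.5]), theta,
                                   A, codes, pen, 5.0, 0.7)
    none = penalized_objective(np.array([0, 0, 0, 0, 0.5, -0.5]), theta,
                               A, codes, pen, 0.0, 0.7)
    assert zero_pen == pytest.approx(none)      # zero penalised block: no penalty


def test_lambda_zero_matches_unpenalised_fit(rng):
    X, y = _ordinal_data(rng, n=250)
    pen = list(X.columns[:4])
    fit = fit_penalized(X, y, pen, lam=0.0, alpha=1.0)
    ref = fit_proportional_odds(X, y)
    # same maximum: compare achieved log-likelihoods
    obj = fit.objective   # mean NLL at lam=0
    assert -obj * len(y) == pytest.approx(ref.loglik, abs=1e-4)
    assert np.allclose(fit.beta, ref.beta, atol=5e-3)
    assert np.allclose(fit.theta, ref.theta, atol=5e-3)


def test_lambda_max_zeroes_everything_and_kkt_holds(rng):
    X, y = _ordinal_data(rng, n=200)
    pen = list(X.columns[:4])
    lams = lambda_path(X, y, pen, alpha=1.0)
    top = fit_penalized(X, y, pen, lams[0], 1.0)
    assert int(top.nonzero_penalized.sum()) == 0
    mid = fit_penalized(X, y, pen, lams[12], 1.0)
    assert mid.max_kkt_violation(X, y) < 1e-5


def test_path_sparsity_monotone_in_lambda(rng):
    X, y = _ordinal_data(rng, n=200)
    pen = list(X.columns)
    lams = lambda_path(X, y, pen, alpha=1.0, n_lambda=15)
    warm, counts = None, []
    for lam in lams:
        fit = fit_penalized(X, y, pen, lam, 1.0, warm=warm)
        warm = (fit.beta_std, fit.a)
        counts.append(int(fit.nonzero_penalized.sum()))
    assert counts == sorted(counts)   # nonzeros grow as lambda shrinks


def test_objective_trace_non_increasing(rng):
    X, y = _ordinal_data(rng, n=150)
    fit = fit_penalized(X, y, list(X.columns), 0.05, 0.5)
    trace = np.asarray(fit.objective_trace)
    assert np.all(np.diff(trace) <= 1e-10)


def _binary_limits_data(rng, n=150, p=4):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
    # pre-standardised so in-solver scaling is the identity
    X = (X - X.mean()) / X.std(ddof=0)
    eta = X.to_numpy() @ np.array([1.0, -0.7, 0.0, 0.0])
    y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float) + 1.0)
    return X, y


@pytest.mark.parametrize("alpha,sk_penalty", [(1.0, "l1"), (0.0, "l2")])
def test_lasso_and_ridge_limits_match_reference(rng, alpha, sk_penalty):
    """Two-category case: our solver vs scikit-learn's dedicated lasso/ridge
    logistic regression at the equivalent penalty strength."""
    X, y = _binary_limits_data(rng)
    lam = 0.08
    fit = fit_penalized(X, y, list(X.columns), lam, alpha, tol=1e-9)
    n = len(y)
    C = 1.0 / (n * lam) if alpha == 1.0 else 1.0 / (n * lam)
    ref = LogisticRegression(penalty=sk_penalty, C=C, solver="liblinear" if
                             alpha == 1.0 else "lbfgs", tol=1e-10, max_iter=5000)
    ref.fit(X.to_numpy(), (y == 2).astype(int))
    assert np.allclose(fit.beta_std, ref.coef_.ravel(), atol=2e-3)


def test_full_reproducibility_under_seed(rng):
    X, y = _ordinal_data(rng, n=150)
    pen = list(X.columns)
    a = bootstrap_inclusion(X, y, pen, 0.05, 0.5, n_bootstrap=25, seed=9)
    b = bootstrap_inclusion(X, y, pen, 0.05, 0.5, n_bootstrap=25, seed=9)
    pd.testing.assert_frame_equal(a.inclusion, b.inclusion)
    assert a.n_redrawn == b.n_redrawn


def test_single_point_grid_returned(rng):
    X, y = _ordinal_data(rng, n=120)
    pen = list(X.columns)
    tun = select_tuning(X, y, pen, alphas=(0.5,), n_lambda=1, seed=2)
    assert tun.alpha == 0.5
    assert len(tun.cv_table) == 1
    assert tun.lam == pytest.approx(tun.cv_table["lam"].iloc[0])


def test_pure_noise_predictors_mostly_zeroed(rng):
    wins = 0
    for rep in range(3):
        X, y = _ordinal_data(rng, n=150, p=5, signal=())
        pen = list(X.columns)
        tun = select_tuning(X, y, pen, alphas=(0.5, 1.0), n_lambda=20, seed=rep)
        fit = fit_penalized(X, y, pen, tun.lam, tun.alpha)
        if int(fit.nonzero_penalized.sum()) == 0:
            wins += 1
    assert wins >= 2


def test_strong_signal_selected_beats_max_lambda(rng):
    X, y = _ordinal_data(rng, n=250, signal=(1.5, -1.2))
    pen = list(X.columns)
    tun = select_tuning(X, y, pen, alphas=(1.0,), n_lambda=20, seed=4)
    tab = tun.cv_table
    at_max = tab.loc[tab["lam"].idxmax(), "oof_loglik"]
    at_sel = tab.loc[np.isclose(tab["lam"], tun.lam), "oof_loglik"].iloc[0]
    assert at_sel >= at_max
    # signal columns survive the selected penalty
    fit = fit_penalized(X, y, pen, tun.lam, tun.alpha)
    assert fit.beta_std[0] != 0 and fit.beta_std[1] != 0


def test_marshall_must_stay_unpenalised():
    with pytest.raises(ValueError, match="[Mm]arshall"):
        ElasticNetConfig(penalized=["marshall_56", "tai_pons_bil"])


def test_unpenalised_variables_report_full_inclusion(rng):
    X, y = _ordinal_data(rng, n=150)
    pen = list(X.columns[:3])
    stab = bootstrap_inclusion(X, y, pen, 0.1, 1.0, n_bootstrap=20, seed=1)
    unpen = stab.inclusion[~stab.inclusion["penalized"]]
    assert (unpen["pct_included"] == 100.0).all()
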