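"""Proportional-odds and binary logistic models: oracles and reporting rules."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from taigrade.regression import (
    FitError,
    ModelSpec,
    fit_binary_logistic,
    fit_model,
    fit_proportional_odds,
    model_fit_table,
    report_table2,
    transform_volume,
)


def _simulate_ordinal(rng, n, beta, thresholds, binary_cols=()):
    """Cumulative-logit draw with known coefficients."""
    p = len(beta)
    X = rng.normal(size=(n, p))
    for j in binary_cols:
        X[:, j] = (rng.random(n) < 0.3).astype(float)
    eta = X @ np.asarray(beta)
    th = np.asarray(thresholds, dtype=float)
    cum = 1.0 / (1.0 + np.exp(-(th[None, :] - eta[:, None])))
    y = (rng.uniform(size=n)[:, None] > cum).sum(axis=1) + 1.0
    cols = [f"x{j}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), pd.Series(y)


@pytest.mark.parametrize("v,expected", [
    (0.0, (0.0, 0.0)),
    (1.0, (1.0, 0.0)),
    (np.e, (1.0, 1.0)),
])
def test_transform_volume(v, expected):
    pres, logv = transform_volume(v)
    assert (pres, logv) == pytest.approx(expected)


def test_transform_volume_rejects_negative():
    with pytest.raises(ValueError):
        transform_volume(-0.1)


def test_two_category_ordinal_equals_binary_logistic(rng):
    X, y = _simulate_ordinal(rng, 300, [0.8, -0.5], [0.3])
    ordinal = fit_proportional_odds(X, y)
    binary = fit_binary_logistic(X, (y == 2).astype(float))
    assert np.allclose(ordinal.beta, binary.beta, atol=1e-6)
    assert ordinal.loglik == pytest.approx(binary.loglik, abs=1e-6)


def test_intercept_only_thresholds_are_cumulative_logits(rng):
    y = pd.Series(rng.integers(1, 5, 200).astype(float))
    res = fit_proportional_odds(pd.DataFrame(index=y.index), y)
    counts = y.value_counts().sort_index().to_numpy()
    cum = np.cumsum(counts)[:-1] / counts.sum()
    assert np.allclose(res.theta, np.log(cum / (1 - cum)))
    assert res.pseudo_r2 == pytest.approx(0.0)


def test_fitted_loglik_at_least_null(rng):
    X, y = _simulate_ordinal(rng, 250, [0.6, 0.0, -0.3], [-1.0, 0.5, 1.5])
    res = fit_proportional_odds(X, y)
    assert res.loglik >= res.loglik_null
    # metric identities
    assert res.aic == pytest.approx(-2 * res.loglik + 2 * res.k)
    assert res.bic == pytest.approx(-2 * res.loglik + res.k * np.log(res.n))
    assert np.all(np.diff(res.theta) > 0)
    assert np.allclose(res.table["or"], np.exp(res.beta))


def test_proportional_odds_matches_generic_optimiser_oracle(rng):
    """Tiny instance: direct likelihood maximisation by a generic optimiser."""
    X, y = _simulate_ordinal(rng, 30, [0.7, -0.4], [-0.5, 0.8])
    res = fit_proportional_odds(X, y)
    cats = np.sort(y.unique())
    codes = np.searchsorted(cats, y)
    A = X.to_numpy()

    def nll(params):
        beta, t1, d = params[:2], params[2], np.exp(params[3:])
        th = np.concatenate([[t1], t1 + np.cumsum(d)])
        eta = A @ beta
        hi = np.where(codes < len(th), th[np.minimum(codes, len(th) - 1)] - eta, np.inf)
        lo = np.where(codes > 0, th[np.maximum(codes - 1, 0)] - eta, -np.inf)
        P = 1 / (1 + np.exp(-hi)) - 1 / (1 + np.exp(-lo))
        return -np.sum(np.log(np.clip(P, 1e-12, None)))

    oracle = minimize(nll, np.zeros(2 + len(cats) - 1), method="Nelder-Mead",
                      options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10})
    assert -oracle.fun == pytest.approx(res.loglik, abs=1e-4)


def test_binary_intercept_only_balanced(rng):
    y = pd.Series([0.0, 1.0] * 40)
    res = fit_binary_logistic(pd.DataFrame(index=y.index), y)
    assert res.theta[0] == pytest.approx(0.0, abs=1e-8)
    assert res.loglik == pytest.approx(-80 * np.log(2))


def test_separation_raises():
    X = pd.DataFrame({"x": [0, 1, 2, 3, 10, 11, 12, 13.0]})
    y = pd.Series([0, 0, 0, 0, 1, 1, 1, 1.0])
    with pytest.raises(FitError):
        fit_binary_logistic(X, y)


def test_binary_estimates_within_2se(rng):
    n, beta_true = 800, 0.9
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(0.2 + beta_true * x)))
    y = pd.Series((rng.random(n) < p).astype(float))
    res = fit_binary_logistic(pd.DataFrame({"x": x}), y)
    assert abs(res.beta["x"] - beta_true) < 2 * res.table.loc["x", "se"]


def test_rank_deficiency_names_collinear_column(rng):
    x = rng.normal(size=100)
    X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=100)})
    y = pd.Series(rng.integers(1, 4, 100).astype(float))
    with pytest.raises(FitError, match="collinear"):
        fit_proportional_odds(X, y)


def test_log_volume_coefficient_scale_equivariant(rng):
    """Rescaling volumes (cm^3 -> mm^3) leaves the log-volume slope unchanged."""
    n = 400
    v = np.where(rng.random(n) < 0.4, 0.0, rng.lognormal(0.5, 1.0, n))
    pres, logv = transform_volume(v)
    eta = 0.5 * pres + 0.6 * logv
    th = np.array([-0.5, 0.8, 2.0])
    cum = 1 / (1 + np.exp(-(th[None, :] - eta[:, None])))
    y = pd.Series((rng.uniform(size=n)[:, None] > cum).sum(axis=1) + 1.0)

    def slope(scale):
        p2, l2 = transform_volume(v * scale)
        X = pd.DataFrame({"pres": p2, "logv": l2})
        return fit_proportional_odds(X, y).beta["logv"]

    assert slope(1.0) == pytest.approx(slope(1000.0), abs=1e-5)


# ---------------------------------------------------------------------------
# reporting rules


def _toy_frame(rng, n=200, p_exposure=0.2, beta_exposure=0.0):
    """Severe-stratum analysis frame with one binary MRI exposure."""
    exposure = (rng.random(n) < p_exposure).astype(float)
    age = rng.uniform(18, 65, n)
    gcs = rng.integers(3, 9, n).astype(float)
    eta = 0.02 * age - 0.1 * gcs + beta_exposure * exposure
    th = np.quantile(eta, [0.12, 0.3, 0.5, 0.65, 0.78, 0.88, 0.95]) + \
        np.linspace(0, 1e-3, 7)
    cum = 1 / (1 + np.exp(-(np.asarray(th)[None, :] - eta[:, None])))
    y = (rng.uniform(size=n)[:, None] > cum).sum(axis=1) + 1
    return pd.DataFrame({
        "age": age, "gcs": gcs,
        "sex_male": (rng.random(n) < 0.75).astype(float), "pupil_uni": 0.0,
        "pupil_bil": 0.0,
        "marshall_2": (rng.random(n) < 0.4).astype(float),
        "marshall_34": 0.0, "marshall_56": 0.0,
        "tai_pons_bil": exposure,
        "response_ordinal": y.astype(float),
        "disability": (y >= 3).astype(float),
        "gose6": 9 - y,
    })


def test_report_suppresses_rare_exposures(rng):
    frame = _toy_frame(rng, n=150)
    frame["tai_pons_bil"] = 0.0
    frame.loc[frame.index[:8], "tai_pons_bil"] = 1.0   # 8 carriers < 10
    tab = report_table2(frame, "severe",
                        exposures=[("Bilateral TAI in pons", "tai_pons_bil",
                                    "identity")])
    row = tab.iloc[0]
    assert row["n"] == 8
    assert row["suppressed"]
    assert np.isnan(row["or"])


def test_zero_variance_exposure_reported_na(rng):
    frame = _toy_frame(rng, n=150, p_exposure=0.3)
    frame["tai_pons_bil"] = 0.0
    tab = report_table2(frame, "severe",
                        exposures=[("Bilateral TAI in pons", "tai_pons_bil",
                                    "identity")])
    assert tab.iloc[0]["suppressed"]


def test_null_exposure_rarely_flagged_significant(rng):
    """Type-I error at the p<0.01 rule: a no-effect exposure is flagged in
    far fewer than 5% of replicates."""
    flags = []
    for _ in range(30):
        frame = _toy_frame(rng, n=500, p_exposure=0.25, beta_exposure=0.0)
        tab = report_table2(frame, "severe",
                            exposures=[("x", "tai_pons_bil", "identity")])
        flags.append(bool(tab.iloc[0]["significant"]))
    assert sum(flags) <= 2   # >= 93% of replicates unflagged


def test_model_fit_table_nested_and_duplicates(rng):
    frame = _toy_frame(rng, n=300, p_exposure=0.3, beta_exposure=1.0)
    m0 = ModelSpec("baseline", stratum="severe")
    m1 = ModelSpec("with exposure", stratum="severe",
                   exposures=[("tai_pons_bil", "identity")])
    tab = model_fit_table(frame, [m0, m1, m1])
    ll = dict(zip(tab["model"], tab["loglik"]))
    assert ll["with exposure"] >= ll["baseline"]       # nesting
    dup = tab[tab["model"] == "with exposure"]
    assert dup.iloc[0]["aic"] == pytest.approx(dup.iloc[1]["aic"])


def test_model_fit_table_guards_observation_set(rng):
    frame = _toy_frame(rng, n=300)
    frame["vol"] = rng.lognormal(0, 1, 300)
    frame.loc[frame.index[:30], "vol"] = np.nan
    m0 = ModelSpec("baseline", stratum="severe")
    m1 = ModelSpec("vol", stratum="severe", exposures=[("vol", "identity")])
    with pytest.raises(FitError, match="observation set"):
        model_fit_table(frame, [m0, m1])


def test_empty_stratum_errors(rng):
    frame = _toy_frame(rng, n=50)
    with pytest.raises(FitError, match="empty stratum"):
        report_table2(frame, "mild")


def test_interaction_term_expands_design(analysis_frame):
    """A DWI-volume exposure with a days-to-MRI interaction adds one
    product column and fits."""
    spec = ModelSpec("dwi x days", stratum="severe",
                     exposures=[("vol_tai_dwi_cm3", "log_volume_pair")],
                     interactions=[("log_vol_tai_dwi_cm3", "days_to_mri")])
    res = fit_model(analysis_frame, spec)
    assert "log_vol_tai_dwi_cm3:days_to_mri" in res.beta.index
    assert res.k == len(res.beta) + len(res.theta)


def test_mild_stratum_uses_binary_disability_model(rng):
    frame = _toy_frame(rng, n=300, p_exposure=0.4, beta_exposure=0.8)
    frame["gcs"] = 15.0
    spec = ModelSpec("mild", stratum="mild",
                     exposures=[("tai_pons_bil", "identity")])
    res = fit_model(frame, spec)
    assert res.kind == "binary"
    assert set(res.beta.index) == {"age", "sex_male", "tai_pons_bil"}
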