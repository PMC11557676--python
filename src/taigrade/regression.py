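"""Adjusted ordinal and binary logistic outcome models.

Proportional-odds (cumulative-logit) regression with the inverted GOSE as
response, and binary logistic regression for the dichotomised outcome, with
the covariate conventions used throughout the analysis:

* volumes enter as a (presence, ln volume) column pair — the natural log of
  a zero volume does not exist, so a presence indicator accompanies the
  log-volume, which is 0 when the lesion is absent;
* the worst Marshall CT score enters as an ordered categorical collapsed to
  {1, 2, 3-4, 5-6} (dummy-coded against 1);
* pupil status enters as two dummies (unilateral / bilateral dilatation);
* per-stratum covariate presets: severe = age + GCS + pupils + Marshall;
  moderate GCS 9-12 = age + GCS + Marshall; moderate GCS 13 = age +
  Marshall; mild = age + sex.

Model fit is summarised by McFadden's pseudo-R², AIC and BIC; effects by
OR = exp(beta) with Wald 95% CIs; p < 0.01 is flagged as significant and
exposures carried by fewer than 10 patients are suppressed (reported NA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from statsmodels.discrete.discrete_model import Logit
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import Cohort
from .grading import extract_features_cohort
from .outcome import construct_gose6, dichotomize

__all__ = [
    "ModelSpec",
    "OrdinalFitResult",
    "FitError",
    "STRATA",
    "STRATUM_COVARIATES",
    "transform_volume",
    "build_analysis_frame",
    "stratum_mask",
    "design_matrix",
    "fit_proportional_odds",
    "fit_binary_logistic",
    "report_table2",
    "model_fit_table",
    "TABLE2_EXPOSURES",
]

P_SIGNIFICANT = 0.01
MIN_EXPOSURE_N = 10

STRATA = ("all", "severe", "moderate_9_12", "moderate_13", "mild")

#: Adjustment covariates per stratum (design-column names).
STRATUM_COVARIATES = {
    "all": ["age", "gcs", "pupil_uni", "pupil_bil", "marshall_2", "marshall_34", "marshall_56"],
    "severe": ["age", "gcs", "pupil_uni", "pupil_bil", "marshall_2", "marshall_34", "marshall_56"],
    "moderate_9_12": ["age", "gcs", "marshall_2", "marshall_34", "marshall_56"],
    "moderate_13": ["age", "marshall_2", "marshall_34", "marshall_56"],
    "mild": ["age", "sex_male"],
}

#: Strata modelled with binary logistic regression on disability (GOSE <= 6);
#: the rest use proportional-odds regression on the inverted GOSE.
BINARY_STRATA = ("moderate_13", "mild")

#: Table-2-style exposure list: (label, feature column, transform).
TABLE2_EXPOSURES = [
    ("Bilateral TAI in brainstem/thalami", "tai_bilat_brainstem_thal", "identity"),
    ("Bilateral TAI in pons", "tai_pons_bil", "identity"),
    ("Bilateral TAI in mesencephalon/thalami", "tai_bilat_mes_thal", "identity"),
    ("Any TAI in brainstem/thalami/basal ganglia", "tai_any_deep", "identity"),
    ("Bilateral TAI in brainstem", "tai_brainstem_bil", "identity"),
    ("Unilateral TAI in brainstem", "tai_brainstem_uni", "identity"),
    ("Bilateral TAI in thalami", "tai_thalamus_bil", "identity"),
    ("Unilateral TAI in thalamus", "tai_thalamus_uni", "identity"),
    ("Bilateral TAI in basal ganglia", "tai_basal_ganglia_bil", "identity"),
    ("Unilateral TAI in basal ganglia", "tai_basal_ganglia_uni", "identity"),
    ("TAI in corpus callosum", "tai_corpus_callosum", "identity"),
    ("TAI in hemispheres", "tai_hemispheric", "identity"),
    ("Vol. TAI on FLAIR", "vol_tai_flair_cm3", "log_volume_pair"),
    ("Vol. TAI on DWI", "vol_tai_dwi_cm3", "log_volume_pair"),
    ("No. TAI on T2*GRE/SWI", "n_tai_t2gre_swi", "count"),
    ("Contusions on CT", "contusion_on_ct", "identity"),
    ("Contusions on MRI", "contusion_on_mri", "identity"),
    ("Vol. contusions on MRI", "vol_contusion_flair_cm3", "log_volume_pair"),
]


class FitError(RuntimeError):
    """Raised on separation, rank deficiency or non-convergence."""


def transform_volume(v_cm3):
    """Volume transform: (presence indicator, natural-log volume).

    Zero volume maps to (0, 0); positive volume to (1, ln v). Vectorised
    over arrays; negative volumes are rejected.
    """
    v = np.asarray(v_cm3, dtype=float)
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    presence = (v > 0).astype(float)
    with np.errstate(divide="ignore"):
        logv = np.where(v > 0, np.log(np.where(v > 0, v, 1.0)), 0.0)
    if np.isscalar(v_cm3) or np.ndim(v_cm3) == 0:
        return float(presence), float(logv)
    return presence, logv


@dataclass
class ModelSpec:
    """A model to fit: stratum covariates + optional exposure terms.

    ``exposures`` is a list of (feature_column, transform) with transform in
    {identity, log_volume_pair, count}. ``interactions`` lists pairs of
    design-column names whose product is added (e.g. a DWI term with days
    to MRI).
    """

    name: str
    stratum: str = "all"
    exposures: list = field(default_factory=list)
    interactions: list = field(default_factory=list)
    include_marshall: bool = True

    @property
    def response(self) -> str:
        return "binary_event" if self.stratum in BINARY_STRATA else "ordinal_inverted_gose"


@dataclass
class OrdinalFitResult:
    """Fit summary shared by the ordinal and binary models."""

    beta: pd.Series          # log-odds per design column
    theta: np.ndarray        # ordered thresholds (binary: single intercept)
    loglik: float
    loglik_null: float
    k: int                   # number of estimated parameters
    n: int
    table: pd.DataFrame      # per-term OR, CI, p, significance
    kind: str                # "ordinal" | "binary"

    @property
    def pseudo_r2(self) -> float:
        return 1.0 - self.loglik / self.loglik_null

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * np.log(self.n)


# ---------------------------------------------------------------------------
# analysis frame and designs


def build_analysis_frame(cohort: Cohort, features: pd.DataFrame | None = None,
                         outcomes6: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge patients, region features and constructed outcomes per patient.

    Adds the derived covariate columns the presets reference (sex_male,
    pupil dummies, collapsed Marshall dummies, marshall_num, severity) and
    ``gose6`` / ``response_ordinal`` when outcomes are constructible.
    """
    if features is None:
        features = extract_features_cohort(cohort)
    pats = cohort.patients.set_index("patient_id").copy()
    pats["severity"] = cohort.severity()
    pats["sex_male"] = (pats["sex"] == "male").astype(float)
    pats["pupil_uni"] = (pats["pupils"] == "unilateral_dilated").astype(float)
    pats["pupil_bil"] = (pats["pupils"] == "bilateral_dilated").astype(float)
    collapse = {"1": "1", "2": "2", "3": "3-4", "4": "3-4", "5": "5-6", "6": "5-6"}
    mcat = pats["marshall"].map(lambda m: collapse.get(m, None))
    pats["marshall_2"] = (mcat == "2").astype(float)
    pats["marshall_34"] = (mcat == "3-4").astype(float)
    pats["marshall_56"] = (mcat == "5-6").astype(float)
    num = {"no_ct": np.nan, "1": 1, "2": 2, "3": 3, "4": 4, "5": 5, "6": 6}
    pats["marshall_num"] = pats["marshall"].map(num).astype(float)
    df = pats.join(features.drop(columns=["contusion_on_ct"], errors="ignore"),
                   how="left")
    if outcomes6 is None:
        cov = pd.DataFrame({
            "age": pats["age"].astype(float),
            "gcs": pats["gcs"].astype(float),
            "marshall_num": pats["marshall_num"],
            "log1p_vol_flair": np.log1p(df["vol_tai_flair_cm3"].astype(float)),
        })
        try:
            outcomes6 = construct_gose6(cohort.outcomes, cov)
        except ValueError:
            outcomes6 = None
    if outcomes6 is not None:
        df = df.join(outcomes6, how="left")
        df["poor_outcome"] = [
            dichotomize(int(g), "poor_vs_favourable") if pd.notna(g) else np.nan
            for g in df["gose6"]
        ]
        df["disability"] = [
            dichotomize(int(g), "disability_vs_good") if pd.notna(g) else np.nan
            for g in df["gose6"]
        ]
    return df


def stratum_mask(df: pd.DataFrame, stratum: str) -> pd.Series:
    gcs = df["gcs"].astype(float)
    if stratum == "all":
        return gcs.notna()
    if stratum == "severe":
        return gcs <= 8
    if stratum == "moderate_9_12":
        return (gcs >= 9) & (gcs <= 12)
    if stratum == "moderate_13":
        return gcs == 13
    if stratum == "mild":
        return gcs >= 14
    raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


def _exposure_columns(df: pd.DataFrame, feature: str, transform: str) -> pd.DataFrame:
    vals = df[feature]
    if transform == "identity":
        return pd.DataFrame({feature: vals.astype(float)})
    if transform == "count":
        return pd.DataFrame({feature: vals.astype(float)})
    if transform == "log_volume_pair":
        pres, logv = transform_volume(vals.to_numpy(dtype=float))
        return pd.DataFrame(
            {f"pres_{feature}": pres, f"log_{feature}": logv}, index=df.index
        )
    raise ValueError(f"unknown exposure transform {transform!r}")


def design_matrix(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Build (X, y) for a model spec on its stratum's complete cases."""
    sub = df[stratum_mask(df, spec.stratum)]
    covs = list(STRATUM_COVARIATES[spec.stratum])
    if not spec.include_marshall:
        covs = [c for c in covs if not c.startswith("marshall")]
    parts = [sub[covs].astype(float)]
    for feature, transform in spec.exposures:
        parts.append(_exposure_columns(sub, feature, transform))
    X = pd.concat(parts, axis=1)
    for a, b in spec.interactions:
        X[f"{a}:{b}"] = X[a] * sub[b].astype(float) if b not in X else X[a] * X[b]
    if spec.response == "binary_event":
        y = sub["disability"]
    else:
        y = sub["response_ordinal"]
    ok = X.notna().all(axis=1) & y.notna()
    X, y = X[ok], y[ok].astype(float)
    # adjustment dummies for levels absent from the stratum are dropped
    # (e.g. no bilateral pupil dilatation among moderate TBI); exposure
    # columns are kept so a constant exposure surfaces as a fit error
    empty_levels = [c for c in covs if c in X.columns and X[c].std() == 0]
    return X.drop(columns=empty_levels), y


# ---------------------------------------------------------------------------
# fitting


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    keep = A.std(axis=0) > 0
    if not keep.all():
        dropped = list(X.columns[~keep])
        raise FitError(f"constant (zero-variance) design columns: {dropped}")
    r = np.linalg.matrix_rank(A)
    if r < A.shape[1]:
        _, _, piv = sla.qr(A, pivoting=True, mode="economic")
        collinear = sorted(X.columns[piv[r:]])
        raise FitError(f"rank-deficient design; collinear columns: {collinear}")


def _wald_table(beta: pd.Series, se: pd.Series, n_exposed: dict | None = None) -> pd.DataFrame:
    from scipy import stats

    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    tab = pd.DataFrame({
        "beta": beta,
        "se": se,
        "or": np.exp(beta),
        "ci_low": np.exp(beta - 1.96 * se),
        "ci_high": np.exp(beta + 1.96 * se),
        "p": p,
    })
    tab["significant"] = tab["p"] < P_SIGNIFICANT
    return tab


def fit_proportional_odds(X: pd.DataFrame, y, maxiter: int = 500) -> OrdinalFitResult:
    """Maximum-likelihood cumulative-logit fit: P(Y <= j | x) = logistic(theta_j - x beta).

    Standard errors come from the observed information at the optimum.
    Raises :class:`FitError` on rank deficiency (naming the collinear
    columns), separation or non-convergence.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    cats = np.sort(y.unique())
    if len(cats) < 2:
        raise FitError("response has fewer than 2 observed categories")
    counts = y.value_counts().reindex(cats).to_numpy(dtype=float)
    ll_null = float(np.sum(counts * np.log(counts / counts.sum())))
    if X.shape[1] == 0:
        # intercept-only: thresholds are the logits of cumulative frequencies
        cum = np.cumsum(counts)[:-1] / counts.sum()
        theta = np.log(cum / (1.0 - cum))
        empty = pd.Series(dtype=float)
        return OrdinalFitResult(
            beta=empty, theta=theta, loglik=ll_null, loglik_null=ll_null,
            k=len(cats) - 1, n=len(y),
            table=pd.DataFrame(columns=["beta", "se", "or", "ci_low",
                                        "ci_high", "p", "significant"]),
            kind="ordinal",
        )
    _check_rank(X)
    if len(cats) == 2:
        # two-category cumulative logit == binary logistic on the indicator
        res = fit_binary_logistic(X, (y == cats[1]).astype(float), maxiter=maxiter)
        return OrdinalFitResult(res.beta, res.theta, res.loglik, res.loglik_null,
                                res.k, res.n, res.table, "ordinal")
    model = OrderedModel(y.to_numpy(), X.to_numpy(dtype=float), distr="logit")
    with np.errstate(all="ignore"):
        fit = model.fit(method="lbfgs", maxiter=maxiter, disp=0)
        if not fit.mle_retvals.get("converged", False):
            fit = model.fit(method="bfgs", maxiter=maxiter, disp=0)
    if not fit.mle_retvals.get("converged", False):
        raise FitError("proportional-odds fit did not converge "
                       f"(gradient norm {np.max(np.abs(fit.score(fit.params))):.3g})")
    p = X.shape[1]
    params = fit.params
    if np.any(np.abs(params[:p]) > 30):
        raise FitError("separation suspected: unbounded coefficient estimates")
    beta = pd.Series(params[:p], index=X.columns)
    theta = model.transform_threshold_params(params)[1:-1]
    with np.errstate(all="ignore"):
        se = pd.Series(np.asarray(fit.bse[:p], dtype=float), index=X.columns)
    k = p + (len(cats) - 1)
    return OrdinalFitResult(
        beta=beta, theta=np.asarray(theta, dtype=float),
        loglik=float(fit.llf), loglik_null=ll_null, k=k, n=len(y),
        table=_wald_table(beta, se), kind="ordinal",
    )


def fit_binary_logistic(X: pd.DataFrame, y, maxiter: int = 200) -> OrdinalFitResult:
    """Binary logistic regression with the same metric surface.

    The intercept is reported via ``theta`` (single threshold, sign chosen
    so P(event) = logistic(x beta - theta), mirroring the cumulative-logit
    parameterisation).
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    if y.nunique() < 2:
        raise FitError("binary response is single-valued")
    if len(X.columns):
        _check_rank(X)
    Xc = X.copy()
    Xc.insert(0, "const", 1.0)
    try:
        with np.errstate(all="ignore"):
            fit = Logit(y.to_numpy(), Xc.to_numpy(dtype=float)).fit(
                disp=0, maxiter=maxiter, method="newton"
            )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitError(f"binary logistic fit failed: {exc}") from exc
    params = np.asarray(fit.params, dtype=float)
    if np.any(np.abs(params) > 30):
        raise FitError("separation suspected: unbounded coefficient estimates")
    if not fit.mle_retvals.get("converged", False):
        raise FitError("binary logistic fit did not converge")
    beta = pd.Series(params[1:], index=X.columns)
    se = pd.Series(np.asarray(fit.bse[1:], dtype=float), index=X.columns)
    n1 = float(y.sum())
    n0 = float(len(y) - n1)
    ll_null = n1 * np.log(n1 / len(y)) + n0 * np.log(n0 / len(y))
    return OrdinalFitResult(
        beta=beta, theta=np.array([-params[0]]),
        loglik=float(fit.llf), loglik_null=float(ll_null),
        k=len(params), n=len(y), table=_wald_table(beta, se), kind="binary",
    )


def fit_model(df: pd.DataFrame, spec: ModelSpec) -> OrdinalFitResult:
    """Fit a :class:`ModelSpec` on the analysis frame."""
    X, y = design_matrix(df, spec)
    if len(X) == 0:
        raise FitError(f"empty stratum {spec.stratum!r}")
    if spec.response == "binary_event":
        return fit_binary_logistic(X, y)
    return fit_proportional_odds(X, y)


# ---------------------------------------------------------------------------
# reporting


def _n_exposed(sub: pd.DataFrame, feature: str, transform: str) -> int:
    v = sub[feature].to_numpy(dtype=float)
    return int(np.sum(v > 0))


def report_table2(df: pd.DataFrame, stratum: str,
                  exposures=TABLE2_EXPOSURES) -> pd.DataFrame:
    """Adjusted single-exposure models, one row per MRI variable.

    Each exposure is fit in its own adjusted model (stratum covariate
    preset + the exposure). Rows whose exposure is carried by fewer than 10
    patients are reported NA; zero-variance exposures are dropped with the
    same NA marker. ``significant`` flags p < 0.01.
    """
    mask = stratum_mask(df, stratum)
    if not mask.any():
        raise FitError(f"empty stratum {stratum!r}")
    sub = df[mask]
    rows = []
    for label, feature, transform in exposures:
        n_exp = _n_exposed(sub, feature, transform)
        row = {
            "variable": label,
            "n": n_exp,
            "pct": 100.0 * n_exp / len(sub),
            "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "p": np.nan, "significant": False, "suppressed": True,
        }
        if n_exp >= MIN_EXPOSURE_N:
            spec = ModelSpec(name=label, stratum=stratum,
                             exposures=[(feature, transform)])
            try:
                res = fit_model(df, spec)
            except FitError:
                rows.append(row)
                continue
            term = (f"log_{feature}" if transform == "log_volume_pair" else feature)
            t = res.table.loc[term]
            row.update(
                {"or": t["or"], "ci_low": t["ci_low"], "ci_high": t["ci_high"],
                 "p": t["p"], "significant": bool(t["significant"]),
                 "suppressed": False}
            )
        rows.append(row)
    return pd.DataFrame(rows)


def model_fit_table(df: pd.DataFrame, specs: list[ModelSpec]) -> pd.DataFrame:
    """Side-by-side fit metrics (k, pseudo-R², AIC, BIC) for several models.

    All models must resolve to the identical observation set (complete
    cases across the union of covariates) — differing n is an error, since
    AIC/BIC are only comparable on common data.
    """
    results, ns, obs_sets = [], [], []
    # comparability: restrict every model to the intersection of complete cases
    idx = None
    for spec in specs:
        X, y = design_matrix(df, spec)
        obs_sets.append(set(X.index))
        idx = set(X.index) if idx is None else idx
    common = set.intersection(*obs_sets) if obs_sets else set()
    for spec, obs in zip(specs, obs_sets):
        if obs != common:
            raise FitError(
                f"model {spec.name!r} resolves to a different observation set "
                f"(n={len(obs)} vs common n={len(common)}); align covariate "
                "completeness before comparing"
            )
    rows = []
    for spec in specs:
        res = fit_model(df, spec)
        rows.append({
            "model": spec.name, "n": res.n, "k": res.k,
            "loglik": res.loglik, "pseudo_r2": res.pseudo_r2,
            "aic": res.aic, "bic": res.bic,
        })
    out = pd.DataFrame(rows)
    out["best_aic"] = out["aic"] == out["aic"].min()
    out["best_bic"] = out["bic"] == out["bic"].min()
    return out
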