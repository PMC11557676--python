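"""Outcome construction: 6-month GOSE, EM imputation, dichotomisations.

The analysis outcome is the Glasgow Outcome Scale Extended (GOSE, 1-8) at
6 months. Patients assessed at 3 and 12 months instead get a weighted
6-month score by linear interpolation in time; remaining missing scores are
filled by a single deterministic expectation-maximisation (EM) imputation
under a joint-normal model of the outcome and a small covariate set. Models
use the *inverted* GOSE (9 - GOSE) so that higher response = worse outcome.

The exact weighting and EM variable set used in the source study are not
public; the defaults here (2/3-1/3 interpolation weights; EM over GOSE,
age, GCS, Marshall score, Trondheim grade and log FLAIR TAI volume) are
reconstructions, both configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "weighted_gose6",
    "dichotomize",
    "em_impute",
    "em_impute_gose",
    "construct_gose6",
    "invert_gose",
    "EMResult",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def weighted_gose6(gose3: int, gose12: int, weight3: float = 2.0 / 3.0) -> int:
    """6-month GOSE as the time-interpolated mean of 3- and 12-month scores.

    Six months sits a third of the way from 3 to 12 months, so the default
    weights are 2/3 on the 3-month and 1/3 on the 12-month score:
    (2*gose3 + gose12)/3, rounded half-up and clipped to [1, 8].
    """
    for name, v in (("gose3", gose3), ("gose12", gose12)):
        if not 1 <= v <= 8:
            raise ValueError(f"{name} must be in [1, 8], got {v}")
    val = weight3 * gose3 + (1.0 - weight3) * gose12
    return int(np.clip(_round_half_up(val), 1, 8))


def dichotomize(gose: int, scheme: str) -> bool:
    """Dichotomise a GOSE score; returns True for the adverse event.

    ``poor_vs_favourable``: poor outcome = GOSE <= 4 (favourable 5-8).
    ``disability_vs_good``: disability = GOSE <= 6 (good recovery 7-8).
    """
    if not 1 <= gose <= 8:
        raise ValueError(f"GOSE must be in [1, 8], got {gose}")
    if scheme == "poor_vs_favourable":
        return gose <= 4
    if scheme == "disability_vs_good":
        return gose <= 6
    raise ValueError(f"unknown dichotomisation scheme {scheme!r}")


def invert_gose(gose):
    """Model response: inverted GOSE (9 - GOSE), higher = worse outcome."""
    return 9 - np.asarray(gose, dtype=float)


@dataclass
class EMResult:
    data: pd.DataFrame          # completed matrix (original column order)
    n_imputed: int
    n_iter: int
    loglik: float
    loglik_trace: list


def em_impute(X: pd.DataFrame, tol: float = 1e-6, max_iter: int = 500) -> EMResult:
    """EM for a joint multivariate-normal model with missing entries.

    E-step: conditional expectations (and conditional covariances) of the
    missing coordinates given the observed ones; M-step: update mean and
    covariance from the completed sufficient statistics. Deterministic (no
    randomness); iterates until the observed-data log-likelihood increases
    by less than ``tol``. The log-likelihood is asserted non-decreasing at
    every iteration.
    """
    cols = list(X.columns)
    Z = X.to_numpy(dtype=float).copy()
    n, p = Z.shape
    miss = np.isnan(Z)
    if miss.all(axis=0).any():
        bad = [c for c, m in zip(cols, miss.all(axis=0)) if m]
        raise ValueError(f"columns entirely missing, cannot impute: {bad}")
    n_missing = int(miss.sum())
    # init: column means, sample covariance of mean-filled data
    mu = np.nanmean(Z, axis=0)
    Zf = np.where(miss, mu, Z)
    sigma = np.cov(Zf, rowvar=False, ddof=0) + 1e-6 * np.eye(p)

    def obs_loglik(mu, sigma):
        ll = 0.0
        for i in range(n):
            o = ~miss[i]
            if not o.any():
                continue
            d = Z[i, o] - mu[o]
            S = sigma[np.ix_(o, o)]
            sign, logdet = np.linalg.slogdet(S)
            ll += -0.5 * (o.sum() * np.log(2 * np.pi) + logdet
                          + d @ np.linalg.solve(S, d))
        return ll

    trace = [obs_loglik(mu, sigma)]
    it = 0
    if n_missing:
        for it in range(1, max_iter + 1):
            # E-step
            Zhat = Z.copy()
            C = np.zeros((p, p))
            for i in range(n):
                m = miss[i]
                if not m.any():
                    continue
                o = ~m
                Soo = sigma[np.ix_(o, o)]
                Smo = sigma[np.ix_(m, o)]
                W = np.linalg.solve(Soo, Smo.T).T
                Zhat[i, m] = mu[m] + W @ (Z[i, o] - mu[o])
                C[np.ix_(m, m)] += sigma[np.ix_(m, m)] - W @ Smo.T
            # M-step
            mu = Zhat.mean(axis=0)
            dev = Zhat - mu
            sigma = (dev.T @ dev + C) / n + 1e-9 * np.eye(p)
            ll = obs_loglik(mu, sigma)
            # slack covers ridge-floor round-off at singular covariances
            assert ll >= trace[-1] - 1e-6 * max(1.0, abs(trace[-1])), (
                f"EM log-likelihood decreased at iteration {it}: "
                f"{trace[-1]} -> {ll}"
            )
            done = ll - trace[-1] < tol
            trace.append(ll)
            if done:
                break
        else:
            raise RuntimeError(
                f"EM did not converge in {max_iter} iterations; "
                f"log-likelihood trace tail {trace[-5:]}"
            )
        Z = np.where(miss, Zhat, Z)
    out = pd.DataFrame(Z, index=X.index, columns=cols)
    return EMResult(out, n_missing, it, trace[-1], trace)


def em_impute_gose(covariates: pd.DataFrame, gose6: pd.Series,
                   tol: float = 1e-6, max_iter: int = 500):
    """Impute missing 6-month GOSE from a completed covariate matrix.

    Missingness must be confined to ``gose6``; covariates with missing
    entries are mean-filled first. Imputed GOSE values are rounded half-up
    and clipped to [1, 8]. Returns (completed gose6 series, EMResult).
    """
    cov = covariates.astype(float)
    cov = cov.fillna(cov.mean())
    X = pd.concat([gose6.rename("gose6").astype(float), cov], axis=1)
    res = em_impute(X, tol=tol, max_iter=max_iter)
    filled = res.data["gose6"]
    completed = pd.Series(
        np.clip(np.floor(filled + 0.5), 1, 8).astype(int),
        index=gose6.index,
        name="gose6",
    )
    # observed values pass through untouched
    obs = gose6.notna()
    completed[obs] = gose6[obs].astype(int)
    return completed, res


def construct_gose6(outcomes: pd.DataFrame,
                    covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build the analysis outcome table from raw 3/6/12-month GOSE columns.

    Priority per patient: observed 6-month score; else weighted mean of the
    3- and 12-month scores when both exist; else EM imputation (requires
    ``covariates``). Returns a frame with ``gose6`` and ``gose6_source``
    (observed / weighted / imputed), indexed by patient_id.
    """
    df = outcomes.set_index("patient_id") if "patient_id" in outcomes else outcomes.copy()
    gose6 = pd.Series(np.nan, index=df.index, dtype=float)
    source = pd.Series("missing", index=df.index, dtype="object")

    obs = df["gose6"].notna()
    gose6[obs] = df.loc[obs, "gose6"].astype(float)
    source[obs] = "observed"

    both = ~obs & df["gose3"].notna() & df["gose12"].notna()
    for pid in df.index[both]:
        gose6[pid] = weighted_gose6(int(df.at[pid, "gose3"]), int(df.at[pid, "gose12"]))
    source[both] = "weighted"

    todo = gose6.isna()
    if todo.any():
        if covariates is None:
            raise ValueError(
                f"{int(todo.sum())} patients lack a 6-month GOSE and no "
                "covariates were supplied for EM imputation"
            )
        completed, _ = em_impute_gose(covariates.reindex(gose6.index), gose6)
        gose6[todo] = completed[todo].astype(float)
        source[todo] = "imputed"

    out = pd.DataFrame({"gose6": gose6.astype(int), "gose6_source": source})
    out["response_ordinal"] = invert_gose(out["gose6"]).astype(int)
    return out
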