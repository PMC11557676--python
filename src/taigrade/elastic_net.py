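"""Proportional-odds ordinal regression with an elastic-net penalty.

Minimises the negative mean cumulative-logit log-likelihood plus
``lambda * (alpha * sum|beta_j| + (1 - alpha)/2 * sum beta_j^2)`` over the
*penalised* columns only; the adjustment covariates (age, GCS, pupils and
the Marshall CT score) are never penalised. Solved by proximal gradient
descent with backtracking line search: the ridge part joins the smooth
term, the l1 part is handled by soft-thresholding, so penalised
coefficients can reach exact zeros.

Tuning (lambda, alpha) is selected by stratified 5-fold cross-validation
maximising out-of-fold log-likelihood over a 50-point log-spaced lambda
path per alpha (warm-started, descending), ties broken toward the sparser
(larger) lambda. Coefficient stability is assessed by refitting on
case-bootstrap resamples at the selected tuning and reporting the
percentage of resamples in which each penalised variable kept a nonzero
coefficient; unpenalised variables report 100% by construction.

Penalised columns are standardised internally to mean 0 / SD 1 using
full-sample statistics (reused unchanged in bootstrap refits);
coefficients are reported on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ElasticNetConfig",
    "PenalizedFit",
    "StabilityResult",
    "penalized_objective",
    "fit_penalized",
    "lambda_path",
    "select_tuning",
    "bootstrap_inclusion",
    "CLINICAL_VARIABLES",
    "QUANTITATIVE_VARIABLES",
    "elastic_net_frame",
]

#: TAI presence/laterality variables (the "clinical" penalised set).
CLINICAL_VARIABLES = [
    "tai_hemispheric",
    "tai_cerebellum",
    "tai_corpus_callosum",
    "tai_internal_capsule_pl_uni",
    "tai_internal_capsule_pl_bil",
    "tai_basal_ganglia_uni",
    "tai_basal_ganglia_bil",
    "tai_thalamus_uni",
    "tai_thalamus_bil",
    "tai_brainstem_uni",
    "tai_brainstem_bil",
    "contusion_on_mri",
]

#: The "quantitative" set adds TAI number and volume variables.
QUANTITATIVE_VARIABLES = CLINICAL_VARIABLES + [
    "n_tai_flair",
    "n_tai_dwi",
    "n_tai_t2gre_swi",
    "vol_tai_flair_cm3",
    "vol_tai_dwi_cm3",
    "vol_contusion_flair_cm3",
]

UNPENALIZED_COVARIATES = [
    "age", "gcs", "pupil_uni", "pupil_bil",
    "marshall_2", "marshall_34", "marshall_56",
]


@dataclass
class ElasticNetConfig:
    """Penalty strength/mixing plus resampling settings.

    ``alpha`` = 1 is the lasso limit, 0 the ridge limit. The unpenalised
    set must contain the Marshall term(s) whenever present in the design —
    the Marshall CT score is always kept in the model.
    """

    lam: float = 0.0
    alpha: float = 1.0
    penalized: list = field(default_factory=list)
    unpenalized: list = field(default_factory=list)
    cv_folds: int = 5
    n_bootstrap: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        marshall_pen = [c for c in self.penalized if str(c).startswith("marshall")]
        if marshall_pen:
            raise ValueError(
                f"the Marshall CT term must stay unpenalised, got {marshall_pen} "
                "in the penalised set"
            )


# ---------------------------------------------------------------------------
# likelihood machinery (category codes 0..K-1; thresholds via theta_1 and
# log-increments so ordering is maintained throughout optimisation)


def _theta_from_a(a: np.ndarray) -> np.ndarray:
    th = np.empty_like(a)
    th[0] = a[0]
    if len(a) > 1:
        th[1:] = a[0] + np.cumsum(np.exp(a[1:]))
    return th


def _a_from_theta(theta: np.ndarray) -> np.ndarray:
    a = np.empty_like(theta)
    a[0] = theta[0]
    if len(theta) > 1:
        a[1:] = np.log(np.diff(theta))
    return a


def _sigmoid(u):
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    e = np.exp(u[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _nll_and_grads(beta, a, X, y, need_grad=True):
    """Mean negative log-likelihood and gradients wrt (beta, a)."""
    n = len(y)
    K1 = len(a)
    theta = _theta_from_a(a)
    eta = X @ beta
    pad = np.full(n, np.inf)
    u_hi = np.where(y < K1, theta[np.minimum(y, K1 - 1)] - eta, pad)
    u_lo = np.where(y > 0, theta[np.maximum(y - 1, 0)] - eta, -pad)
    F_hi = np.where(np.isinf(u_hi), 1.0, _sigmoid(u_hi))
    F_lo = np.where(np.isinf(u_lo), 0.0, _sigmoid(u_lo))
    P = np.clip(F_hi - F_lo, 1e-300, None)
    nll = -np.mean(np.log(P))
    if not need_grad:
        return nll, None, None
    f_hi = np.where(np.isinf(u_hi), 0.0, F_hi * (1.0 - F_hi))
    f_lo = np.where(np.isinf(u_lo), 0.0, F_lo * (1.0 - F_lo))
    # d(-ll_i)/d eta and d(-ll_i)/d theta_j
    g_eta = (f_hi - f_lo) / P
    grad_beta = X.T @ g_eta / n
    g_theta = np.zeros(K1)
    w_hi = -f_hi / P
    w_lo = f_lo / P
    hi_idx = np.minimum(y, K1 - 1)
    lo_idx = np.maximum(y - 1, 0)
    np.add.at(g_theta, hi_idx[y < K1], w_hi[y < K1])
    np.add.at(g_theta, lo_idx[y > 0], w_lo[y > 0])
    g_theta /= n
    # chain rule to a: theta_m = a_1 + sum_{j<=m, j>=2} exp(a_j)
    grad_a = np.empty(K1)
    grad_a[0] = g_theta.sum()
    if K1 > 1:
        rev_cum = np.cumsum(g_theta[::-1])[::-1]
        grad_a[1:] = np.exp(a[1:]) * rev_cum[1:]
    return nll, grad_beta, grad_a


def penalized_objective(beta, theta, X, y, pen_mask, lam, alpha):
    """Objective value: mean NLL + elastic-net penalty on penalised betas."""
    beta = np.asarray(beta, dtype=float)
    a = _a_from_theta(np.asarray(theta, dtype=float))
    nll, _, _ = _nll_and_grads(beta, a, np.asarray(X, float),
                               np.asarray(y, int), need_grad=False)
    bp = beta[np.asarray(pen_mask, bool)]
    pen = lam * (alpha * np.abs(bp).sum() + 0.5 * (1.0 - alpha) * (bp ** 2).sum())
    return nll + pen


@dataclass
class PenalizedFit:
    beta: pd.Series            # original-scale coefficients
    theta: np.ndarray          # original-scale thresholds
    beta_std: np.ndarray       # standardised-scale coefficients (exact zeros)
    a: np.ndarray              # threshold parameters (standardised scale)
    lam: float
    alpha: float
    pen_mask: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    objective: float
    objective_trace: list
    n_iter: int
    converged: bool
    categories: np.ndarray

    @property
    def nonzero_penalized(self) -> np.ndarray:
        return (self.beta_std != 0) & self.pen_mask

    def max_kkt_violation(self, X: pd.DataFrame, y) -> float:
        """Largest subgradient-optimality violation at the solution.

        For zeroed penalised columns |d(smooth)/d beta_j| must not exceed
        lambda*alpha; for active columns the subgradient must vanish.
        """
        Xs, codes = _standardize_codes(X, y, self.mu, self.sd, self.categories)
        nll, gb, ga = _nll_and_grads(self.beta_std, self.a, Xs, codes)
        gb = gb + self.lam * (1.0 - self.alpha) * self.beta_std * self.pen_mask
        viol = [np.max(np.abs(ga))] if len(ga) else [0.0]
        thr = self.lam * self.alpha
        for j in range(len(gb)):
            if self.pen_mask[j]:
                if self.beta_std[j] == 0:
                    viol.append(max(0.0, abs(gb[j]) - thr))
                else:
                    viol.append(abs(gb[j] + thr * np.sign(self.beta_std[j])))
            else:
                viol.append(abs(gb[j]))
        return float(np.max(viol))


def _standardize_codes(X, y, mu, sd, categories):
    Xs = (np.asarray(X, dtype=float) - mu) / sd
    codes = np.searchsorted(categories, np.asarray(y, dtype=float))
    return Xs, codes


def _solve(Xs, codes, K, pen_mask, lam, alpha, beta0, a0,
           tol=1e-7, max_iter=20000, kkt_tol=1e-7):
    """Monotone FISTA (accelerated proximal gradient with backtracking).

    The momentum step is only accepted when it lowers the objective, so the
    recorded objective trace is non-increasing (asserted). Terminates when
    either the parameter step falls below ``tol`` or the subgradient (KKT)
    violation falls below ``kkt_tol``.
    """
    thr = lam * alpha

    def smooth(beta, a):
        nll, gb, ga = _nll_and_grads(beta, a, Xs, codes)
        ridge = 0.5 * lam * (1.0 - alpha) * np.sum((beta * pen_mask) ** 2)
        gb = gb + lam * (1.0 - alpha) * beta * pen_mask
        return nll + ridge, gb, ga

    def l1(beta):
        return thr * np.abs(beta[pen_mask]).sum()

    def prox_step(beta, a, f, gb, ga, t):
        """Backtracked proximal step from (beta, a); returns new state."""
        while True:
            nb = beta - t * gb
            shrink = np.maximum(np.abs(nb[pen_mask]) - t * thr, 0.0)
            nb[pen_mask] = np.sign(nb[pen_mask]) * shrink
            na = a - t * ga
            fn, gbn, gan = smooth(nb, na)
            db, da = nb - beta, na - a
            quad = f + gb @ db + ga @ da + (db @ db + da @ da) / (2.0 * t)
            if fn <= quad + 1e-12 or t < 1e-14:
                return nb, na, fn, gbn, gan, t
            t *= 0.5

    def kkt_violation(beta, gb, ga):
        v = np.max(np.abs(ga)) if len(ga) else 0.0
        zero = pen_mask & (beta == 0)
        act = pen_mask & (beta != 0)
        if zero.any():
            v = max(v, float(np.max(np.maximum(np.abs(gb[zero]) - thr, 0.0))))
        if act.any():
            v = max(v, float(np.max(np.abs(gb[act] + thr * np.sign(beta[act])))))
        if (~pen_mask).any():
            v = max(v, float(np.max(np.abs(gb[~pen_mask]))))
        return v

    beta, a = beta0.copy(), a0.copy()
    f, gb, ga = smooth(beta, a)
    trace = [f + l1(beta)]
    yb, ya = beta.copy(), a.copy()   # extrapolated point
    tk = 1.0
    t = 1.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        fy, gby, gay = smooth(yb, ya)
        nb, na, fn, gbn, gan, t = prox_step(yb, ya, fy, gby, gay, t)
        if fn + l1(nb) > trace[-1] + 1e-12:
            # momentum overshot: restart from the last accepted point
            tk = 1.0
            nb, na, fn, gbn, gan, t = prox_step(beta, a, f, gb, ga, t)
        step = max(np.max(np.abs(nb - beta)),
                   np.max(np.abs(na - a)) if len(a) else 0.0)
        tk_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        mom = (tk - 1.0) / tk_next
        yb = nb + mom * (nb - beta)
        ya = na + mom * (na - a)
        tk = tk_next
        beta, a, f, gb, ga = nb, na, fn, gbn, gan
        obj = f + l1(beta)
        assert obj <= trace[-1] + 1e-10, "objective increased during descent"
        trace.append(obj)
        if step < tol or kkt_violation(beta, gb, ga) < kkt_tol:
            converged = True
            break
        t = min(t * 1.3, 10.0)
    if not converged:
        raise RuntimeError(
            f"penalised fit did not converge in {max_iter} iterations; "
            f"objective tail {trace[-3:]}"
        )
    return beta, a, trace, n_iter


def _prep(X: pd.DataFrame, y, penalized, mu=None, sd=None, categories=None):
    cols = list(X.columns)
    pen_mask = np.array([c in set(penalized) for c in cols])
    A = X.to_numpy(dtype=float)
    if mu is None:
        mu = A.mean(axis=0)
        sd = A.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    if categories is None:
        categories = np.sort(np.unique(np.asarray(y, dtype=float)))
    return cols, pen_mask, mu, sd, categories


def fit_penalized(X: pd.DataFrame, y, penalized, lam, alpha,
                  mu=None, sd=None, categories=None, warm=None,
                  tol=1e-7, max_iter=20000) -> PenalizedFit:
    """Fit the penalised proportional-odds model at fixed (lambda, alpha).

    ``penalized`` lists the design columns subject to the penalty; the rest
    (and the thresholds) are unpenalised. ``mu``/``sd`` override the
    standardisation statistics (used by bootstrap refits so resamples share
    the full-sample scaling). ``warm`` is an optional (beta_std, a) start.
    """
    cols, pen_mask, mu, sd, categories = _prep(X, y, penalized, mu, sd, categories)
    Xs, codes = _standardize_codes(X, y, mu, sd, categories)
    K = len(categories)
    if K < 2:
        raise ValueError("response must have at least 2 observed categories")
    if warm is not None:
        beta0, a0 = warm[0].copy(), warm[1].copy()
    else:
        beta0 = np.zeros(len(cols))
        freq = np.bincount(codes, minlength=K) + 0.5
        cum = np.cumsum(freq)[:-1] / freq.sum()
        a0 = _a_from_theta(np.log(cum / (1.0 - cum)))
    beta, a, trace, n_iter = _solve(Xs, codes, K, pen_mask, lam, alpha,
                                    beta0, a0, tol=tol, max_iter=max_iter)
    theta_std = _theta_from_a(a)
    beta_orig = beta / sd
    theta_orig = theta_std + float(np.sum(beta * mu / sd))
    return PenalizedFit(
        beta=pd.Series(beta_orig, index=cols), theta=theta_orig,
        beta_std=beta, a=a, lam=float(lam), alpha=float(alpha),
        pen_mask=pen_mask, mu=mu, sd=sd,
        objective=trace[-1], objective_trace=trace, n_iter=n_iter,
        converged=True, categories=categories,
    )


def _oof_loglik(fit: PenalizedFit, X: pd.DataFrame, y) -> float:
    Xs, codes = _standardize_codes(X, y, fit.mu, fit.sd, fit.categories)
    nll, _, _ = _nll_and_grads(fit.beta_std, fit.a, Xs, codes, need_grad=False)
    return -nll * len(codes)


def lambda_path(X: pd.DataFrame, y, penalized, alpha,
                n_lambda=50, ratio=1e-3, mu=None, sd=None) -> np.ndarray:
    """Log-spaced lambda path from lambda_max down to ratio*lambda_max.

    lambda_max is the smallest penalty that zeroes every penalised
    coefficient: the largest score-gradient magnitude over penalised
    columns at the solution with the penalised set held at zero, divided
    by alpha (floored at 0.01 so the ridge limit keeps a finite path).
    """
    cols, pen_mask, mu, sd, categories = _prep(X, y, penalized, mu, sd)
    Xs, codes = _standardize_codes(X, y, mu, sd, categories)
    # solve with penalised block forced to zero: infinite l1 on that block
    beta0 = np.zeros(len(cols))
    freq = np.bincount(codes, minlength=len(categories)) + 0.5
    cum = np.cumsum(freq)[:-1] / freq.sum()
    a0 = _a_from_theta(np.log(cum / (1.0 - cum)))
    beta, a, _, _ = _solve(Xs, codes, len(categories), pen_mask, 1e12, 1.0,
                           beta0, a0, tol=1e-8)
    _, gb, _ = _nll_and_grads(beta, a, Xs, codes)
    gmax = float(np.max(np.abs(gb[pen_mask]))) if pen_mask.any() else 1.0
    # 2% headroom so the top of the path is strictly in the all-zero region
    lam_max = 1.02 * gmax / max(alpha, 0.01)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


@dataclass
class TuningResult:
    lam: float
    alpha: float
    cv_table: pd.DataFrame   # columns: alpha, lam, oof_loglik


def select_tuning(X: pd.DataFrame, y, penalized,
                  alphas=(0.1, 0.25, 0.5, 0.75, 1.0),
                  n_lambda=50, folds=5, seed=0) -> TuningResult:
    """Pick (lambda, alpha) by stratified K-fold out-of-fold log-likelihood.

    Folds are stratified by response category and seeded. Ties are broken
    toward the larger lambda (the sparser model), then larger alpha.
    """
    y = np.asarray(y, dtype=float)
    cols, pen_mask, mu, sd, categories = _prep(X, y, penalized)
    counts = pd.Series(y).value_counts()
    n_splits = min(folds, int(counts.min())) if counts.min() < folds else folds
    if n_splits < 2:
        raise ValueError("response categories too sparse for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    records = []
    for alpha in alphas:
        lams = lambda_path(X, y, penalized, alpha, n_lambda=n_lambda, mu=mu, sd=sd)
        oof = np.zeros(len(lams))
        for tr, te in splits:
            Xtr, ytr = X.iloc[tr], y[tr]
            Xte, yte = X.iloc[te], y[te]
            warm = None
            for i, lam in enumerate(lams):
                fit = fit_penalized(Xtr, ytr, penalized, lam, alpha,
                                    mu=mu, sd=sd, categories=categories, warm=warm)
                warm = (fit.beta_std, fit.a)
                oof[i] += _oof_loglik(fit, Xte, yte)
        for lam, ll in zip(lams, oof):
            records.append({"alpha": alpha, "lam": lam, "oof_loglik": ll})
    tab = pd.DataFrame(records)
    best_ll = tab["oof_loglik"].max()
    near = tab[tab["oof_loglik"] >= best_ll - 1e-9]
    best = near.sort_values(["lam", "alpha"], ascending=False).iloc[0]
    return TuningResult(lam=float(best["lam"]), alpha=float(best["alpha"]), cv_table=tab)


@dataclass
class StabilityResult:
    inclusion: pd.DataFrame    # index=variable; pct_included, sign, penalized
    lam: float
    alpha: float
    n_bootstrap: int
    n_redrawn: int
    seed: int


def bootstrap_inclusion(X: pd.DataFrame, y, penalized, lam, alpha,
                        n_bootstrap=500, seed=0) -> StabilityResult:
    """Bootstrap inclusion percentages at fixed tuning.

    Case-resamples with replacement, refits, and records for each penalised
    variable the share of resamples where its coefficient stayed nonzero.
    Tuning is held fixed across refits (selected once on the full sample).
    Resamples with fewer than 2 observed response categories are redrawn
    (counted). Unpenalised variables are reported at 100%.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    cols, pen_mask, mu, sd, categories = _prep(X, y, penalized)
    full = fit_penalized(X, y, penalized, lam, alpha, mu=mu, sd=sd,
                         categories=categories)
    warm = (full.beta_std, full.a)
    n = len(y)
    included = np.zeros(len(cols))
    coef_sum = np.zeros(len(cols))
    n_redrawn = 0
    b = 0
    while b < n_bootstrap:
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if len(np.unique(yb)) < 2:
            n_redrawn += 1
            continue
        fit = fit_penalized(X.iloc[idx], yb, penalized, lam, alpha,
                            mu=mu, sd=sd, categories=categories,
                            warm=warm, tol=1e-6)
        nz = fit.beta_std != 0
        included += nz
        coef_sum += fit.beta_std
        b += 1
    pct = np.where(pen_mask, 100.0 * included / n_bootstrap, 100.0)
    sign = np.sign(coef_sum)
    tab = pd.DataFrame(
        {"pct_included": pct, "sign": sign, "penalized": pen_mask}, index=cols
    )
    return StabilityResult(inclusion=tab, lam=float(lam), alpha=float(alpha),
                           n_bootstrap=n_bootstrap, n_redrawn=n_redrawn, seed=seed)


def elastic_net_frame(df: pd.DataFrame, model: str = "clinical",
                      stratum_mask=None):
    """Design (X, y, penalised columns) for the packaged elastic-net models.

    ``clinical`` uses TAI presence/laterality variables; ``quantitative``
    adds number and volume variables. Core covariates and the Marshall
    score are unpenalised. Response: inverted GOSE.
    """
    if model == "clinical":
        pen = [v for v in CLINICAL_VARIABLES if v in df.columns]
    elif model == "quantitative":
        pen = [v for v in QUANTITATIVE_VARIABLES if v in df.columns]
    else:
        raise ValueError(f"unknown elastic-net model {model!r}")
    sub = df if stratum_mask is None else df[stratum_mask]
    cols = UNPENALIZED_COVARIATES + pen
    X = sub[cols].astype(float)
    y = sub["response_ordinal"]
    ok = X.notna().all(axis=1) & y.notna()
    return X[ok], y[ok].astype(float), pen
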