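"""Model comparison: cross-validated AUC and an ordered trend test.

Prognostic models are compared by the area under the ROC curve for
predicting the dichotomised outcome (poor outcome, GOSE <= 4, in severe
TBI; disability, GOSE <= 6, in moderate TBI), computed over pooled
out-of-fold predictions from a stratified 10-fold cross-validation and
accompanied by a percentile bootstrap 95% CI over the pooled
(prediction, label) pairs. Monotone decreasing trends of lesion burden
across ordered GOSE groups are tested with the Jonckheere-Terpstra
statistic (normal approximation with tie correction; exact permutation
null for small samples).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .grading import apply_grading, load_ruleset
from .regression import (
    FitError,
    ModelSpec,
    design_matrix,
    fit_binary_logistic,
    fit_model,
    fit_proportional_odds,
    stratum_mask,
)

__all__ = [
    "auc_rank",
    "CVResult",
    "cv_auc",
    "comparison_table",
    "jonckheere_terpstra",
    "JTResult",
]

#: Event definitions on the inverted-GOSE scale: event iff response >= cut.
EVENT_CUTS = {"poor_vs_favourable": 5, "disability_vs_good": 3}


def auc_rank(predictions, labels) -> float:
    """AUC by the rank (Mann-Whitney) statistic with average-rank ties.

    Equals the all-pairs proportion of concordant (prediction, label)
    pairs, ties counted 1/2.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class CVResult:
    mean_auc: float
    ci_low: float
    ci_high: float
    event_scheme: str
    n: int
    n_events: int
    folds: int
    seed: int
    predictions: pd.Series   # pooled out-of-fold P(event), index = patient_id
    labels: pd.Series


def _predict_event_ordinal(res, X: pd.DataFrame, train_categories, cut) -> np.ndarray:
    """P(inverted response >= cut | x) from a fitted cumulative-logit model."""
    eta = X.to_numpy(dtype=float) @ res.beta.to_numpy()
    m = int(np.sum(np.asarray(train_categories) < cut))
    if m == 0:
        return np.ones(len(X))
    if m >= len(train_categories):
        return np.zeros(len(X))
    u = res.theta[m - 1] - eta
    return 1.0 - 1.0 / (1.0 + np.exp(-u))


def cv_auc(df: pd.DataFrame, spec: ModelSpec, event_scheme: str,
           folds: int = 10, seed: int = 0, n_boot: int = 2000,
           pooled: bool = True) -> CVResult:
    """Cross-validated AUC for predicting the dichotomised outcome.

    Stratified fold split on the event label; the model is refit on each
    training set and the held-out patients receive the model-implied event
    probability (ordinal models: the cumulative probability of the event
    categories; binary models: the fitted probability). AUC is computed on
    the pooled out-of-fold pairs (``pooled=False`` averages per-fold AUCs
    instead) and the CI by case-bootstrap of those pairs (percentile,
    ``n_boot`` resamples, no refitting).
    """
    if event_scheme not in EVENT_CUTS:
        raise ValueError(f"unknown event scheme {event_scheme!r}")
    X, y = design_matrix(df, spec)
    if spec.response == "binary_event":
        event = y.astype(int)
    else:
        event = (y >= EVENT_CUTS[event_scheme]).astype(int)
    n_events = int(event.sum())
    n_non = len(event) - n_events
    if n_events < 10 or n_non < 10:
        raise FitError(
            f"cv_auc needs >= 10 events and >= 10 non-events in stratum "
            f"{spec.stratum!r} (got {n_events} / {n_non}); analysis not performed"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = pd.Series(np.nan, index=X.index, dtype=float)
    fold_aucs = []
    for tr, te in skf.split(np.zeros(len(X)), event):
        Xtr, Xte = X.iloc[tr], X.iloc[te]
        if spec.response == "binary_event":
            res = fit_binary_logistic(Xtr, y.iloc[tr])
            eta = Xte.to_numpy(dtype=float) @ res.beta.to_numpy() - res.theta[0]
            p = 1.0 / (1.0 + np.exp(-eta))
        else:
            ytr = y.iloc[tr]
            res = fit_proportional_odds(Xtr, ytr)
            cats = np.sort(ytr.unique())
            if len(cats) == 2:
                # degenerate training fold: binary surrogate on the indicator
                eta = Xte.to_numpy(dtype=float) @ res.beta.to_numpy() - res.theta[0]
                p_hi = 1.0 / (1.0 + np.exp(-eta))
                cut = EVENT_CUTS[event_scheme]
                p = p_hi if cats[1] >= cut else np.zeros(len(Xte))
            else:
                p = _predict_event_ordinal(res, Xte, cats, EVENT_CUTS[event_scheme])
        preds.iloc[te] = p
        ev_te = event.iloc[te]
        if ev_te.nunique() == 2:
            fold_aucs.append(auc_rank(p, ev_te))
    mean_auc = (auc_rank(preds, event) if pooled
                else float(np.mean(fold_aucs)))
    rng = np.random.default_rng(seed)
    boots = []
    pv, ev = preds.to_numpy(), event.to_numpy()
    while len(boots) < n_boot:
        idx = rng.integers(0, len(pv), len(pv))
        if ev[idx].min() == ev[idx].max():
            continue
        boots.append(auc_rank(pv[idx], ev[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CVResult(mean_auc=mean_auc, ci_low=float(lo), ci_high=float(hi),
                    event_scheme=event_scheme, n=len(event), n_events=n_events,
                    folds=folds, seed=seed, predictions=preds, labels=event)


#: (model label, exposure builder) rows of the comparison table, in order.
GRADING_MODELS = ["standard", "stockholm", "gcs_based", "trondheim"]


def comparison_table(df: pd.DataFrame, stratum: str, folds: int = 10,
                     seed: int = 0, n_boot: int = 2000,
                     gradings=GRADING_MODELS) -> pd.DataFrame:
    """Table of adjusted models: baseline, the four gradings, volumetric.

    Each grading enters as a single integer-scored covariate added to the
    stratum's baseline covariates; the volumetric rows use the
    (presence, ln volume) transform. Reports pseudo-R², AIC, BIC and the
    cross-validated AUC with bootstrap CI (poor outcome for severe TBI,
    disability for moderate).
    """
    df = df.copy()
    for name in gradings:
        rs = load_ruleset(name)
        df[f"grade_{name}"] = [
            apply_grading(row, rs) for _, row in df.iterrows()
        ]
    scheme = "poor_vs_favourable" if stratum == "severe" else "disability_vs_good"
    models = [("baseline", [])]
    models += [(f"grading_{g}", [(f"grade_{g}", "identity")]) for g in gradings]
    models += [
        ("tai_flair_volume", [("vol_tai_flair_cm3", "log_volume_pair")]),
        ("tbi_flair_volume", [("vol_tai_flair_cm3", "log_volume_pair"),
                              ("vol_contusion_flair_cm3", "log_volume_pair")]),
        ("contusion_volume", [("vol_contusion_flair_cm3", "log_volume_pair")]),
    ]
    rows = []
    n_ref = None
    for name, exposures in models:
        spec = ModelSpec(name=name, stratum=stratum, exposures=exposures)
        res = fit_model(df, spec)
        if n_ref is None:
            n_ref = res.n
        elif res.n != n_ref:
            raise FitError(
                f"model {name!r} fits n={res.n}, expected n={n_ref}: models "
                "must share the observation set"
            )
        row = {"model": name, "n": res.n, "k": res.k,
               "pseudo_r2": res.pseudo_r2, "aic": res.aic, "bic": res.bic}
        try:
            cv = cv_auc(df, spec, scheme, folds=folds, seed=seed, n_boot=n_boot)
            row.update({"mean_auc": cv.mean_auc, "auc_ci_low": cv.ci_low,
                        "auc_ci_high": cv.ci_high})
        except FitError:
            row.update({"mean_auc": np.nan, "auc_ci_low": np.nan,
                        "auc_ci_high": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra


@dataclass
class JTResult:
    statistic: float
    z: float | None
    p_value: float
    alternative: str
    method: str   # "normal" | "exact"


def _jt_statistic(groups) -> float:
    t = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            less = np.sum(a[:, None] < b[None, :])
            ties = np.sum(a[:, None] == b[None, :])
            t += less + 0.5 * ties
    return float(t)


def jonckheere_terpstra(groups, alternative: str = "increasing",
                        exact_max_n: int = 12) -> JTResult:
    """Jonckheere-Terpstra test for an ordered trend across groups.

    ``groups`` is a sequence of value arrays ordered by the grouping
    variable (e.g. GOSE category). ``alternative='increasing'`` tests for
    values increasing along the group order, ``'decreasing'`` the reverse.
    Total n <= ``exact_max_n`` uses the exact permutation null; larger
    samples the tie-corrected normal approximation.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty ordered groups")
    if alternative == "decreasing":
        res = jonckheere_terpstra(groups[::-1], "increasing", exact_max_n)
        return JTResult(res.statistic, res.z, res.p_value, "decreasing", res.method)
    if alternative != "increasing":
        raise ValueError(f"unknown alternative {alternative!r}")

    t_obs = _jt_statistic(groups)
    sizes = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n = len(pooled)

    if n <= exact_max_n:
        # exact permutation null: all distinct assignments of the pooled
        # values to groups of the given sizes
        count = 0
        total = 0
        idx_all = list(range(n))

        def assignments(remaining, k):
            if k == len(sizes) - 1:
                yield [remaining]
                return
            for chosen in itertools.combinations(remaining, sizes[k]):
                rest = [i for i in remaining if i not in set(chosen)]
                for tail in assignments(rest, k + 1):
                    yield [list(chosen)] + tail

        for assign in assignments(idx_all, 0):
            gs = [pooled[ix] for ix in assign]
            if _jt_statistic(gs) >= t_obs - 1e-12:
                count += 1
            total += 1
        return JTResult(t_obs, None, count / total, "increasing", "exact")

    mean = (n * n - np.sum(sizes ** 2)) / 4.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    t1 = np.sum(sizes * (sizes - 1) * (2 * sizes + 5))
    t2 = np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))
    a = n * (n - 1) * (2 * n + 5) - t1 - t2
    b = (np.sum(sizes * (sizes - 1) * (sizes - 2))
         * np.sum(tie_counts * (tie_counts - 1) * (tie_counts - 2)))
    c = (np.sum(sizes * (sizes - 1)) * np.sum(tie_counts * (tie_counts - 1)))
    var = a / 72.0 + b / (36.0 * n * (n - 1) * (n - 2)) + c / (8.0 * n * (n - 1))
    if var <= 0:
        return JTResult(t_obs, 0.0, 1.0, "increasing", "normal")
    # continuity correction: the statistic lives on a half-integer lattice
    z = (t_obs - mean - 0.5) / np.sqrt(var)
    return JTResult(t_obs, float(z), float(stats.norm.sf(z)), "increasing", "normal")
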