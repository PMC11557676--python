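"""Region-level TAI features and rule-based anatomical grading.

A patient's lesion annotations are reduced to per-region presence and
laterality flags plus volume/count totals (:func:`extract_features`), and a
grading rule set — an ordered table of (grade, predicate) pairs over those
flags — assigns the final grade as the highest satisfied rule
(:func:`apply_grading`).

Four rule sets ship as editable YAML data files: ``trondheim`` (grades 0-5,
5 = bilateral pontine TAI, 4 = bilateral mesencephalic or thalamic TAI),
``standard`` (Gentry/Adams, grades 0-3), and approximate reconstructions of
the ``stockholm`` and ``gcs_based`` gradings.

Laterality semantics: a region group is *bilateral* when lesions are present
on both the left and the right entries of that group, on any MRI sequence
(the sequences may differ between sides); *unilateral* means presence on
exactly one side. The brainstem is bilateral when any single segment
(mesencephalon, pons, medulla) is itself bilateral.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, load_ontology

__all__ = [
    "FEATURE_FLAGS",
    "extract_features",
    "extract_features_cohort",
    "GradingRuleSet",
    "load_ruleset",
    "apply_grading",
    "grade_cohort",
]

#: Boolean feature flags rule-set predicates may reference.
FEATURE_FLAGS = (
    "any_tai",
    "tai_hemispheric",
    "tai_cerebellum",
    "tai_corpus_callosum",
    "tai_internal_capsule_pl_uni",
    "tai_internal_capsule_pl_bil",
    "tai_basal_ganglia_uni",
    "tai_basal_ganglia_bil",
    "tai_thalamus_uni",
    "tai_thalamus_bil",
    "tai_mesencephalon_uni",
    "tai_mesencephalon_bil",
    "tai_pons_uni",
    "tai_pons_bil",
    "tai_medulla_uni",
    "tai_medulla_bil",
    "tai_cerebellar_peduncle_uni",
    "tai_cerebellar_peduncle_bil",
    "tai_brainstem_any",
    "tai_brainstem_uni",
    "tai_brainstem_bil",
)

_BRAINSTEM_GROUPS = ("mesencephalon", "pons", "medulla")
_LATERAL_GROUPS = (
    "internal_capsule_pl",
    "basal_ganglia",
    "thalamus",
    "mesencephalon",
    "pons",
    "medulla",
    "cerebellar_peduncle",
)


def extract_features(lesions: pd.DataFrame, contusion: pd.Series | None = None,
                     ontology: pd.DataFrame | None = None) -> dict:
    """Reduce one patient's lesion annotations to region-level features.

    A region group counts as involved when any of its locations has
    ``present=true`` on any sequence. Volume totals are sums of
    ``volume_cm3`` over present lesions per sequence; count totals are sums
    of ``count``.
    """
    if ontology is None:
        ontology = load_ontology()
    groups = dict(zip(ontology["code"], ontology["region_group"]))

    present = lesions[lesions["present"]] if len(lesions) else lesions
    feats: dict = {}

    sides_by_group: dict[str, set] = {}
    for _, row in present.iterrows():
        grp = groups[row["location_code"]]
        sides_by_group.setdefault(grp, set()).add(row["side"])

    def _has(grp):
        return grp in sides_by_group

    def _bil(grp):
        s = sides_by_group.get(grp, set())
        return "left" in s and "right" in s

    feats["tai_hemispheric"] = _has("hemispheric_wm")
    feats["tai_cerebellum"] = _has("cerebellum")
    feats["tai_corpus_callosum"] = _has("corpus_callosum")
    for grp in _LATERAL_GROUPS:
        b = _bil(grp)
        feats[f"tai_{grp}_bil"] = b
        feats[f"tai_{grp}_uni"] = _has(grp) and not b
    feats["tai_brainstem_any"] = any(_has(g) for g in _BRAINSTEM_GROUPS)
    feats["tai_brainstem_bil"] = any(_bil(g) for g in _BRAINSTEM_GROUPS)
    feats["tai_brainstem_uni"] = feats["tai_brainstem_any"] and not feats["tai_brainstem_bil"]
    feats["any_tai"] = bool(len(present))

    def _total(seq, col):
        sub = present[present["sequence"] == seq]
        return float(sub[col].astype(float).sum()) if len(sub) else 0.0

    feats["vol_tai_flair_cm3"] = _total("FLAIR", "volume_cm3")
    feats["vol_tai_dwi_cm3"] = _total("DWI", "volume_cm3")
    feats["n_tai_flair"] = int(_total("FLAIR", "count"))
    feats["n_tai_dwi"] = int(_total("DWI", "count"))
    feats["n_tai_t2gre_swi"] = int(_total("T2GRE_SWI", "count"))
    bs_codes = {c for c, g in groups.items() if g in _BRAINSTEM_GROUPS}
    bs = present[(present["sequence"] == "T2GRE_SWI")
                 & present["location_code"].isin(bs_codes)]
    feats["n_tai_brainstem_t2gre_swi"] = int(bs["count"].astype(float).sum()) if len(bs) else 0

    if contusion is not None:
        feats["contusion_on_mri"] = bool(contusion["present_mri"])
        feats["vol_contusion_flair_cm3"] = float(contusion["volume_cm3_flair"])
    else:
        feats["contusion_on_mri"] = False
        feats["vol_contusion_flair_cm3"] = 0.0
    return feats


def extract_features_cohort(cohort: Cohort) -> pd.DataFrame:
    """Feature table for every patient in the cohort (index = patient_id).

    Adds the composite flags used as model exposures: ``tai_bilat_brainstem_thal``
    (bilateral brainstem or thalami), ``tai_bilat_mes_thal`` (bilateral
    mesencephalon or thalami) and ``tai_any_deep`` (any TAI in brainstem,
    thalamus or basal ganglia, either laterality).
    """
    pids = pd.Index(cohort.patient_ids, name="patient_id")
    groups = dict(zip(cohort.ontology["code"], cohort.ontology["region_group"]))
    pres = cohort.lesions[cohort.lesions["present"].astype(bool)].copy()
    pres["region_group"] = pres["location_code"].map(groups)

    # laterality per (patient, region group), any sequence
    lat = (
        pres.assign(L=pres["side"] == "left", R=pres["side"] == "right", has=True)
        .groupby(["patient_id", "region_group"])[["L", "R", "has"]]
        .any()
    )
    def _col(grp, what):
        if (grp in lat.index.get_level_values(1)):
            s = lat.xs(grp, level="region_group")[what]
        else:
            s = pd.Series(dtype=bool)
        return s.reindex(pids, fill_value=False)

    feats = pd.DataFrame(index=pids)
    feats["tai_hemispheric"] = _col("hemispheric_wm", "has")
    feats["tai_cerebellum"] = _col("cerebellum", "has")
    feats["tai_corpus_callosum"] = _col("corpus_callosum", "has")
    for grp in _LATERAL_GROUPS:
        bil = _col(grp, "L") & _col(grp, "R")
        feats[f"tai_{grp}_bil"] = bil
        feats[f"tai_{grp}_uni"] = _col(grp, "has") & ~bil
    feats["tai_brainstem_any"] = False
    feats["tai_brainstem_bil"] = False
    for g in _BRAINSTEM_GROUPS:
        feats["tai_brainstem_any"] |= feats[f"tai_{g}_uni"] | feats[f"tai_{g}_bil"]
        feats["tai_brainstem_bil"] |= feats[f"tai_{g}_bil"]
    feats["tai_brainstem_uni"] = feats["tai_brainstem_any"] & ~feats["tai_brainstem_bil"]
    feats["any_tai"] = (
        pres.groupby("patient_id").size().reindex(pids, fill_value=0) > 0
    )

    vol = (
        pres.pivot_table(index="patient_id", columns="sequence",
                         values="volume_cm3", aggfunc="sum")
        .reindex(pids, columns=list(("FLAIR", "DWI")), fill_value=0.0)
        .fillna(0.0)
    )
    cnt = (
        pres.pivot_table(index="patient_id", columns="sequence",
                         values="count", aggfunc="sum")
        .reindex(pids, columns=list(("FLAIR", "DWI", "T2GRE_SWI")), fill_value=0)
        .fillna(0)
    )
    feats["vol_tai_flair_cm3"] = vol["FLAIR"].astype(float)
    feats["vol_tai_dwi_cm3"] = vol["DWI"].astype(float)
    feats["n_tai_flair"] = cnt["FLAIR"].astype(int)
    feats["n_tai_dwi"] = cnt["DWI"].astype(int)
    feats["n_tai_t2gre_swi"] = cnt["T2GRE_SWI"].astype(int)
    bs = pres[(pres["sequence"] == "T2GRE_SWI")
              & pres["region_group"].isin(_BRAINSTEM_GROUPS)]
    feats["n_tai_brainstem_t2gre_swi"] = (
        bs.groupby("patient_id")["count"].sum().reindex(pids, fill_value=0).astype(int)
    )
    cont = cohort.contusions.set_index("patient_id")
    feats["contusion_on_mri"] = (
        cont["present_mri"].reindex(pids, fill_value=False).astype(bool)
    )
    feats["vol_contusion_flair_cm3"] = (
        cont["volume_cm3_flair"].reindex(pids, fill_value=0.0).astype(float)
    )
    feats["tai_bilat_brainstem_thal"] = feats["tai_brainstem_bil"] | feats["tai_thalamus_bil"]
    feats["tai_bilat_mes_thal"] = feats["tai_mesencephalon_bil"] | feats["tai_thalamus_bil"]
    feats["tai_any_deep"] = (
        feats["tai_brainstem_any"]
        | feats["tai_thalamus_uni"] | feats["tai_thalamus_bil"]
        | feats["tai_basal_ganglia_uni"] | feats["tai_basal_ganglia_bil"]
    )
    ct = cohort.patients.set_index("patient_id")["contusion_on_ct"]
    feats["contusion_on_ct"] = ct.reindex(feats.index).fillna(False).astype(bool)
    return feats


# ---------------------------------------------------------------------------
# rule engine


def _compile_predicate(expr: str):
    """Compile a boolean expression over feature-flag names.

    Only ``and``/``or``/``not``, parentheses and known flag names are
    allowed — predicates are pure functions of the flag vector.
    """
    tree = ast.parse(expr, mode="eval")
    for node in ast.walk(tree):
        if isinstance(node, ast.Name):
            if node.id not in FEATURE_FLAGS:
                raise ValueError(f"unknown feature flag in predicate: {node.id!r}")
        elif not isinstance(node, (ast.Expression, ast.BoolOp, ast.And, ast.Or,
                                   ast.UnaryOp, ast.Not, ast.Load)):
            raise ValueError(f"disallowed syntax in predicate: {expr!r}")
    code = compile(tree, "<predicate>", "eval")
    names = [n.id for n in ast.walk(tree) if isinstance(n, ast.Name)]
    return code, names


@dataclass
class GradingRuleSet:
    """Ordered grade→predicate table; final grade = highest satisfied rule."""

    name: str
    no_tai_grade: int
    rules: list  # [(grade, predicate_source, compiled_code)]

    @classmethod
    def from_yaml(cls, path_or_text) -> "GradingRuleSet":
        text = str(path_or_text)
        if "\n" not in text and Path(text).exists():
            raw = Path(text).read_text()
        else:
            raw = text
        doc = yaml.safe_load(raw)
        rules = []
        last = None
        for entry in doc["rules"]:
            grade = int(entry["grade"])
            if last is not None and grade <= last:
                raise ValueError(
                    f"ruleset {doc['name']}: grades must be strictly increasing"
                )
            last = grade
            code, _ = _compile_predicate(entry["predicate"])
            rules.append((grade, entry["predicate"], code))
        return cls(name=doc["name"], no_tai_grade=int(doc["no_tai_grade"]), rules=rules)

    @property
    def grades(self) -> list[int]:
        return sorted({self.no_tai_grade} | {g for g, _, _ in self.rules})


_BUILTIN = ("trondheim", "standard", "stockholm", "gcs_based")
_cache: dict[str, GradingRuleSet] = {}


def load_ruleset(name: str) -> GradingRuleSet:
    """Load a packaged rule set by name, or any rule file by path."""
    if name in _BUILTIN:
        if name not in _cache:
            text = (
                resources.files("taigrade.data.rulesets")
                .joinpath(f"{name}.yaml")
                .read_text()
            )
            _cache[name] = GradingRuleSet.from_yaml(text)
        return _cache[name]
    p = Path(name)
    if p.exists():
        return GradingRuleSet.from_yaml(p)
    raise ValueError(
        f"unknown ruleset {name!r}: expected one of {list(_BUILTIN)} or a rule-file path"
    )


def apply_grading(features, ruleset: GradingRuleSet | str) -> int:
    """Grade one feature vector: the maximum grade whose predicate holds.

    ``features`` is any mapping with the :data:`FEATURE_FLAGS` keys (a dict
    from :func:`extract_features` or a row of
    :func:`extract_features_cohort`). Patients without TAI receive the rule
    set's ``no_tai_grade``.
    """
    if isinstance(ruleset, str):
        ruleset = load_ruleset(ruleset)
    env = {k: bool(features[k]) for k in FEATURE_FLAGS if k in features}
    if not env.get("any_tai", True):
        return ruleset.no_tai_grade
    grade = ruleset.no_tai_grade
    for g, _, code in ruleset.rules:
        if eval(code, {"__builtins__": {}}, env):
            grade = max(grade, g)
    return grade


def grade_cohort(cohort_or_features, ruleset: GradingRuleSet | str,
                 outcome: pd.Series | None = None):
    """Grade every patient; return (per-patient grades, per-grade summary).

    ``outcome`` is an optional numeric series (e.g. 6-month GOSE) indexed by
    patient_id; the summary then reports n, mean and SD of the outcome per
    grade, rows ordered by grade and emitted only for grades with n >= 1.
    """
    if isinstance(ruleset, str):
        ruleset = load_ruleset(ruleset)
    feats = (
        cohort_or_features
        if isinstance(cohort_or_features, pd.DataFrame)
        else extract_features_cohort(cohort_or_features)
    )
    grades = pd.Series(
        [apply_grading(row, ruleset) for _, row in feats.iterrows()],
        index=feats.index,
        name=f"grade_{ruleset.name}",
    )
    rows = []
    for g in sorted(grades.unique()):
        members = grades.index[grades == g]
        row = {"grade": int(g), "n": int(len(members))}
        if outcome is not None:
            vals = outcome.reindex(members).dropna().astype(float)
            row["outcome_mean"] = float(vals.mean()) if len(vals) else np.nan
            row["outcome_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else (
                0.0 if len(vals) == 1 else np.nan
            )
        rows.append(row)
    return grades, pd.DataFrame(rows)
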