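"""Feature extraction and the four anatomical grading rule sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taigrade.grading import (
    FEATURE_FLAGS,
    apply_grading,
    extract_features,
    extract_features_cohort,
    grade_cohort,
    load_ruleset,
)

from conftest import make_lesions

# Fig-style exemplar lesion profiles and their expected Trondheim grades
EXEMPLARS = {
    5: [("pons_tegmental", "left", "FLAIR"), ("pons_tegmental", "right", "FLAIR"),
        ("cerebellar_peduncle_middle", "left", "T2GRE_SWI"),
        ("cerebellar_peduncle_middle", "right", "T2GRE_SWI")],
    4: [("mesencephalon_tectum", "left", "FLAIR"),
        ("mesencephalon_tectum", "right", "DWI")],
    3: [("thalamus", "left", "FLAIR")],
    2: [("cc_truncus", "midline", "FLAIR")],
    1: [("frontal_wm", "right", "FLAIR")],
}


@pytest.mark.parametrize("expected,entries", sorted(EXEMPLARS.items()))
def test_trondheim_exemplar_profiles(expected, entries):
    feats = extract_features(make_lesions(entries))
    assert apply_grading(feats, "trondheim") == expected


def test_brainstem_tai_is_standard_grade_3():
    """Unilateral brainstem TAI plus hemispheric TAI: standard grade 3."""
    feats = extract_features(make_lesions(
        [("frontal_wm", "left", "FLAIR"), ("pons_ventral", "left", "FLAIR")]))
    assert apply_grading(feats, "standard") == 3


def test_no_tai_grades():
    feats = extract_features(make_lesions([]))
    assert apply_grading(feats, "trondheim") == 0
    assert apply_grading(feats, "standard") == 0
    # the Stockholm grading does not separate no-TAI from hemispheric TAI
    assert apply_grading(feats, "stockholm") == 1


def test_gcs_based_worst_grade_is_bilateral_brainstem_or_thalami():
    bil_thal = extract_features(make_lesions(
        [("thalamus", "left", "FLAIR"), ("thalamus", "right", "T2GRE_SWI")]))
    assert apply_grading(bil_thal, "gcs_based") == 4


def test_bilaterality_across_sequences():
    """Left pons on DWI plus right pons on T2*GRE/SWI counts as bilateral."""
    feats = extract_features(make_lesions(
        [("pons_ventral", "left", "DWI"), ("pons_tegmental", "right", "T2GRE_SWI")]))
    assert feats["tai_pons_bil"] and not feats["tai_pons_uni"]
    one_side = extract_features(make_lesions([("pons_ventral", "left", "DWI")]))
    assert one_side["tai_pons_uni"] and not one_side["tai_pons_bil"]


def test_volume_totals_sum_per_sequence():
    feats = extract_features(make_lesions(
        [("frontal_wm", "left", "FLAIR", 0.5), ("cc_genu", "midline", "FLAIR", 0.83),
         ("frontal_wm", "left", "DWI", 0.2)]))
    assert feats["vol_tai_flair_cm3"] == pytest.approx(1.33)
    assert feats["vol_tai_dwi_cm3"] == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# independent oracle: grade definitions re-coded by hand


def _oracle_trondheim(f):
    if f["tai_pons_bil"]:
        return 5
    if f["tai_mesencephalon_bil"] or f["tai_thalamus_bil"] or f["tai_medulla_bil"]:
        return 4
    if (f["tai_thalamus_uni"] or f["tai_brainstem_uni"]
            or f["tai_cerebellar_peduncle_uni"] or f["tai_cerebellar_peduncle_bil"]
            or f["tai_basal_ganglia_uni"] or f["tai_basal_ganglia_bil"]):
        return 3
    if f["tai_corpus_callosum"]:
        return 2
    if (f["tai_hemispheric"] or f["tai_cerebellum"]
            or f["tai_internal_capsule_pl_uni"] or f["tai_internal_capsule_pl_bil"]):
        return 1
    return 0


def _oracle_standard(f):
    if (f["tai_brainstem_any"] or f["tai_cerebellar_peduncle_uni"]
            or f["tai_cerebellar_peduncle_bil"]):
        return 3
    if f["tai_corpus_callosum"]:
        return 2
    if any(f[k] for k in ("tai_hemispheric", "tai_cerebellum",
                          "tai_internal_capsule_pl_uni", "tai_internal_capsule_pl_bil",
                          "tai_basal_ganglia_uni", "tai_basal_ganglia_bil",
                          "tai_thalamus_uni", "tai_thalamus_bil")):
        return 1
    return 0


def _consistent_feature_vectors():
    """Enumerate the boolean lattice over independent flags, derive the rest."""
    base = ["tai_hemispheric", "tai_cerebellum", "tai_corpus_callosum",
            "tai_internal_capsule_pl", "tai_basal_ganglia", "tai_thalamus",
            "tai_mesencephalon", "tai_pons", "tai_medulla", "tai_cerebellar_peduncle"]
    lateral = base[3:]
    for bits in range(3 ** len(lateral) * 2 ** 3):
        f = {}
        rem, code = bits, []
        for _ in lateral:
            rem, r = divmod(rem, 3)
            code.append(r)          # 0 absent, 1 unilateral, 2 bilateral
        f["tai_hemispheric"] = bool(rem & 1)
        f["tai_cerebellum"] = bool(rem & 2)
        f["tai_corpus_callosum"] = bool(rem & 4)
        for name, r in zip(lateral, code):
            f[f"{name}_uni"] = r == 1
            f[f"{name}_bil"] = r == 2
        bs = ["tai_mesencephalon", "tai_pons", "tai_medulla"]
        f["tai_brainstem_bil"] = any(f[f"{g}_bil"] for g in bs)
        f["tai_brainstem_any"] = any(f[f"{g}_uni"] or f[f"{g}_bil"] for g in bs)
        f["tai_brainstem_uni"] = f["tai_brainstem_any"] and not f["tai_brainstem_bil"]
        f["any_tai"] = any(f.get(k, False) for k in FEATURE_FLAGS if k != "any_tai")
        yield f


def test_rule_engine_matches_hand_coded_oracle():
    """Max-satisfied-rule engine equals independent per-grade predicates
    over the exhaustive feature lattice."""
    tron = load_ruleset("trondheim")
    std = load_ruleset("standard")
    n = 0
    for f in _consistent_feature_vectors():
        assert apply_grading(f, tron) == _oracle_trondheim(f)
        assert apply_grading(f, std) == _oracle_standard(f)
        n += 1
    assert n == 3 ** 7 * 8


def test_trondheim_dominates_standard_mapping():
    """On any feature vector: standard 1 -> Trondheim >= 1, 2 -> >= 2, 3 -> >= 3."""
    tron, std = load_ruleset("trondheim"), load_ruleset("standard")
    for f in _consistent_feature_vectors():
        s, t = apply_grading(f, std), apply_grading(f, tron)
        if s in (2, 3):
            assert t >= s
        elif s == 1:
            assert t >= 1


def test_every_feature_vector_receives_one_known_grade():
    for name in ("trondheim", "standard", "stockholm", "gcs_based"):
        rs = load_ruleset(name)
        for f in _consistent_feature_vectors():
            assert apply_grading(f, rs) in rs.grades


_ONT_ENTRIES = None


def _lesion_entries(ontology):
    global _ONT_ENTRIES
    if _ONT_ENTRIES is None:
        _ONT_ENTRIES = [
            (r["code"], r["side"], seq)
            for _, r in ontology.iterrows()
            for seq in ("FLAIR", "DWI", "T2GRE_SWI")
        ]
    return _ONT_ENTRIES


@settings(max_examples=60, deadline=None)
@given(data=st.data())
def test_adding_a_lesion_never_lowers_any_grade(ontology, data):
    entries = _lesion_entries(ontology)
    subset = data.draw(st.lists(st.sampled_from(entries), max_size=10, unique=True))
    extra = data.draw(st.sampled_from(entries))
    before = extract_features(make_lesions(subset))
    after = extract_features(make_lesions(list(dict.fromkeys(subset + [extra]))))
    for name in ("trondheim", "standard", "stockholm", "gcs_based"):
        rs = load_ruleset(name)
        assert apply_grading(after, rs) >= apply_grading(before, rs)


def test_vectorised_cohort_features_match_per_patient_reference(paper_cohort):
    feats = extract_features_cohort(paper_cohort)
    by_patient = dict(tuple(paper_cohort.lesions.groupby("patient_id")))
    cont = paper_cohort.contusions.set_index("patient_id")
    empty = paper_cohort.lesions.iloc[0:0]
    rng = np.random.default_rng(3)
    for pid in rng.choice(paper_cohort.patient_ids, 40, replace=False):
        ref = extract_features(by_patient.get(pid, empty), cont.loc[pid],
                               paper_cohort.ontology)
        row = feats.loc[pid]
        for key, val in ref.items():
            if isinstance(val, float):
                assert row[key] == pytest.approx(val), (pid, key)
            else:
                assert bool(row[key]) == bool(val), (pid, key)


def test_grade_cohort_summary(paper_cohort):
    outcome = pd.Series(8.0, index=paper_cohort.patient_ids)
    grades, summary = grade_cohort(paper_cohort, "trondheim", outcome=outcome)
    assert set(grades.unique()) <= {0, 1, 2, 3, 4, 5}
    assert (summary["n"] >= 1).all()
    assert list(summary["grade"]) == sorted(summary["grade"])
    # constant outcome: mean 8, SD 0 in every grade
    assert summary["outcome_mean"].eq(8.0).all()
    assert summary["outcome_sd"].eq(0.0).all()


def test_unknown_ruleset_rejected():
    with pytest.raises(ValueError, match="oslo"):
        load_ruleset("oslo")
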