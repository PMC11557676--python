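"""Cohort data model: patients, lesion annotations, contusions, outcomes.

The cohort is a set of four delimited text tables sharing a ``patient_id``
key, plus a packaged anatomical ontology of 58 sided locations at which
traumatic axonal injury (TAI) is registered per MRI sequence.

CSV dialect (enforced): UTF-8, comma-separated, ``.`` decimal, empty cell
means missing. Booleans are written ``true``/``false``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortValidationError",
    "Cohort",
    "load_ontology",
    "classify_severity",
    "read_cohort",
    "write_cohort",
    "SEQUENCES",
    "SIDES",
    "MARSHALL_LEVELS",
    "PUPIL_LEVELS",
]

SEQUENCES = ("FLAIR", "DWI", "T2GRE_SWI")
SIDES = ("left", "right", "midline")
SEXES = ("male", "female")
PUPIL_LEVELS = ("normal", "unilateral_dilated", "bilateral_dilated")
MARSHALL_LEVELS = ("no_ct", "1", "2", "3", "4", "5", "6")
REGION_GROUPS = (
    "hemispheric_wm",
    "cerebellum",
    "corpus_callosum",
    "basal_ganglia",
    "thalamus",
    "internal_capsule_pl",
    "mesencephalon",
    "pons",
    "medulla",
    "cerebellar_peduncle",
)

PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "gcs", "pupils", "marshall",
    "days_to_mri", "contusion_on_ct",
]
LESION_COLUMNS = [
    "patient_id", "location_code", "side", "sequence", "present",
    "count", "volume_cm3",
]
CONTUSION_COLUMNS = ["patient_id", "present_mri", "volume_cm3_flair"]
OUTCOME_COLUMNS = ["patient_id", "gose3", "gose6", "gose12"]


class CohortValidationError(ValueError):
    """Raised when cohort tables violate the documented schema.

    ``messages`` lists every violation found, each naming the file, row
    (0-based data row) and column concerned.
    """

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("cohort validation failed:\n" + "\n".join(self.messages))


def load_ontology() -> pd.DataFrame:
    """Return the packaged 58-entry location ontology.

    Columns: ``code``, ``side``, ``region_group``, ``label``. Each (code,
    side) pair is one registrable location; paired structures appear once
    per side, midline structures once. The file is a replaceable data
    resource: substituting a different location list (with the same
    columns) changes no code as long as region groups are preserved.
    """
    with resources.files("taigrade.data").joinpath("ontology.csv").open("rb") as fh:
        ont = pd.read_csv(fh, dtype=str)
    if list(ont.columns) != ["code", "side", "region_group", "label"]:
        raise CohortValidationError(["ontology.csv: unexpected column set"])
    errs = []
    if len(ont) != 58:
        errs.append(f"ontology.csv: expected 58 entries, found {len(ont)}")
    if ont.duplicated(["code", "side"]).any():
        errs.append("ontology.csv: duplicate (code, side) entries")
    groups_per_code = ont.groupby("code")["region_group"].nunique()
    bad = groups_per_code[groups_per_code > 1]
    for code in bad.index:
        errs.append(f"ontology.csv: code {code} maps to multiple region groups")
    unknown = set(ont["region_group"]) - set(REGION_GROUPS)
    if unknown:
        errs.append(f"ontology.csv: unknown region groups {sorted(unknown)}")
    if errs:
        raise CohortValidationError(errs)
    return ont


def classify_severity(gcs: int) -> str:
    """Map an admission GCS score to a TBI severity stratum.

    Severe: GCS 3-8; moderate: 9-13 (a GCS of 13 counts as moderate);
    mild: 14-15.
    """
    gcs = int(gcs)
    if not 3 <= gcs <= 15:
        raise ValueError(f"GCS score must be in [3, 15], got {gcs}")
    if gcs <= 8:
        return "severe"
    if gcs <= 13:
        return "moderate"
    return "mild"


@dataclass
class Cohort:
    """Validated per-patient tables joined on ``patient_id``."""

    patients: pd.DataFrame
    lesions: pd.DataFrame
    contusions: pd.DataFrame
    outcomes: pd.DataFrame
    ontology: pd.DataFrame = field(default_factory=load_ontology)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])

    def severity(self) -> pd.Series:
        """Severity stratum per patient; missing GCS yields NaN."""
        gcs = self.patients["gcs"]
        out = pd.Series(pd.NA, index=self.patients.index, dtype="object")
        ok = gcs.notna()
        out[ok] = [classify_severity(g) for g in gcs[ok]]
        out.index = self.patients["patient_id"].values
        return out


# ---------------------------------------------------------------------------
# reading


def _read_table(path: Path, columns: list[str], errs: list[str]) -> pd.DataFrame:
    if not path.exists():
        errs.append(f"{path.name}: file not found at {path}")
        return pd.DataFrame(columns=columns)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    df = df.replace({"": None})
    if list(df.columns) != columns:
        errs.append(
            f"{path.name}: expected columns {columns}, found {list(df.columns)}"
        )
        return pd.DataFrame(columns=columns)
    return df


def _num(df, col, fname, errs, *, integer=False, required=True, minimum=None):
    out = []
    for i, v in enumerate(df[col]):
        if v is None:
            if required:
                errs.append(f"{fname}: row {i}, column {col}: missing value")
            out.append(np.nan)
            continue
        try:
            x = float(v)
        except ValueError:
            errs.append(f"{fname}: row {i}, column {col}: not numeric: {v!r}")
            out.append(np.nan)
            continue
        if integer and x != int(x):
            errs.append(f"{fname}: row {i}, column {col}: not an integer: {v!r}")
        if minimum is not None and x < minimum:
            errs.append(f"{fname}: row {i}, column {col}: value {v} < {minimum}")
        out.append(x)
    return pd.array(out, dtype="Int64" if integer else "float64") if integer else np.array(out)


def _cat(df, col, fname, allowed, errs, *, required=True):
    out = []
    for i, v in enumerate(df[col]):
        if v is None:
            if required:
                errs.append(f"{fname}: row {i}, column {col}: missing value")
            out.append(None)
            continue
        if v not in allowed:
            errs.append(
                f"{fname}: row {i}, column {col}: {v!r} not in {sorted(allowed)}"
            )
            out.append(None)
        else:
            out.append(v)
    return pd.array(out, dtype="object")


def _bool(df, col, fname, errs):
    mapping = {"true": True, "false": False}
    out = []
    for i, v in enumerate(df[col]):
        if v is None or str(v).lower() not in mapping:
            errs.append(f"{fname}: row {i}, column {col}: expected true/false, got {v!r}")
            out.append(False)
        else:
            out.append(mapping[str(v).lower()])
    return np.array(out, dtype=bool)


def read_cohort(directory: str | Path) -> Cohort:
    """Read and validate a cohort from ``patients/lesions/contusions/outcomes.csv``.

    Every schema violation found is collected and reported in a single
    :class:`CohortValidationError` naming file, row and column.
    """
    directory = Path(directory)
    errs: list[str] = []
    ontology = load_ontology()

    raw_p = _read_table(directory / "patients.csv", PATIENT_COLUMNS, errs)
    raw_l = _read_table(directory / "lesions.csv", LESION_COLUMNS, errs)
    raw_c = _read_table(directory / "contusions.csv", CONTUSION_COLUMNS, errs)
    raw_o = _read_table(directory / "outcomes.csv", OUTCOME_COLUMNS, errs)
    if errs:
        raise CohortValidationError(errs)

    patients = pd.DataFrame({"patient_id": raw_p["patient_id"]})
    patients["age"] = _num(raw_p, "age", "patients.csv", errs, minimum=0.0)
    patients["sex"] = _cat(raw_p, "sex", "patients.csv", SEXES, errs)
    patients["gcs"] = _num(raw_p, "gcs", "patients.csv", errs, integer=True, required=False)
    patients["pupils"] = _cat(raw_p, "pupils", "patients.csv", PUPIL_LEVELS, errs)
    patients["marshall"] = _cat(raw_p, "marshall", "patients.csv", MARSHALL_LEVELS, errs)
    patients["days_to_mri"] = _num(
        raw_p, "days_to_mri", "patients.csv", errs, integer=True, minimum=0
    )
    patients["contusion_on_ct"] = _bool(raw_p, "contusion_on_ct", "patients.csv", errs)
    for i, g in enumerate(patients["gcs"]):
        if g is not pd.NA and not 3 <= g <= 15:
            errs.append(f"patients.csv: row {i}, column gcs: GCS {g} outside [3, 15]")
    if patients["patient_id"].duplicated().any():
        dups = patients.loc[patients["patient_id"].duplicated(), "patient_id"]
        errs.append(f"patients.csv: duplicate patient_id values {sorted(set(dups))}")

    lesions = pd.DataFrame({"patient_id": raw_l["patient_id"]})
    lesions["location_code"] = raw_l["location_code"]
    lesions["side"] = _cat(raw_l, "side", "lesions.csv", SIDES, errs)
    lesions["sequence"] = _cat(raw_l, "sequence", "lesions.csv", SEQUENCES, errs)
    lesions["present"] = _bool(raw_l, "present", "lesions.csv", errs)
    lesions["count"] = _num(raw_l, "count", "lesions.csv", errs, integer=True, minimum=0)
    lesions["volume_cm3"] = _num(
        raw_l, "volume_cm3", "lesions.csv", errs, minimum=0.0, required=False
    )
    lesions["volume_cm3"] = np.where(
        np.isnan(lesions["volume_cm3"].to_numpy(dtype=float)), 0.0, lesions["volume_cm3"]
    )

    valid_pairs = set(zip(ontology["code"], ontology["side"]))
    valid_codes = set(ontology["code"])
    for i, row in lesions.iterrows():
        if row["location_code"] not in valid_codes:
            errs.append(
                f"lesions.csv: row {i}, column location_code: unknown location "
                f"code {row['location_code']!r}"
            )
        elif row["side"] is not None and (row["location_code"], row["side"]) not in valid_pairs:
            errs.append(
                f"lesions.csv: row {i}, column side: location {row['location_code']!r} "
                f"has no {row['side']!r} entry in the ontology"
            )
        if not row["present"]:
            if row["count"] is not pd.NA and row["count"] != 0:
                errs.append(
                    f"lesions.csv: row {i}, column count: present=false but count={row['count']}"
                )
            if row["volume_cm3"] != 0:
                errs.append(
                    f"lesions.csv: row {i}, column volume_cm3: present=false but "
                    f"volume={row['volume_cm3']}"
                )
        if row["sequence"] == "T2GRE_SWI" and row["volume_cm3"] != 0:
            errs.append(
                f"lesions.csv: row {i}, column volume_cm3: volumes are segmented on "
                "FLAIR and DWI only; T2GRE_SWI rows must have no volume"
            )
    dup_mask = lesions.duplicated(["patient_id", "location_code", "side", "sequence"])
    for i in lesions.index[dup_mask]:
        r = lesions.loc[i]
        errs.append(
            f"lesions.csv: row {i}: duplicate annotation for "
            f"({r['patient_id']}, {r['location_code']}, {r['side']}, {r['sequence']})"
        )

    contusions = pd.DataFrame({"patient_id": raw_c["patient_id"]})
    contusions["present_mri"] = _bool(raw_c, "present_mri", "contusions.csv", errs)
    contusions["volume_cm3_flair"] = _num(
        raw_c, "volume_cm3_flair", "contusions.csv", errs, minimum=0.0, required=False
    )
    contusions["volume_cm3_flair"] = np.where(
        np.isnan(contusions["volume_cm3_flair"].to_numpy(dtype=float)),
        0.0,
        contusions["volume_cm3_flair"],
    )
    for i, row in contusions.iterrows():
        if not row["present_mri"] and row["volume_cm3_flair"] != 0:
            errs.append(
                f"contusions.csv: row {i}, column volume_cm3_flair: present_mri=false "
                f"but volume={row['volume_cm3_flair']}"
            )
    if contusions["patient_id"].duplicated().any():
        errs.append("contusions.csv: duplicate patient_id rows")

    outcomes = pd.DataFrame({"patient_id": raw_o["patient_id"]})
    for col in ("gose3", "gose6", "gose12"):
        outcomes[col] = _num(raw_o, col, "outcomes.csv", errs, integer=True, required=False)
        for i, g in enumerate(outcomes[col]):
            if g is not pd.NA and not 1 <= g <= 8:
                errs.append(
                    f"outcomes.csv: row {i}, column {col}: GOSE {g} outside [1, 8]"
                )
    if outcomes["patient_id"].duplicated().any():
        errs.append("outcomes.csv: duplicate patient_id rows")

    known = set(patients["patient_id"])
    for fname, tbl in (
        ("lesions.csv", lesions),
        ("contusions.csv", contusions),
        ("outcomes.csv", outcomes),
    ):
        stray = set(tbl["patient_id"]) - known
        if stray:
            errs.append(f"{fname}: patient_id values not in patients.csv: {sorted(stray)}")

    if errs:
        raise CohortValidationError(errs)
    return Cohort(patients, lesions, contusions, outcomes, ontology)


# ---------------------------------------------------------------------------
# writing


def _fmt(v):
    if v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v)):
        return ""
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _write_table(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    buf = io.StringIO()
    buf.write(",".join(columns) + "\n")
    for _, row in df.iterrows():
        buf.write(",".join(_fmt(row[c]) for c in columns) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write the four cohort tables; ``read_cohort`` round-trips exactly.

    Missing values are written as empty cells (the documented sentinel);
    an empty cohort yields header-only files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_table(cohort.patients, PATIENT_COLUMNS, directory / "patients.csv")
    _write_table(cohort.lesions, LESION_COLUMNS, directory / "lesions.csv")
    _write_table(cohort.contusions, CONTUSION_COLUMNS, directory / "contusions.csv")
    _write_table(cohort.outcomes, OUTCOME_COLUMNS, directory / "outcomes.csv")
    return directory
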