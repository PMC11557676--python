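"""Shared fixtures: lesion-profile builders and a session-wide synthetic cohort."""

import numpy as np
import pandas as pd
import pytest

from taigrade.cohort import load_ontology
from taigrade.regression import build_analysis_frame
from taigrade.simulate import generate, preset_paper


def make_lesions(entries, patient_id="p1"):
    """Lesion-annotation frame from (location_code, side, sequence[, volume]) tuples."""
    rows = []
    for e in entries:
        code, side, seq = e[:3]
        vol = e[3] if len(e) > 3 else 0.0
        rows.append({
            "patient_id": patient_id, "location_code": code, "side": side,
            "sequence": seq, "present": True, "count": 1, "volume_cm3": vol,
        })
    return pd.DataFrame(
        rows,
        columns=["patient_id", "location_code", "side", "sequence",
                 "present", "count", "volume_cm3"],
    )


@pytest.fixture(scope="session")
def ontology():
    return load_ontology()


@pytest.fixture(scope="session")
def paper_cohort():
    """One synthetic cohort at the default calibration (fixed seed)."""
    return generate(preset_paper(), seed=7)


@pytest.fixture(scope="session")
def analysis_frame(paper_cohort):
    """Merged per-patient frame (covariates + features + constructed outcome)."""
    return build_analysis_frame(paper_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
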