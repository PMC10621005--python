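"""Shared fixtures: printed-margin cohort reconstruction and synthetic data."""

from __future__ import annotations

import numpy as np
import pytest

from cytocad.datatypes import PatientRecord
from cytocad.simulate import SimConfig, default_catalog, generate_cohort

# Discovery-cohort margins (CAD- n=38, CAD+ n=79): per-variable counts of
# trait-positive patients in each group.  SMuRFless counts (12 and 26) are
# not assigned directly -- they emerge from how the risk factors are packed
# below.
TABLE1_MARGINS = {
    "sex_male": (13, 47),
    "hypertension": (10, 40),
    "diabetes": (2, 6),
    "hyperlipidaemia": (15, 47),
    "current_smoking": (5, 8),
    "smoking_history_gt10py": (5, 18),
    "family_history": (11, 22),
    "antiplatelet": (8, 15),
    "statin": (7, 31),
    "beta_blocker": (5, 14),
    "ace_arb": (8, 33),
}

# index ranges (within each CAD group) that carry each SMuRF, packed so that
# exactly 26 of 38 CAD- and 68 of 79 CAD+ patients have at least one SMuRF
# (leaving the printed 12 and 11 SMuRFless patients)
_SMURF_PACKING = {
    False: {  # CAD- group, 38 patients
        "current_smoking": range(0, 5),
        "smoking_history_gt10py": range(5, 10),
        "hypertension": range(0, 10),
        "diabetes": range(10, 12),
        "hyperlipidaemia": range(11, 26),
    },
    True: {  # CAD+ group, 79 patients
        "current_smoking": range(0, 8),
        "smoking_history_gt10py": range(8, 26),
        "hypertension": range(0, 40),
        "diabetes": range(40, 46),
        "hyperlipidaemia": range(21, 68),
    },
}

_NON_SMURF = ("family_history", "antiplatelet", "statin", "beta_blocker", "ace_arb")


def build_table1_records() -> list[PatientRecord]:
    """117 patient records whose 2x2 margins reproduce the printed table."""
    records = []
    for cad, n_group in ((False, 38), (True, 79)):
        packing = _SMURF_PACKING[cad]
        n_male = TABLE1_MARGINS["sex_male"][int(cad)]
        # deterministic age spread around the printed group means
        base_age = 64.0 if cad else 53.0
        for i in range(n_group):
            kwargs = {f: (i in packing[f]) for f in packing}
            for f in _NON_SMURF:
                kwargs[f] = i < TABLE1_MARGINS[f][int(cad)]
            records.append(
                PatientRecord(
                    patient_id=f"{'P' if cad else 'N'}{i:03d}",
                    age=base_age + (i % 21) - 10,
                    sex="male" if i < n_male else "female",
                    gensini=7.5 if cad else 0.0,
                    cohort="discovery",
                    bmi=27.1,
                    **kwargs,
                )
            )
    return records


@pytest.fixture(scope="session")
def table1_records() -> list[PatientRecord]:
    return build_table1_records()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def sim_cohort():
    """Default-size synthetic study population (117 + 58 patients)."""
    return generate_cohort(SimConfig(seed=20))


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
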