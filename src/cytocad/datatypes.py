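"""Core data model: patients, subset catalog, proportion matrix, analysis config.

The analysis operates on two joined tables: a patient metadata table
(demographics, risk factors, medications, Gensini score) and a patient x
subset matrix of immune-cell proportions on the percent scale.  CAD status
is always *derived* from the Gensini score (> 0 means CAD+), never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column or field is missing or unrecognised."""


class ValidationError(ValueError):
    """A value violates a domain invariant (range, eligibility, ...)."""


class DegenerateTableError(ValueError):
    """A contingency table has a zero margin and the test is undefined."""


class SeparationError(RuntimeError):
    """Logistic fit diverged: outcome perfectly separated by a predictor."""


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge within its iteration budget."""


#: The 11 major immune populations the subset catalog draws from.
MAJOR_POPULATIONS: tuple[str, ...] = (
    "CD4 Tconv",
    "Treg",
    "CD8 T cells",
    "gd T cells",
    "NKT cells",
    "B cells",
    "NK cells",
    "Monocytes",
    "pDC",
    "mDC",
    "Basophils",
)

BOOL_FIELDS: tuple[str, ...] = (
    "hypertension",
    "diabetes",
    "hyperlipidaemia",
    "current_smoking",
    "smoking_history_gt10py",
    "family_history",
    "statin",
    "ace_arb",
    "antiplatelet",
    "beta_blocker",
)

#: Standard modifiable risk factors; a patient with none of these is SMuRFless.
SMURF_FIELDS: tuple[str, ...] = (
    "hypertension",
    "diabetes",
    "hyperlipidaemia",
    "current_smoking",
    "smoking_history_gt10py",
)

COHORTS = ("discovery", "validation")


@dataclass
class PatientRecord:
    patient_id: str
    age: float
    sex: str  # "male" | "female"
    hypertension: bool
    diabetes: bool
    hyperlipidaemia: bool
    current_smoking: bool
    smoking_history_gt10py: bool
    family_history: bool
    statin: bool
    ace_arb: bool
    antiplatelet: bool
    beta_blocker: bool
    gensini: float
    cohort: str = "discovery"
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValidationError(
                f"patient {self.patient_id!r}: age {self.age} < 18 (eligibility)"
            )
        if self.gensini < 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: gensini {self.gensini} < 0"
            )
        if self.sex not in ("male", "female"):
            raise ValidationError(
                f"patient {self.patient_id!r}: sex {self.sex!r} not male/female"
            )
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"patient {self.patient_id!r}: cohort {self.cohort!r} unknown"
            )

    @property
    def cad_status(self) -> bool:
        """CAD+ iff Gensini score > 0 (a zero score defines the CAD- group)."""
        return self.gensini > 0

    @property
    def smurfless(self) -> bool:
        """True when no standard modifiable risk factor is present."""
        return not any(getattr(self, f) for f in SMURF_FIELDS)


PATIENT_FIELDS: tuple[str, ...] = tuple(f.name for f in fields(PatientRecord))
REQUIRED_PATIENT_COLUMNS: tuple[str, ...] = tuple(
    n for n in PATIENT_FIELDS if n != "bmi"
)


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabulate records, adding the derived cad_status and smurfless columns."""
    rows = []
    for r in records:
        row = {name: getattr(r, name) for name in PATIENT_FIELDS}
        row["cad_status"] = r.cad_status
        row["smurfless"] = r.smurfless
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index("patient_id", drop=False)


@dataclass(frozen=True)
class SubsetDefinition:
    subset_id: str
    label: str
    major_population: str
    denominator: str  # "total_live" | "parent_population"

    def __post_init__(self) -> None:
        if self.major_population not in MAJOR_POPULATIONS:
            raise ValidationError(
                f"subset {self.subset_id!r}: unknown major population "
                f"{self.major_population!r}"
            )
        if self.denominator not in ("total_live", "parent_population"):
            raise ValidationError(
                f"subset {self.subset_id!r}: denominator must be total_live "
                f"or parent_population"
            )


class SubsetCatalog:
    """Ordered collection of subset definitions with unique ids."""

    def __init__(self, subsets: Iterable[SubsetDefinition]):
        self.subsets: list[SubsetDefinition] = list(subsets)
        self._by_id = {s.subset_id: s for s in self.subsets}
        if len(self._by_id) != len(self.subsets):
            seen: set[str] = set()
            for s in self.subsets:
                if s.subset_id in seen:
                    raise ValidationError(f"duplicate subset_id {s.subset_id!r}")
                seen.add(s.subset_id)

    def __len__(self) -> int:
        return len(self.subsets)

    def __contains__(self, subset_id: str) -> bool:
        return subset_id in self._by_id

    def __getitem__(self, subset_id: str) -> SubsetDefinition:
        try:
            return self._by_id[subset_id]
        except KeyError:
            raise KeyError(f"unknown subset {subset_id!r}") from None

    @property
    def subset_ids(self) -> list[str]:
        return [s.subset_id for s in self.subsets]

    def total_live_ids(self) -> list[str]:
        return [s.subset_id for s in self.subsets if s.denominator == "total_live"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset_id": [s.subset_id for s in self.subsets],
                "label": [s.label for s in self.subsets],
                "major_population": [s.major_population for s in self.subsets],
                "denominator": [s.denominator for s in self.subsets],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SubsetCatalog":
        required = {"subset_id", "label", "major_population", "denominator"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"catalog missing columns: {sorted(missing)}")
        return cls(
            SubsetDefinition(
                subset_id=str(row.subset_id),
                label=str(row.label),
                major_population=str(row.major_population),
                denominator=str(row.denominator),
            )
            for row in df.itertuples(index=False)
        )


class ProportionsMatrix:
    """Patient x subset percent matrix (values in [0, 100], no missing)."""

    def __init__(self, values: pd.DataFrame):
        if values.isna().any().any():
            bad = values.index[values.isna().any(axis=1)][0]
            raise ValidationError(f"missing proportion values in row {bad!r}")
        arr = values.to_numpy(dtype=float)
        if arr.size and (arr.min() < 0 or arr.max() > 100):
            i, j = np.unravel_index(
                np.argmax((arr < 0) | (arr > 100)), arr.shape
            )
            raise ValidationError(
                f"proportion {arr[i, j]} outside [0, 100] at "
                f"({values.index[i]!r}, {values.columns[j]!r})"
            )
        self.values = values.astype(float)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def subset_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate_against(self, catalog: SubsetCatalog) -> None:
        unknown = [c for c in self.values.columns if c not in catalog]
        if unknown:
            raise SchemaError(f"unknown subset columns: {unknown}")
        total_ids = [c for c in catalog.total_live_ids() if c in self.values.columns]
        if total_ids:
            sums = self.values[total_ids].sum(axis=1)
            # small numerical headroom on the compositional bound
            if (sums > 100 + 1e-9).any():
                bad = sums.index[sums > 100 + 1e-9][0]
                raise ValidationError(
                    f"%total subsets sum to {sums.loc[bad]:.3f} > 100 for "
                    f"patient {bad!r}"
                )

    def aligned_to(self, patient_ids: Sequence[str]) -> "ProportionsMatrix":
        missing = [p for p in patient_ids if p not in self.values.index]
        if missing:
            raise SchemaError(f"patients missing from proportions: {missing}")
        return ProportionsMatrix(self.values.loc[list(patient_ids)])


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters shared across pipeline stages."""

    seed: int = 0
    cv_folds: int = 5
    cv_repeats: int = 20
    screen_top_m: int = 18
    age_cutoff: float = 55.0
    alpha_tiers: tuple[float, ...] = (0.1, 0.05, 0.01, 0.001)
    table1_test_rule: str = "chi2_always"  # or "paper_footnote"
    fold_change_scale: str = "raw"  # or "log"
    screen_rank_key: str = "distance"  # |AUC-0.5|; or "raw"
    n_lambda: int = 50
    svm_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValidationError("cv_repeats must be >= 1")
        if self.screen_top_m < 1:
            raise ValidationError("screen_top_m must be >= 1")
        if self.table1_test_rule not in ("paper_footnote", "chi2_always"):
            raise ValidationError(f"unknown table1_test_rule {self.table1_test_rule!r}")
        if self.fold_change_scale not in ("raw", "log"):
            raise ValidationError(f"unknown fold_change_scale {self.fold_change_scale!r}")
        if self.screen_rank_key not in ("distance", "raw"):
            raise ValidationError(f"unknown screen_rank_key {self.screen_rank_key!r}")
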