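"""Reading and writing the delimited-text tables the pipeline consumes.

Patient metadata and subset proportions are separate comma-delimited UTF-8
tables joined on patient_id.  Booleans accept {0,1,true,false,yes,no}
case-insensitively and are written back as 0/1; sex accepts
{male,female,m,f} plus 0/1 (1 = male).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .datatypes import (
    BOOL_FIELDS,
    REQUIRED_PATIENT_COLUMNS,
    AnalysisConfig,
    PatientRecord,
    ProportionsMatrix,
    SchemaError,
    SubsetCatalog,
    ValidationError,
)

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def _parse_bool(value, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"row {row}: cannot parse boolean {column}={value!r}")


def _parse_sex(value, row: int) -> str:
    s = str(value).strip().lower()
    if s in ("male", "m", "1"):
        return "male"
    if s in ("female", "f", "0"):
        return "female"
    raise ValidationError(f"row {row}: cannot parse sex {value!r}")


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read and validate a patient metadata table.

    Raises SchemaError naming any missing required column, ValidationError
    with the offending row index for out-of-domain values.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"patient table missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        kwargs = {
            "patient_id": str(getattr(row, "patient_id")),
            "age": float(getattr(row, "age")),
            "sex": _parse_sex(getattr(row, "sex"), i),
            "gensini": float(getattr(row, "gensini")),
            "cohort": str(getattr(row, "cohort")).strip().lower(),
        }
        for b in BOOL_FIELDS:
            kwargs[b] = _parse_bool(getattr(row, b), b, i)
        if "bmi" in df.columns:
            raw = getattr(row, "bmi")
            kwargs["bmi"] = None if pd.isna(raw) or raw == "" else float(raw)
        try:
            records.append(PatientRecord(**kwargs))
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from None
    return records


def write_patient_table(records: Sequence[PatientRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age": r.age,
            "sex": r.sex,
            **{b: int(getattr(r, b)) for b in BOOL_FIELDS},
            "gensini": r.gensini,
            "cohort": r.cohort,
            "bmi": "" if r.bmi is None else r.bmi,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_proportions(
    path: str | Path, catalog: SubsetCatalog | None = None
) -> ProportionsMatrix:
    """Read a patient x subset percent matrix, first column = patient_id."""
    df = pd.read_csv(path)
    if df.columns[0] != "patient_id":
        raise SchemaError("proportions table must start with a patient_id column")
    df = df.set_index("patient_id")
    df.index = df.index.astype(str)
    matrix = ProportionsMatrix(df)
    if catalog is not None:
        matrix.validate_against(catalog)
        # reorder columns to catalog order for the subsets present
        order = [s for s in catalog.subset_ids if s in df.columns]
        matrix = ProportionsMatrix(matrix.values[order])
    return matrix


def write_proportions(matrix: ProportionsMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.insert(0, "patient_id", out.index)
    out.to_csv(path, index=False)


def read_catalog(path: str | Path) -> SubsetCatalog:
    return SubsetCatalog.from_frame(pd.read_csv(path, dtype=str))


def write_catalog(catalog: SubsetCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, index=False)


def read_config(path: str | Path) -> AnalysisConfig:
    """Parse a flat key = value config file into an AnalysisConfig."""
    values: dict[str, object] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"config line {lineno}: expected key = value")
        key, raw = (s.strip() for s in line.split("=", 1))
        values[key] = raw
    kwargs: dict[str, object] = {}
    defaults = AnalysisConfig()
    for key, raw in values.items():
        if not hasattr(defaults, key):
            raise SchemaError(f"unknown config key {key!r}")
        current = getattr(defaults, key)
        if key == "alpha_tiers":
            kwargs[key] = tuple(float(v) for v in str(raw).split(","))
        elif isinstance(current, bool):
            kwargs[key] = _parse_bool(raw, key, 0)
        elif isinstance(current, int):
            kwargs[key] = int(raw)
        elif isinstance(current, float):
            kwargs[key] = float(raw)
        else:
            kwargs[key] = str(raw)
    return AnalysisConfig(**kwargs)


def write_config(cfg: AnalysisConfig, path: str | Path) -> None:
    lines = []
    for key, value in vars(cfg).items():
        if isinstance(value, tuple):
            value = ",".join(str(v) for v in value)
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
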