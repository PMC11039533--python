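"""Cohort file I/O: CSV/TSV with a canonical, unit-suffixed column dictionary.

Canonical headers carry their units (``ast_u_l``, ``platelets_1e9_l``, ...)
because the scoring formulas are unit-critical; a mapping from arbitrary
source headers to canonical names can be supplied. Unknown columns are
preserved untouched on round-trip. Malformed rows are collected into an
ingest report with their row numbers; the read fails outright only above a
configurable error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from pydantic import ValidationError

from .errors import InvalidInputError
from .records import HistologyRecord, PatientRecord, TEMeasurement

CANONICAL_COLUMNS = [
    "id", "age", "sex", "ast_u_l", "alt_u_l", "platelets_1e9_l",
    "glucose_mg_dl", "insulin_uu_ml", "insulin_treated", "t2d", "elf",
    "fib4", "te_kpa", "te_iqr_median", "te_n", "fibrosis_stage",
    "steatosis", "inflammation", "ballooning",
]

_BOOL_TOKENS = {
    "true": True, "1": True, "yes": True, "t": True,
    "false": False, "0": False, "no": False, "f": False,
}


@dataclass
class IngestReport:
    n_rows: int = 0
    n_ok: int = 0
    missingness: Dict[str, int] = field(default_factory=dict)
    errors: List[Tuple[int, str]] = field(default_factory=list)  # (row, message)
    warnings: List[str] = field(default_factory=list)


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in ("", "nan", "na"):
        return None
    if token not in _BOOL_TOKENS:
        raise InvalidInputError(f"cannot parse boolean {value!r}")
    return _BOOL_TOKENS[token]


def _get(row: pd.Series, col: str):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str) and v.strip().lower() in ("", "nan", "na"):
        return None
    return v


def _num(row: pd.Series, col: str) -> Optional[float]:
    v = _get(row, col)
    if v is None:
        return None
    try:
        return float(v)
    except (TypeError, ValueError) as exc:
        raise InvalidInputError(f"column {col!r}: malformed numeric {v!r}") from exc


def _int(row: pd.Series, col: str) -> Optional[int]:
    v = _num(row, col)
    return None if v is None else int(v)


def row_to_record(row: pd.Series, row_number: int) -> PatientRecord:
    te = None
    if _get(row, "te_kpa") is not None:
        te = TEMeasurement(
            stiffness=_num(row, "te_kpa"),
            iqr_over_median=_num(row, "te_iqr_median"),
            n_measurements=_int(row, "te_n"),
        )
    histology = None
    if _get(row, "fibrosis_stage") is not None:
        histology = HistologyRecord(
            steatosis=_int(row, "steatosis") or 0,
            lobular_inflammation=_int(row, "inflammation") or 0,
            ballooning=_int(row, "ballooning") or 0,
            fibrosis_stage=_int(row, "fibrosis_stage"),
        )
    rec_id = _get(row, "id")
    return PatientRecord(
        id=str(rec_id) if rec_id is not None else f"row-{row_number}",
        age=_num(row, "age"),
        sex=_get(row, "sex"),
        ast=_num(row, "ast_u_l"),
        alt=_num(row, "alt_u_l"),
        platelets=_num(row, "platelets_1e9_l"),
        fasting_glucose=_num(row, "glucose_mg_dl"),
        fasting_insulin=_num(row, "insulin_uu_ml"),
        insulin_treated=_parse_bool(_get(row, "insulin_treated")),
        t2d=_parse_bool(_get(row, "t2d")),
        elf=_num(row, "elf"),
        fib4=_num(row, "fib4"),
        te=te,
        histology=histology,
    )


def read_cohort(
    path,
    column_map: Optional[Dict[str, str]] = None,
    max_error_rate: float = 0.5,
) -> Tuple[List[PatientRecord], IngestReport]:
    """Read a CSV/TSV cohort into validated records plus an ingest report.

    ``column_map`` maps canonical names to the file's headers. Rows that
    fail validation are reported by row number (1-based, excluding header)
    and skipped; the whole read raises only when the error rate exceeds
    ``max_error_rate``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    if column_map:
        df = df.rename(columns={src: canon for canon, src in column_map.items()})

    report = IngestReport(n_rows=len(df))
    for col in CANONICAL_COLUMNS:
        if col in df.columns:
            report.missingness[col] = int(df[col].isna().sum())
    if len(df) == 0:
        report.warnings.append("empty cohort file")
        return [], report

    records: List[PatientRecord] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(row_to_record(row, i))
            report.n_ok += 1
        except (InvalidInputError, ValidationError) as exc:
            report.errors.append((i, str(exc)))
    if report.n_rows and len(report.errors) / report.n_rows > max_error_rate:
        raise InvalidInputError(
            f"{len(report.errors)}/{report.n_rows} rows failed ingest "
            f"(first: row {report.errors[0][0]}: {report.errors[0][1]})"
        )
    return records, report


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "age": r.age,
                "sex": r.sex,
                "ast_u_l": r.ast,
                "alt_u_l": r.alt,
                "platelets_1e9_l": r.platelets,
                "glucose_mg_dl": r.fasting_glucose,
                "insulin_uu_ml": r.fasting_insulin,
                "insulin_treated": r.insulin_treated,
                "t2d": r.t2d,
                "elf": r.elf,
                "fib4": r.fib4,
                "te_kpa": r.te.stiffness if r.te else None,
                "te_iqr_median": r.te.iqr_over_median if r.te else None,
                "te_n": r.te.n_measurements if r.te else None,
                "fibrosis_stage": r.histology.fibrosis_stage if r.histology else None,
                "steatosis": r.histology.steatosis if r.histology else None,
                "inflammation": (
                    r.histology.lobular_inflammation if r.histology else None
                ),
                "ballooning": r.histology.ballooning if r.histology else None,
            }
        )
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write records as CSV/TSV with canonical headers (numeric cells at
    full float precision so round-trips are lossless to 1e-9)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    records_to_frame(records).to_csv(path, sep=sep, index=False, float_format="%.12g")
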