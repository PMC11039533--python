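"""Closed-form serum biomarker indices: FIB-4 and HOMA-IR.

FIB-4 = age[years] * AST[U/L] / (platelets[10^9/L] * sqrt(ALT[U/L])).
HOMA-IR = fasting glucose[mg/dL] * fasting insulin[uU/mL] / 405, with
insulin-treated patients excluded from the calculation (the index assumes
endogenous insulin) via an explicit tri-state result.

No rounding happens here: classification at the 1.30 / 2.67 FIB-4 boundaries
must not depend on display precision.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Union

from .errors import InvalidInputError, UnitError
from .records import PLATELET_UNIT_GUARD, PatientRecord

#: HOMA-IR threshold flagging insulin resistance in a Caucasian population
HOMA_IR_CUTOFF = 3.02

#: normalisation constant of the homeostatic model
HOMA_DENOMINATOR = 405.0


class HomaStatus(enum.Enum):
    VALUE = "value"
    EXCLUDED = "excluded"  # insulin-treated: index not interpretable
    MISSING = "missing"  # inputs absent


@dataclass(frozen=True)
class HomaResult:
    """Tri-state HOMA-IR so summaries can report true denominators."""

    status: HomaStatus
    value: Union[float, None] = None

    @property
    def is_excluded(self) -> bool:
        return self.status is HomaStatus.EXCLUDED


HOMA_EXCLUDED = HomaResult(HomaStatus.EXCLUDED)
HOMA_MISSING = HomaResult(HomaStatus.MISSING)


def _require_positive(**named: float) -> None:
    for name, value in named.items():
        if value is None or math.isnan(value):
            raise InvalidInputError(f"{name} is missing or NaN")
        if not value > 0:
            raise InvalidInputError(f"{name} must be > 0, got {value}")


def compute_fib4(
    age: float,
    ast: float,
    platelets: float,
    alt: float,
    *,
    platelet_unit_guard: float = PLATELET_UNIT_GUARD,
) -> float:
    """FIB-4 index from its four components.

    Parameters
    ----------
    age : years (real-valued; fractional ages are accepted as-is)
    ast, alt : aminotransferases, U/L
    platelets : 10^9/L; values above ``platelet_unit_guard`` raise
        :class:`UnitError` as probable cells/uL mis-units.
    """
    _require_positive(age=age, ast=ast, platelets=platelets, alt=alt)
    if platelets > platelet_unit_guard:
        raise UnitError(
            f"platelets = {platelets}: expected 10^9/L "
            f"(> {platelet_unit_guard:.0f} suggests cells/uL)"
        )
    return age * ast / (platelets * math.sqrt(alt))


def compute_homa_ir(
    fasting_glucose: float,
    fasting_insulin: float,
    insulin_treated: bool = False,
) -> HomaResult:
    """HOMA-IR = glucose * insulin / 405; excluded for insulin-treated patients."""
    if insulin_treated:
        return HOMA_EXCLUDED
    _require_positive(
        fasting_glucose=fasting_glucose, fasting_insulin=fasting_insulin
    )
    return HomaResult(
        HomaStatus.VALUE, fasting_glucose * fasting_insulin / HOMA_DENOMINATOR
    )


def classify_insulin_resistance(
    homa_ir: Union[float, HomaResult], cutoff: float = HOMA_IR_CUTOFF
) -> Union[bool, HomaResult]:
    """True iff HOMA-IR >= 3.02. Excluded/missing markers propagate unchanged."""
    if isinstance(homa_ir, HomaResult):
        if homa_ir.status is not HomaStatus.VALUE:
            return homa_ir
        homa_ir = homa_ir.value
    if homa_ir is None or math.isnan(homa_ir):
        raise InvalidInputError("HOMA-IR is missing or NaN")
    return homa_ir >= cutoff


def record_fib4(record: PatientRecord) -> float:
    """FIB-4 for a record: the supplied score if present, else computed from labs."""
    if record.fib4 is not None:
        return record.fib4
    if not record.has_fib4_inputs():
        raise InvalidInputError(
            f"record {record.id}: FIB-4 absent and components incomplete"
        )
    return compute_fib4(record.age, record.ast, record.platelets, record.alt)
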