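"""Typed patient-level records with strict unit semantics.

The FIB-4 index is unit-critical: age in years, AST/ALT in U/L and platelets
in 10^9/L. Every record is validated on construction; a platelet count that
looks like cells/uL (> ``PLATELET_UNIT_GUARD``) is rejected rather than
silently producing a FIB-4 a thousand-fold too small.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import InvalidInputError, UnitError

#: platelet counts above this (10^9/L) are treated as mis-united cells/uL
PLATELET_UNIT_GUARD = 1000.0

#: plausibility window for the ELF score (unitless immunoassay index)
ELF_WINDOW = (5.0, 15.0)

#: study inclusion threshold
MIN_AGE = 18.0


class HistologyRecord(BaseModel):
    """CRN liver-biopsy scoring: steatosis 0-3, lobular inflammation 0-3,
    hepatocyte ballooning 0-2, fibrosis stage 0-4.

    The NAFLD activity score (NAS) is the unweighted sum of the first three
    components; it is always recomputed, never trusted from input.
    """

    model_config = ConfigDict(frozen=True)

    steatosis: int
    lobular_inflammation: int
    ballooning: int
    fibrosis_stage: int
    nas: Optional[int] = None

    @field_validator("steatosis", "lobular_inflammation")
    @classmethod
    def _score_0_3(cls, v: int) -> int:
        if not 0 <= v <= 3:
            raise InvalidInputError(f"histology component must be in 0..3, got {v}")
        return v

    @field_validator("ballooning")
    @classmethod
    def _score_0_2(cls, v: int) -> int:
        if not 0 <= v <= 2:
            raise InvalidInputError(f"ballooning must be in 0..2, got {v}")
        return v

    @field_validator("fibrosis_stage")
    @classmethod
    def _stage_0_4(cls, v: int) -> int:
        if not 0 <= v <= 4:
            raise InvalidInputError(f"fibrosis stage must be in 0..4, got {v}")
        return v

    @model_validator(mode="after")
    def _recompute_nas(self) -> "HistologyRecord":
        total = self.steatosis + self.lobular_inflammation + self.ballooning
        if self.nas is not None and self.nas != total:
            raise InvalidInputError(
                f"supplied NAS {self.nas} != recomputed sum {total}"
            )
        object.__setattr__(self, "nas", total)
        return self


class TEMeasurement(BaseModel):
    """One transient-elastography (FibroScan) examination.

    A reading is reliable only when the IQR/median ratio of the individual
    shots is < 0.30 and at least 10 shots were acquired; see
    :func:`fibrostage.staging.te_validity`.
    """

    model_config = ConfigDict(frozen=True)

    stiffness: float  # kPa
    iqr_over_median: Optional[float] = None
    n_measurements: Optional[int] = None
    probe: Optional[str] = None  # "M" or "XL"

    @field_validator("stiffness")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise InvalidInputError(f"stiffness must be > 0 kPa, got {v}")
        return v

    @field_validator("iqr_over_median")
    @classmethod
    def _nonneg(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v < 0:
            raise InvalidInputError(f"IQR/median ratio must be >= 0, got {v}")
        return v

    @field_validator("n_measurements")
    @classmethod
    def _nonneg_count(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v < 0:
            raise InvalidInputError(f"n_measurements must be >= 0, got {v}")
        return v

    @field_validator("probe")
    @classmethod
    def _probe(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in {"M", "XL"}:
            raise InvalidInputError(f"probe must be 'M' or 'XL', got {v!r}")
        return v


class PatientRecord(BaseModel):
    """One subject: demographics, labs, biomarker scores, optional TE and
    biopsy truth.

    Units: age years, AST/ALT U/L, platelets 10^9/L, fasting glucose mg/dL,
    fasting insulin uU/mL. ELF and FIB-4 are unitless indices.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    age: Optional[float] = None
    sex: Optional[str] = None  # "female" / "male"
    ast: Optional[float] = None
    alt: Optional[float] = None
    platelets: Optional[float] = None
    fasting_glucose: Optional[float] = None
    fasting_insulin: Optional[float] = None
    insulin_treated: Optional[bool] = None
    t2d: Optional[bool] = None
    elf: Optional[float] = None
    fib4: Optional[float] = None
    te: Optional[TEMeasurement] = None
    histology: Optional[HistologyRecord] = None

    @field_validator("age")
    @classmethod
    def _adult(cls, v: Optional[float]) -> Optional[float]:
        if v is None:
            return v
        if v < MIN_AGE:
            raise InvalidInputError(f"age must be >= {MIN_AGE:.0f} years, got {v}")
        return v

    @field_validator("sex")
    @classmethod
    def _sex(cls, v: Optional[str]) -> Optional[str]:
        if v is None:
            return v
        norm = {"female": "female", "f": "female", "male": "male", "m": "male"}.get(
            str(v).strip().lower()
        )
        if norm is None:
            raise InvalidInputError(f"sex must be female/male, got {v!r}")
        return norm

    @field_validator(
        "ast", "alt", "fasting_glucose", "fasting_insulin", "fib4"
    )
    @classmethod
    def _strictly_positive(cls, v: Optional[float], info) -> Optional[float]:
        if v is not None and not v > 0:
            raise InvalidInputError(f"{info.field_name} must be > 0, got {v}")
        return v

    @field_validator("platelets")
    @classmethod
    def _platelet_units(cls, v: Optional[float]) -> Optional[float]:
        if v is None:
            return v
        if not v > 0:
            raise InvalidInputError(f"platelets must be > 0, got {v}")
        if v > PLATELET_UNIT_GUARD:
            raise UnitError(
                f"platelets = {v}: expected 10^9/L; values > "
                f"{PLATELET_UNIT_GUARD:.0f} suggest cells/uL"
            )
        return v

    @field_validator("elf")
    @classmethod
    def _elf_window(cls, v: Optional[float]) -> Optional[float]:
        if v is None:
            return v
        lo, hi = ELF_WINDOW
        if not lo <= v <= hi:
            raise InvalidInputError(
                f"ELF = {v} outside plausibility window [{lo}, {hi}]"
            )
        return v

    def has_fib4_inputs(self) -> bool:
        """True when the four FIB-4 components are all present."""
        return None not in (self.age, self.ast, self.platelets, self.alt)
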