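"""Sequential FIB-4 -> ELF triage and the transient-elastography overlay.

The algorithm computes FIB-4 in everyone. FIB-4 < 1.30 rules the patient
into the low-risk F0-1 tier and FIB-4 >= 2.67 into the high-risk F3-4 tier
without any further testing. Only the intermediate band (1.30 <= FIB-4 <
2.67) triggers an ELF measurement: ELF < 8.30 -> F0-1, ELF >= 9.50 -> F3-4,
and the remaining intermediate ELF band (8.30 <= ELF < 9.50) is flagged as
high risk of significant fibrosis (F2-4) rather than classified.

All interval boundaries are closed-low / open-high, exactly as the decision
rules are stated clinically. TE never overrides the biomarker tier; it is an
advisory concordance overlay applied only to reliable examinations.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

from .errors import InvalidInputError, MissingELFError
from .records import PatientRecord, TEMeasurement
from .scores import record_fib4


class Tier(enum.IntEnum):
    """Three-way triage output, ordered by fibrosis severity."""

    F0_1 = 0
    F2_4_INDETERMINATE = 1
    F3_4 = 2


class DecisionBasis(enum.Enum):
    FIB4_LOW = "fib4_low"
    FIB4_HIGH = "fib4_high"
    ELF_LOW = "elf_low"
    ELF_HIGH = "elf_high"
    ELF_INTERMEDIATE = "elf_intermediate"


class CutoffConfig(BaseModel):
    """All decision thresholds, defaulting to the published values."""

    model_config = ConfigDict(frozen=True)

    fib4_low: float = 1.30
    fib4_high: float = 2.67
    elf_low: float = 8.30
    elf_high: float = 9.50
    te_f2plus: float = 8.0  # kPa, F >= 2 concordance
    te_f34: float = 9.6  # kPa, F3-4 concordance
    te_f24: float = 7.0  # kPa, F2-4 concordance
    te_max_iqr_over_median: float = 0.30
    te_min_measurements: int = 10
    require_elf_always: bool = False  # strict mode: ELF demanded for every record

    @model_validator(mode="after")
    def _ordered(self) -> "CutoffConfig":
        if not self.fib4_low < self.fib4_high:
            raise InvalidInputError("fib4_low must be < fib4_high")
        if not self.elf_low < self.elf_high:
            raise InvalidInputError("elf_low must be < elf_high")
        for name in ("fib4_low", "elf_low", "te_f2plus", "te_f34", "te_f24"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")
        return self


DEFAULT_CUTOFFS = CutoffConfig()


@dataclass(frozen=True)
class TierAssignment:
    tier: Tier
    decided_by: DecisionBasis
    elf_required: bool


def assign_tier(
    fib4: float,
    elf: Optional[float] = None,
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
    *,
    record_id: Optional[str] = None,
) -> TierAssignment:
    """Apply the sequential two-biomarker decision rule to one subject.

    ELF may be missing only when FIB-4 already decides the tier (unless the
    config's strict mode demands ELF for every record).
    """
    if fib4 is None or math.isnan(fib4):
        raise InvalidInputError(f"record {record_id}: FIB-4 is missing or NaN")
    if elf is not None and math.isnan(elf):
        raise InvalidInputError(f"record {record_id}: ELF is NaN")

    in_band = cutoffs.fib4_low <= fib4 < cutoffs.fib4_high
    if cutoffs.require_elf_always and elf is None:
        raise MissingELFError(record_id)

    if fib4 < cutoffs.fib4_low:
        return TierAssignment(Tier.F0_1, DecisionBasis.FIB4_LOW, elf_required=False)
    if fib4 >= cutoffs.fib4_high:
        return TierAssignment(Tier.F3_4, DecisionBasis.FIB4_HIGH, elf_required=False)

    assert in_band
    if elf is None:
        raise MissingELFError(record_id)
    if elf < cutoffs.elf_low:
        return TierAssignment(Tier.F0_1, DecisionBasis.ELF_LOW, elf_required=True)
    if elf >= cutoffs.elf_high:
        return TierAssignment(Tier.F3_4, DecisionBasis.ELF_HIGH, elf_required=True)
    return TierAssignment(
        Tier.F2_4_INDETERMINATE, DecisionBasis.ELF_INTERMEDIATE, elf_required=True
    )


def te_validity(te: TEMeasurement, cutoffs: CutoffConfig = DEFAULT_CUTOFFS) -> bool:
    """Reliability rule for one TE exam: IQR/M < 0.30 and >= 10 shots.

    Missing quality fields make the exam unreliable rather than erroring.
    """
    if te.iqr_over_median is None or te.n_measurements is None:
        return False
    return (
        te.iqr_over_median < cutoffs.te_max_iqr_over_median
        and te.n_measurements >= cutoffs.te_min_measurements
    )


@dataclass(frozen=True)
class TEConcordance:
    """Advisory agreement between the biomarker tier and liver stiffness."""

    te_valid: bool
    f2plus_concordant: Optional[bool] = None  # tier in {F2-4, F3-4} vs >= 8 kPa
    f34_concordant: Optional[bool] = None  # tier F3-4 vs >= 9.6 kPa
    f24_concordant: Optional[bool] = None  # tier F2-4 vs >= 7.0 kPa


def te_overlay(
    tier: Tier, te: TEMeasurement, cutoffs: CutoffConfig = DEFAULT_CUTOFFS
) -> TEConcordance:
    """Check stiffness thresholds against an assigned tier; never reclassifies."""
    if not te_validity(te, cutoffs):
        return TEConcordance(te_valid=False)
    f2plus = None
    f34 = None
    f24 = None
    if tier in (Tier.F3_4, Tier.F2_4_INDETERMINATE):
        f2plus = te.stiffness >= cutoffs.te_f2plus
    if tier is Tier.F3_4:
        f34 = te.stiffness >= cutoffs.te_f34
    if tier is Tier.F2_4_INDETERMINATE:
        f24 = te.stiffness >= cutoffs.te_f24
    return TEConcordance(
        te_valid=True,
        f2plus_concordant=f2plus,
        f34_concordant=f34,
        f24_concordant=f24,
    )


@dataclass
class TierDistribution:
    """Cohort-level staging result: counts, fractions and per-record tiers."""

    n: int
    counts: Dict[Tier, int]
    fractions: Dict[Tier, float]
    n_elf_required: int
    n_missing_elf: int
    assignments: List[Optional[TierAssignment]] = field(default_factory=list)
    failures: List[tuple] = field(default_factory=list)  # (record id, reason)

    @property
    def n_staged(self) -> int:
        return sum(self.counts.values())


def stage_cohort(
    records: Sequence[PatientRecord],
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
) -> TierDistribution:
    """Stage every record with sufficient inputs; count and list the rest.

    Records with FIB-4 in the intermediate band but no ELF are tallied in
    ``n_missing_elf`` and listed in ``failures`` instead of being dropped
    silently.
    """
    counts = {tier: 0 for tier in Tier}
    assignments: List[Optional[TierAssignment]] = []
    failures: List[tuple] = []
    n_elf_required = 0
    n_missing_elf = 0

    for rec in records:
        try:
            fib4 = record_fib4(rec)
            assignment = assign_tier(fib4, rec.elf, cutoffs, record_id=rec.id)
        except MissingELFError:
            n_missing_elf += 1
            n_elf_required += 1
            failures.append((rec.id, "missing ELF in intermediate FIB-4 band"))
            assignments.append(None)
            continue
        except InvalidInputError as exc:
            failures.append((rec.id, str(exc)))
            assignments.append(None)
            continue
        counts[assignment.tier] += 1
        if assignment.elf_required:
            n_elf_required += 1
        assignments.append(assignment)

    n_staged = sum(counts.values())
    fractions = {
        tier: (counts[tier] / n_staged if n_staged else 0.0) for tier in Tier
    }
    return TierDistribution(
        n=len(records),
        counts=counts,
        fractions=fractions,
        n_elf_required=n_elf_required,
        n_missing_elf=n_missing_elf,
        assignments=assignments,
        failures=failures,
    )
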