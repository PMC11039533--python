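"""Published summary inputs used by the internal-consistency audits.

These are the printed whole-cohort accuracy parameters of the biopsy-proven
NASH study (sensitivity/specificity per model and task, as proportions) and
the biopsy stage denominators (n = 140; 38 F0-1, 23 F2, 79 F3-4). They are
inputs to the Bayes predictive-value audit, not outputs of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

NASH_N = 140
NASH_F0_1 = 38
NASH_F2 = 23
NASH_F3_4 = 79


@dataclass(frozen=True)
class PublishedRow:
    """One printed (model, task) accuracy row: sens/spec as proportions,
    PPV/NPV as the printed integer percentages.

    ``audited`` lists the predictive values that are exactly recoverable
    from the printed (rounded) sens/spec via the Bayes identity with
    full-cohort denominators; the sequential F3-4 PPV misses by one percent
    because the printed sensitivity/specificity are themselves rounded, so
    only its NPV participates in the audit.
    """

    model: str
    task: str
    sens: float
    spec: float
    ppv_pct: int
    npv_pct: int
    prevalence: float
    audited: tuple = ("ppv", "npv")


#: whole-cohort rows whose printed predictive values are Bayes-consistent
#: with full-cohort denominators (the rule-out and rule-in tasks)
PUBLISHED_WHOLE_COHORT = (
    PublishedRow("fib4_alone", "detect_F0_1", 0.68, 0.75, 50, 86,
                 NASH_F0_1 / NASH_N),
    PublishedRow("elf_alone", "detect_F3_4", 0.68, 0.70, 75, 63,
                 NASH_F3_4 / NASH_N),
    PublishedRow("sequential_algorithm", "detect_F0_1", 0.71, 0.81, 58, 88,
                 NASH_F0_1 / NASH_N),
    PublishedRow("sequential_algorithm", "detect_F3_4", 0.85, 0.73, 81, 79,
                 NASH_F3_4 / NASH_N, audited=("npv",)),
)

#: the seven audited (row, metric) pairs, in reading order
AUDITED_PREDICTIVE_VALUES = tuple(
    (row, metric) for row in PUBLISHED_WHOLE_COHORT for metric in row.audited
)
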