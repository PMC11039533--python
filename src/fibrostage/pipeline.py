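"""End-to-end composition (score -> stage -> evaluate) and report rendering.

Percentages in rendered tables are rounded half-up to integers, matching
clinical-table convention (banker's rounding is explicitly avoided);
machine-readable outputs keep full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import __version__
from .accuracy import AccuracyReport, IndeterminatePolicy, model_comparison_report
from .cohort_sim import preset, sample_cohort
from .errors import InvalidInputError
from .io import read_cohort, records_to_frame, write_cohort
from .records import PatientRecord
from .scores import record_fib4
from .staging import CutoffConfig, Tier, TierDistribution, stage_cohort

logger = logging.getLogger("fibrostage")

TIER_LABELS = {
    Tier.F0_1: "F0-1 (low risk)",
    Tier.F2_4_INDETERMINATE: "F2-4 (indeterminate, high risk of significant fibrosis)",
    Tier.F3_4: "F3-4 (high risk, advanced fibrosis)",
}


def round_half_up_percent(fraction: Optional[float]) -> Optional[int]:
    """0.805 -> 81, 0.5849 -> 58; None passes through (undefined metric)."""
    if fraction is None:
        return None
    # scale inside Decimal: 0.805 * 100 == 80.4999... in binary floats
    return int(
        (Decimal(repr(float(fraction))) * 100).quantize(0, rounding=ROUND_HALF_UP)
    )


def render_tier_distribution(dist: TierDistribution, title: str = "") -> str:
    """Three-bar text summary of the triage outcome."""
    lines = []
    if title:
        lines.append(title)
    lines.append(f"staged n = {dist.n_staged} (of {dist.n} records)")
    for tier in Tier:
        pct = round_half_up_percent(dist.fractions[tier])
        bar = "#" * (pct // 2 if pct is not None else 0)
        lines.append(
            f"  {TIER_LABELS[tier]:<58s} {dist.counts[tier]:>7d}  {pct:>3d}%  {bar}"
        )
    lines.append(
        f"  ELF required (intermediate FIB-4): {dist.n_elf_required}; "
        f"missing ELF: {dist.n_missing_elf}"
    )
    return "\n".join(lines)


def render_accuracy_table(report: AccuracyReport) -> str:
    """Human-readable model-comparison table, integer percentages."""
    header = (
        f"{'Model':<22s} {'Task':<14s} {'Cut-off':<10s} {'AUC':>5s} "
        f"{'Se%':>4s} {'Sp%':>4s} {'PPV%':>5s} {'NPV%':>5s} {'n':>5s}"
    )
    lines = [header, "-" * len(header)]
    for r in report.rows:
        def pct(est):
            v = round_half_up_percent(est.value)
            return f"{v:d}" if v is not None else "-"

        auc = f"{r.auc.auc:.2f}" if r.auc else "-"
        lines.append(
            f"{r.model:<22s} {r.task:<14s} {r.cutoff_label:<10s} {auc:>5s} "
            f"{pct(r.metrics.sensitivity):>4s} {pct(r.metrics.specificity):>4s} "
            f"{pct(r.metrics.ppv):>5s} {pct(r.metrics.npv):>5s} {r.n:>5d}"
        )
    lines.append(
        f"(indeterminate policy: {report.policy}; CI method: {report.ci_method}; "
        f"records without biopsy truth: {report.n_missing_truth})"
    )
    return "\n".join(lines)


@dataclass
class PipelineConfig:
    """Everything run_pipeline needs; mirrors the CLI flags."""

    input_path: Optional[str] = None
    preset: Optional[str] = None
    n: Optional[int] = None
    seed: int = 0
    rho: float = 0.0
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    policy: str = "negative"
    ci_method: str = "wilson"
    evaluate: bool = False
    out_dir: str = "results"


@dataclass
class PipelineArtifacts:
    cohort_csv: Path
    tiers_csv: Path
    tier_distribution_json: Path
    accuracy_tsv: Optional[Path]
    accuracy_json: Optional[Path]
    log_path: Path
    tier_distribution: TierDistribution
    accuracy_report: Optional[AccuracyReport]


def _load_records(config: PipelineConfig) -> List[PatientRecord]:
    if config.input_path:
        records, report = read_cohort(config.input_path)
        logger.info("read %d records (%d errors)", report.n_ok, len(report.errors))
        return records
    if config.preset:
        spec = preset(config.preset, n=config.n, rho=config.rho)
        records = sample_cohort(spec, seed=config.seed)
        logger.info("simulated %d records from preset %s", len(records), config.preset)
        return records
    raise InvalidInputError("config must name an input file or a simulation preset")


def run_pipeline(config: PipelineConfig) -> PipelineArtifacts:
    """Score, stage and (optionally) evaluate a cohort, writing all artifacts.

    Deterministic given config + seed. Every output embeds the cutoff
    configuration and package version; the log records counts per stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        records = _load_records(config)
        logger.info("n_read=%d", len(records))

        # scoring: fill FIB-4 from labs where absent
        scored: List[PatientRecord] = []
        for rec in records:
            if rec.fib4 is None and rec.has_fib4_inputs():
                rec = rec.model_copy(update={"fib4": record_fib4(rec)})
            scored.append(rec)
        n_scored = sum(1 for r in scored if r.fib4 is not None)
        logger.info("n_scored=%d", n_scored)

        cohort_csv = out / "cohort_scored.csv"
        write_cohort(scored, cohort_csv)

        dist = stage_cohort(scored, config.cutoffs)
        logger.info("n_staged=%d", dist.n_staged)

        meta = {
            "version": __version__,
            "cutoffs": config.cutoffs.model_dump(),
            "seed": config.seed,
        }
        tiers_csv = out / "tiers.csv"
        frame = records_to_frame(scored)
        frame["tier"] = [
            a.tier.name if a is not None else None for a in dist.assignments
        ]
        frame["decided_by"] = [
            a.decided_by.value if a is not None else None for a in dist.assignments
        ]
        frame.to_csv(tiers_csv, index=False, float_format="%.12g")

        dist_json = out / "tier_distribution.json"
        dist_json.write_text(
            json.dumps(
                {
                    **meta,
                    "n": dist.n,
                    "n_staged": dist.n_staged,
                    "counts": {t.name: c for t, c in dist.counts.items()},
                    "fractions": {t.name: f for t, f in dist.fractions.items()},
                    "n_elf_required": dist.n_elf_required,
                    "n_missing_elf": dist.n_missing_elf,
                },
                indent=2,
            )
        )

        accuracy_tsv = accuracy_json = None
        acc_report = None
        if config.evaluate:
            if not any(r.histology is not None for r in scored):
                raise InvalidInputError(
                    "accuracy evaluation requested but no record carries "
                    "biopsy truth (fibrosis_stage)"
                )
            acc_report = model_comparison_report(
                scored,
                config.cutoffs,
                indeterminate_policy=IndeterminatePolicy(config.policy),
                ci_method=config.ci_method,
                seed=config.seed,
            )
            logger.info("n_evaluated=%d", len(scored) - acc_report.n_missing_truth)
            accuracy_tsv = out / "accuracy.tsv"
            pd.DataFrame(acc_report.to_records()).to_csv(
                accuracy_tsv, sep="\t", index=False, float_format="%.12g"
            )
            accuracy_json = out / "accuracy.json"
            accuracy_json.write_text(
                json.dumps({**meta, "rows": acc_report.to_records()}, indent=2)
            )

        return PipelineArtifacts(
            cohort_csv, tiers_csv, dist_json, accuracy_tsv, accuracy_json,
            log_path, dist, acc_report,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
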