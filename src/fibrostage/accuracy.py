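"""Diagnostic-accuracy evaluation against biopsy truth.

Binary tasks are built from the triage tiers (or from a score plus cut-off),
tallied into 2x2 tables, and summarised as sensitivity / specificity / PPV /
NPV with 95% CIs plus ROC-AUC. The indeterminate F2-4 tier is neither
positive nor negative for the F0-1 and F3-4 tasks, so an explicit policy
(negative / exclude / positive) governs it; "negative" keeps full-cohort
denominators, under which PPV and NPV reproduce the Bayes identity

    PPV = se*p / (se*p + (1-sp)*(1-p))
    NPV = sp*(1-p) / (sp*(1-p) + (1-se)*p)

with p the empirical prevalence, exactly.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    InvalidInputError,
    SeparationError,
    UndefinedMetricError,
)
from .records import PatientRecord
from .scores import record_fib4
from .staging import CutoffConfig, DEFAULT_CUTOFFS, Tier, assign_tier, te_validity

# ---------------------------------------------------------------------------
# binary tasks


@dataclass(frozen=True)
class BinaryTask:
    """A dichotomisation of the 0-4 biopsy stage plus a tier->positive rule.

    ``positive_tiers`` are tiers that predict positive by rule;
    ``negative_tiers`` predict negative by rule; any remaining tier is
    indeterminate for this task and handled by policy.
    """

    name: str
    positive_truth: frozenset
    positive_tiers: frozenset
    negative_tiers: frozenset

    def __post_init__(self):
        if not self.positive_truth or not self.positive_truth <= frozenset(range(5)):
            raise InvalidInputError(
                f"positive_truth must be a nonempty subset of 0..4, "
                f"got {set(self.positive_truth)}"
            )


DETECT_F0_1 = BinaryTask(
    "detect_F0_1",
    positive_truth=frozenset({0, 1}),
    positive_tiers=frozenset({Tier.F0_1}),
    negative_tiers=frozenset({Tier.F3_4}),
)
DETECT_F3_4 = BinaryTask(
    "detect_F3_4",
    positive_truth=frozenset({3, 4}),
    positive_tiers=frozenset({Tier.F3_4}),
    negative_tiers=frozenset({Tier.F0_1}),
)
DETECT_F2_4 = BinaryTask(
    "detect_F2_4",
    positive_truth=frozenset({2, 3, 4}),
    positive_tiers=frozenset({Tier.F2_4_INDETERMINATE}),
    negative_tiers=frozenset({Tier.F0_1, Tier.F3_4}),
)
DETECT_FGE2 = BinaryTask(
    "detect_Fge2",
    positive_truth=frozenset({2, 3, 4}),
    positive_tiers=frozenset({Tier.F2_4_INDETERMINATE, Tier.F3_4}),
    negative_tiers=frozenset({Tier.F0_1}),
)

TASKS: Dict[str, BinaryTask] = {
    t.name: t for t in (DETECT_F0_1, DETECT_F3_4, DETECT_F2_4, DETECT_FGE2)
}


def binarize_truth(fibrosis_stage: int, task: BinaryTask) -> bool:
    """Map a 0-4 biopsy stage to the task's positive/negative truth."""
    if fibrosis_stage not in range(5):
        raise InvalidInputError(
            f"fibrosis stage must be in 0..4, got {fibrosis_stage}"
        )
    return fibrosis_stage in task.positive_truth


class IndeterminatePolicy(enum.Enum):
    NEGATIVE = "negative"
    EXCLUDE = "exclude"
    POSITIVE = "positive"


# ---------------------------------------------------------------------------
# confusion tables and proportion metrics


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n if self.n else float("nan")

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.n_excluded + other.n_excluded,
        )


def confusion_from_predictions(
    predictions: Sequence[bool], truths: Sequence[bool]
) -> ConfusionTable:
    preds = np.asarray(predictions, dtype=bool)
    y = np.asarray(truths, dtype=bool)
    if preds.shape != y.shape:
        raise InvalidInputError(
            f"length mismatch: {preds.shape[0]} predictions vs {y.shape[0]} truths"
        )
    return ConfusionTable(
        tp=int(np.sum(preds & y)),
        fp=int(np.sum(preds & ~y)),
        tn=int(np.sum(~preds & ~y)),
        fn=int(np.sum(~preds & y)),
    )


def confusion(
    tiers: Sequence[Tier],
    truths: Sequence[int],
    task: BinaryTask,
    indeterminate_policy: IndeterminatePolicy = IndeterminatePolicy.NEGATIVE,
) -> ConfusionTable:
    """Tally a 2x2 table from triage tiers and biopsy stages.

    Tiers outside the task's by-rule positive/negative sets follow the
    indeterminate policy; with ``EXCLUDE`` they are removed from the
    denominators and counted in ``n_excluded``.
    """
    if len(tiers) != len(truths):
        raise InvalidInputError(
            f"length mismatch: {len(tiers)} tiers vs {len(truths)} truths"
        )
    if len(tiers) == 0:
        raise InvalidInputError("empty cohort")
    tp = fp = tn = fn = n_excluded = 0
    for tier, stage in zip(tiers, truths):
        truth = binarize_truth(stage, task)
        if tier in task.positive_tiers:
            pred: Optional[bool] = True
        elif tier in task.negative_tiers:
            pred = False
        elif indeterminate_policy is IndeterminatePolicy.EXCLUDE:
            n_excluded += 1
            continue
        else:
            pred = indeterminate_policy is IndeterminatePolicy.POSITIVE
        if pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp, fp, tn, fn, n_excluded)


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with a 95% CI, or an explicit undefined marker."""

    value: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    numerator: int = 0
    denominator: int = 0
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.value is not None


def _proportion(numer: int, denom: int, ci_method: str, label: str) -> MetricEstimate:
    if denom == 0:
        return MetricEstimate(
            None, numerator=numer, denominator=0,
            reason=f"{label} undefined: empty denominator",
        )
    method = {"wilson": "wilson", "exact": "beta"}[ci_method]
    low, high = proportion_confint(numer, denom, alpha=0.05, method=method)
    return MetricEstimate(numer / denom, float(low), float(high), numer, denom)


@dataclass(frozen=True)
class AccuracyMetrics:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate


def accuracy_metrics(
    ct: ConfusionTable, ci_method: str = "wilson"
) -> AccuracyMetrics:
    """Sens/spec/PPV/NPV with 95% CIs (Wilson score by default, Clopper-
    Pearson as ``"exact"``). Empty denominators yield explicit undefined
    estimates, never NaN propagation."""
    if ci_method not in ("wilson", "exact"):
        raise InvalidInputError(f"unknown ci_method {ci_method!r}")
    return AccuracyMetrics(
        sensitivity=_proportion(ct.tp, ct.tp + ct.fn, ci_method, "sensitivity"),
        specificity=_proportion(ct.tn, ct.tn + ct.fp, ci_method, "specificity"),
        ppv=_proportion(ct.tp, ct.tp + ct.fp, ci_method, "PPV"),
        npv=_proportion(ct.tn, ct.tn + ct.fn, ci_method, "NPV"),
    )


def predictive_values_from_prevalence(
    sens: float, spec: float, prevalence: float
) -> Tuple[Optional[float], Optional[float]]:
    """Bayes identity: (PPV, NPV) from sensitivity, specificity, prevalence.

    Returns ``None`` for a branch whose denominator is zero (e.g. NPV of a
    perfectly sensitive test in an all-positive population).
    """
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise InvalidInputError(f"{name} must be in [0, 1], got {v}")
    p = prevalence
    ppv_den = sens * p + (1.0 - spec) * (1.0 - p)
    npv_den = spec * (1.0 - p) + (1.0 - sens) * p
    ppv = sens * p / ppv_den if ppv_den > 0 else None
    npv = spec * (1.0 - p) / npv_den if npv_den > 0 else None
    return ppv, npv


# ---------------------------------------------------------------------------
# ROC-AUC


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    ci_method: str
    n_pos: int
    n_neg: int


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float) -> Tuple[float, float]:
    # rank-variance (DeLong) closed form for a single AUC via placements
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = norm.ppf(0.975) * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> AUCResult:
    """AUC-ROC with the higher-score-is-positive orientation.

    The point estimate equals the Mann-Whitney probability
    P(score_pos > score_neg) + 0.5 * P(tie). CI by stratified bootstrap
    (default, ``n_boot`` resamples) or by the DeLong rank-variance closed
    form (``"rank-variance"``).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise InvalidInputError("scores and labels must be the same length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUC undefined: {n_pos} positive and {n_neg} negative labels"
        )
    auc = float(roc_auc_score(y, s))

    if ci_method == "rank-variance":
        low, high = _delong_ci(s, y, auc)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y)
        neg_idx = np.flatnonzero(~y)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            pi = rng.choice(pos_idx, n_pos, replace=True)
            ni = rng.choice(neg_idx, n_neg, replace=True)
            idx = np.concatenate([pi, ni])
            boots[b] = roc_auc_score(y[idx], s[idx])
        low, high = (float(q) for q in np.quantile(boots, [0.025, 0.975]))
    else:
        raise InvalidInputError(f"unknown ci_method {ci_method!r}")
    return AUCResult(auc, low, high, ci_method, n_pos, n_neg)


def _safe_auc(scores, labels, ci_method: str, seed: int) -> Optional[AUCResult]:
    """AUC for report rows: None (not an exception) when truth is single-class."""
    try:
        return roc_auc(scores, labels, ci_method, seed=seed)
    except UndefinedMetricError:
        return None


# ---------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class LogisticFit:
    params: np.ndarray  # [intercept, coef...]
    predicted: np.ndarray  # fitted P(y=1) per record
    converged: bool


def fit_logistic(features: np.ndarray, labels: Sequence[bool]) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS via statsmodels).

    Raises :class:`SeparationError` on perfect or quasi-complete separation
    instead of returning divergent coefficients.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise InvalidInputError(
            f"need n > n_features + 1, got n={len(y)}, p={X.shape[1]}"
        )
    if y.min() == y.max():
        raise InvalidInputError("labels are single-class")
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # PerfectSeparationWarning -> error
        try:
            res = sm.Logit(y, design).fit(method="newton", disp=False, maxiter=100)
        except (PerfectSeparationError, Warning) as exc:
            raise SeparationError(f"separation detected: {exc}") from exc
    grad_norm = float(np.linalg.norm(res.model.score(res.params)))
    if not res.mle_retvals.get("converged", False) or grad_norm > 1e-8:
        raise SeparationError(
            f"logistic fit did not converge (gradient norm {grad_norm:.3g})"
        )
    predicted = res.predict(design)
    if np.min(predicted) <= 1e-10 or np.max(predicted) >= 1 - 1e-10:
        raise SeparationError("fitted probabilities at 0/1: quasi-separation")
    return LogisticFit(np.asarray(res.params), np.asarray(predicted), True)


# ---------------------------------------------------------------------------
# model comparison (whole-cohort and stratified reports)

MODEL_NAMES = (
    "fib4_alone",
    "elf_alone",
    "multivariate_logit",
    "sequential_algorithm",
    "te",
)


@dataclass
class ModelRow:
    """One (model, task) row of an accuracy report."""

    model: str
    task: str
    cutoff_label: str
    n: int
    n_excluded: int
    prevalence: float
    confusion_table: ConfusionTable
    metrics: AccuracyMetrics
    auc: Optional[AUCResult]
    note: str = ""


@dataclass
class AccuracyReport:
    rows: List[ModelRow]
    n_records: int
    n_missing_truth: int
    policy: str
    ci_method: str

    def to_records(self) -> List[dict]:
        out = []
        for r in self.rows:
            d = {
                "model": r.model,
                "task": r.task,
                "cutoff": r.cutoff_label,
                "n": r.n,
                "n_excluded": r.n_excluded,
                "prevalence": r.prevalence,
                "tp": r.confusion_table.tp,
                "fp": r.confusion_table.fp,
                "tn": r.confusion_table.tn,
                "fn": r.confusion_table.fn,
                "note": r.note,
            }
            for name in ("sensitivity", "specificity", "ppv", "npv"):
                est: MetricEstimate = getattr(r.metrics, name)
                d[name] = est.value
                d[f"{name}_ci_low"] = est.ci_low
                d[f"{name}_ci_high"] = est.ci_high
            d["auc"] = r.auc.auc if r.auc else None
            d["auc_ci_low"] = r.auc.ci_low if r.auc else None
            d["auc_ci_high"] = r.auc.ci_high if r.auc else None
            out.append(d)
        return out


def _cohort_arrays(records: Sequence[PatientRecord], cutoffs: CutoffConfig):
    """Extract aligned fib4/elf/stage/tier arrays for records with truth."""
    fib4, elf, stage, tiers, te_vals = [], [], [], [], []
    n_missing_truth = 0
    for rec in records:
        if rec.histology is None:
            n_missing_truth += 1
            continue
        f = record_fib4(rec)
        fib4.append(f)
        elf.append(rec.elf)
        stage.append(rec.histology.fibrosis_stage)
        tiers.append(assign_tier(f, rec.elf, cutoffs, record_id=rec.id).tier)
        if rec.te is not None and te_validity(rec.te, cutoffs):
            te_vals.append(rec.te.stiffness)
        else:
            te_vals.append(None)
    return (
        np.array(fib4),
        np.array([e if e is not None else np.nan for e in elf]),
        np.array(stage),
        tiers,
        te_vals,
        n_missing_truth,
    )


def _threshold_rows(
    model: str,
    values: np.ndarray,
    stage: np.ndarray,
    tasks: Sequence[Tuple[BinaryTask, bool, str]],
    ci_method: str,
    auc_ci_method: str,
    seed: int,
) -> List[ModelRow]:
    """Rows for a single continuous score with rule-out / rule-in cut-offs.

    ``tasks`` holds (task, positive_below, cutoff_label): positive_below=True
    means the prediction is positive when the score is *below* the threshold
    (the rule-out direction), and the AUC score is negated accordingly.
    """
    rows = []
    for task, positive_below, label in tasks:
        thresh = float(label.split()[-1])
        truth = np.array([binarize_truth(int(s), task) for s in stage])
        preds = values < thresh if positive_below else values >= thresh
        ct = confusion_from_predictions(preds, truth)
        auc_scores = -values if positive_below else values
        auc = _safe_auc(auc_scores, truth, auc_ci_method, seed)
        rows.append(
            ModelRow(
                model, task.name, label, ct.n, 0, ct.prevalence, ct,
                accuracy_metrics(ct, ci_method), auc,
            )
        )
    return rows


def model_comparison_report(
    records: Sequence[PatientRecord],
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
    models: Sequence[str] = MODEL_NAMES,
    indeterminate_policy: IndeterminatePolicy = IndeterminatePolicy.NEGATIVE,
    ci_method: str = "wilson",
    auc_ci_method: str = "bootstrap",
    seed: int = 0,
) -> AccuracyReport:
    """Compare the triage models against biopsy truth.

    Models: FIB-4 alone (both cut-offs), ELF alone (both cut-offs), a
    bivariate logistic fit on (FIB-4, ELF), the sequential algorithm (all
    four tasks), and TE at the 8 kPa F>=2 threshold on reliable exams.
    AUC for the sequential algorithm uses the ordinal tier as the score
    (the F2-4 task uses the tier-membership indicator, since the middle
    tier is not ordinally extreme). Records without biopsy truth are
    excluded and counted.
    """
    fib4, elf, stage, tiers, te_vals, n_missing_truth = _cohort_arrays(
        records, cutoffs
    )
    if len(stage) == 0:
        raise InvalidInputError("no records with biopsy truth")
    rows: List[ModelRow] = []

    if "fib4_alone" in models:
        rows += _threshold_rows(
            "fib4_alone", fib4, stage,
            [(DETECT_F0_1, True, f"< {cutoffs.fib4_low}"),
             (DETECT_F3_4, False, f">= {cutoffs.fib4_high}")],
            ci_method, auc_ci_method, seed,
        )
    if "elf_alone" in models and not np.isnan(elf).any():
        rows += _threshold_rows(
            "elf_alone", elf, stage,
            [(DETECT_F0_1, True, f"< {cutoffs.elf_low}"),
             (DETECT_F3_4, False, f">= {cutoffs.elf_high}")],
            ci_method, auc_ci_method, seed,
        )
    if "multivariate_logit" in models and not np.isnan(elf).any():
        X = np.column_stack([fib4, elf])
        for task in (DETECT_F0_1, DETECT_F3_4):
            truth = np.array([binarize_truth(int(s), task) for s in stage])
            try:
                fit = fit_logistic(X, truth)
            except SeparationError as exc:
                rows.append(
                    ModelRow(
                        "multivariate_logit", task.name, "-", 0, len(stage),
                        float("nan"),
                        ConfusionTable(0, 0, 0, 0, len(stage)),
                        accuracy_metrics(ConfusionTable(0, 0, 0, 0), ci_method),
                        None, note=str(exc),
                    )
                )
                continue
            preds = fit.predicted >= 0.5
            ct = confusion_from_predictions(preds, truth)
            auc = _safe_auc(fit.predicted, truth, auc_ci_method, seed)
            rows.append(
                ModelRow(
                    "multivariate_logit", task.name, "-", ct.n, 0,
                    ct.prevalence, ct, accuracy_metrics(ct, ci_method), auc,
                )
            )
    if "sequential_algorithm" in models:
        ordinal = np.array([int(t) for t in tiers], dtype=float)
        for task in (DETECT_F0_1, DETECT_F3_4, DETECT_F2_4, DETECT_FGE2):
            truth = np.array([binarize_truth(int(s), task) for s in stage])
            ct = confusion(tiers, stage, task, indeterminate_policy)
            if task is DETECT_F0_1:
                auc_scores = -ordinal
            elif task is DETECT_F2_4:
                auc_scores = (ordinal == float(Tier.F2_4_INDETERMINATE)).astype(float)
            else:
                auc_scores = ordinal
            auc = _safe_auc(auc_scores, truth, auc_ci_method, seed)
            rows.append(
                ModelRow(
                    "sequential_algorithm", task.name, "combined", ct.n,
                    ct.n_excluded, ct.prevalence, ct,
                    accuracy_metrics(ct, ci_method), auc,
                )
            )
    if "te" in models:
        mask = [v is not None for v in te_vals]
        if any(mask):
            stiff = np.array([v for v in te_vals if v is not None])
            te_stage = stage[np.array(mask)]
            rows += _threshold_rows(
                "te", stiff, te_stage,
                [(DETECT_FGE2, False, f">= {cutoffs.te_f2plus}")],
                ci_method, auc_ci_method, seed,
            )

    return AccuracyReport(
        rows, len(records), n_missing_truth,
        indeterminate_policy.value, ci_method,
    )


def stratified_report(
    records: Sequence[PatientRecord],
    stratifier: str = "t2d",
    **kwargs,
) -> Dict[object, AccuracyReport]:
    """model_comparison_report applied independently per stratum.

    Empty strata are skipped with a warning; per-stratum prevalence is used
    throughout (the point of the stratification).
    """
    groups: Dict[object, List[PatientRecord]] = {}
    for rec in records:
        key = getattr(rec, stratifier)
        if key is None:
            raise InvalidInputError(
                f"record {rec.id}: stratifier {stratifier!r} undefined"
            )
        groups.setdefault(key, []).append(rec)
    out = {}
    for key, group in sorted(groups.items(), key=lambda kv: str(kv[0])):
        if not group:
            warnings.warn(f"stratum {key!r} is empty; skipped")
            continue
        out[key] = model_comparison_report(group, **kwargs)
    return out
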