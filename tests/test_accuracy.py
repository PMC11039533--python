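"""Confusion tables, proportion CIs, Bayes identities, ROC-AUC, logistic fits."""

import math

import numpy as np
import pytest

from fibrostage.accuracy import (
    DETECT_F0_1,
    DETECT_F2_4,
    DETECT_F3_4,
    DETECT_FGE2,
    ConfusionTable,
    IndeterminatePolicy,
    accuracy_metrics,
    binarize_truth,
    confusion,
    fit_logistic,
    model_comparison_report,
    predictive_values_from_prevalence,
    roc_auc,
    stratified_report,
)
from fibrostage.errors import (
    InvalidInputError,
    SeparationError,
    UndefinedMetricError,
)
from fibrostage.pipeline import round_half_up_percent
from fibrostage.records import HistologyRecord, PatientRecord
from fibrostage.staging import Tier


class TestBinarizeTruth:
    @pytest.mark.parametrize(
        "stage, task, expected",
        [
            (3, DETECT_F3_4, True),
            (2, DETECT_F3_4, False),
            (2, DETECT_FGE2, True),
            (1, DETECT_F0_1, True),
            (2, DETECT_F2_4, True),
            (0, DETECT_FGE2, False),
        ],
    )
    def test_membership(self, stage, task, expected):
        assert binarize_truth(stage, task) is expected

    def test_out_of_range_stage(self):
        with pytest.raises(InvalidInputError):
            binarize_truth(5, DETECT_F3_4)


class TestConfusion:
    TIERS = [Tier.F3_4, Tier.F0_1, Tier.F2_4_INDETERMINATE]
    TRUTHS = [4, 0, 3]

    def test_three_record_hand_count_negative_policy(self):
        ct = confusion(self.TIERS, self.TRUTHS, DETECT_F3_4,
                       IndeterminatePolicy.NEGATIVE)
        assert (ct.tp, ct.tn, ct.fn, ct.fp) == (1, 1, 1, 0)
        assert ct.n_excluded == 0

    def test_exclude_policy(self):
        ct = confusion(self.TIERS, self.TRUTHS, DETECT_F3_4,
                       IndeterminatePolicy.EXCLUDE)
        assert (ct.tp, ct.tn, ct.fn, ct.fp, ct.n_excluded) == (1, 1, 0, 0, 1)

    def test_policy_switch_changes_only_fn_tn_for_f34(self, nash_cohort):
        from fibrostage.accuracy import _cohort_arrays
        from fibrostage.staging import DEFAULT_CUTOFFS

        _, _, stage, tiers, _, _ = _cohort_arrays(nash_cohort, DEFAULT_CUTOFFS)
        neg = confusion(tiers, stage, DETECT_F3_4, IndeterminatePolicy.NEGATIVE)
        exc = confusion(tiers, stage, DETECT_F3_4, IndeterminatePolicy.EXCLUDE)
        assert neg.tp == exc.tp and neg.fp == exc.fp
        assert (neg.fn - exc.fn) + (neg.tn - exc.tn) == exc.n_excluded

    def test_brute_force_tally_on_synthetic_cohort(self, nash_cohort):
        from fibrostage.accuracy import _cohort_arrays
        from fibrostage.staging import DEFAULT_CUTOFFS

        _, _, stage, tiers, _, _ = _cohort_arrays(nash_cohort, DEFAULT_CUTOFFS)
        for task in (DETECT_F0_1, DETECT_F3_4, DETECT_F2_4, DETECT_FGE2):
            ct = confusion(tiers, stage, task, IndeterminatePolicy.NEGATIVE)
            # independent nested-loop tally
            tp = fp = tn = fn = 0
            for t, s in zip(tiers, stage):
                truth = s in task.positive_truth
                pred = t in task.positive_tiers
                if pred and truth:
                    tp += 1
                elif pred:
                    fp += 1
                elif truth:
                    fn += 1
                else:
                    tn += 1
            assert (ct.tp, ct.fp, ct.tn, ct.fn) == (tp, fp, tn, fn), task.name

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            confusion([Tier.F0_1], [0, 1], DETECT_F0_1)


class TestAccuracyMetrics:
    def test_hand_arithmetic(self):
        m = accuracy_metrics(ConfusionTable(tp=8, fn=2, tn=6, fp=4))
        assert m.sensitivity.value == pytest.approx(0.800)
        assert m.specificity.value == pytest.approx(0.600)
        assert m.ppv.value == pytest.approx(8 / 12)
        assert m.npv.value == pytest.approx(0.750)

    def test_empty_positive_class_is_undefined_not_nan(self):
        m = accuracy_metrics(ConfusionTable(tp=0, fn=0, tn=5, fp=5))
        assert not m.sensitivity.defined
        assert "undefined" in m.sensitivity.reason
        assert m.specificity.value == pytest.approx(0.5)

    def test_wilson_interval_8_of_10(self):
        # closed-form Wilson: centre (p + z^2/2n)/(1 + z^2/n), etc.
        m = accuracy_metrics(ConfusionTable(tp=8, fn=2, tn=0, fp=0))
        assert m.sensitivity.ci_low == pytest.approx(0.490, abs=0.005)
        assert m.sensitivity.ci_high == pytest.approx(0.943, abs=0.005)

    def test_ci_bounds_bracket_point(self, nash_cohort):
        rep = model_comparison_report(nash_cohort, seed=0,
                                      auc_ci_method="rank-variance")
        for row in rep.rows:
            for name in ("sensitivity", "specificity", "ppv", "npv"):
                est = getattr(row.metrics, name)
                if est.defined:
                    assert est.ci_low <= est.value <= est.ci_high

    def test_wilson_coverage_at_n50_p08(self):
        # empirical 95% CI coverage over 5000 binomial replicates
        from statsmodels.stats.proportion import proportion_confint

        rng = np.random.default_rng(1234)
        counts = rng.binomial(50, 0.8, size=5000)
        low, high = proportion_confint(counts, 50, alpha=0.05, method="wilson")
        coverage = np.mean((low <= 0.8) & (0.8 <= high))
        assert 0.92 <= coverage <= 0.98


class TestBayesIdentity:
    @pytest.mark.parametrize(
        "sens, spec, prev, ppv_pct, npv_pct",
        [
            (0.68, 0.75, 38 / 140, 50, 86),  # rule-out score, F0-1 task
            (0.68, 0.70, 79 / 140, 75, 63),  # second-line score, F3-4 task
        ],
    )
    def test_published_rounded_predictive_values(
        self, sens, spec, prev, ppv_pct, npv_pct
    ):
        ppv, npv = predictive_values_from_prevalence(sens, spec, prev)
        assert round_half_up_percent(ppv) == ppv_pct
        assert round_half_up_percent(npv) == npv_pct

    def test_perfect_test(self):
        assert predictive_values_from_prevalence(1.0, 1.0, 0.5) == (1.0, 1.0)

    def test_undefined_branch(self):
        ppv, npv = predictive_values_from_prevalence(0.0, 1.0, 0.0)
        assert ppv is None  # no positive predictions possible
        assert npv == 1.0

    def test_out_of_range_inputs(self):
        with pytest.raises(InvalidInputError):
            predictive_values_from_prevalence(1.2, 0.5, 0.5)

    def test_closure_against_confusion_tables(self, nash_cohort):
        # with the "negative" policy the full-cohort denominators make
        # PPV/NPV from counts equal the Bayes identity exactly
        rep = model_comparison_report(nash_cohort, seed=0,
                                      auc_ci_method="rank-variance")
        for row in rep.rows:
            m = row.metrics
            if not all(e.defined for e in (m.sensitivity, m.specificity,
                                           m.ppv, m.npv)):
                continue
            if row.n_excluded:
                continue
            ppv, npv = predictive_values_from_prevalence(
                m.sensitivity.value, m.specificity.value, row.prevalence
            )
            assert ppv == pytest.approx(m.ppv.value, abs=1e-12), row
            assert npv == pytest.approx(m.npv.value, abs=1e-12), row


class TestRocAuc:
    def test_perfect_separation_and_ties(self):
        assert roc_auc([1, 2, 3, 4], [False, False, True, True],
                       "rank-variance").auc == 1.0
        assert roc_auc([5, 5, 5, 5], [False, True, False, True],
                       "rank-variance").auc == 0.5

    def test_pair_enumeration_example(self):
        # positives score {2, 4}, negatives {1, 3}: 3 of 4 pairs won
        res = roc_auc([1, 2, 3, 4], [False, True, False, True], "rank-variance")
        assert res.auc == pytest.approx(0.75)

    def test_matches_exhaustive_mann_whitney(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.linspace(0, 1, 17), size=n)  # force ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            res = roc_auc(scores, labels, "rank-variance")
            pos = scores[labels]
            neg = scores[~labels]
            wins = ties = 0
            for p in pos:
                for q in neg:
                    if p > q:
                        wins += 1
                    elif p == q:
                        ties += 1
            expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert res.auc == pytest.approx(expected, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 2, 3], [True, True, True])

    def test_bootstrap_ci_brackets_point(self):
        rng = np.random.default_rng(11)
        scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(1, 1, 40)])
        labels = np.array([False] * 60 + [True] * 40)
        res = roc_auc(scores, labels, "bootstrap", n_boot=500, seed=3)
        assert res.ci_low <= res.auc <= res.ci_high
        assert res.ci_low > 0.5  # clearly informative scores


class TestFitLogistic:
    def test_saturated_2x2_closed_form(self):
        # event rates 0.25 vs 0.75 -> slope = logit(0.75) - logit(0.25) = ln 9
        x = np.repeat([0.0, 1.0], 40)
        y = np.concatenate([
            np.tile([1, 0, 0, 0], 10),  # 10/40 events
            np.tile([1, 1, 1, 0], 10),  # 30/40 events
        ]).astype(bool)
        fit = fit_logistic(x, y)
        assert fit.params[1] == pytest.approx(math.log(9), abs=1e-6)
        assert fit.predicted[0] == pytest.approx(0.25, abs=1e-6)
        assert fit.predicted[-1] == pytest.approx(0.75, abs=1e-6)

    def test_null_model_coefficient_near_zero(self):
        x = np.repeat([0.0, 1.0], 50)
        y = np.tile([True, False], 50)
        fit = fit_logistic(x, y)
        assert abs(fit.params[1]) < 1e-6

    def test_separable_data_raises(self):
        x = np.arange(20, dtype=float)
        y = x >= 10
        with pytest.raises(SeparationError):
            fit_logistic(x, y)


class TestReports:
    def test_model_comparison_shape_and_consistency(self, nash_cohort):
        rep = model_comparison_report(nash_cohort, seed=0,
                                      auc_ci_method="rank-variance")
        models = {r.model for r in rep.rows}
        assert models == {"fib4_alone", "elf_alone", "multivariate_logit",
                          "sequential_algorithm", "te"}
        seq_tasks = {r.task for r in rep.rows
                     if r.model == "sequential_algorithm"}
        assert seq_tasks == {"detect_F0_1", "detect_F3_4", "detect_F2_4",
                             "detect_Fge2"}
        for r in rep.rows:
            if r.auc is not None:
                assert 0.0 <= r.auc.auc <= 1.0

    def test_degenerate_all_f0_cohort_flags_undefined_sens(self):
        records = [
            PatientRecord(
                id=f"d{i}", fib4=0.8 + i / 100, elf=8.0,
                histology=HistologyRecord(
                    steatosis=1, lobular_inflammation=0, ballooning=0,
                    fibrosis_stage=0,
                ),
            )
            for i in range(12)
        ]
        rep = model_comparison_report(
            records, models=("sequential_algorithm",), seed=0,
            auc_ci_method="rank-variance",
        )
        # all truth F0: detect_F3_4 rows cannot have AUC or sensitivity
        rows = {r.task: r for r in rep.rows}
        assert not rows["detect_F3_4"].metrics.sensitivity.defined

    def test_stratified_pooled_confusion_additivity(self, nash_cohort):
        reps = stratified_report(
            nash_cohort, "t2d", models=("sequential_algorithm",), seed=0,
            auc_ci_method="rank-variance",
        )
        assert set(reps) == {False, True}
        whole = model_comparison_report(
            nash_cohort, models=("sequential_algorithm",), seed=0,
            auc_ci_method="rank-variance",
        )
        for task in ("detect_F0_1", "detect_F3_4"):
            parts = [
                r.confusion_table
                for rep in reps.values()
                for r in rep.rows
                if r.task == task
            ]
            pooled = parts[0] + parts[1]
            target = next(
                r.confusion_table for r in whole.rows if r.task == task
            )
            assert (pooled.tp, pooled.fp, pooled.tn, pooled.fn) == (
                target.tp, target.fp, target.tn, target.fn,
            )

    def test_stratifier_missing_raises(self, nash_cohort):
        bare = [r.model_copy(update={"t2d": None}) for r in nash_cohort[:5]]
        with pytest.raises(InvalidInputError):
            stratified_report(bare, "t2d")
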