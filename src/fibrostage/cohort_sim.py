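"""Synthetic cohorts calibrated to published median (Q1-Q3) summaries.

Biomarkers (FIB-4, ELF, liver stiffness) are positive and right-skewed, so
each is modelled as lognormal, with parameters recovered from a printed
median and quartiles: mu = ln(median) and sigma = (ln Q3 - ln Q1) / (2 z75),
z75 = Phi^{-1}(0.75). The FIB-4/ELF joint distribution uses a Gaussian
copula on the log scale with correlation ``rho`` (default 0: the source
summaries are marginal only).

Two cohort shapes are supported:

* labelled, biopsy-proven NASH-like: fixed per-stage counts (stratified
  sampling), stage-conditional biomarker distributions, histology truth;
* unlabelled, primary-care-like: a single marginal FIB-4/ELF pair.

``tier_probabilities_closed_form`` gives the exact triage-tier probabilities
implied by a (FIB-4, ELF) specification, serving as the analytic oracle for
simulated staged fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import multivariate_normal, norm

from .errors import InvalidInputError
from .records import ELF_WINDOW, HistologyRecord, PatientRecord, TEMeasurement
from .scores import compute_fib4
from .staging import CutoffConfig, DEFAULT_CUTOFFS, Tier

Z75 = float(norm.ppf(0.75))  # 0.674489750196...


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal on the positive half-line, parameterised on the log scale."""

    mu: float
    sigma: float
    fitted_from: Optional[Tuple[float, float, float]] = None  # (median, q1, q3)

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidInputError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0

    def quantile(self, q: float) -> float:
        if self.degenerate:
            return self.median
        return math.exp(self.mu + self.sigma * norm.ppf(q))

    def zscore(self, x: float) -> float:
        """Standard-normal coordinate of a threshold x on the log scale."""
        if x <= 0:
            raise InvalidInputError(f"threshold must be > 0, got {x}")
        if self.degenerate:
            return math.inf if x > self.median else -math.inf
        return (math.log(x) - self.mu) / self.sigma


def fit_lognormal_from_quartiles(
    median: float, q1: float, q3: float
) -> LognormalSpec:
    """Recover (mu, sigma) from printed median (Q1-Q3).

    The symmetric log-quartile estimator preserves the median exactly and
    matches the IQR in log width; when the printed quartiles are exactly
    lognormal-consistent the fitted quartiles reproduce them exactly.
    """
    if not (q1 > 0 and median > 0 and q3 > 0):
        raise InvalidInputError("median and quartiles must be > 0")
    if not q1 <= median <= q3:
        raise InvalidInputError(
            f"need q1 <= median <= q3, got ({q1}, {median}, {q3})"
        )
    sigma = (math.log(q3) - math.log(q1)) / (2.0 * Z75)
    return LognormalSpec(math.log(median), sigma, fitted_from=(median, q1, q3))


# ---------------------------------------------------------------------------
# closed-form tier probabilities (analytic oracle)


def _binorm_cdf(a: float, b: float, rho: float) -> float:
    """P(Z1 <= a, Z2 <= b) for standard bivariate normal, corr rho."""
    if a == -math.inf or b == -math.inf:
        return 0.0
    if a == math.inf and b == math.inf:
        return 1.0
    if a == math.inf:
        return float(norm.cdf(b))
    if b == math.inf:
        return float(norm.cdf(a))
    if rho == 0.0:
        return float(norm.cdf(a) * norm.cdf(b))
    return float(
        multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf(
            [a, b]
        )
    )


def tier_probabilities_closed_form(
    fib4: LognormalSpec,
    elf: LognormalSpec,
    rho: float = 0.0,
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
) -> Dict[Tier, float]:
    """Exact triage-tier probabilities under the log-scale Gaussian copula.

    P(F3-4)  = P(fib4 >= high) + P(fib4 in band, elf >= elf_high)
    P(F0-1)  = P(fib4 < low)   + P(fib4 in band, elf < elf_low)
    P(F2-4)  = P(fib4 in band, elf_low <= elf < elf_high)
    """
    if not -1.0 <= rho <= 1.0:
        raise InvalidInputError(f"rho must be in [-1, 1], got {rho}")
    zf_lo = fib4.zscore(cutoffs.fib4_low)
    zf_hi = fib4.zscore(cutoffs.fib4_high)
    ze_lo = elf.zscore(cutoffs.elf_low)
    ze_hi = elf.zscore(cutoffs.elf_high)

    def rect(zf_a, zf_b, ze_a, ze_b) -> float:
        # P(zf_a <= Zf < zf_b, ze_a <= Ze < ze_b)
        return (
            _binorm_cdf(zf_b, ze_b, rho)
            - _binorm_cdf(zf_a, ze_b, rho)
            - _binorm_cdf(zf_b, ze_a, rho)
            + _binorm_cdf(zf_a, ze_a, rho)
        )

    p_low_fib4 = float(norm.cdf(zf_lo)) if not math.isinf(zf_lo) else (
        1.0 if zf_lo > 0 else 0.0
    )
    p_high_fib4 = float(norm.sf(zf_hi)) if not math.isinf(zf_hi) else (
        0.0 if zf_hi > 0 else 1.0
    )

    neg_inf, pos_inf = -math.inf, math.inf
    p_f01 = p_low_fib4 + rect(zf_lo, zf_hi, neg_inf, ze_lo)
    p_f34 = p_high_fib4 + rect(zf_lo, zf_hi, ze_hi, pos_inf)
    p_f24 = rect(zf_lo, zf_hi, ze_lo, ze_hi)

    total = p_f01 + p_f24 + p_f34
    if abs(total - 1.0) > 1e-8:
        raise AssertionError(f"tier probabilities sum to {total}, not 1")
    return {
        Tier.F0_1: p_f01 / total,
        Tier.F2_4_INDETERMINATE: p_f24 / total,
        Tier.F3_4: p_f34 / total,
    }


# ---------------------------------------------------------------------------
# cohort specifications


@dataclass(frozen=True)
class CovariateSpec:
    """Demographic generation rules (not calibrated beyond printed summaries)."""

    age_mean: float = 57.0
    age_sd: float = 10.0
    female_rate: float = 0.50
    t2d_rate: Optional[float] = None  # None: t2d left unset


@dataclass(frozen=True)
class StageDistributionSpec:
    """One biopsy-stage stratum of a labelled cohort."""

    stage_label: str  # "F0_1" | "F2" | "F3_4"
    prevalence_count: int
    fib4: LognormalSpec
    elf: LognormalSpec
    te: Optional[LognormalSpec] = None
    rho: float = 0.0

    def __post_init__(self):
        if self.stage_label not in ("F0_1", "F2", "F3_4"):
            raise InvalidInputError(f"unknown stage label {self.stage_label!r}")
        if self.prevalence_count < 0:
            raise InvalidInputError("prevalence_count must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise InvalidInputError(f"rho must be in [-1, 1], got {self.rho}")


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic cohort.

    Labelled mode: ``stages`` present, per-stage counts exact (must sum to
    n). Unlabelled mode: marginal ``fib4``/``elf`` pair with copula ``rho``.
    """

    name: str
    n: int
    stages: Optional[Tuple[StageDistributionSpec, ...]] = None
    fib4: Optional[LognormalSpec] = None
    elf: Optional[LognormalSpec] = None
    rho: float = 0.0
    covariates: CovariateSpec = field(default_factory=CovariateSpec)

    def __post_init__(self):
        if self.n < 0:
            raise InvalidInputError("n must be >= 0")
        if self.stages is not None:
            total = sum(s.prevalence_count for s in self.stages)
            if total != self.n:
                raise InvalidInputError(
                    f"stage counts sum to {total}, cohort n = {self.n}"
                )
        elif self.fib4 is None or self.elf is None:
            raise InvalidInputError(
                "either stages or marginal fib4+elf specs are required"
            )

    @property
    def labelled(self) -> bool:
        return self.stages is not None


# ---------------------------------------------------------------------------
# sampling


def _bivariate_lognormal(
    rng: np.random.Generator,
    n: int,
    fib4: LognormalSpec,
    elf: LognormalSpec,
    rho: float,
) -> Tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * z2
    fib4_draws = np.exp(fib4.mu + fib4.sigma * z1)
    # ELF is reported within an assay plausibility window; truncate the
    # rare tail draws (mass ~1e-5 for the calibrated specs) to it
    elf_draws = np.clip(np.exp(elf.mu + elf.sigma * z2), *ELF_WINDOW)
    return fib4_draws, elf_draws


def _stage_to_fibrosis(
    rng: np.random.Generator, label: str, n: int
) -> np.ndarray:
    """Refine a coarse stage group into 0-4 stages (uniform within group)."""
    if label == "F0_1":
        return rng.integers(0, 2, size=n)
    if label == "F2":
        return np.full(n, 2)
    return 3 + rng.integers(0, 2, size=n)


def _histology(rng: np.random.Generator, stage: int) -> HistologyRecord:
    # uncalibrated CRN components; only fibrosis_stage carries truth
    return HistologyRecord(
        steatosis=int(rng.integers(0, 4)),
        lobular_inflammation=int(rng.integers(0, 4)),
        ballooning=int(rng.integers(0, 3)),
        fibrosis_stage=int(stage),
    )


def _covariates(
    rng: np.random.Generator, cov: CovariateSpec, n: int
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    age = np.clip(rng.normal(cov.age_mean, cov.age_sd, size=n), 18.0, 95.0)
    female = rng.random(n) < cov.female_rate
    t2d = None if cov.t2d_rate is None else rng.random(n) < cov.t2d_rate
    return age, female, t2d


def sample_cohort(spec: CohortSpec, seed: int) -> List[PatientRecord]:
    """Draw a cohort; the (spec, seed) pair fully determines the output.

    Stream splitting: the master seed spawns one child stream per stage (or
    one for the marginal pool) and, within each, separate generators for
    biomarkers, TE, histology refinement and covariates, so enabling TE
    sampling never perturbs the FIB-4/ELF draws.
    """
    master = np.random.SeedSequence(seed)
    records: List[PatientRecord] = []

    if spec.labelled:
        stage_seeds = master.spawn(len(spec.stages))
        idx = 0
        for stage_spec, ss in zip(spec.stages, stage_seeds):
            bio_ss, te_ss, hist_ss, cov_ss = ss.spawn(4)
            m = stage_spec.prevalence_count
            rng_bio = np.random.default_rng(bio_ss)
            fib4, elf = _bivariate_lognormal(
                rng_bio, m, stage_spec.fib4, stage_spec.elf, stage_spec.rho
            )
            rng_hist = np.random.default_rng(hist_ss)
            stages = _stage_to_fibrosis(rng_hist, stage_spec.stage_label, m)
            age, female, t2d = _covariates(
                np.random.default_rng(cov_ss), spec.covariates, m
            )
            te_stiff = None
            if stage_spec.te is not None:
                rng_te = np.random.default_rng(te_ss)
                z = rng_te.standard_normal(m)
                te_stiff = np.exp(stage_spec.te.mu + stage_spec.te.sigma * z)
                te_iqr = rng_te.uniform(0.05, 0.25, size=m)
            for j in range(m):
                te = None
                if te_stiff is not None:
                    te = TEMeasurement(
                        stiffness=float(te_stiff[j]),
                        iqr_over_median=float(te_iqr[j]),
                        n_measurements=10,
                    )
                records.append(
                    PatientRecord(
                        id=f"{spec.name}-{idx:06d}",
                        age=float(age[j]),
                        sex="female" if female[j] else "male",
                        fib4=float(fib4[j]),
                        elf=float(elf[j]),
                        t2d=bool(t2d[j]) if t2d is not None else None,
                        te=te,
                        histology=_histology(rng_hist, int(stages[j])),
                    )
                )
                idx += 1
    else:
        bio_ss, _te_ss, _hist_ss, cov_ss = master.spawn(4)
        rng_bio = np.random.default_rng(bio_ss)
        fib4, elf = _bivariate_lognormal(
            rng_bio, spec.n, spec.fib4, spec.elf, spec.rho
        )
        age, female, t2d = _covariates(
            np.random.default_rng(cov_ss), spec.covariates, spec.n
        )
        for j in range(spec.n):
            records.append(
                PatientRecord(
                    id=f"{spec.name}-{j:06d}",
                    age=float(age[j]),
                    sex="female" if female[j] else "male",
                    fib4=float(fib4[j]),
                    elf=float(elf[j]),
                    t2d=bool(t2d[j]) if t2d is not None else None,
                )
            )
    return records


def sample_fib4_components(
    target_fib4_spec: LognormalSpec, n: int, seed: int
) -> List[dict]:
    """Per-record (age, AST, ALT, platelets) consistent with a target FIB-4
    distribution.

    Age, ALT and platelets are drawn from plausible adult ranges; AST is
    back-solved so the recomputed FIB-4 equals the target draw, giving a
    round-trip fixture for the score computation.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: List[dict] = []
    if n == 0:
        return out
    z = rng.standard_normal(n)
    fib4_target = np.exp(target_fib4_spec.mu + target_fib4_spec.sigma * z)
    age = rng.uniform(25.0, 85.0, size=n)
    alt = np.exp(rng.normal(math.log(40.0), 0.4, size=n))
    platelets = np.clip(rng.normal(240.0, 60.0, size=n), 50.0, 600.0)
    ast = fib4_target * platelets * np.sqrt(alt) / age
    for j in range(n):
        fib4 = compute_fib4(
            float(age[j]), float(ast[j]), float(platelets[j]), float(alt[j])
        )
        out.append(
            {
                "age": float(age[j]),
                "ast": float(ast[j]),
                "alt": float(alt[j]),
                "platelets": float(platelets[j]),
                "fib4": fib4,
            }
        )
    return out


# ---------------------------------------------------------------------------
# bundled presets calibrated to the published summary tables


def nash_preset(n: Optional[int] = None, rho: float = 0.0) -> CohortSpec:
    """Biopsy-proven NASH-like cohort: stage counts 38/23/79 (n=140) with
    stage-conditional FIB-4/ELF/stiffness distributions."""
    base = {
        "F0_1": (38, (1.04, 0.85, 1.36), (8.93, 8.52, 9.47), (9.00, 7.90, 10.80)),
        "F2": (23, (1.50, 1.08, 1.82), (9.31, 8.83, 9.75), (9.65, 7.88, 12.45)),
        "F3_4": (79, (1.95, 1.44, 3.01), (10.10, 9.22, 10.91), (15.00, 10.95, 20.90)),
    }
    total = sum(c for c, *_ in base.values())
    scale = 1.0 if n is None else n / total
    stages = []
    counts = {k: v[0] for k, v in base.items()}
    if n is not None:
        counts = {k: round(v * scale) for k, v in counts.items()}
        drift = n - sum(counts.values())
        counts["F3_4"] += drift  # keep the total exact
    for label, (_, f, e, t) in base.items():
        stages.append(
            StageDistributionSpec(
                stage_label=label,
                prevalence_count=counts[label],
                fib4=fit_lognormal_from_quartiles(*f),
                elf=fit_lognormal_from_quartiles(*e),
                te=fit_lognormal_from_quartiles(*t),
                rho=rho,
            )
        )
    return CohortSpec(
        name="nash_table2",
        n=sum(counts.values()),
        stages=tuple(stages),
        covariates=CovariateSpec(
            age_mean=59.0, age_sd=10.0, female_rate=81 / 140, t2d_rate=0.66
        ),
    )


def t2d_preset(n: int = 141, rho: float = 0.0) -> CohortSpec:
    """Primary-care type-2-diabetes follow-up cohort (marginal biomarkers)."""
    return CohortSpec(
        name="t2d_table1",
        n=n,
        fib4=fit_lognormal_from_quartiles(1.19, 0.85, 1.53),
        elf=fit_lognormal_from_quartiles(9.66, 9.13, 10.23),
        rho=rho,
        covariates=CovariateSpec(
            age_mean=57.0, age_sd=10.0, female_rate=71 / 141, t2d_rate=1.0
        ),
    )


def cld_preset(n: int = 138, rho: float = 0.0) -> CohortSpec:
    """Primary-care chronic-liver-disease initial-study cohort."""
    return CohortSpec(
        name="cld_table1",
        n=n,
        fib4=fit_lognormal_from_quartiles(1.29, 0.92, 1.78),
        elf=fit_lognormal_from_quartiles(9.41, 8.90, 10.22),
        rho=rho,
        covariates=CovariateSpec(
            age_mean=56.0, age_sd=11.0, female_rate=68 / 138, t2d_rate=None
        ),
    )


PRESETS = {
    "nash_table2": nash_preset,
    "t2d_table1": t2d_preset,
    "cld_table1": cld_preset,
}


def preset(name: str, n: Optional[int] = None, rho: float = 0.0) -> CohortSpec:
    if name not in PRESETS:
        raise InvalidInputError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    if name == "nash_table2":
        return nash_preset(n=n, rho=rho)
    builder = PRESETS[name]
    return builder(rho=rho) if n is None else builder(n=n, rho=rho)
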