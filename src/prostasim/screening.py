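"""Screening strategies and the PSA → MRI → biopsy decision tree.

A strategy screens men from a start age (45/50/55/60) to the fixed end age
74 at a 1/2/3/5-year interval, with either a fixed 4.0 ng/mL PSA cutoff or
age-specific cutoffs (2/3/4/7 ng/mL for <50, 50-59, 60-69, >=70).  A PSA
above the cutoff triggers multiparametric MRI; PI-RADS >= 4 (modelled as a
binary test with the published sensitivity/specificity) triggers a targeted
biopsy; PSA above 10 ng/mL goes directly to systematic biopsy.  Biopsy
specificity is 1.0, so no false-positive diagnoses occur.  Adherence is
100% throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .natural_history import Individual, mean_log_psa
from .parameters import PsaGrowthParams, RiskStratification, TestCharacteristics

FIXED_4 = "fixed_4"
AGE_SPECIFIC = "age_specific"

#: left-closed age bands for the age-specific cutoffs
_AGE_BANDS = ((50, 2.0), (60, 3.0), (70, 4.0), (np.inf, 7.0))


@dataclass(frozen=True)
class ScreeningStrategy:
    """One screening protocol (or one arm of a risk-stratified protocol)."""

    name: str
    start_age: int = 45
    end_age: int = 74
    interval: int = 1
    cutoff_mode: str = FIXED_4
    active: bool = True                      # False = no screening for this arm
    # risk stratification
    risk_stratified: bool = False
    genetic_test: str = "none"               # none / prs / wgs
    high_risk_arm: Optional["ScreeningStrategy"] = None
    average_risk_arm: Optional["ScreeningStrategy"] = None

    def __post_init__(self) -> None:
        if self.active and self.start_age > self.end_age:
            raise ValueError("start_age must not exceed end_age")
        if self.active and self.interval < 1:
            raise ValueError("interval must be >= 1 year")
        if self.risk_stratified and self.genetic_test == "none":
            raise ValueError("risk-stratified strategies need a genetic test")

    @staticmethod
    def no_screening(name: str = "no_screening") -> "ScreeningStrategy":
        return ScreeningStrategy(name=name, active=False)

    @staticmethod
    def stratified(name: str, high_risk_arm: "ScreeningStrategy",
                   average_risk_arm: "ScreeningStrategy",
                   genetic_test: str = "prs") -> "ScreeningStrategy":
        return ScreeningStrategy(
            name=name, risk_stratified=True, genetic_test=genetic_test,
            high_risk_arm=high_risk_arm, average_risk_arm=average_risk_arm,
            active=high_risk_arm.active or average_risk_arm.active)

    def arm(self, risk_group: str) -> "ScreeningStrategy":
        """The schedule that applies to a man of the given risk group."""
        if not self.risk_stratified:
            return self
        return self.high_risk_arm if risk_group == "high" else self.average_risk_arm


def psa_threshold(age, cutoff_mode: str):
    """PSA test-positive threshold in ng/mL at the given age."""
    if cutoff_mode == FIXED_4:
        out = np.full(np.shape(age), 4.0) if np.ndim(age) else 4.0
        return out
    if cutoff_mode != AGE_SPECIFIC:
        raise ValueError(f"unknown cutoff mode {cutoff_mode!r}")
    age = np.asarray(age, float)
    out = np.select([age < 50, age < 60, age < 70], [2.0, 3.0, 4.0], default=7.0)
    return out if out.ndim else float(out)


def build_schedule(strategy: ScreeningStrategy, risk_group: str = "average"
                   ) -> np.ndarray:
    """Sorted integer screening ages for the applicable arm; empty if none."""
    arm = strategy.arm(risk_group)
    if arm is None or not arm.active:
        return np.array([], int)
    return np.arange(arm.start_age, arm.end_age + 1, arm.interval)


@dataclass
class VisitOutcome:
    outcome: str                 # negative / mri_negative / biopsy_negative / screen_detected
    psa_value: float
    n_psa: int = 1
    n_mri: int = 0
    n_biopsy: int = 0


def screening_visit(individual: Individual, age: float,
                    strategy: ScreeningStrategy,
                    tests: TestCharacteristics = TestCharacteristics(),
                    psa_params: PsaGrowthParams = PsaGrowthParams(),
                    rng: np.random.Generator | None = None) -> VisitOutcome:
    """One screening visit for one man (scalar reference path).

    The vectorized engine implements the same cascade over arrays; this
    function is the readable single-individual version used for unit tests
    and event-level traces.
    """
    rng = rng or np.random.default_rng()
    if individual.diagnosed:
        raise ValueError("screening a diagnosed individual")
    if age >= individual.other_cause_death_age:
        raise ValueError("screening a dead individual")

    has_cancer = individual.onset_age is not None and individual.onset_age <= age
    onset = individual.onset_age if has_cancer else None
    grade = individual.grade if has_cancer else None
    eps = rng.normal(0.0, psa_params.sigma_eps)
    psa_value = float(np.exp(mean_log_psa(age, onset, grade, psa_params) + eps))

    arm = strategy.arm(individual.risk_group)
    threshold = psa_threshold(age, arm.cutoff_mode)
    visit = VisitOutcome("negative", psa_value)
    if psa_value <= threshold:
        return visit

    if psa_value > tests.direct_biopsy_psa:
        biopsy = True                      # systematic biopsy, no MRI triage
    else:
        visit.n_mri = 1
        p_mri_pos = tests.mri_sens if has_cancer else 1.0 - tests.mri_spec
        if rng.random() >= p_mri_pos:
            visit.outcome = "mri_negative"
            return visit
        biopsy = True

    if biopsy:
        visit.n_biopsy = 1
        p_detect = tests.biopsy_sens if has_cancer else 1.0 - tests.biopsy_spec
        if rng.random() < p_detect:
            visit.outcome = "screen_detected"
            individual.diagnosed = True
            individual.diagnosis_age = age
            met = individual.metastasis_age
            individual.stage_at_diagnosis = (
                "metastatic" if met is not None and met <= age else "localized")
        else:
            visit.outcome = "biopsy_negative"
    return visit


def stratify_population(n: int, risk: RiskStratification,
                        rng: np.random.Generator,
                        family_history_prevalence_zero: bool = False,
                        zero_fh_fraction: float | None = None) -> np.ndarray:
    """Assign risk groups: True = high risk, expected share high_risk_fraction.

    The zero-family-history scenario replaces the fraction by
    ``zero_fh_fraction`` (PRS-top-quartile and rare-mutation carriers only).
    """
    frac = risk.high_risk_fraction
    if family_history_prevalence_zero:
        if zero_fh_fraction is None:
            raise ValueError("zero-family-history scenario needs its fraction")
        frac = zero_fh_fraction
    return rng.random(n) < frac
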