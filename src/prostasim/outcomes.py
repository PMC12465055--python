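"""Clinical outcome metrics and harm-benefit trade-off counts.

Average incidence and metastatic-at-detection rates are pooled person-time
rates (incidence density): total events over total person-years lived at
ages 45-84 across the horizon, per 100,000.  The M/I ratio is the share of
incident cases already metastatic at diagnosis.  The annual case-fatality
rate divides prostate-cancer deaths by the person-years lived by diagnosed
patients (prevalent cases), pooled over the horizon; the per-year trace of
annual ratios is also reported.  By
default every death occurring in a Markov disease state counts as a
prostate-cancer death (the transition probabilities were estimated from
complete follow-up of a diagnosed cohort); attribution can be restricted
to deaths from the metastatic states.

"Lives gained" in the harm-benefit comparison are averted all-cause deaths
within the horizon — men alive under the strategy who would have died
under the baseline.  With heavy overdiagnosis the in-state death count can
rise even as survival improves (more men die inside the prognosis model
simply because more men are in it), so in-state death attributions can
yield negative values; they remain available as options.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .engine import ScenarioResult


@dataclass(frozen=True)
class ClinicalOutcomes:
    avg_incidence_per_100k: float
    metastatic_at_detection_per_100k: float
    mi_ratio: Optional[float]          # %, None when no diagnoses
    annual_cfr: Optional[float]        # %, None when never any prevalent patients
    incidence_trace: np.ndarray        # per-year incidence per 100k
    metastatic_trace: np.ndarray
    cfr_trace: np.ndarray              # per-year CFR %, NaN where undefined


@dataclass(frozen=True)
class HarmBenefit:
    extra_psa_tests: float
    extra_biopsies: float
    extra_treatments: float
    lives_gained: float
    tests_per_life_gained: Optional[float]
    biopsies_per_life_gained: Optional[float]
    treatments_per_life_gained: Optional[float]


def clinical_metrics(result: "ScenarioResult",
                     death_attribution: str = "all") -> ClinicalOutcomes:
    """Compute the headline clinical metrics from a scenario's tallies."""
    py = result.person_years_window
    if py.sum() <= 0:
        raise ValueError("no person-years in the 45-84 window")
    with np.errstate(divide="ignore", invalid="ignore"):
        inc_trace = np.where(py > 0, result.diagnoses_window / py, np.nan) * 1e5
        met_trace = np.where(py > 0, result.met_diagnoses_window / py, np.nan) * 1e5
    avg_inc = float(result.diagnoses_window.sum() / py.sum() * 1e5)
    avg_met = float(result.met_diagnoses_window.sum() / py.sum() * 1e5)

    total_diag = result.diagnoses_window.sum()
    mi = (float(result.met_diagnoses_window.sum() / total_diag * 100.0)
          if total_diag > 0 else None)

    deaths = result.pca_deaths(death_attribution)
    denom = result.diagnosed_person_years
    with np.errstate(divide="ignore", invalid="ignore"):
        cfr_trace = np.where(denom > 0, deaths / denom, np.nan) * 100.0
    # person-time estimator: stable even when the early prevalent pool is tiny
    cfr = (float(deaths.sum() / denom.sum() * 100.0)
           if denom.sum() > 0 else None)

    return ClinicalOutcomes(avg_inc, avg_met, mi, cfr,
                            inc_trace, met_trace, cfr_trace)


def harm_benefit(strategy_result: "ScenarioResult",
                 baseline_result: "ScenarioResult",
                 death_attribution: str = "total") -> HarmBenefit:
    """Extra tests/biopsies/treatments per life gained vs the baseline.

    Lives gained are deaths averted over the horizon: all-cause deaths by
    default (``"total"``), or averted Markov-state deaths under the
    ``"all"`` / ``"metastatic"`` attributions.  Ratios are undefined
    (None) when no lives are gained.
    """
    if strategy_result.n != baseline_result.n:
        raise ValueError("strategy and baseline must share the population")
    extra_tests = strategy_result.n_psa_tests - baseline_result.n_psa_tests
    extra_biopsies = strategy_result.n_biopsies - baseline_result.n_biopsies
    extra_treatments = strategy_result.n_treatments - baseline_result.n_treatments
    if death_attribution == "total":
        lives = float(baseline_result.total_deaths_window
                      - strategy_result.total_deaths_window)
    else:
        lives = float(baseline_result.pca_deaths(death_attribution).sum()
                      - strategy_result.pca_deaths(death_attribution).sum())

    def ratio(x: float) -> Optional[float]:
        return x / lives if lives > 0 else None

    return HarmBenefit(extra_tests, extra_biopsies, extra_treatments, lives,
                       ratio(extra_tests), ratio(extra_biopsies),
                       ratio(extra_treatments))
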