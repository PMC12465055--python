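"""Screening decision tree: thresholds, schedules, visit cascade, stratification."""

import numpy as np
import pytest

from prostasim import (HIGH_RISK, PsaGrowthParams, RiskStratification,
                       ScreeningStrategy, TestCharacteristics, build_schedule,
                       psa_threshold, screening_visit, stratify_population)
from prostasim.natural_history import Individual
from prostasim.screening import AGE_SPECIFIC, FIXED_4


class TestThresholds:
    @pytest.mark.parametrize("age, expected", [
        (48, 2.0), (55, 3.0), (65, 4.0), (72, 7.0),
        (50, 3.0), (60, 4.0), (70, 7.0),   # left-closed band edges
        (49, 2.0), (59, 3.0), (69, 4.0),
    ])
    def test_age_specific_bands(self, age, expected):
        assert psa_threshold(age, AGE_SPECIFIC) == expected

    @pytest.mark.parametrize("age", [45, 60, 74])
    def test_fixed_cutoff(self, age):
        assert psa_threshold(age, FIXED_4) == 4.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            psa_threshold(50, "bogus")


class TestSchedules:
    def test_three_screens_every_five_years_from_60(self):
        s = ScreeningStrategy("lc", 60, 74, 5, FIXED_4)
        assert build_schedule(s).tolist() == [60, 65, 70]

    def test_annual_from_45_gives_30_visits(self):
        s = ScreeningStrategy("a", 45, 74, 1, FIXED_4)
        assert build_schedule(s).size == 30

    def test_inactive_arm_has_empty_schedule(self):
        assert build_schedule(ScreeningStrategy.no_screening()).size == 0

    def test_stratified_arms_resolve_by_risk_group(self):
        strat = ScreeningStrategy.stratified(
            "s", ScreeningStrategy("hr", 45, 74, 1),
            ScreeningStrategy.no_screening("avg"), "prs")
        assert build_schedule(strat, "high").size == 30
        assert build_schedule(strat, "average").size == 0

    def test_stratified_requires_genetic_test(self):
        with pytest.raises(ValueError):
            ScreeningStrategy(name="bad", risk_stratified=True)


def _man(onset=None, grade=None, met=None):
    return Individual(0, 50.0, grade=grade, onset_age=onset, metastasis_age=met,
                      other_cause_death_age=120.0)


class TestVisit:
    strategy = ScreeningStrategy("a", 45, 74, 1, FIXED_4)

    def test_psa_below_threshold_is_negative(self):
        psa = PsaGrowthParams(sigma_eps=0.0)   # healthy median at 50 is 2.6
        visit = screening_visit(_man(), 50.0, self.strategy, psa_params=psa,
                                rng=np.random.default_rng(0))
        assert visit.outcome == "negative"
        assert (visit.n_psa, visit.n_mri, visit.n_biopsy) == (1, 0, 0)

    def test_detection_probability_is_mri_times_biopsy_sensitivity(self):
        """Cancer on the MRI pathway detects with 0.89 x 0.64 = 0.5696."""
        rng = np.random.default_rng(42)
        n, hits, path = 100_000, 0, 0
        psa = PsaGrowthParams(sigma_eps=0.3)
        for _ in range(n):
            man = _man(onset=55.0, grade=HIGH_RISK)
            visit = screening_visit(man, 66.0, self.strategy, psa_params=psa, rng=rng)
            if visit.psa_value > 4.0 and visit.psa_value <= 10.0:
                path += 1
                hits += visit.outcome == "screen_detected"
        p = hits / path
        se = np.sqrt(0.5696 * (1 - 0.5696) / path)
        assert abs(p - 0.5696) < 3 * se

    def test_no_false_positive_diagnoses(self):
        """Perfect biopsy specificity: a cancer-free man is never diagnosed."""
        rng = np.random.default_rng(1)
        biopsies = 0
        for _ in range(30_000):
            man = _man()
            visit = screening_visit(man, 74.0, self.strategy, rng=rng)
            biopsies += visit.n_biopsy
            assert visit.outcome != "screen_detected"
            assert not man.diagnosed
        assert biopsies > 0   # the pathway was actually exercised

    def test_stage_set_by_metastasis_status(self):
        rng = np.random.default_rng(2)
        for met, stage in [(60.0, "metastatic"), (None, "localized")]:
            while True:
                man = _man(onset=55.0, grade=HIGH_RISK, met=met)
                screening_visit(man, 72.0, self.strategy, rng=rng)
                if man.diagnosed:
                    assert man.stage_at_diagnosis == stage
                    break

    def test_visit_on_diagnosed_or_dead_man_rejected(self):
        man = _man()
        man.diagnosed = True
        with pytest.raises(ValueError):
            screening_visit(man, 60.0, self.strategy)
        dead = _man()
        dead.other_cause_death_age = 55.0
        with pytest.raises(ValueError):
            screening_visit(dead, 60.0, self.strategy)


class TestStratification:
    def test_fraction_recovered(self, rng):
        n = 100_000
        high = stratify_population(n, RiskStratification(), rng)
        se = np.sqrt(0.332 * 0.668 / n)
        assert abs(high.mean() - 0.332) < 3 * se

    def test_zero_fraction_all_average(self, rng):
        assert not stratify_population(1000, RiskStratification(high_risk_fraction=0.0),
                                       rng).any()

    def test_prs_cost_arithmetic(self):
        assert 1000 * RiskStratification().prs_cost == pytest.approx(16_810.0)

    def test_zero_family_history_scenario(self, rng):
        n = 100_000
        high = stratify_population(n, RiskStratification(), rng,
                                   family_history_prevalence_zero=True,
                                   zero_fh_fraction=0.25)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(high.mean() - 0.25) < 3 * se
        with pytest.raises(ValueError):
            stratify_population(10, RiskStratification(), rng,
                                family_history_prevalence_zero=True)
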