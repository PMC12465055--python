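"""Scenario engine: determinism, common random numbers, strategy grid."""

import numpy as np
import pytest

from prostasim import (ScreeningStrategy, SyntheticConfig, clinical_metrics,
                       icer, make_population, run_grid, run_scenario,
                       simulate_cohort, strategy_grid)
from prostasim.engine import conventional_grid, risk_stratified_grid
from prostasim.screening import AGE_SPECIFIC, FIXED_4


@pytest.fixture(scope="module")
def cohort():
    pyramid, life = make_population(SyntheticConfig(n_individuals=30_000))
    return simulate_cohort(30_000, pyramid, life, seed=17)


def results_equal(a, b):
    assert a.total_cost == b.total_cost
    assert a.total_qalys == b.total_qalys
    assert np.array_equal(a.diagnoses_window, b.diagnoses_window)
    assert np.array_equal(a.pca_deaths_all, b.pca_deaths_all)
    assert a.n_psa_tests == b.n_psa_tests
    assert a.n_biopsies == b.n_biopsies


class TestDeterminism:
    def test_same_seed_reproduces_bitwise(self, cohort):
        s = ScreeningStrategy("a", 50, 74, 2, FIXED_4)
        results_equal(run_scenario(cohort, s, seed=5),
                      run_scenario(cohort, s, seed=5))

    def test_empty_schedule_equals_no_screening(self, cohort):
        """A strategy that never screens reproduces the baseline exactly."""
        baseline = run_scenario(cohort, ScreeningStrategy.no_screening(), seed=5)
        inert = ScreeningStrategy("inert", active=False)
        results_equal(run_scenario(cohort, inert, seed=5), baseline)

    def test_cohort_generation_deterministic(self):
        pyramid, life = make_population(SyntheticConfig(n_individuals=5000))
        a = simulate_cohort(5000, pyramid, life, seed=3)
        b = simulate_cohort(5000, pyramid, life, seed=3)
        assert np.array_equal(a.onset_age, b.onset_age)
        assert np.array_equal(a.clinical_detection_age, b.clinical_detection_age)
        assert np.array_equal(a.screen_eps, b.screen_eps)


class TestCommonRandomNumbers:
    def test_latent_timelines_shared_across_strategies(self, cohort):
        """The latent cohort object is reused: screening changes detection
        timing only, so clinical-detection and onset ages are untouched."""
        before = cohort.onset_age.copy()
        run_scenario(cohort, ScreeningStrategy("a", 45, 74, 1, FIXED_4), seed=5)
        assert np.array_equal(cohort.onset_age, before)

    def test_shorter_interval_never_reduces_psa_tests(self, cohort):
        tests = []
        for interval in (5, 3, 2, 1):
            s = ScreeningStrategy(f"i{interval}", 50, 74, interval, FIXED_4)
            tests.append(run_scenario(cohort, s, seed=5).n_psa_tests)
        assert all(b >= a for a, b in zip(tests, tests[1:]))

    def test_screening_cannot_worsen_stage_at_fixed_seed(self, cohort):
        base = run_scenario(cohort, ScreeningStrategy.no_screening(), seed=5)
        screened = run_scenario(cohort, ScreeningStrategy("a", 45, 74, 1,
                                                          FIXED_4), seed=5)
        assert screened.met_diagnoses_window.sum() <= base.met_diagnoses_window.sum()


class TestStrategyGrid:
    def test_conventional_grid_is_full_cartesian_product(self):
        grid = conventional_grid()
        assert len(grid) == 32
        assert len({s.name for s in grid}) == 32

    def test_full_grid_reaches_published_strategy_count(self):
        grid = strategy_grid()
        assert len(grid) >= 56
        assert len({s.name for s in grid}) == len(grid)

    def test_risk_stratified_arms_structure(self):
        for s in risk_stratified_grid():
            assert s.risk_stratified and s.genetic_test in ("prs", "wgs")
            assert s.high_risk_arm.start_age == 45
            assert s.high_risk_arm.interval == 1

    def test_run_grid_row_count_matches_strategies(self, cohort):
        strategies = [ScreeningStrategy("x", 60, 74, 5, FIXED_4),
                      ScreeningStrategy("y", 55, 74, 3, AGE_SPECIFIC)]
        table = run_grid(cohort, strategies, seed=5)
        assert len(table) == 2
        assert set(table["strategy"]) == {"x", "y"}


class TestDoseResponse:
    def test_earlier_start_never_reduces_qaly_gain(self, cohort):
        """Annual screening from 45 gains at least as many QALYs as from 50."""
        base = run_scenario(cohort, ScreeningStrategy.no_screening(), seed=5)
        gains = []
        for start in (50, 45):
            r = run_scenario(cohort, ScreeningStrategy(f"s{start}", start, 74, 1,
                                                       AGE_SPECIFIC), seed=5)
            gains.append(r.qalys_per_capita - base.qalys_per_capita)
        assert gains[1] >= gains[0]

    def test_all_strategies_gain_qalys(self, cohort):
        base = run_scenario(cohort, ScreeningStrategy.no_screening(), seed=5)
        for s in [ScreeningStrategy("lc", 60, 74, 5, FIXED_4),
                  ScreeningStrategy("hi", 45, 74, 1, AGE_SPECIFIC)]:
            r = run_scenario(cohort, s, seed=5)
            assert r.qalys_per_capita > base.qalys_per_capita

    def test_screening_incidence_stabilises_after_initial_rise(self, cohort):
        """Universal screening raises incidence sharply in early years,
        then the rate levels off rather than growing without bound."""
        r = run_scenario(cohort, ScreeningStrategy("a", 45, 74, 1, FIXED_4),
                         seed=5)
        trace = r.diagnoses_window / r.person_years_window * 1e5
        early_peak = trace[:12].max()
        late_mean = trace[-10:].mean()
        assert early_peak > 0
        assert late_mean < 1.6 * early_peak


class TestRiskStratified:
    def test_prs_cost_charged_once_per_man(self, cohort):
        inert_arms = ScreeningStrategy.stratified(
            "inert", ScreeningStrategy.no_screening("h"),
            ScreeningStrategy.no_screening("a"), "prs")
        base = run_scenario(cohort, ScreeningStrategy.no_screening(), seed=5)
        r = run_scenario(cohort, inert_arms, seed=5)
        assert r.total_cost - base.total_cost == pytest.approx(
            cohort.n * 16.81)
        assert r.total_qalys == base.total_qalys

    def test_arms_screen_disjoint_groups(self, cohort):
        hr_only = ScreeningStrategy.stratified(
            "hr_only", ScreeningStrategy("h", 45, 74, 1, FIXED_4),
            ScreeningStrategy.no_screening("a"), "prs")
        avg_only = ScreeningStrategy.stratified(
            "avg_only", ScreeningStrategy.no_screening("h"),
            ScreeningStrategy("a", 45, 74, 1, FIXED_4), "prs")
        both = ScreeningStrategy.stratified(
            "both", ScreeningStrategy("h", 45, 74, 1, FIXED_4),
            ScreeningStrategy("a", 45, 74, 1, FIXED_4), "prs")
        n_hr = run_scenario(cohort, hr_only, seed=5).n_psa_tests
        n_avg = run_scenario(cohort, avg_only, seed=5).n_psa_tests
        n_both = run_scenario(cohort, both, seed=5).n_psa_tests
        assert n_hr + n_avg == n_both
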