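"""Latent disease process: PSA growth curve, event-time samplers, oracles."""

import numpy as np
import pytest
from scipy import integrate, stats

from prostasim import (HIGH_RISK, LOW_RISK, NaturalHistoryParams,
                       PsaGrowthParams, assign_grade, mean_log_psa,
                       sample_onset_age, sample_psa)
from prostasim.natural_history import (Individual, detection_cumulative_hazard,
                                       exp_psa_integral, exp_psa_integral_inv,
                                       onset_cumulative_hazard,
                                       sample_detection_age,
                                       sample_metastasis_age,
                                       sample_progression)

NH = NaturalHistoryParams()
PSA = PsaGrowthParams()


class TestMeanLogPsa:
    @pytest.mark.parametrize("age, onset, grade, expected", [
        (50.0, None, None, -0.1061 + 0.0215 * 50),       # healthy at 50 -> 0.9689
        (0.0, None, None, -0.1061),                      # intercept
        (65.0, 60.0, HIGH_RISK, -0.1061 + 0.0215 * 65 + 0.1051 * 5),
        (65.0, 60.0, LOW_RISK, -0.1061 + 0.0215 * 65 + 0.0566 * 5),
        (55.0, 60.0, HIGH_RISK, -0.1061 + 0.0215 * 55),  # before onset: healthy line
    ])
    def test_change_point_closed_form(self, age, onset, grade, expected):
        assert mean_log_psa(age, onset, grade) == pytest.approx(expected, abs=1e-12)

    def test_median_psa_at_50_is_2_635(self):
        assert np.exp(mean_log_psa(50.0)) == pytest.approx(2.635, abs=5e-3)

    def test_grade_required_with_onset(self):
        with pytest.raises(ValueError):
            mean_log_psa(65.0, 60.0, None)


class TestSamplePsa:
    def test_degenerate_noise_is_exact(self, rng):
        psa = PsaGrowthParams(sigma_eps=0.0)
        assert sample_psa(50.0, psa=psa, rng=rng) == pytest.approx(
            np.exp(0.9689), abs=1e-9)

    def test_always_positive(self, rng):
        vals = sample_psa(np.full(1000, 80.0), np.full(1000, 45.0),
                          np.full(1000, HIGH_RISK, dtype=object), PSA, rng)
        assert (vals > 0).all()

    def test_log_mean_matches_closed_form(self, rng):
        n = 100_000
        vals = sample_psa(np.full(n, 50.0), psa=PSA, rng=rng)
        se = PSA.sigma_eps / np.sqrt(n)
        assert abs(np.log(vals).mean() - 0.9689) < 3 * se


class TestOnset:
    def test_zero_hazard_never_onsets(self, rng):
        out = sample_onset_age(NaturalHistoryParams(gamma_o=0.0), rng=rng)
        assert out is None

    def test_cumulative_onset_matches_closed_form(self, rng):
        n = 100_000
        ages = sample_onset_age(NH, 40.0, rng, size=n)
        p = 1 - np.exp(-NH.gamma_o * (70 ** 2 - 40 ** 2) / 2)
        assert p == pytest.approx(0.327, abs=5e-3)
        se = np.sqrt(p * (1 - p) / n)
        assert abs((ages <= 70).mean() - p) < 3 * se

    def test_smaller_hazard_gives_stochastically_later_onset(self, rng):
        n = 100_000
        u = rng.exponential(size=n)
        t_hi = np.sqrt(40 ** 2 + 2 * u / NH.gamma_o)
        t_lo = np.sqrt(40 ** 2 + 2 * u / (NH.gamma_o / 2))
        assert (t_lo >= t_hi).all()   # first-order dominance, common draws


class TestGrade:
    def test_degenerate_proportions(self, rng):
        assert assign_grade(1.0, rng) == LOW_RISK
        assert assign_grade(0.0, rng) == HIGH_RISK

    def test_published_proportion_binomial(self, rng):
        n = 100_000
        grades = assign_grade(NH.gamma_lr, rng, size=n)
        frac = (grades == LOW_RISK).mean()
        se = np.sqrt(0.673 * 0.327 / n)
        assert abs(frac - 0.673) < 3 * se

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_grade(1.2, rng)


class TestProgression:
    def test_zero_hazards_never_progress(self, rng):
        nh0 = NaturalHistoryParams(gamma_m=0.0, gamma_c=0.0)
        ind = Individual(0, 50.0, grade=HIGH_RISK, onset_age=55.0)
        met, det = sample_progression(ind, nh0, PSA, rng)
        assert met is None and det is None

    def test_requires_onset(self, rng):
        with pytest.raises(ValueError):
            sample_progression(Individual(0, 50.0), NH, PSA, rng)

    def test_event_ordering_invariant(self, rng):
        n = 20_000
        onset = np.full(n, 55.0)
        ax = np.full(n, PSA.a2)
        tm = sample_metastasis_age(onset, ax, NH, PSA, rng, size=n)
        td = sample_detection_age(onset, tm, ax, NH, PSA, rng, size=n)
        assert (tm >= onset).all()
        assert (td >= onset).all()

    def test_survival_matches_quadrature_oracle(self, rng):
        """Empirical metastasis-time survival vs exp(-integral lambda_m) by
        numerical quadrature of the hazard exp(P(t)) * gamma_m."""
        n = 100_000
        onset = 60.0
        ax = PSA.a2
        tm = sample_metastasis_age(np.full(n, onset), np.full(n, ax),
                                   NH, PSA, rng, size=n)
        for t in (65.0, 70.0, 75.0, 80.0, 85.0):
            lam, _ = integrate.quad(
                lambda u: NH.gamma_m * np.exp(mean_log_psa(u, onset, HIGH_RISK)),
                onset, t)
            expected = np.exp(-lam)
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs((tm > t).mean() - expected) < 4 * se

    def test_detection_survival_with_boost_matches_quadrature(self, rng):
        """Detection survival honouring the post-metastasis hazard boost."""
        n = 100_000
        onset, tm_fixed = 60.0, 68.0
        ax = PSA.a1
        td = sample_detection_age(np.full(n, onset), np.full(n, tm_fixed),
                                  np.full(n, ax), NH, PSA, rng, size=n)
        for t in (66.0, 72.0, 78.0):
            def hazard(u):
                boost = NH.theta_c if u > tm_fixed else 1.0
                return NH.gamma_c * boost * np.exp(mean_log_psa(u, onset, LOW_RISK))
            lam, _ = integrate.quad(hazard, onset, t, points=[tm_fixed])
            expected = np.exp(-lam)
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs((td > t).mean() - expected) < 4 * se

    def test_unit_multiplier_leaves_detection_distribution_unchanged(self, rng):
        """With theta_c = 1 the metastasis time must not influence detection."""
        n = 50_000
        nh1 = NaturalHistoryParams(theta_c=1.0)
        onset = np.full(n, 60.0)
        ax = np.full(n, PSA.a1)
        early_met = sample_detection_age(onset, np.full(n, 61.0), ax, nh1, PSA,
                                         np.random.default_rng(7), size=n)
        late_met = sample_detection_age(onset, np.full(n, 95.0), ax, nh1, PSA,
                                        np.random.default_rng(11), size=n)
        ks = stats.ks_2samp(early_met, late_met)
        assert ks.pvalue > 0.01

    def test_published_multiplier_accelerates_detection(self, rng):
        """theta_c = 19.1334 shortens metastasis-to-detection delay (paired)."""
        n = 50_000
        onset = np.full(n, 60.0)
        tm = np.full(n, 65.0)
        ax = np.full(n, PSA.a2)
        boosted = sample_detection_age(onset, tm, ax, NH, PSA,
                                       np.random.default_rng(3), size=n)
        flat = sample_detection_age(onset, tm, ax, NaturalHistoryParams(theta_c=1.0),
                                    PSA, np.random.default_rng(3), size=n)
        assert np.median(boosted) < np.median(flat)

    def test_conditioning_on_entry_age_excludes_earlier_detection(self, rng):
        n = 20_000
        onset = np.full(n, 45.0)
        tm = np.full(n, np.inf)
        ax = np.full(n, PSA.a2)
        td = sample_detection_age(onset, tm, ax, NH, PSA, rng, size=n,
                                  condition_age=np.full(n, 70.0))
        assert (td > 70.0).all()

    def test_doubling_gamma_c_halves_median_delay_with_frozen_psa(self):
        """In a constant-PSA regime detection is exponential, so doubling
        gamma_c exactly halves the median onset-to-detection delay."""
        flat = PsaGrowthParams(a0=0.0, a1=0.0, a2=0.0, b=0.5)
        n = 200_000
        onset = np.full(n, 60.0)
        tm = np.full(n, np.inf)
        ax = np.zeros(n)
        base = sample_detection_age(onset, tm, ax, NH, flat,
                                    np.random.default_rng(5), size=n)
        doubled = sample_detection_age(
            onset, tm, ax, NaturalHistoryParams(gamma_c=2 * NH.gamma_c), flat,
            np.random.default_rng(5), size=n)
        ratio = np.median(doubled - 60.0) / np.median(base - 60.0)
        assert ratio == pytest.approx(0.5, rel=1e-9)   # common draws: exact


def test_cumulative_hazard_inverse_round_trip():
    t = np.array([61.0, 70.0, 95.0])
    onset = np.full(3, 60.0)
    ax = np.full(3, PSA.a2)
    vals = exp_psa_integral(t, onset, ax, PSA)
    back = exp_psa_integral_inv(vals, onset, ax, PSA)
    assert np.allclose(back, t, rtol=1e-10)


def test_onset_cumulative_hazard_quadratic_form():
    assert onset_cumulative_hazard(70.0, NH.gamma_o, 40.0) == pytest.approx(
        NH.gamma_o * (70 ** 2 - 40 ** 2) / 2)
    assert onset_cumulative_hazard(30.0, NH.gamma_o, 40.0) == 0.0
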