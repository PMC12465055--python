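"""Hazard grid search and MCMC recovery of the PSA growth parameters."""

import numpy as np
import pandas as pd
import pytest

from prostasim import (IncidenceCurve, NaturalHistoryParams, PsaGrowthParams,
                       SyntheticConfig, grid_search_hazards, incidence_curve,
                       mae, make_hazard_simulator, make_population,
                       make_reference_incidence, make_screening_trial,
                       mcmc_calibrate_psa, multiplier_grid)


class TestMultiplierGrid:
    def test_sixteen_stride_values(self):
        strides = np.arange(1.0, 4.01, 0.2)
        assert strides.size == 16

    def test_combined_candidate_set_has_31_values(self):
        grid = multiplier_grid()
        assert grid.size == 31          # 2 x 16 - 1 (1.0 counted once)
        assert np.unique(grid).size == 31

    def test_endpoints(self):
        grid = multiplier_grid()
        assert grid.min() == pytest.approx(0.25)
        assert grid.max() == pytest.approx(4.0)


class TestMae:
    bands = ((45, 49), (50, 54))

    def test_identical_curves(self):
        c = IncidenceCurve(self.bands, np.array([10.0, 20.0]))
        assert mae(c, c) == 0.0

    def test_constant_offset(self):
        a = IncidenceCurve(self.bands, np.array([10.0, 20.0]))
        b = IncidenceCurve(self.bands, np.array([15.0, 25.0]))
        assert mae(a, b) == 5.0

    def test_mixed_offsets(self):
        a = IncidenceCurve(self.bands, np.array([10.0, 20.0]))
        b = IncidenceCurve(self.bands, np.array([12.0, 16.0]))
        assert mae(a, b) == pytest.approx(3.0)

    def test_band_mismatch_rejected(self):
        a = IncidenceCurve(self.bands, np.array([1.0, 2.0]))
        b = IncidenceCurve(((45, 49), (50, 59)), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            mae(a, b)


class TestGridSearch:
    config = SyntheticConfig(n_individuals=4000, seed=9)

    def _simulator(self):
        pyramid, life = make_population(self.config)
        return make_hazard_simulator(NaturalHistoryParams(), PsaGrowthParams(),
                                     pyramid, life, n=4000, seed=9)

    def test_self_consistent_reference_recovers_unity(self):
        sim = self._simulator()
        result = grid_search_hazards(NaturalHistoryParams(), sim, sim(1.0, 1.0),
                                     candidates=np.array([0.5, 1.0, 2.0]))
        assert result.best_multipliers == (1.0, 1.0)
        assert result.best_mae == 0.0

    def test_planted_multipliers_recovered_exactly(self):
        """Reference generated at (2.0, 0.5) is identified over the full grid."""
        sim = self._simulator()
        reference = make_reference_incidence(self.config, (2.0, 0.5), n=4000)
        result = grid_search_hazards(NaturalHistoryParams(), sim, reference)
        assert result.best_multipliers == (2.0, 0.5)

    def test_returned_mae_is_grid_minimum(self):
        sim = self._simulator()
        reference = make_reference_incidence(self.config, (1.2, 1.0), n=4000)
        result = grid_search_hazards(NaturalHistoryParams(), sim, reference,
                                     candidates=np.array([0.5, 1.0, 1.2, 2.0]))
        assert result.best_mae == result.grid["mae"].min()
        assert len(result.grid) == 16

    def test_failing_candidate_is_skipped_with_record(self):
        calls = {}

        def sim(m1, m2):
            if (m1, m2) == (2.0, 2.0):
                raise RuntimeError("boom")
            return IncidenceCurve(((45, 49),), np.array([abs(m1 - 1) + abs(m2 - 1)]))

        ref = IncidenceCurve(((45, 49),), np.array([0.0]))
        with pytest.warns(UserWarning):
            result = grid_search_hazards(NaturalHistoryParams(), sim, ref,
                                         candidates=np.array([1.0, 2.0]))
        assert result.best_multipliers == (1.0, 1.0)
        assert (2.0, 2.0, "boom") in result.skipped


class TestMcmc:
    def test_parameter_recovery_on_synthetic_trial(self):
        """Posterior concentrates near the generating values (small run)."""
        trial = make_screening_trial(SyntheticConfig(seed=4), n_subjects=600,
                                     visits_per_subject=5)
        post = mcmc_calibrate_psa(trial, n_walkers=24, n_steps=800, seed=4)
        truth = {"a0": 0.0215, "a1": 0.0566, "a2": 0.1051, "b": -0.1061,
                 "sigma_eps": 0.2}
        for name, value in truth.items():
            mean = post.samples[name].mean()
            sd = post.samples[name].std()
            assert abs(mean - value) < 4 * sd, f"{name}: {mean} vs {value} (sd {sd})"

    def test_posterior_tightens_with_more_data(self):
        """Doubling the trial size shrinks the posterior spread (bias -> 0)."""
        sds = []
        for n_sub in (300, 1200):
            trial = make_screening_trial(SyntheticConfig(seed=2),
                                         n_subjects=n_sub, visits_per_subject=5)
            post = mcmc_calibrate_psa(trial, n_walkers=24, n_steps=600, seed=2)
            sds.append(post.samples["a0"].std())
        assert sds[1] < sds[0]

    def test_noise_free_data_collapses_onto_least_squares(self):
        """With sigma_eps ~ 0 the posterior for (a0, b) concentrates on the
        ordinary-least-squares healthy-line fit."""
        cfg = SyntheticConfig(seed=5, psa=PsaGrowthParams(sigma_eps=1e-3),
                              nh=NaturalHistoryParams(gamma_o=0.0))
        trial = make_screening_trial(cfg, n_subjects=150, visits_per_subject=4)
        X = np.column_stack([trial["age"], np.ones(len(trial))])
        beta, *_ = np.linalg.lstsq(X, np.log(trial["psa"]), rcond=None)
        post = mcmc_calibrate_psa(trial, n_walkers=24, n_steps=500, seed=5)
        assert post.samples["a0"].median() == pytest.approx(beta[0], abs=5e-4)
        assert post.samples["b"].median() == pytest.approx(beta[1], abs=3e-2)

    def test_non_positive_psa_rejected(self):
        bad = pd.DataFrame({"age": [50.0], "psa": [0.0]})
        with pytest.raises(ValueError):
            mcmc_calibrate_psa(bad)
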