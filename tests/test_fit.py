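"""Bayesian model fitting: recovery, prediction bands, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from cephgrowth import (FitConfig, McmcConfig, PopulationConfig,
                        PosteriorSamples, check_convergence,
                        draw_cross_section, fit_cross_sectional,
                        fit_longitudinal, generate_population,
                        posterior_predict)
from cephgrowth.fit import (log_posterior_cross_sectional, log_prior,
                            loglik_cross_sectional)

SHORT_MCMC = FitConfig(mode="mcmc", mcmc=McmcConfig(iterations=2500, thin=5, seed=1))


@pytest.fixture(scope="module")
def pop100():
    return generate_population(PopulationConfig(n_individuals=100, seed=3))


@pytest.fixture(scope="module")
def mcmc_post(pop100, good_prior):
    return fit_longitudinal(pop100, good_prior, SHORT_MCMC)


class TestLongitudinal:
    def test_mcmc_recovers_truth(self, mcmc_post, truth):
        med = mcmc_post.median_params()
        assert med.f == pytest.approx(truth.f, rel=0.05)
        assert med.a1 == pytest.approx(truth.a1, rel=0.05)
        assert abs(med.c1 - truth.c1) < 0.5
        assert abs(med.c2 - truth.c2) < 0.5

    def test_mcmc_recovers_measurement_error(self, mcmc_post, pop100):
        sigma_truth = pop100.provenance.sigma
        assert np.median(mcmc_post.flat("sigma")) == pytest.approx(sigma_truth, rel=0.10)

    def test_intercepts_centered_at_zero(self, mcmc_post, pop100):
        a_id = mcmc_post.flat("a_id")  # (draws, n_individuals)
        n_id = a_id.shape[1]
        bound = 2 * pop100.provenance.sigma_id / np.sqrt(n_id)
        assert abs(a_id.mean()) < bound

    def test_rate_truncation_respected(self, mcmc_post):
        assert np.all(mcmc_post.flat("b1") > 0)
        assert np.all(mcmc_post.flat("b2") > 0)
        assert np.all(mcmc_post.flat("sigma") > 0)
        assert np.all(mcmc_post.flat("sigma_id") > 0)

    def test_equal_draws_across_chains(self, mcmc_post):
        # every parameter has the same chain count and, within a
        # parameter, equally many retained draws per chain (the intercept
        # vector is deliberately thinned relative to the scalars)
        scalar_shapes = {v.shape for v in mcmc_post.draws.values() if v.ndim == 2}
        assert len(scalar_shapes) == 1
        assert mcmc_post.n_chains == 4
        assert mcmc_post.draws["a_id"].shape[0] == 4

    def test_rejects_singleton_individuals(self, good_prior):
        table = pd.DataFrame({
            "individual_id": ["A", "A", "B"],
            "sex": "F", "age": [5.0, 6.0, 7.0], "trait": "t",
            "value": [70.0, 72.0, 74.0],
        })
        with pytest.raises(ValueError, match=">= 2 observations"):
            # bypass dataset validation to hit the fit-level precondition
            from cephgrowth.simulate import LongitudinalDataset
            ds = LongitudinalDataset.__new__(LongitudinalDataset)
            ds.table = table
            ds.provenance = None
            fit_longitudinal(ds, good_prior)

    def test_map_mode_close_to_mcmc(self, pop100, good_prior, mcmc_post):
        m = fit_longitudinal(pop100, good_prior, FitConfig(mode="map"))
        assert m.mode == "map"
        assert m.n_draws_per_chain == 1
        assert m.median_params().f == pytest.approx(mcmc_post.median_params().f, abs=0.5)


class TestCrossSectional:
    def test_noiseless_map_recovery(self, good_prior):
        cfg = PopulationConfig(n_individuals=300, sigma=0.0, sigma_id=0.0, seed=11)
        data = generate_population(cfg)
        cs = draw_cross_section(data, "full", 1)
        post = fit_cross_sectional(cs, good_prior, FitConfig(mode="map"))
        est, t = post.median_params(), cfg.params
        assert est.f == pytest.approx(t.f, rel=0.01)
        assert est.a1 == pytest.approx(t.a1, rel=0.01)
        assert abs(est.c1 - t.c1) < 0.1
        assert abs(est.c2 - t.c2) < 0.1

    def test_minimum_size_flagged(self, pop200, good_prior):
        cs = draw_cross_section(pop200, 5, 4)
        post = fit_cross_sectional(cs, good_prior, FitConfig(mode="map"))
        assert "usable-with-caution" in post.flags
        with pytest.raises(ValueError, match="n >= 5"):
            fit_cross_sectional(cs.table.iloc[:4], good_prior)

    def test_rejects_repeated_individuals(self, pop200, good_prior):
        dup = pop200.table.groupby("individual_id").head(2).iloc[:20]
        with pytest.raises(ValueError, match="one observation per individual"):
            fit_cross_sectional(dup, good_prior)

    def test_map_deterministic(self, pop200, good_prior):
        cs = draw_cross_section(pop200, 80, 5)
        a = fit_cross_sectional(cs, good_prior, FitConfig(mode="map"))
        b = fit_cross_sectional(cs, good_prior, FitConfig(mode="map"))
        assert all(np.array_equal(a.draws[k], b.draws[k]) for k in a.draws)

    def test_mcmc_deterministic_for_seed(self, pop200, good_prior):
        cs = draw_cross_section(pop200, 40, 6)
        cfg = FitConfig(mode="mcmc", mcmc=McmcConfig(iterations=400, seed=2))
        a = fit_cross_sectional(cs, good_prior, cfg)
        b = fit_cross_sectional(cs, good_prior, cfg)
        assert all(np.array_equal(a.draws[k], b.draws[k]) for k in a.draws)

    def test_sigma_confounds_phenotypic_variation(self, pop500, good_prior):
        # longitudinal modeling separates measurement error from
        # between-individual variation; cross-sectional modeling cannot,
        # so its sigma approaches the total apparent SD
        cfg = pop500.provenance
        total_sd = np.hypot(cfg.sigma, cfg.sigma_id)
        longi = fit_longitudinal(pop500, good_prior, FitConfig(mode="map"))
        assert float(longi.flat("sigma")[0]) == pytest.approx(cfg.sigma, rel=0.15)
        cs = draw_cross_section(pop500, 300, 8)
        cross = fit_cross_sectional(cs, good_prior, FitConfig(mode="map"))
        assert float(cross.flat("sigma")[0]) == pytest.approx(total_sd, rel=0.15)

    def test_map_objective_is_the_model_log_density(self, pop200, good_prior, rng):
        # the penalized likelihood used for map mode is the same joint
        # density the sampler explores (additive constant zero here)
        cs = draw_cross_section(pop200, 50, 9)
        ages = cs.table["age"].to_numpy()
        values = cs.table["value"].to_numpy()
        for _ in range(20):
            theta = np.array([
                rng.uniform(90, 110), rng.uniform(80, 95), rng.uniform(0.2, 1.5),
                rng.uniform(1, 5), rng.uniform(0.2, 1.5), rng.uniform(9, 14),
                rng.uniform(0.5, 5),
            ])
            lp = log_posterior_cross_sectional(theta, good_prior, ages, values)
            expected = log_prior(theta, good_prior, False) + loglik_cross_sectional(theta, ages, values)
            assert lp == pytest.approx(expected, rel=1e-12)


class TestPosteriorPredict:
    def test_band_nesting_at_every_age(self, mcmc_post):
        grid = np.linspace(5, 20, 31)
        bands = posterior_predict(mcmc_post, grid, levels=(50, 80, 98))
        for age_idx in range(grid.size):
            assert bands.lower[98][age_idx] <= bands.lower[80][age_idx] <= bands.lower[50][age_idx]
            assert bands.upper[50][age_idx] <= bands.upper[80][age_idx] <= bands.upper[98][age_idx]
            assert bands.lower[50][age_idx] <= bands.median[age_idx] <= bands.upper[50][age_idx]

    def test_point_mass_bands_collapse(self, pop200, good_prior):
        post = fit_longitudinal(pop200, good_prior, FitConfig(mode="map"))
        grid = np.linspace(5, 20, 16)
        bands = posterior_predict(post, grid, target="mean-curve")
        for lev in bands.levels:
            assert np.array_equal(bands.lower[lev], bands.median)
            assert np.array_equal(bands.upper[lev], bands.median)

    def test_new_observation_coverage(self, mcmc_post):
        held = generate_population(PopulationConfig(n_individuals=140, seed=901))
        ages = held.table["age"].to_numpy()
        values = held.table["value"].to_numpy()
        assert ages.size >= 1000
        bands = posterior_predict(mcmc_post, ages, levels=(98,), target="new-observation", seed=4)
        inside = (values >= bands.lower[98]) & (values <= bands.upper[98])
        assert 0.96 <= inside.mean() <= 1.0

    def test_invalid_level_rejected(self, mcmc_post):
        with pytest.raises(ValueError):
            posterior_predict(mcmc_post, np.linspace(5, 20, 5), levels=(0,))
        with pytest.raises(ValueError):
            posterior_predict(mcmc_post, np.linspace(5, 20, 5), levels=(100,))


class TestConvergence:
    def _make_post(self, arrays):
        return PosteriorSamples(draws=arrays, mode="mcmc", model="cross_sectional")

    def test_well_mixed_chains_pass(self, rng):
        draws = {"f": rng.normal(size=(4, 2000))}
        report = check_convergence(self._make_post(draws))
        assert report.rhat["f"] < 1.01
        assert report.passed

    def test_iid_ess_near_draw_count(self, rng):
        draws = {"f": rng.normal(size=(4, 2000))}
        report = check_convergence(self._make_post(draws))
        assert 0.8 * 8000 <= report.ess["f"] <= 1.25 * 8000

    def test_offset_chains_fail(self, rng):
        a = rng.normal(size=(1, 2000))
        b = rng.normal(size=(1, 2000)) + 5.0
        report = check_convergence(self._make_post({"f": np.vstack([a, b])}))
        assert report.rhat["f"] > 1.1
        assert not report.passed

    def test_requires_multiple_mcmc_chains(self, rng, pop200, good_prior):
        single = self._make_post({"f": rng.normal(size=(1, 500))})
        with pytest.raises(ValueError, match="2 chains"):
            check_convergence(single)
        mp = fit_longitudinal(pop200, good_prior, FitConfig(mode="map"))
        with pytest.raises(ValueError, match="MCMC"):
            check_convergence(mp)
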