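"""Gaussian conditioning oracle, hyperparameter inference, and field
prediction for the kriging model."""

import numpy as np
import pytest

from eivsdm.gridmaps import PredictionGrid
from eivsdm.inference import InferenceConfig
from eivsdm.kriging import (
    FieldPosterior,
    LatentFieldModel,
    PriorConfig,
    fit_latent_field,
    gp_conditional,
    predict_field,
)
from eivsdm.random_fields import (
    FieldRealization,
    MaternParams,
    matern_covariance_matrix,
    simulate_grf,
)


def _brute_force_conditional(obs, model, targets):
    """Independent oracle: condition the explicit joint MVN by block
    partitioning, built directly from covariance blocks."""
    from scipy.spatial.distance import cdist

    from eivsdm.random_fields import matern_correlation

    all_pts = np.vstack([np.asarray(targets, float), obs.points])
    nt = len(targets)
    d = cdist(all_pts, all_pts)
    K = model.matern.variance * matern_correlation(d, model.matern.range)
    np.fill_diagonal(K, model.matern.variance)
    K[nt:, nt:] += (model.noise_variance + 1e-8 * model.matern.variance) * np.eye(len(obs))
    Ktt, Kto, Koo = K[:nt, :nt], K[:nt, nt:], K[nt:, nt:]
    Koo_inv = np.linalg.inv(Koo)
    mean = model.intercept + Kto @ Koo_inv @ (obs.values - model.intercept)
    cov = Ktt - Kto @ Koo_inv @ Kto.T
    return mean, cov


class TestGpConditional:
    def test_matches_brute_force_partition_oracle(self, rng):
        obs = FieldRealization(points=rng.uniform(size=(5, 2)),
                               values=rng.standard_normal(5))
        model = LatentFieldModel(
            intercept=0.4,
            matern=MaternParams(variance=0.8, range=0.25),
            noise_variance=0.15,
        )
        targets = rng.uniform(size=(3, 2))
        mean, cov = gp_conditional(obs, model, targets)
        mean_o, cov_o = _brute_force_conditional(obs, model, targets)
        np.testing.assert_allclose(mean, mean_o, atol=1e-10)
        np.testing.assert_allclose(cov, cov_o, atol=1e-10)

    def test_noiseless_interpolation(self, rng):
        pts = rng.uniform(size=(6, 2))
        vals = rng.standard_normal(6)
        obs = FieldRealization(points=pts, values=vals)
        model = LatentFieldModel(
            intercept=0.0, matern=MaternParams(variance=1.0, range=0.3))
        mean, cov = gp_conditional(obs, model, pts[2:3])
        assert mean[0] == pytest.approx(vals[2], abs=1e-5)
        assert cov[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_prior_reversion_far_away(self, rng):
        obs = FieldRealization(points=rng.uniform(size=(5, 2)),
                               values=rng.standard_normal(5) + 2.0)
        model = LatentFieldModel(
            intercept=1.5, matern=MaternParams(variance=0.6, range=0.1))
        far = np.array([[50 * 0.1 + 1.0, 0.5]])
        mean, cov = gp_conditional(obs, model, far)
        assert mean[0] == pytest.approx(1.5, abs=1e-4)
        assert cov[0, 0] == pytest.approx(0.6, abs=1e-4)

    def test_posterior_sd_at_obs_below_prior_sd(self, noisy_field_obs):
        obs, _ = noisy_field_obs
        model = LatentFieldModel(
            intercept=0.0, matern=MaternParams(variance=1.0, range=0.3),
            noise_variance=0.2)
        _, cov = gp_conditional(obs, model, obs.points[:10])
        assert np.all(np.sqrt(np.diag(cov)) <= 1.0 + 1e-12)


class TestFitLatentField:
    def test_fixed_everything_reduces_to_gp_conditional(self, noisy_field_obs):
        obs, _ = noisy_field_obs
        model = LatentFieldModel(
            intercept=0.0, matern=MaternParams(variance=1.0, range=0.3),
            noise_variance=0.0)
        post = fit_latent_field(
            obs, fixed={"alpha": 0.0, "sigma2": 1.0, "range": 0.3, "delta2": 0.0})
        targets = obs.points[:4]
        mean, sd = post.latent_moments(targets)
        mean_o, cov_o = gp_conditional(obs, model, targets)
        # latent_moments runs on the interpolated Matérn table (~3e-7)
        np.testing.assert_allclose(mean, mean_o, atol=1e-5)
        np.testing.assert_allclose(sd, np.sqrt(np.diag(cov_o)), atol=1e-4)

    def test_duplicate_obs_identify_noise_floor(self, rng):
        # two measurements at identical locations with different values
        # force a delta2 posterior bounded away from zero
        base = rng.uniform(size=(15, 2))
        pts = np.vstack([base, base])
        vals = np.concatenate([rng.standard_normal(15), rng.standard_normal(15) + 0.0])
        obs = FieldRealization(points=pts, values=vals)
        post = fit_latent_field(obs, inference=InferenceConfig(seed=1, n_draws=600))
        assert post.hyper_summaries.loc["delta2", "q2.5"] > 1e-4

    def test_hyperparameter_recovery_and_coverage(self):
        # simulation-based calibration at reduced replicates: the 95%
        # intervals should cover the truth in most replicate fits
        truth = {"alpha": 0.0, "sigma2": 0.5, "range": 0.3, "delta2": 0.3}
        rng = np.random.default_rng(21)
        params = MaternParams(variance=0.5, range=0.3)
        hits = {k: 0 for k in truth}
        R = 10
        for r in range(R):
            pts = rng.uniform(size=(100, 2))
            latent = simulate_grf(pts, params, seed=500 + r)
            obs = FieldRealization(
                points=pts,
                values=latent.values + rng.normal(scale=np.sqrt(0.3), size=100),
            )
            post = fit_latent_field(obs, inference=InferenceConfig(seed=r, n_draws=600))
            s = post.hyper_summaries
            for k, v in truth.items():
                if s.loc[k, "q2.5"] <= v <= s.loc[k, "q97.5"]:
                    hits[k] += 1
        for k, h in hits.items():
            assert h >= 7, f"{k}: {h}/{R} coverage too low"

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_mcmc_engine_agrees_with_laplace(self, noisy_field_obs):
        obs, _ = noisy_field_obs
        lap = fit_latent_field(obs, inference=InferenceConfig(seed=3, n_draws=800))
        mc = fit_latent_field(
            obs,
            inference=InferenceConfig(engine="mcmc", seed=3, n_warmup=400,
                                      n_draws=3200),
        )
        sl, sm = lap.hyper_summaries, mc.hyper_summaries
        for name in ("alpha", "sigma2"):
            assert sl.loc[name, "mean"] == pytest.approx(
                sm.loc[name, "mean"], abs=3 * max(sl.loc[name, "sd"], 0.05)
            )

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_mcmc_engine_deterministic(self, noisy_field_obs):
        obs, _ = noisy_field_obs
        cfg = InferenceConfig(engine="mcmc", seed=5, n_warmup=50, n_draws=600)
        a = fit_latent_field(obs, inference=cfg)
        b = fit_latent_field(obs, inference=cfg)
        np.testing.assert_array_equal(a.hyper_draws, b.hyper_draws)

    def test_warns_below_ten_observations(self, rng):
        obs = FieldRealization(points=rng.uniform(size=(5, 2)),
                               values=rng.standard_normal(5))
        with pytest.warns(UserWarning, match="observations"):
            fit_latent_field(obs, inference=InferenceConfig(seed=0, n_draws=500))


class TestPredictField:
    def test_sd_smaller_near_data_cluster(self, rng):
        pts = 0.05 * rng.uniform(size=(40, 2))  # all data in one corner
        obs = FieldRealization(points=pts, values=rng.standard_normal(40))
        model = LatentFieldModel(
            intercept=0.0, matern=MaternParams(variance=1.0, range=0.3),
            noise_variance=0.1)
        post = FieldPosterior.from_fixed(obs, model)
        grid = PredictionGrid.unit_square(4)
        out = predict_field(post, grid)
        centres = grid.cell_centres()
        near = np.argmin(np.linalg.norm(centres - [0.025, 0.025], axis=1))
        far = np.argmax(np.linalg.norm(centres - [0.025, 0.025], axis=1))
        assert out.sd[near] < out.sd[far]

    def test_fixed_hyper_mean_map_equals_gp_conditional(self, noisy_field_obs):
        obs, _ = noisy_field_obs
        model = LatentFieldModel(
            intercept=0.2, matern=MaternParams(variance=0.8, range=0.35),
            noise_variance=0.2)
        post = FieldPosterior.from_fixed(obs, model)
        grid = PredictionGrid.unit_square(5)
        out = predict_field(post, grid)
        mean_o, _ = gp_conditional(obs, model, grid.cell_centres())
        # prediction path uses the interpolated Matérn table (~3e-7)
        np.testing.assert_allclose(out.mean, mean_o, atol=1e-5)

    def test_constant_observations_give_constant_map(self, rng):
        pts = rng.uniform(size=(20, 2))
        obs = FieldRealization(points=pts, values=np.full(20, 1.7))
        model = LatentFieldModel(
            intercept=1.7, matern=MaternParams(variance=0.5, range=0.4))
        post = FieldPosterior.from_fixed(obs, model)
        out = predict_field(post, PredictionGrid.unit_square(3))
        np.testing.assert_allclose(out.mean, 1.7, atol=1e-6)

    def test_empty_grid_rejected(self, noisy_field_obs):
        obs, _ = noisy_field_obs
        post = FieldPosterior.from_fixed(
            obs, LatentFieldModel(0.0, MaternParams(1.0, 0.3), 0.1))
        with pytest.raises(ValueError):
            PredictionGrid(n_x=0, n_y=3)

    def test_berkson_shrinkage_of_predictions(self, rng):
        # kriging predictions are less variable than the truth they estimate
        params = MaternParams(variance=1.0, range=0.3)
        pts = rng.uniform(size=(80, 2))
        latent = simulate_grf(pts, params, seed=91)
        obs = FieldRealization(
            points=pts, values=latent.values + rng.normal(scale=0.55, size=80))
        post = fit_latent_field(obs, inference=InferenceConfig(seed=2, n_draws=500))
        targets = rng.uniform(size=(300, 2))
        mean, _ = post.latent_moments(targets)
        truth_draw = simulate_grf(targets, params, seed=92)
        assert np.var(mean) <= np.var(truth_draw.values) + 0.1
        assert np.var(mean) < np.var(obs.values)
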