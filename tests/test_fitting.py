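"""Direct / two-stage / joint fitters: structural contracts, reductions
to closed forms, and model comparison."""

import numpy as np
import pandas as pd
import pytest

from eivsdm.fitting import (
    compare_models,
    fit_direct,
    fit_joint,
    fit_two_stage,
    predict_covariate_map,
    predict_occurrence_map,
)
from eivsdm.gridmaps import GridMap, PredictionGrid
from eivsdm.inference import InferenceConfig
from eivsdm.sdm import SdmSpec, SpeciesObservations, logistic_link
from eivsdm.simulation import SimulationConfig, generate_dataset

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


@pytest.fixture(scope="module")
def aligned_fit_pair(tiny_aligned_noiseless):
    """Direct and two-stage fits on the same aligned noiseless data,
    same seeds."""
    data = tiny_aligned_noiseless
    spec = SdmSpec(linear_terms=("x1", "x2"), spatial_residual=True)
    inf = InferenceConfig(n_warmup=200, n_draws=600, seed=31)
    direct = fit_direct(data.species, spec, inference=inf)
    two = fit_two_stage(data.species, data.abiotic, spec, inference=inf)
    return data, spec, direct, two


class TestFitDirect:
    def test_requires_aligned_covariates(self, tiny_misaligned):
        spec = SdmSpec(linear_terms=("x1", "x2"))
        with pytest.raises(ValueError, match="two_stage|joint"):
            fit_direct(tiny_misaligned.species, spec,
                       inference=InferenceConfig(seed=0, n_draws=500))

    def test_zero_variance_covariate_keeps_prior(self, rng, fast_inference):
        n = 150
        pts = rng.uniform(size=(n, 2))
        y = rng.integers(0, 2, size=n)
        cov = pd.DataFrame({"flat": np.zeros(n)})
        sp = SpeciesObservations(points=pts, y=y, covariates=cov)
        spec = SdmSpec(linear_terms=("flat",), spatial_residual=False)
        fit = fit_direct(sp, spec, inference=fast_inference)
        # no information: posterior sd should stay near the prior sd ~ sqrt(1000)
        assert fit.coef_summary.loc["flat", "sd"] > 15.0

    def test_spline_term_fits_and_sums_to_zero(self, rng, fast_inference):
        n = 300
        pts = rng.uniform(size=(n, 2))
        z = rng.uniform(size=n)
        eta = -1.0 + np.sin(2 * np.pi * z)
        y = (rng.uniform(size=n) < logistic_link(eta)).astype(int)
        sp = SpeciesObservations(points=pts, y=y, covariates=pd.DataFrame({"z": z}))
        spec = SdmSpec(linear_terms=(), spline_terms=("z",), n_bins=8,
                       spatial_residual=False)
        fit = fit_direct(sp, spec, inference=fast_inference)
        u = fit.spline_draws["z"]
        np.testing.assert_allclose(u.sum(axis=1), 0.0, atol=1e-6)
        curve = fit.spline_summary("z")["mean"].to_numpy()
        # recovered shape correlates with the generating sinusoid
        target = np.sin(2 * np.pi * fit.spline_midpoints["z"])
        assert np.corrcoef(curve, target)[0, 1] > 0.6


class TestTwoStage:
    def test_aligned_noiseless_plug_in_consistency(self, aligned_fit_pair):
        # with abiotic data observed exactly at species locations and no
        # measurement error, stage-1 means reproduce the observations and
        # the two-stage fit agrees with the direct fit
        data, spec, direct, two = aligned_fit_pair
        x_hat = two.covariate_table["x1"].to_numpy()
        x_obs = data.species.covariates["x1"].to_numpy()
        assert np.corrcoef(x_hat, x_obs)[0, 1] > 0.99
        for term in ("x1", "x2"):
            d, t = direct.coef_summary.loc[term], two.coef_summary.loc[term]
            assert t["mean"] == pytest.approx(d["mean"], abs=3 * d["sd"] / 2)

    def test_stage1_posteriors_recorded(self, aligned_fit_pair):
        *_, two = aligned_fit_pair
        assert set(two.stage1) == {"x1", "x2"}
        assert "stage1" in two.diagnostics

    def test_missing_abiotic_term_rejected(self, tiny_misaligned):
        spec = SdmSpec(linear_terms=("x1", "x2", "ph"))
        with pytest.raises(ValueError, match="ph"):
            fit_two_stage(tiny_misaligned.species, tiny_misaligned.abiotic, spec,
                          inference=InferenceConfig(seed=0, n_draws=500))

    def test_no_uncertain_covariates_reduces_to_direct(self, rng):
        n = 120
        pts = rng.uniform(size=(n, 2))
        y = rng.integers(0, 2, size=n)
        sp = SpeciesObservations(points=pts, y=y)
        spec = SdmSpec(linear_terms=(), spatial_residual=True)
        inf = InferenceConfig(n_warmup=100, n_draws=500, seed=4)
        two = fit_two_stage(sp, {}, spec, inference=inf)
        assert two.kind == "two_stage"
        assert two.stage1 == {}
        assert two.beta_draws.shape[1] == 1  # intercept only


class TestJoint:
    def test_misaligned_fit_structure(self, tiny_misaligned, fast_inference):
        spec = SdmSpec(linear_terms=("x1", "x2"), spatial_residual=True)
        fit = fit_joint(tiny_misaligned.species, tiny_misaligned.abiotic, spec,
                        inference=fast_inference)
        assert fit.kind == "joint"
        # every parameter in the spec has a posterior entry
        assert fit.beta_draws.shape[1] == 3
        assert set(fit.field_draws) == {"x1", "x2"}
        assert set(fit.field_hyper_draws) == {"x1", "x2"}
        assert fit.W_hyper_draws is not None
        assert np.all(fit.coef_summary["sd"] >= 0)
        # latent field union covers species and abiotic points
        assert fit.field_draws["x1"].shape[1] == 240

    def test_latent_field_tracks_truth_better_than_prior(self, tiny_misaligned,
                                                         fast_inference):
        spec = SdmSpec(linear_terms=("x1", "x2"), spatial_residual=True)
        fit = fit_joint(tiny_misaligned.species, tiny_misaligned.abiotic, spec,
                        inference=fast_inference)
        idx = fit.diagnostics["_species_index"]["x1"]
        x_post = fit.field_draws["x1"][:, idx].mean(axis=0)
        truth = tiny_misaligned.truth.x1_species
        rmse = np.sqrt(np.mean((x_post - truth) ** 2))
        assert rmse < np.sqrt(np.mean(truth**2))  # beats the zero prior mean

    def test_runtime_budget_flags_partial_result(self, tiny_misaligned):
        spec = SdmSpec(linear_terms=("x1", "x2"), spatial_residual=True)
        inf = InferenceConfig(n_warmup=5, n_draws=2000, seed=3, max_seconds=2.0)
        with pytest.warns(UserWarning, match="stopped"):
            fit = fit_joint(tiny_misaligned.species, tiny_misaligned.abiotic, spec,
                            inference=inf)
        assert fit.diagnostics["truncated"]
        assert 0 < fit.n_draws < 2000


class TestAsymptoticAgreement:
    def test_joint_matches_direct_in_aligned_noiseless_limit(
            self, tiny_aligned_noiseless, fast_inference):
        """With co-located, error-free covariates there is no covariate
        uncertainty left: the joint model degenerates to the direct fit."""
        data = tiny_aligned_noiseless
        spec = SdmSpec(linear_terms=("x1", "x2"), spatial_residual=True)
        direct = fit_direct(data.species, spec, inference=fast_inference)
        joint = fit_joint(data.species, data.abiotic, spec,
                          inference=fast_inference)
        for term in ("x1", "x2"):
            d = direct.coef_summary.loc[term]
            j = joint.coef_summary.loc[term]
            assert j["mean"] == pytest.approx(d["mean"], abs=3 * d["sd"] / 2)

    def test_gap_shrinks_with_abiotic_information(self):
        """As abiotic coverage grows (at fixed measurement error) the two
        estimators' coefficient gap shrinks; seed-averaged to beat the
        per-dataset Monte-Carlo noise of a single comparison."""
        gaps = {40: [], 400: []}
        spec = SdmSpec(linear_terms=("x1", "x2"), spatial_residual=True)
        for seed in (77, 78):
            for m_abiotic in gaps:
                cfg = SimulationConfig(n_species=250, n_abiotic=m_abiotic,
                                       misaligned=True, measurement_error=True)
                data = generate_dataset(cfg, run_seed=seed)
                inf = InferenceConfig(n_warmup=150, n_draws=500, seed=5,
                                      n_field_draws=20)
                two = fit_two_stage(data.species, data.abiotic, spec,
                                    inference=inf)
                joint = fit_joint(data.species, data.abiotic, spec,
                                  inference=inf)
                gaps[m_abiotic].append(np.linalg.norm(
                    two.coef_summary["mean"].to_numpy()[1:]
                    - joint.coef_summary["mean"].to_numpy()[1:]))
        assert np.mean(gaps[400]) <= np.mean(gaps[40]) + 0.05


class TestPredictMaps:
    def test_intercept_only_constant_map(self, rng, fast_inference):
        n = 200
        pts = rng.uniform(size=(n, 2))
        y = (rng.uniform(size=n) < 0.3).astype(int)
        sp = SpeciesObservations(points=pts, y=y)
        spec = SdmSpec(linear_terms=(), spatial_residual=False)
        fit = fit_direct(sp, spec, inference=fast_inference)
        grid = PredictionGrid.unit_square(3)
        log_odds, prob = predict_occurrence_map(fit, grid, n_draws=200)
        assert np.ptp(log_odds.mean) < 1e-9
        expect = logistic_link(fit.beta_draws[:, 0]).mean()
        assert prob.mean[0] == pytest.approx(expect, abs=0.02)

    def test_probability_bounds(self, tiny_misaligned, fast_inference):
        spec = SdmSpec(linear_terms=("x1", "x2"), spatial_residual=True)
        fit = fit_two_stage(tiny_misaligned.species, tiny_misaligned.abiotic,
                            spec, inference=fast_inference)
        _, prob = predict_occurrence_map(fit, PredictionGrid.unit_square(5),
                                         n_draws=30)
        assert np.all((prob.mean > 0) & (prob.mean < 1))
        assert np.all(prob.sd <= 0.5)

    def test_mean_of_draws_not_link_of_mean(self):
        # a skewed two-point posterior distinguishes E[g(eta)] from g(E[eta])
        draws = np.array([-4.0, 2.0])
        mean_of_g = logistic_link(draws).mean()
        g_of_mean = logistic_link(draws.mean())
        assert mean_of_g != pytest.approx(g_of_mean, abs=0.05)
        # the map path averages on the probability scale
        grid = PredictionGrid.unit_square(1)
        gm = GridMap(grid=grid, mean=[mean_of_g], sd=[0.1], quantity="probability")
        assert gm.mean[0] == pytest.approx(mean_of_g)

    def test_covariate_map_two_stage_vs_joint(self, tiny_misaligned, fast_inference):
        spec = SdmSpec(linear_terms=("x1", "x2"), spatial_residual=True)
        grid = PredictionGrid.unit_square(5)
        two = fit_two_stage(tiny_misaligned.species, tiny_misaligned.abiotic,
                            spec, inference=fast_inference)
        m = predict_covariate_map(two, grid, "x1", n_draws=20)
        assert m.quantity == "covariate:x1"
        assert np.all(m.sd >= 0)
        with pytest.raises(ValueError):
            predict_covariate_map(
                fit_direct(tiny_misaligned.species,
                           SdmSpec(linear_terms=(), spatial_residual=True),
                           inference=fast_inference),
                grid, "x1")


class TestCompareModels:
    def test_self_comparison_gives_unit_correlations(self, aligned_fit_pair):
        data, spec, direct, _ = aligned_fit_pair
        grid = PredictionGrid.unit_square(4)
        m = GridMap(grid=grid, mean=np.linspace(0, 1, 16), sd=np.ones(16))
        rep = compare_models(direct, direct, {"prob": m}, {"prob": m})
        assert rep.coefficient_correlation == pytest.approx(1.0)
        assert rep.map_correlations["prob"] == pytest.approx(1.0)

    def test_negated_map_gives_minus_one(self, aligned_fit_pair):
        _, _, direct, two = aligned_fit_pair
        grid = PredictionGrid.unit_square(4)
        m = GridMap(grid=grid, mean=np.linspace(0, 1, 16), sd=np.ones(16))
        neg = GridMap(grid=grid, mean=-np.linspace(0, 1, 16), sd=np.ones(16))
        rep = compare_models(direct, two, {"prob": m}, {"prob": neg})
        assert rep.map_correlations["prob"] == pytest.approx(-1.0)

    def test_constant_map_reported_undefined(self, aligned_fit_pair):
        _, _, direct, two = aligned_fit_pair
        grid = PredictionGrid.unit_square(4)
        m = GridMap(grid=grid, mean=np.linspace(0, 1, 16), sd=np.ones(16))
        const = GridMap(grid=grid, mean=np.full(16, 0.4), sd=np.ones(16))
        rep = compare_models(direct, two, {"prob": m}, {"prob": const})
        assert rep.map_correlations["prob"] is None
        assert "undefined" in str(rep)

    def test_mismatched_grids_rejected(self, aligned_fit_pair):
        _, _, direct, two = aligned_fit_pair
        a = GridMap(grid=PredictionGrid.unit_square(4), mean=np.zeros(16),
                    sd=np.ones(16))
        b = GridMap(grid=PredictionGrid.unit_square(5), mean=np.zeros(25),
                    sd=np.ones(25))
        with pytest.raises(ValueError):
            compare_models(direct, two, {"m": a}, {"m": b})
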