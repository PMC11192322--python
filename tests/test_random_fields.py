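"""Matérn correlation, covariance matrices, field simulation, and the
confounded covariate construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import kv

from eivsdm.random_fields import (
    FieldRealization,
    MaternParams,
    make_confounded_pair,
    matern_correlation,
    matern_covariance_matrix,
    simulate_grf,
)

# independent high-precision Bessel oracle for the nu=1 Matérn correlation
def _matern1_oracle(d, rng_):
    kd = np.sqrt(8.0) / rng_ * np.asarray(d, dtype=float)
    return np.where(kd == 0, 1.0, kd * kv(1, np.where(kd == 0, 1.0, kd)))


class TestMaternCorrelation:
    def test_unit_at_zero_distance(self):
        assert matern_correlation(0.0, 0.3) == 1.0

    def test_value_at_range_is_near_0p14(self):
        # at d = range the correlation is sqrt(8)*K1(sqrt(8)) ~ 0.139,
        # the conventional "practically uncorrelated" distance
        oracle = float(np.sqrt(8.0) * kv(1, np.sqrt(8.0)))
        for r in (0.1, 0.3, 2.0):
            assert matern_correlation(r, r) == pytest.approx(oracle, rel=1e-12)
        assert oracle == pytest.approx(0.14, abs=0.002)

    @given(st.floats(0.001, 10.0), st.floats(0.001, 10.0), st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing(self, d1, d2, rng_):
        # strict decrease holds wherever the Bessel tail has not underflowed
        # to zero (d/range < ~250); keep the search inside that regime
        lo, hi = sorted((d1, d2))
        if hi - lo < 1e-9:
            return
        assert matern_correlation(lo, rng_) > matern_correlation(hi, rng_)

    def test_vanishes_far_beyond_range(self):
        assert matern_correlation(20 * 0.3, 0.3) < 1e-6

    def test_matches_bessel_oracle_on_grid(self):
        d = np.linspace(0.01, 2.0, 50)
        np.testing.assert_allclose(
            matern_correlation(d, 0.37), _matern1_oracle(d, 0.37), rtol=1e-12
        )

    def test_rejects_bad_range(self):
        with pytest.raises(ValueError):
            matern_correlation(1.0, 0.0)
        with pytest.raises(ValueError):
            matern_correlation(1.0, -2.0)


class TestMaternParams:
    def test_rejects_nonpositive_variance_and_range(self):
        with pytest.raises(ValueError):
            MaternParams(variance=0.0, range=0.3)
        with pytest.raises(ValueError):
            MaternParams(variance=0.5, range=-1.0)

    def test_rejects_other_smoothness(self):
        with pytest.raises(ValueError):
            MaternParams(variance=0.5, range=0.3, smoothness=1.5)

    def test_kappa_relation(self):
        p = MaternParams(variance=0.5, range=0.3)
        assert p.kappa == pytest.approx(np.sqrt(8.0) / 0.3)


class TestCovarianceMatrix:
    def test_diagonal_is_variance(self, rng):
        pts = rng.uniform(size=(12, 2))
        cov = matern_covariance_matrix(pts, MaternParams(variance=0.7, range=0.2))
        np.testing.assert_allclose(np.diag(cov), 0.7)

    def test_off_diagonal_at_known_distance(self):
        pts = [(0.0, 0.0), (0.3, 0.0)]
        cov = matern_covariance_matrix(pts, MaternParams(variance=0.5, range=0.3))
        oracle = 0.5 * float(np.sqrt(8.0) * kv(1, np.sqrt(8.0)))
        assert cov[0, 1] == pytest.approx(oracle, rel=1e-12)
        assert cov[0, 1] == pytest.approx(0.07, abs=0.001)

    def test_symmetric_psd_random_configurations(self, rng):
        for n in (5, 50, 200):
            pts = rng.uniform(size=(n, 2)) * rng.uniform(0.5, 5.0)
            cov = matern_covariance_matrix(
                pts, MaternParams(variance=1.3, range=0.4))
            np.testing.assert_allclose(cov, cov.T)
            assert np.linalg.eigvalsh(cov).min() >= -1e-8

    def test_duplicate_points_allowed_nan_rejected(self):
        p = MaternParams(variance=1.0, range=0.5)
        cov = matern_covariance_matrix([(0, 0), (0, 0)], p)
        np.testing.assert_allclose(cov, 1.0)
        with pytest.raises(ValueError):
            matern_covariance_matrix([(np.nan, 0), (0, 0)], p)


class TestSimulateGrf:
    def test_seed_determinism(self, rng):
        pts = rng.uniform(size=(30, 2))
        p = MaternParams(variance=0.5, range=0.3)
        a = simulate_grf(pts, p, seed=5)
        b = simulate_grf(pts, p, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        c = simulate_grf(pts, p, seed=6)
        assert not np.array_equal(a.values, c.values)

    def test_moments_match_target(self, rng):
        # Monte-Carlo oracle: pooled mean ~ 0 and variance ~ sigma2 over
        # replicate draws, within 3 Monte-Carlo standard errors
        pts = rng.uniform(size=(200, 2))
        p = MaternParams(variance=0.5, range=0.3)
        draws = np.array([simulate_grf(pts, p, seed=s).values for s in range(200)])
        assert abs(draws.mean()) < 3 * draws.std() / np.sqrt(200)
        pointwise_var = draws.var(axis=0, ddof=1)
        se = 0.5 * np.sqrt(2.0 / 199)
        assert abs(pointwise_var.mean() - 0.5) < 3 * se

    def test_empirical_correlation_tracks_matern_curve(self, rng):
        # variogram-style Monte-Carlo check: correlations of point pairs
        # binned by distance reproduce the theoretical curve
        pts = rng.uniform(size=(120, 2))
        p = MaternParams(variance=1.0, range=0.4)
        draws = np.array([simulate_grf(pts, p, seed=s).values for s in range(400)])
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        emp = np.corrcoef(draws.T)
        for lo, hi in [(0.05, 0.15), (0.25, 0.35), (0.6, 0.8)]:
            sel = (d > lo) & (d < hi)
            theo = matern_correlation(d[sel], 0.4).mean()
            assert emp[sel].mean() == pytest.approx(theo, abs=0.08)


class TestConfoundedPair:
    def test_zero_fields_give_zero_pair(self, rng):
        pts = rng.uniform(size=(10, 2))
        z = FieldRealization(points=pts, values=np.zeros(10))
        x1, x2 = make_confounded_pair(z, z, z)
        np.testing.assert_array_equal(x1.values, 0.0)
        np.testing.assert_array_equal(x2.values, 0.0)

    def test_elementwise_sums(self, rng):
        pts = rng.uniform(size=(15, 2))
        z, z1, z2 = (
            FieldRealization(points=pts, values=rng.standard_normal(15))
            for _ in range(3)
        )
        x1, x2 = make_confounded_pair(z, z1, z2)
        np.testing.assert_allclose(x1.values, z.values + z1.values)
        np.testing.assert_allclose(x2.values, z.values + z2.values)

    def test_implied_variance_one_covariance_half(self, rng):
        # moments Var[X1] = Var[X2] = 1.0, Cov = 0.5, Corr = 0.5 when the
        # component fields have variance 0.5
        pts = rng.uniform(size=(400, 2))
        p = MaternParams(variance=0.5, range=0.3)
        vals1, vals2 = [], []
        for s in range(60):
            z = simulate_grf(pts, p, seed=3 * s)
            z1 = simulate_grf(pts, p, seed=3 * s + 1)
            z2 = simulate_grf(pts, p, seed=3 * s + 2)
            x1, x2 = make_confounded_pair(z, z1, z2)
            vals1.append(x1.values)
            vals2.append(x2.values)
        v1, v2 = np.concatenate(vals1), np.concatenate(vals2)
        assert np.var(v1) == pytest.approx(1.0, abs=0.07)
        assert np.var(v2) == pytest.approx(1.0, abs=0.07)
        cov = np.mean(v1 * v2) - v1.mean() * v2.mean()
        assert cov == pytest.approx(0.5, abs=0.05)
        assert np.corrcoef(v1, v2)[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_mismatched_points_rejected(self, rng):
        a = FieldRealization(points=rng.uniform(size=(5, 2)), values=np.zeros(5))
        b = FieldRealization(points=rng.uniform(size=(5, 2)), values=np.zeros(5))
        with pytest.raises(ValueError):
            make_confounded_pair(a, a, b)


class TestFieldRealizationIO:
    def test_csv_round_trip(self, tmp_path, rng):
        f = FieldRealization(points=rng.uniform(size=(8, 2)),
                             values=rng.standard_normal(8))
        path = tmp_path / "field.csv"
        f.to_csv(path)
        g = FieldRealization.from_csv(path)
        np.testing.assert_allclose(g.points, f.points)
        np.testing.assert_allclose(g.values, f.values)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            FieldRealization(points=rng.uniform(size=(4, 2)), values=np.zeros(3))
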