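"""Fitting the species distribution model three ways.

* ``fit_direct`` — logistic GAMM on covariate values observed at the
  species locations, taken at face value (attenuated under measurement
  error: regression dilution).
* ``fit_two_stage`` — kriging posterior means of each uncertain
  covariate are plugged into the GAMM as known constants.
* ``fit_joint`` — one hierarchical posterior over the kriging models
  and the GAMM simultaneously; covariate values at species locations
  are latent variables, so their uncertainty propagates into the
  coefficients and species data feed back into the fields.

All three use Pólya-Gamma data augmentation: given ω ~ PG(1, η) per
observation, every Gaussian block (coefficients, splines, spatial
residual, latent covariate fields) has a conjugate multivariate-normal
full conditional, and variance/range hyperparameters are updated by
Metropolis steps (range on a precomputed log-spaced grid).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.spatial.distance import cdist

from .gridmaps import GridMap, PredictionGrid
from .inference import (
    InferenceConfig,
    RangeGridCov,
    effective_sample_size,
    sample_polya_gamma,
    split_rhat,
)
from .kriging import FieldPosterior, LatentFieldModel, PriorConfig, fit_latent_field
from .random_fields import (
    JITTER,
    FieldRealization,
    MaternParams,
    as_points,
    matern_correlation_fast,
)
from .sdm import (
    SdmSpec,
    SpeciesObservations,
    bin_covariate,
    logistic_link,
    rw2_structure,
)

#: |η| cap inside the Pólya-Gamma augmentation.  Unbounded η lets weakly
#: identified fits drift into a saturated absorbing state (ω → 0, pseudo-data
#: → ±∞); capping at 10 (probabilities within 5e-5 of 0/1) bounds the
#: pseudo-data while leaving realistic log-odds untouched.
ETA_CAP = 10.0

__all__ = [
    "FittedModel",
    "fit_direct",
    "fit_two_stage",
    "fit_joint",
    "predict_occurrence_map",
    "predict_covariate_map",
    "compare_models",
    "ComparisonReport",
]


# ---------------------------------------------------------------------------
# Small Gibbs building blocks
# ---------------------------------------------------------------------------

def _sample_mvn_canonical(Q: np.ndarray, b: np.ndarray, rng,
                          overwrite: bool = False) -> np.ndarray:
    """Draw from N(Q⁻¹ b, Q⁻¹) given precision Q and linear term b.

    With ``overwrite=True`` the buffer Q is destroyed (hot Gibbs path).
    """
    L = cholesky(Q, lower=True, overwrite_a=overwrite, check_finite=False)
    mean = cho_solve((L, True), b, check_finite=False)
    z = rng.standard_normal(len(b))
    return mean + solve_triangular(L, z, lower=True, trans="T", check_finite=False)


def _update_variance(q: float, n: int, sigma2: float, log_sd: float, rng) -> float:
    """Independence-MH update of a field variance given quad form q = rᵀR⁻¹r.

    Proposal is the inverse-gamma conditional under a flat prior; the
    acceptance ratio then reduces to the N(0, log_sd²) prior on log σ².
    """
    prop = 1.0 / rng.gamma(shape=0.5 * n, scale=2.0 / q)
    v = log_sd**2
    log_acc = (np.log(sigma2) ** 2 - np.log(prop) ** 2) / (2.0 * v)
    if np.log(rng.uniform()) < log_acc:
        return float(prop)
    return sigma2


def _update_range_idx(
    cov: RangeGridCov, idx: int, sigma2: float, resid: np.ndarray,
    log_sd: float, rng, window: int = 2,
) -> int:
    """MH move of the range grid index, proposal uniform on a ±window."""
    lo, hi = max(0, idx - window), min(len(cov.ranges) - 1, idx + window)
    cands = [k for k in range(lo, hi + 1) if k != idx]
    prop = int(rng.choice(cands))
    plo, phi = max(0, prop - window), min(len(cov.ranges) - 1, prop + window)
    n_back = (phi - plo + 1) - 1
    v = log_sd**2
    log_acc = (
        cov.log_likelihood(prop, sigma2, resid)
        - cov.log_likelihood(idx, sigma2, resid)
        - np.log(cov.ranges[prop]) ** 2 / (2 * v)
        + np.log(cov.ranges[idx]) ** 2 / (2 * v)
        + np.log(len(cands))
        - np.log(n_back)
    )
    if np.log(rng.uniform()) < log_acc:
        return prop
    return idx


def _gaussian_marginal_loglik(cov: RangeGridCov, idx: int, sigma2: float,
                              prec: np.ndarray, val: np.ndarray,
                              mean: float) -> float:
    """log N(y; mean·1, σ²R(r) + diag(1/prec)) over entries with prec > 0.

    ``prec``/``val`` accumulate (precision, precision-weighted value) of
    possibly several Gaussian observations per point; entries with no
    observation are marginalized away by simply dropping them.
    """
    sel = prec > 0
    y = val[sel] / prec[sel]
    R = cov.corr(idx)
    if sel.all():
        C = sigma2 * R
    else:
        C = sigma2 * R[np.ix_(sel, sel)]
    C[np.diag_indices(len(y))] += 1.0 / prec[sel]
    L = cholesky(C, lower=True, overwrite_a=True, check_finite=False)
    resid = y - mean
    half = solve_triangular(L, resid, lower=True, check_finite=False)
    return float(-np.sum(np.log(np.diag(L))) - 0.5 * half @ half)


def _collapsed_hyper_mh(
    cov: RangeGridCov, idx: int, sigma2: float, delta2,
    prec_fn, priors: PriorConfig, rng, mean: float = 0.0,
    n_props: int = 2, window: int = 2,
) -> tuple[int, float, float]:
    """Metropolis moves of (range index, σ², δ²) with the latent field
    integrated out analytically.

    Hyperparameters conditioned on a latent-field draw barely move (the
    field pins them); marginalizing the field lets them jump between
    regimes — e.g. short-range/zero-nugget vs long-range/large-nugget.
    ``prec_fn(delta2)`` must return the (precision, weighted-value)
    accumulation of all Gaussian observations of the field;
    ``delta2=None`` marks blocks without their own noise parameter (the
    SDM spatial residual).
    """
    v = priors.log_hyper_sd**2
    prec, val = prec_fn(delta2)
    cur = _gaussian_marginal_loglik(cov, idx, sigma2, prec, val, mean)

    def log_prior(i, s2, d2):
        lp = -np.log(cov.ranges[i]) ** 2 / (2 * v) - np.log(s2) ** 2 / (2 * v)
        if d2 is not None:
            # Gamma(a, b) on 1/δ² with log-δ² Jacobian
            lp += (-priors.precision_shape * np.log(d2)
                   - priors.precision_rate / d2)
        return lp

    for _ in range(n_props):
        lo, hi = max(0, idx - window), min(len(cov.ranges) - 1, idx + window)
        cands = [k for k in range(lo, hi + 1) if k != idx]
        idx_p = int(rng.choice(cands))
        plo, phi = max(0, idx_p - window), min(len(cov.ranges) - 1, idx_p + window)
        s2_p = float(np.exp(np.log(sigma2) + 0.35 * rng.standard_normal()))
        d2_p = delta2 if delta2 is None else float(
            np.exp(np.log(delta2) + 0.35 * rng.standard_normal()))
        prec_p, val_p = (prec, val) if delta2 is None else prec_fn(d2_p)
        prop = _gaussian_marginal_loglik(cov, idx_p, s2_p, prec_p, val_p, mean)
        log_acc = (
            prop - cur
            + log_prior(idx_p, s2_p, d2_p) - log_prior(idx, sigma2, delta2)
            + np.log(len(cands)) - np.log((phi - plo + 1) - 1)
        )
        if np.log(rng.uniform()) < log_acc:
            idx, sigma2, delta2, cur = idx_p, s2_p, d2_p, prop
    return idx, sigma2, delta2


def _marginal_beta_update(
    terms: list, fields: dict, spatial, beta: np.ndarray, t: np.ndarray,
    omega: np.ndarray, spl_vals: np.ndarray, prior_prec_beta: np.ndarray,
    rng, scales: np.ndarray, moment_cache: dict, n_props: int = 3,
) -> tuple[np.ndarray, int]:
    """Metropolis move of the coefficients with every latent field and the
    spatial residual integrated out, then an exact joint redraw of those
    latents given the new coefficients (Matheron conditioning).

    The coefficient of an uncertain covariate and the covariate's latent
    values form a near-ridge that alternating conditional updates cross
    very slowly; moving β against its collapsed target and reconstructing
    the latents exactly restores mixing.  Returns the new β and the
    number of accepted proposals; mutates ``fields``/``spatial`` state.
    """
    N = len(omega)
    p = len(beta)
    # conditional moments of each latent field at the species rows given
    # its own abiotic observations (species data marginalized out); cached
    # per hyperparameter state — constant for the whole run when the field
    # hyperparameters are fixed (empirical Bayes)
    ms, Cs, Lcs = [], [], []
    for term in terms:
        blk = fields[term]
        key = (term, blk.idx, round(blk.sigma2, 12), round(blk.delta2, 12),
               round(blk.alpha, 12))
        if key not in moment_cache:
            moment_cache.clear()  # hypers moved: old moments are stale
            R = blk.cov.corr(blk.idx)
            s, a = blk.s_idx, blk.a_idx
            A = R[np.ix_(a, a)] + (blk.delta2 / blk.sigma2 + JITTER) * np.eye(len(a))
            cf = cho_factor(A, lower=True)
            R_sa = R[s][:, a]
            m = blk.alpha + R_sa @ cho_solve(cf, blk.obs.values - blk.alpha)
            C = blk.sigma2 * (R[np.ix_(s, s)] - R_sa @ cho_solve(cf, R_sa.T))
            Lc = np.linalg.cholesky(C + JITTER * blk.sigma2 * np.eye(N))
            moment_cache[key] = (m, C, Lc)
        m, C, Lc = moment_cache[key]
        ms.append(m)
        Cs.append(C)
        Lcs.append(Lc)
    sigma_w = (spatial.sigma2 * spatial.cov.corr(spatial.idx)
               if spatial is not None else None)
    base = np.diag(1.0 / omega) if sigma_w is None else \
        sigma_w + np.diag(1.0 / omega)
    buf = np.empty_like(base)

    def collapsed(beta_vec):
        mean = np.full(N, beta_vec[0]) + spl_vals
        np.copyto(buf, base)
        for j in range(len(terms)):
            b = beta_vec[j + 1]
            mean = mean + b * ms[j]
            np.add(buf, (b * b) * Cs[j], out=buf)
        L = cholesky(buf, lower=True, overwrite_a=False, check_finite=False)
        half = solve_triangular(L, t - mean, lower=True, check_finite=False)
        ll = -np.sum(np.log(np.diag(L))) - 0.5 * half @ half
        lp = -0.5 * float(beta_vec @ (prior_prec_beta * beta_vec))
        return ll + lp, L

    cur_ll, cur_L = collapsed(beta)
    accepted = 0
    for _ in range(n_props):
        prop = beta + scales * rng.standard_normal(p)
        prop_ll, prop_L = collapsed(prop)
        if np.log(rng.uniform()) < prop_ll - cur_ll:
            beta, cur_ll, cur_L = prop, prop_ll, prop_L
            accepted += 1

    # exact joint redraw of (x_1(s), ..., x_K(s), W) | beta via Matheron:
    # prior draw, then correct by the gain times the pseudo-data residual
    x_priors = []
    t_prior = np.full(N, beta[0]) + spl_vals + rng.standard_normal(N) / np.sqrt(omega)
    for j, term in enumerate(terms):
        xp = ms[j] + Lcs[j] @ rng.standard_normal(N)
        x_priors.append(xp)
        t_prior = t_prior + beta[j + 1] * xp
    if spatial is not None:
        w_prior = np.sqrt(spatial.sigma2) * (
            spatial.cov.corr_chol(spatial.idx) @ rng.standard_normal(N))
        t_prior = t_prior + w_prior
    gain = cho_solve((cur_L, True), t - t_prior, check_finite=False)
    for j, term in enumerate(terms):
        blk = fields[term]
        x_new = x_priors[j] + beta[j + 1] * (Cs[j] @ gain)
        blk.x[blk.s_idx] = x_new
        _refresh_field_obs_part(blk, rng)
    if spatial is not None:
        spatial.w = w_prior + sigma_w @ gain
    return beta, accepted


def _refresh_field_obs_part(blk, rng):
    """Redraw latent values at measurement-only union points given the
    species-row values just reconstructed and the noisy observations."""
    s_set = np.unique(blk.s_idx)
    rest = np.setdiff1d(np.arange(blk.n), s_set)
    if len(rest) == 0:
        return
    Lam = blk.cov.precision(blk.idx, blk.sigma2)
    P = Lam[np.ix_(rest, rest)].copy()
    P[np.diag_indices(len(rest))] += 1.0 / blk.delta2
    xc = blk.x - blk.alpha
    b = -Lam[rest][:, s_set] @ xc[s_set]
    b += (blk.obs.values[rest] - blk.alpha) / blk.delta2
    draw = _sample_mvn_canonical(P, b, rng, overwrite=True)
    blk.x[rest] = blk.alpha + draw


class _SplineBlock:
    """One RW2 spline term: bin assignment, penalty, state."""

    def __init__(self, name: str, values: np.ndarray, n_bins: int):
        self.name = name
        self.assignment, self.midpoints = bin_covariate(values, n_bins)
        self.d = n_bins
        self.K = rw2_structure(n_bins)
        self.A_counts = np.bincount(self.assignment, minlength=n_bins).astype(float)
        self.u = np.zeros(n_bins)
        self.zeta2 = 1.0

    def values_at_obs(self) -> np.ndarray:
        return self.u[self.assignment]

    def update(self, resid: np.ndarray, omega: np.ndarray, priors: PriorConfig, rng):
        """Gibbs update of (u, ζ²) given partial residual on the t scale."""
        aw = np.bincount(self.assignment, weights=omega, minlength=self.d)
        b = np.bincount(self.assignment, weights=omega * resid, minlength=self.d)
        Q = self.K / self.zeta2 + np.diag(aw) + 1e-8 * np.eye(self.d)
        L = cholesky(Q, lower=True, check_finite=False)
        mean = cho_solve((L, True), b, check_finite=False)
        u = mean + solve_triangular(L, rng.standard_normal(self.d),
                                    lower=True, trans="T", check_finite=False)
        # sum-to-zero constraint by conditioning: u | 1ᵀu = 0
        qi1 = cho_solve((L, True), np.ones(self.d), check_finite=False)
        u = u - qi1 * (u.sum() / qi1.sum())
        self.u = u
        d2 = np.diff(u, n=2)
        shape = priors.precision_shape + 0.5 * len(d2)
        rate = priors.precision_rate + 0.5 * float(d2 @ d2)
        self.zeta2 = 1.0 / rng.gamma(shape=shape, scale=1.0 / rate)


class _SpatialBlock:
    """Matérn spatial residual W(s) with its (σ₀², r₀) hyperparameters."""

    def __init__(self, points: np.ndarray, inference: InferenceConfig,
                 cov: RangeGridCov | None = None):
        if cov is None:
            # a residual with range below the data's resolution degenerates
            # into a free per-point logit that can separate binary data;
            # floor the range grid at ~3x the nearest-neighbour spacing
            pts = as_points(points)
            d = cdist(pts, pts)
            np.fill_diagonal(d, np.inf)
            nn = float(np.median(d.min(axis=1)))
            cov = RangeGridCov(pts, n_grid=inference.range_grid_size,
                               min_range=3.0 * nn)
        self.cov = cov
        self.n = len(points)
        self.w = np.zeros(self.n)
        self.sigma2 = 0.5
        self.idx = self.cov.index_of(
            float(np.exp(np.mean(np.log(self.cov.ranges)))))

    @property
    def range(self) -> float:
        return float(self.cov.ranges[self.idx])

    def update_hypers(self, priors: PriorConfig, rng):
        q = self.cov.quad_form(self.idx, self.w)
        self.sigma2 = _update_variance(q, self.n, self.sigma2, priors.log_hyper_sd, rng)
        self.idx = _update_range_idx(
            self.cov, self.idx, self.sigma2, self.w, priors.log_hyper_sd, rng)

    def update_hypers_collapsed(self, resid: np.ndarray, omega: np.ndarray,
                                priors: PriorConfig, rng):
        """(σ₀², r₀) move with W integrated out of the PG pseudo-model."""
        def prec_fn(_):
            return omega, omega * resid

        self.idx, self.sigma2, _ = _collapsed_hyper_mh(
            self.cov, self.idx, self.sigma2, None, prec_fn, priors, rng)


class _LatentFieldBlock:
    """One uncertain covariate in the joint model.

    Latent values live on the union of species and abiotic measurement
    locations; abiotic observations attach through N(x, δ²) and species
    data through the Pólya-Gamma pseudo-likelihood (unless feedback is
    cut).  Hyperparameters (α, σ², r, δ²) are updated by conjugate or
    grid-MH steps.
    """

    def __init__(self, name: str, abiotic: FieldRealization,
                 species_points: np.ndarray, inference: InferenceConfig,
                 cov: RangeGridCov | None = None):
        self.name = name
        self.obs = abiotic
        sp = as_points(species_points)
        ap = abiotic.points
        # map species/abiotic rows into the union point set (dedup aligned case)
        d = cdist(sp, ap)
        nearest = d.argmin(axis=1)
        is_dup = d[np.arange(len(sp)), nearest] < 1e-12
        extra = np.where(~is_dup)[0]
        self.points = np.vstack([ap, sp[extra]])
        self.a_idx = np.arange(len(ap))
        self.s_idx = np.where(is_dup, nearest, 0)
        pos = {int(e): len(ap) + k for k, e in enumerate(extra)}
        for e in extra:
            self.s_idx[e] = pos[int(e)]
        self.cov = cov if cov is not None else RangeGridCov(
            self.points, n_grid=inference.range_grid_size)
        self.n = len(self.points)
        self._Qbuf = np.empty((self.n, self.n))
        # moment-based initial hyperparameters
        v = max(np.var(abiotic.values), 1e-6)
        self.alpha = float(np.mean(abiotic.values))
        self.sigma2 = 0.7 * v
        self.delta2 = max(0.3 * v, 1e-4)
        self.idx = self.cov.index_of(0.3 * float(cdist(self.points[:1], self.points).max()))
        self.x = np.full(self.n, self.alpha)
        self.x[self.a_idx] = abiotic.values
        self.fixed_hypers = False

    @property
    def range(self) -> float:
        return float(self.cov.ranges[self.idx])

    def x_at_species(self) -> np.ndarray:
        return self.x[self.s_idx]

    def update_x(self, beta_j: float, resid_s: np.ndarray, omega: np.ndarray,
                 feedback: bool, rng):
        """Sample latent values given PG residual resid_s = t − η₋ⱼ."""
        dprec = np.zeros(self.n)
        lin = np.zeros(self.n)
        np.add.at(dprec, self.a_idx, 1.0 / self.delta2)
        np.add.at(lin, self.a_idx, self.obs.values / self.delta2)
        if feedback:
            np.add.at(dprec, self.s_idx, beta_j**2 * omega)
            np.add.at(lin, self.s_idx, beta_j * omega * resid_s)
        Q = self.cov.precision_into(self.idx, self.sigma2, out=self._Qbuf)
        Q[np.diag_indices(self.n)] += dprec
        b = (self.alpha / self.sigma2) * self.cov.inv_dot_one(self.idx) + lin
        self.x = _sample_mvn_canonical(Q, b, rng, overwrite=True)

    def update_hypers(self, priors: PriorConfig, rng):
        if self.fixed_hypers:
            return
        Rinv_one = self.cov.inv_dot_one(self.idx) / self.sigma2
        prec_a = float(Rinv_one.sum()) + 1.0 / priors.fixed_effect_variance
        mean_a = float(self.x @ Rinv_one) / prec_a
        self.alpha = mean_a + rng.standard_normal() / np.sqrt(prec_a)
        resid = self.x - self.alpha
        q = self.cov.quad_form(self.idx, resid)
        self.sigma2 = _update_variance(q, self.n, self.sigma2, priors.log_hyper_sd, rng)
        self.idx = _update_range_idx(
            self.cov, self.idx, self.sigma2, resid, priors.log_hyper_sd, rng)
        err = self.obs.values - self.x[self.a_idx]
        shape = priors.precision_shape + 0.5 * len(err)
        rate = priors.precision_rate + 0.5 * float(err @ err)
        self.delta2 = 1.0 / rng.gamma(shape=shape, scale=1.0 / rate)

    def update_hypers_collapsed(self, beta_j: float, resid_s: np.ndarray,
                                omega: np.ndarray, feedback: bool,
                                priors: PriorConfig, rng):
        """(σ², r, δ²) move with the latent covariate field integrated out."""
        if self.fixed_hypers:
            return
        def prec_fn(d2):
            prec = np.zeros(self.n)
            val = np.zeros(self.n)
            np.add.at(prec, self.a_idx, 1.0 / d2)
            np.add.at(val, self.a_idx, self.obs.values / d2)
            if feedback:
                np.add.at(prec, self.s_idx, beta_j**2 * omega)
                np.add.at(val, self.s_idx, beta_j * omega * resid_s)
            return prec, val

        self.idx, self.sigma2, self.delta2 = _collapsed_hyper_mh(
            self.cov, self.idx, self.sigma2, self.delta2, prec_fn, priors, rng,
            mean=self.alpha)


# ---------------------------------------------------------------------------
# Fitted-model container
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """Posterior draws and summaries for one fitted SDM.

    ``beta_draws`` columns are (intercept, *linear_terms).  For the
    joint model, ``field_draws``/``field_hyper_draws`` hold latent
    covariate values on their union point sets and (α, σ², r, δ²); for
    the two-stage model ``stage1`` holds the per-covariate kriging
    posteriors.  ``W_draws``/``W_hyper_draws`` hold the spatial residual
    at the training locations and (σ₀², r₀).
    """

    kind: str
    spec: SdmSpec
    species: SpeciesObservations
    beta_draws: np.ndarray
    covariate_table: pd.DataFrame
    W_draws: np.ndarray | None = None
    W_hyper_draws: np.ndarray | None = None
    spline_draws: dict = field(default_factory=dict)
    spline_midpoints: dict = field(default_factory=dict)
    spline_zeta2_draws: dict = field(default_factory=dict)
    field_draws: dict = field(default_factory=dict)
    field_points: dict = field(default_factory=dict)
    field_hyper_draws: dict = field(default_factory=dict)
    stage1: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def coef_names(self) -> list[str]:
        return ["intercept", *self.spec.linear_terms]

    @property
    def coef_summary(self) -> pd.DataFrame:
        d = self.beta_draws
        return pd.DataFrame(
            {
                "mean": d.mean(axis=0),
                "sd": d.std(axis=0, ddof=1),
                "q2.5": np.percentile(d, 2.5, axis=0),
                "q97.5": np.percentile(d, 97.5, axis=0),
            },
            index=self.coef_names,
        )

    def spline_summary(self, term: str) -> pd.DataFrame:
        """(bin_midpoint, mean, sd, q2.5, q97.5) table for one spline."""
        u = self.spline_draws[term]
        return pd.DataFrame(
            {
                "bin_midpoint": self.spline_midpoints[term],
                "mean": u.mean(axis=0),
                "sd": u.std(axis=0, ddof=1),
                "q2.5": np.percentile(u, 2.5, axis=0),
                "q97.5": np.percentile(u, 97.5, axis=0),
            }
        )

    @property
    def n_draws(self) -> int:
        return len(self.beta_draws)

    def eta_draws(self) -> np.ndarray:
        """(n_draws, N) draws of the linear predictor at training points."""
        n, N = self.n_draws, len(self.species)
        eta = np.tile(self.beta_draws[:, :1], (1, N))
        for j, term in enumerate(self.spec.linear_terms):
            if self.kind == "joint":
                blk_idx = self._species_index(term)
                xs = self.field_draws[term][:, blk_idx]
                eta += self.beta_draws[:, j + 1 : j + 2] * xs
            else:
                x = self.covariate_table[term].to_numpy(dtype=float)
                eta += np.outer(self.beta_draws[:, j + 1], x)
        for term in self.spec.spline_terms:
            assignment, _ = bin_covariate(
                self.covariate_table[term].to_numpy(dtype=float), self.spec.n_bins
            )
            eta += self.spline_draws[term][:, assignment]
        if self.W_draws is not None:
            eta += self.W_draws
        return eta

    def mu_draws(self) -> np.ndarray:
        """(n_draws, N) draws of the occurrence probability at training points."""
        return logistic_link(self.eta_draws())

    def _species_index(self, term: str) -> np.ndarray:
        return self.diagnostics["_species_index"][term]


# ---------------------------------------------------------------------------
# Core Gibbs loop
# ---------------------------------------------------------------------------

def _run_gibbs(
    species: SpeciesObservations,
    spec: SdmSpec,
    X: np.ndarray,
    priors: PriorConfig,
    inference: InferenceConfig,
    kind: str,
    fields: dict | None = None,
    rng: np.random.Generator | None = None,
    hyper_schedule: list[dict] | None = None,
) -> FittedModel:
    """Shared Pólya-Gamma Gibbs sampler.

    ``X`` is the (N, K) matrix of linear covariate values (ignored for
    terms driven by latent ``fields`` in the joint model, where it only
    sets plotting/initial values).  ``fields`` maps linear-term names to
    `_LatentFieldBlock` instances (joint model only).
    """
    rng = rng if rng is not None else inference.rng()
    y = species.y
    N = len(y)
    K = len(spec.linear_terms)
    fields = fields or {}
    joint = kind == "joint"

    splines = []
    for term in spec.spline_terms:
        vals = species.covariates[term].to_numpy(dtype=float)
        splines.append(_SplineBlock(term, vals, spec.n_bins))

    spatial = None
    if spec.spatial_residual:
        spatial = _SpatialBlock(species.points, inference)

    p = 1 + K
    beta = np.zeros(p)
    prev = float(np.clip(y.mean(), 0.02, 0.98))
    beta[0] = np.log(prev / (1 - prev))
    prior_prec_beta = np.full(p, 1.0 / priors.fixed_effect_variance)

    def design() -> np.ndarray:
        B = np.empty((N, p))
        B[:, 0] = 1.0
        for j, term in enumerate(spec.linear_terms):
            B[:, j + 1] = fields[term].x_at_species() if term in fields else X[:, j]
        return B

    # iteration plan: contiguous keep window after warmup, or — with a
    # hyperparameter schedule (joint "cut" mode) — segments with fixed
    # field hyperparameters, each preceded by a short re-equilibration
    SEG_DISCARD = 25
    if hyper_schedule:
        n_seg = len(hyper_schedule)
        seg_keep = int(np.ceil(inference.n_draws / n_seg))
        keep_flag: list[bool] = []
        apply_at: dict[int, int] = {}
        for h in range(n_seg):
            apply_at[len(keep_flag)] = h
            discard = inference.n_warmup if h == 0 else SEG_DISCARD
            keep_flag.extend([False] * discard)
            keep_flag.extend(
                [True] * min(seg_keep, inference.n_draws - h * seg_keep))
        keep_flag_arr = np.array(keep_flag)
    else:
        apply_at = {}
        keep_flag_arr = np.arange(
            inference.n_warmup + inference.n_draws) >= inference.n_warmup
    n_iter = len(keep_flag_arr)
    Qbw = np.empty((p + N, p + N)) if spatial else None
    mh_scales = np.full(p, 0.12)
    mh_accepts = mh_tries = 0
    moment_cache: dict = {}
    keep_beta = np.empty((inference.n_draws, p))
    keep_W = np.empty((inference.n_draws, N)) if spatial else None
    keep_Wh = np.empty((inference.n_draws, 2)) if spatial else None
    keep_spl = {s.name: np.empty((inference.n_draws, s.d)) for s in splines}
    keep_z2 = {s.name: np.empty(inference.n_draws) for s in splines}
    keep_x = {t: np.empty((inference.n_draws, blk.n)) for t, blk in fields.items()}
    keep_xh = {t: np.empty((inference.n_draws, 4)) for t in fields}

    t0 = time.monotonic()
    truncated = False
    kept = 0
    for it in range(n_iter):
        if it in apply_at:
            for term, model in hyper_schedule[apply_at[it]].items():
                blk = fields[term]
                blk.alpha = model.intercept
                blk.sigma2 = model.matern.variance
                blk.delta2 = max(model.noise_variance, 1e-6)
                blk.idx = blk.cov.index_of(model.matern.range)
                blk.fixed_hypers = True
        B = design()
        spl_vals = sum((s.values_at_obs() for s in splines), np.zeros(N))
        w = spatial.w if spatial else np.zeros(N)
        eta = B @ beta + spl_vals + w
        omega = sample_polya_gamma(np.clip(eta, -ETA_CAP, ETA_CAP), rng)
        t = (y - 0.5) / omega

        # every few sweeps of a joint fit, move the spatial-residual
        # hyperparameters with W marginalized out — conditioned on a W
        # draw they barely move.  The direct/two-stage samplers mix fine
        # without this and are left alone
        collapse_now = it % 4 == 0
        if spatial and collapse_now and fields:
            spatial.update_hypers_collapsed(t - B @ beta - spl_vals, omega,
                                            priors, rng)

        # coefficients and spatial residual in one Gaussian block: W is
        # spatially confounded with the covariates, so separate updates
        # mix very slowly
        resid = t - spl_vals
        if spatial:
            Bw = B * omega[:, None]
            Q = Qbw
            Q[:p, :p] = Bw.T @ B + np.diag(prior_prec_beta)
            Q[:p, p:] = Bw.T
            Q[p:, :p] = Bw
            spatial.cov.precision_into(spatial.idx, spatial.sigma2, out=Q[p:, p:])
            Q[p:, p:][np.diag_indices(N)] += omega
            b = np.concatenate([B.T @ (omega * resid), omega * resid])
            draw = _sample_mvn_canonical(Q, b, rng, overwrite=True)
            beta, spatial.w = draw[:p], draw[p:]
            spatial.update_hypers(priors, rng)
            w = spatial.w
        else:
            Q = (B * omega[:, None]).T @ B + np.diag(prior_prec_beta)
            beta = _sample_mvn_canonical(Q, B.T @ (omega * (resid - w)), rng)

        # splines
        if splines:
            base = B @ beta + w
            for s in splines:
                others = sum(
                    (o.values_at_obs() for o in splines if o is not s), np.zeros(N)
                )
                s.update(t - base - others, omega, priors, rng)
            spl_vals = sum((s.values_at_obs() for s in splines), np.zeros(N))

        # latent covariate fields (joint model)
        if fields:
            use_kernel = inference.feedback
            for j, term in enumerate(spec.linear_terms):
                if term not in fields:
                    continue
                blk = fields[term]
                if blk.fixed_hypers and use_kernel:
                    # latent values are redrawn exactly inside the
                    # marginal-coefficient kernel below
                    continue
                eta_minus = (
                    B @ beta + spl_vals + w
                    - beta[j + 1] * blk.x_at_species()
                )
                if collapse_now:
                    blk.update_hypers_collapsed(
                        beta[j + 1], t - eta_minus, omega,
                        inference.feedback, priors, rng)
                blk.update_x(beta[j + 1], t - eta_minus, omega,
                             inference.feedback, rng)
                blk.update_hypers(priors, rng)
                B = design()

            # marginal coefficient move: beta and the latent fields form a
            # near-ridge, so every other sweep beta is moved against its
            # collapsed target (fields and W integrated out) and the
            # latents are redrawn exactly given the new beta
            if use_kernel and it % 2 == 0:
                eta = B @ beta + spl_vals + (spatial.w if spatial else 0.0)
                omega = sample_polya_gamma(np.clip(eta, -ETA_CAP, ETA_CAP), rng)
                t = (y - 0.5) / omega
                beta, n_acc = _marginal_beta_update(
                    list(spec.linear_terms), fields, spatial, beta, t, omega,
                    spl_vals, prior_prec_beta, rng, mh_scales, moment_cache)
                mh_accepts += n_acc
                mh_tries += 3
                if it < inference.n_warmup and it % 20 == 18:
                    rate = mh_accepts / max(mh_tries, 1)
                    mh_scales *= 1.25 if rate > 0.3 else 0.8
                    mh_accepts = mh_tries = 0
                B = design()
                w = spatial.w if spatial else np.zeros(N)

        if keep_flag_arr[it]:
            k = kept
            keep_beta[k] = beta
            if spatial:
                keep_W[k] = spatial.w
                keep_Wh[k] = (spatial.sigma2, spatial.range)
            for s in splines:
                keep_spl[s.name][k] = s.u
                keep_z2[s.name][k] = s.zeta2
            for term, blk in fields.items():
                keep_x[term][k] = blk.x
                keep_xh[term][k] = (blk.alpha, blk.sigma2, blk.range, blk.delta2)
            kept = k + 1
        if (
            inference.max_seconds is not None
            and it % 25 == 24
            and time.monotonic() - t0 > inference.max_seconds
        ):
            truncated = True
            break

    if truncated:
        warnings.warn(
            f"{kind} fit stopped after {time.monotonic() - t0:.0f}s with "
            f"{kept}/{inference.n_draws} draws kept",
            stacklevel=2,
        )
        if kept == 0:
            raise RuntimeError("runtime budget exhausted before any draws were kept")
        keep_beta = keep_beta[:kept]
        keep_W = keep_W[:kept] if spatial else None
        keep_Wh = keep_Wh[:kept] if spatial else None
        keep_spl = {k_: v[:kept] for k_, v in keep_spl.items()}
        keep_z2 = {k_: v[:kept] for k_, v in keep_z2.items()}
        keep_x = {k_: v[:kept] for k_, v in keep_x.items()}
        keep_xh = {k_: v[:kept] for k_, v in keep_xh.items()}

    chain = keep_beta[:, min(1, p - 1)]
    q = len(chain) // 4
    rhat = split_rhat(chain[: 4 * q].reshape(4, q)) if q >= 4 else np.nan
    ess = effective_sample_size(chain)
    diagnostics = {
        "kind": kind,
        "runtime_s": time.monotonic() - t0,
        "n_kept": len(keep_beta),
        "truncated": truncated,
        "rhat_beta": float(rhat) if np.isfinite(rhat) else None,
        "ess_beta": float(ess),
        "converged": bool(
            (not truncated)
            and (not np.isfinite(rhat)
                 # between-segment hyperparameter variance is real posterior
                 # spread, not non-convergence, under a hyper schedule
                 or rhat < inference.rhat_threshold + (0.2 if hyper_schedule else 0.0))
        ),
        "constraints": {"splines": "sum-to-zero over bins"},
        "_species_index": {t: blk.s_idx for t, blk in fields.items()},
    }

    cov_table = species.covariates.copy()
    for j, term in enumerate(spec.linear_terms):
        if term not in cov_table.columns:
            cov_table[term] = X[:, j]
    return FittedModel(
        kind=kind,
        spec=spec,
        species=species,
        beta_draws=keep_beta,
        covariate_table=cov_table,
        W_draws=keep_W,
        W_hyper_draws=keep_Wh,
        spline_draws=keep_spl,
        spline_midpoints={s.name: s.midpoints for s in splines},
        spline_zeta2_draws=keep_z2,
        field_draws=keep_x,
        field_points={t: blk.points for t, blk in fields.items()},
        field_hyper_draws=keep_xh,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Public fitters
# ---------------------------------------------------------------------------

def _covariate_matrix(species: SpeciesObservations, spec: SdmSpec) -> np.ndarray:
    cols = []
    for term in spec.linear_terms:
        if term not in species.covariates.columns or \
                species.covariates[term].isna().any():
            raise ValueError(
                f"covariate {term!r} is not observed at every species location; "
                "use fit_two_stage or fit_joint for misaligned data"
            )
        cols.append(species.covariates[term].to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(species), 0))


def fit_direct(
    species: SpeciesObservations,
    spec: SdmSpec,
    inference: InferenceConfig | None = None,
    priors: PriorConfig | None = None,
) -> FittedModel:
    """Logistic GAMM treating observed covariate values as exact truth.

    Only possible with spatially aligned data; with measurement error
    present the linear effects suffer regression dilution.
    """
    inference = inference or InferenceConfig()
    priors = priors or spec.priors
    X = _covariate_matrix(species, spec)
    return _run_gibbs(species, spec, X, priors, inference, kind="direct")


def fit_two_stage(
    species: SpeciesObservations,
    abiotic: dict[str, FieldRealization],
    spec: SdmSpec,
    priors: PriorConfig | None = None,
    inference: InferenceConfig | None = None,
    stage1_inference: InferenceConfig | None = None,
) -> FittedModel:
    """Krige each uncertain covariate, then plug posterior means into the GAMM.

    Stage 1 fits an independent kriging model per linear term from its
    noisy point observations; stage 2 runs `fit_direct` on the predicted
    means x̂ⱼ(sᵢ).  The kriging uncertainty is discarded — that is the
    point of comparison with the joint model.

    Stage 1 uses the multi-start Laplace engine by default — the
    mode-centred approximation a practitioner's kriging software
    computes; its light hyperparameter tails keep the plug-in means
    stable.  Pass ``stage1_inference`` to override (engine, chain
    lengths, seed offset are all taken from it).
    """
    inference = inference or InferenceConfig()
    priors = priors or spec.priors
    missing = [t for t in spec.linear_terms if t not in abiotic]
    if missing:
        raise ValueError(f"no abiotic observations supplied for {missing}")
    seeds = np.random.SeedSequence(inference.seed).generate_state(
        len(spec.linear_terms) + 1) % (2**31)
    if stage1_inference is None:
        stage1_inference = InferenceConfig(
            **{**inference.__dict__, "engine": "laplace"})

    stage1: dict[str, FieldPosterior] = {}
    species2 = SpeciesObservations(
        points=species.points, y=species.y, covariates=species.covariates.copy()
    )
    for k, term in enumerate(spec.linear_terms):
        cfg = InferenceConfig(**{**stage1_inference.__dict__, "seed": int(seeds[k])})
        post = fit_latent_field(abiotic[term], priors, cfg)
        stage1[term] = post
        mean, _ = post.latent_moments(
            species.points, n_hyper_draws=inference.n_field_draws)
        species2.covariates[term] = mean

    X = _covariate_matrix(species2, spec)
    fit = _run_gibbs(
        species2, spec, X, priors, inference, kind="two_stage",
        rng=np.random.default_rng(int(seeds[-1])),
    )
    fit.stage1 = stage1
    for term, post in stage1.items():
        fit.diagnostics.setdefault("stage1", {})[term] = post.diagnostics
    return fit


def fit_joint(
    species: SpeciesObservations,
    abiotic: dict[str, FieldRealization],
    spec: SdmSpec,
    priors: PriorConfig | None = None,
    inference: InferenceConfig | None = None,
    field_hypers: dict[str, LatentFieldModel] | str = "cut",
    n_hyper_sets: int = 6,
) -> FittedModel:
    """Joint errors-in-variables fit of kriging models and GAMM.

    One posterior over all K + 1 sub-models: latent covariate values at
    species locations are random variables feeding η, so coefficient
    posteriors carry the covariate uncertainty and species data inform
    the fields (feedback; disable via ``inference.feedback = False``).

    ``field_hypers`` controls the covariate-field hyperparameters
    (α, σ², r, δ²).  Fully sampled hyperparameters ("sample") sit on a
    ridge with the coefficients and latent fields and mix prohibitively
    slowly, so the default "cut" propagates their stage-1 kriging
    posterior by running the sampler in ``n_hyper_sets`` segments, each
    conditioned on one posterior draw of the hyperparameters
    (multiple-imputation style; species data do not feed back into the
    hyperparameters, but do feed back into the latent field values).
    "empirical_bayes" fixes them at the stage-1 posterior medians; a
    mapping of term → `LatentFieldModel` fixes them at supplied values,
    and a mapping of term → `FieldPosterior` (e.g. the ``stage1`` of a
    two-stage fit on the same data) reuses those posteriors for the
    schedule instead of refitting stage 1.
    """
    inference = inference or InferenceConfig()
    priors = priors or spec.priors
    missing = [t for t in spec.linear_terms if t not in abiotic]
    if missing:
        raise ValueError(f"no abiotic observations supplied for {missing}")

    fixed_hypers: dict[str, LatentFieldModel] = {}
    hyper_schedule: list[dict[str, LatentFieldModel]] | None = None
    supplied_posteriors = (
        isinstance(field_hypers, dict)
        and field_hypers
        and all(isinstance(v, FieldPosterior) for v in field_hypers.values())
    )
    if (field_hypers in ("cut", "empirical_bayes") or supplied_posteriors) \
            and spec.linear_terms:
        seeds = np.random.SeedSequence(inference.seed + 101).generate_state(
            len(spec.linear_terms) + 1) % (2**31)
        stage1_draws: dict[str, np.ndarray] = {}
        if supplied_posteriors:
            stage1_draws = {t: field_hypers[t].hyper_draws
                            for t in spec.linear_terms}
            field_hypers = "cut"
        else:
            s1_cfg = dict(inference.__dict__)
            s1_cfg.update(engine="laplace")
            for k, term in enumerate(spec.linear_terms):
                cfg = InferenceConfig(**{**s1_cfg, "seed": int(seeds[k])})
                post = fit_latent_field(abiotic[term], priors, cfg)
                stage1_draws[term] = post.hyper_draws

        def _model(row) -> LatentFieldModel:
            return LatentFieldModel(
                intercept=float(row[0]),
                matern=MaternParams(variance=float(row[1]), range=float(row[2])),
                noise_variance=float(row[3]),
            )

        medians = {t: _model(np.median(d, axis=0)) for t, d in stage1_draws.items()}
        if field_hypers == "empirical_bayes":
            fixed_hypers = medians
        else:
            pick = np.random.default_rng(int(seeds[-1]))
            hyper_schedule = [medians]
            for _ in range(max(n_hyper_sets, 1) - 1):
                hyper_schedule.append({
                    t: _model(d[pick.integers(0, len(d))])
                    for t, d in stage1_draws.items()
                })
            fixed_hypers = medians  # initial state before the schedule kicks in
    elif isinstance(field_hypers, dict):
        fixed_hypers = dict(field_hypers)
    elif field_hypers != "sample":
        raise ValueError(f"unknown field_hypers option {field_hypers!r}")

    fields: dict[str, _LatentFieldBlock] = {}
    cov_cache: list[tuple[np.ndarray, RangeGridCov]] = []
    for term in spec.linear_terms:
        # share one RangeGridCov between covariates whose point sets coincide
        blk = _LatentFieldBlock(
            term, abiotic[term], species.points, inference,
            cov=_find_cached(cov_cache, abiotic[term], species.points),
        )
        cov_cache.append((blk.points, blk.cov))
        if term in fixed_hypers:
            m = fixed_hypers[term]
            blk.alpha = m.intercept
            blk.sigma2 = m.matern.variance
            blk.delta2 = max(m.noise_variance, 1e-6)
            blk.idx = blk.cov.index_of(m.matern.range)
            blk.fixed_hypers = True
        fields[term] = blk
    X = np.column_stack(
        [fields[t].x_at_species() for t in spec.linear_terms]
    ) if spec.linear_terms else np.empty((len(species), 0))
    return _run_gibbs(
        species, spec, X, priors, inference, kind="joint", fields=fields,
        hyper_schedule=hyper_schedule,
    )


def _find_cached(cache, abiotic: FieldRealization, species_points) -> RangeGridCov | None:
    """Reuse a RangeGridCov when another covariate shares the union points."""
    sp = as_points(species_points)
    d = cdist(sp, abiotic.points)
    nearest = d.argmin(axis=1)
    dup = d[np.arange(len(sp)), nearest] < 1e-12
    pts = np.vstack([abiotic.points, sp[~dup]])
    for cached_pts, cov in cache:
        if cached_pts.shape == pts.shape and np.array_equal(cached_pts, pts):
            return cov
    return None


# ---------------------------------------------------------------------------
# Prediction at new locations / on grids
# ---------------------------------------------------------------------------

class _ConditionalField:
    """Per-range-index cached Gaussian conditioning of a Matérn field.

    Conditions field values at target points on known values at source
    points, for draws whose range lives on a small discrete grid: the
    expensive Corr_ts R_ss⁻¹ and conditional-correlation Cholesky are
    computed once per distinct range value.
    """

    def __init__(self, source_points: np.ndarray, target_points: np.ndarray):
        self.src = source_points
        self.tgt = target_points
        self._cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def _factors(self, rng_val: float):
        key = round(float(rng_val), 12)
        if key not in self._cache:
            n = len(self.src)
            R_ss = matern_correlation_fast(cdist(self.src, self.src), rng_val)
            np.fill_diagonal(R_ss, 1.0 + JITTER)
            C_ts = matern_correlation_fast(cdist(self.tgt, self.src), rng_val)
            cf = cho_factor(R_ss, lower=True)
            proj = cho_solve(cf, C_ts.T).T  # C_ts R_ss⁻¹
            R_tt = matern_correlation_fast(cdist(self.tgt, self.tgt), rng_val)
            np.fill_diagonal(R_tt, 1.0)
            cond = R_tt - proj @ C_ts.T
            cond = 0.5 * (cond + cond.T) + JITTER * np.eye(len(self.tgt))
            L = np.linalg.cholesky(cond)
            self._cache[key] = (proj, L)
        return self._cache[key]

    def conditional_mean(self, values: np.ndarray, rng_val: float,
                         mean: float = 0.0) -> np.ndarray:
        proj, _ = self._factors(rng_val)
        return mean + proj @ (values - mean)

    def conditional_draw(self, values: np.ndarray, rng_val: float, sigma2: float,
                         rng: np.random.Generator, mean: float = 0.0) -> np.ndarray:
        proj, L = self._factors(rng_val)
        m = mean + proj @ (values - mean)
        return m + np.sqrt(sigma2) * (L @ rng.standard_normal(len(self.tgt)))


def _thin_indices(n: int, n_max: int) -> np.ndarray:
    if n <= n_max:
        return np.arange(n)
    return np.linspace(0, n - 1, n_max).round().astype(int)


def predict_eta_draws(
    fit: FittedModel,
    points,
    covariate_values: pd.DataFrame | None = None,
    n_draws: int = 60,
    rng: np.random.Generator | None = None,
    include_field_noise: bool = True,
) -> np.ndarray:
    """Joint posterior draws of η at new points, shape (n_draws, n_points).

    Uncertain covariates come from the model's own machinery (stage-1
    kriging draws for two-stage — as the plug-in means, constants per
    stage-1 posterior mean — latent-field conditional draws for joint);
    spline covariates must be supplied in ``covariate_values``.  The
    spatial residual is conditionally simulated per draw.
    """
    pts = as_points(points)
    rng = rng or np.random.default_rng(0)
    idx = _thin_indices(fit.n_draws, n_draws)
    n_out, n_pts = len(idx), len(pts)
    eta = np.tile(fit.beta_draws[idx, :1], (1, n_pts))

    for j, term in enumerate(fit.spec.linear_terms):
        betas = fit.beta_draws[idx, j + 1]
        if fit.kind == "joint":
            cond = _ConditionalField(fit.field_points[term], pts)
            for k, i in enumerate(idx):
                a, s2, r, _ = fit.field_hyper_draws[term][i]
                xv = fit.field_draws[term][i]
                if include_field_noise:
                    xt = cond.conditional_draw(xv, r, s2, rng, mean=a)
                else:
                    xt = cond.conditional_mean(xv, r, mean=a)
                eta[k] += betas[k] * xt
        elif fit.kind == "two_stage":
            mean, _ = fit.stage1[term].latent_moments(pts, n_hyper_draws=n_draws)
            eta += np.outer(betas, mean)
        else:  # direct: values must be observed at the prediction points
            if covariate_values is None or term not in covariate_values.columns:
                raise ValueError(
                    f"direct model needs observed covariate {term!r} at prediction "
                    "points (it has no kriging model to interpolate with)"
                )
            eta += np.outer(betas, covariate_values[term].to_numpy(dtype=float))

    for term in fit.spec.spline_terms:
        if covariate_values is None or term not in covariate_values.columns:
            raise ValueError(f"spline covariate {term!r} required at prediction points")
        vals = covariate_values[term].to_numpy(dtype=float)
        train_vals = fit.covariate_table[term].to_numpy(dtype=float)
        _, midpoints = bin_covariate(train_vals, fit.spec.n_bins)
        edges_lo, edges_hi = train_vals.min(), train_vals.max()
        width = (edges_hi - edges_lo) / fit.spec.n_bins
        assignment = np.clip(
            ((vals - edges_lo) / width).astype(int), 0, fit.spec.n_bins - 1
        )
        eta += fit.spline_draws[term][idx][:, assignment]

    if fit.W_draws is not None:
        cond = _ConditionalField(fit.species.points, pts)
        for k, i in enumerate(idx):
            s2, r = fit.W_hyper_draws[i]
            if include_field_noise:
                eta[k] += cond.conditional_draw(fit.W_draws[i], r, s2, rng)
            else:
                eta[k] += cond.conditional_mean(fit.W_draws[i], r)
    return eta


def predict_occurrence_map(
    fit: FittedModel,
    grid: PredictionGrid,
    covariate_values: pd.DataFrame | None = None,
    n_draws: int = 60,
    rng: np.random.Generator | None = None,
) -> tuple[GridMap, GridMap]:
    """Posterior (mean, sd) maps of log-odds η and probability μ.

    Probability summaries are computed draw-wise — mean of
    logistic(η draws), never logistic of the mean draw.
    """
    eta = predict_eta_draws(fit, grid.cell_centres(), covariate_values,
                            n_draws=n_draws, rng=rng)
    mu = logistic_link(eta)
    log_odds = GridMap(grid=grid, mean=eta.mean(0), sd=eta.std(0, ddof=1),
                       quantity="log_odds")
    prob = GridMap(grid=grid, mean=mu.mean(0), sd=mu.std(0, ddof=1),
                   quantity="probability")
    return log_odds, prob


def predict_covariate_map(
    fit: FittedModel,
    grid: PredictionGrid,
    term: str,
    n_draws: int = 60,
    rng: np.random.Generator | None = None,
) -> GridMap:
    """Posterior (mean, sd) map of one uncertain covariate's latent field."""
    pts = grid.cell_centres()
    rng = rng or np.random.default_rng(0)
    if fit.kind == "two_stage":
        mean, sd = fit.stage1[term].latent_moments(pts, n_hyper_draws=n_draws)
        return GridMap(grid=grid, mean=mean, sd=sd, quantity=f"covariate:{term}")
    if fit.kind != "joint":
        raise ValueError("direct model has no covariate field to map")
    idx = _thin_indices(fit.n_draws, n_draws)
    cond = _ConditionalField(fit.field_points[term], pts)
    draws = np.empty((len(idx), len(pts)))
    for k, i in enumerate(idx):
        a, s2, r, _ = fit.field_hyper_draws[term][i]
        draws[k] = cond.conditional_draw(fit.field_draws[term][i], r, s2, rng, mean=a)
    return GridMap(grid=grid, mean=draws.mean(0), sd=draws.std(0, ddof=1),
                   quantity=f"covariate:{term}")


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def _pearson_or_none(a: np.ndarray, b: np.ndarray):
    a, b = np.asarray(a, float), np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return None  # undefined for constant or degenerate inputs
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ComparisonReport:
    """Pairwise comparison of two fitted models on the same spec/grid."""

    coefficients: pd.DataFrame
    coefficient_correlation: float | None
    map_correlations: dict

    def __str__(self) -> str:  # forest-plot style text table
        lines = ["coefficient comparison (A vs B):", self.coefficients.to_string()]
        lines.append(f"coefficient correlation: {self.coefficient_correlation}")
        for name, r in self.map_correlations.items():
            lines.append(f"map correlation [{name}]: "
                         f"{'undefined (constant map)' if r is None else f'{r:.4f}'}")
        return "\n".join(lines)


def compare_models(
    fitA: FittedModel,
    fitB: FittedModel,
    mapsA: dict[str, GridMap] | None = None,
    mapsB: dict[str, GridMap] | None = None,
) -> ComparisonReport:
    """Compare coefficients and prediction maps of two fits.

    Returns the per-coefficient forest table, the Pearson correlation of
    coefficient posterior means, and a per-map Pearson correlation over
    unmasked cells (None where a map is constant — reported as
    undefined rather than propagating NaN).
    """
    if fitA.spec.linear_terms != fitB.spec.linear_terms:
        raise ValueError("fits have different model specifications")
    sa, sb = fitA.coef_summary, fitB.coef_summary
    coef = sa.join(sb, lsuffix="_A", rsuffix="_B")
    coef_corr = _pearson_or_none(sa["mean"].to_numpy(), sb["mean"].to_numpy())

    map_corr: dict = {}
    mapsA, mapsB = mapsA or {}, mapsB or {}
    for name in sorted(set(mapsA) & set(mapsB)):
        ma, mb = mapsA[name], mapsB[name]
        if ma.grid != mb.grid:
            raise ValueError(f"maps {name!r} are on different grids")
        keep = np.ones(ma.grid.n_cells, dtype=bool)
        if ma.mask is not None:
            keep &= ~ma.mask
        if mb.mask is not None:
            keep &= ~mb.mask
        map_corr[name] = _pearson_or_none(ma.mean[keep], mb.mean[keep])
    return ComparisonReport(
        coefficients=coef,
        coefficient_correlation=coef_corr,
        map_correlations=map_corr,
    )
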