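"""Shared inference machinery: configuration, Pólya-Gamma draws,
cached range-grid covariances, and convergence diagnostics.

Two sampling engines exist in the package.  Kriging hyperparameter
posteriors (4 parameters, Gaussian marginal likelihood) use either a
Laplace approximation on the log scale or emcee ensemble MCMC.  The
logistic GAMMs (direct / two-stage / joint) use a Pólya-Gamma Gibbs
sampler: augmenting each Bernoulli observation with ω ~ PG(1, η) makes
every latent Gaussian block conditionally conjugate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist

from .random_fields import JITTER, as_points, matern_correlation_fast

__all__ = ["InferenceConfig", "sample_polya_gamma"]


@dataclass
class InferenceConfig:
    """Engine settings shared by all fitters.

    ``engine`` selects the kriging hyperparameter method ("laplace" or
    "mcmc").  ``n_warmup``/``n_draws`` control both the Gibbs samplers
    (warmup discarded, draws kept) and the MCMC engine.  ``feedback``
    lets the joint model's species data inform the covariate fields
    (cutting it yields a sensitivity-analysis variant).  ``max_seconds``
    is a soft budget for joint fits: exceeded, the sampler stops early
    and flags the result.
    """

    engine: str = "laplace"
    n_chains: int = 4
    n_warmup: int = 500
    n_draws: int = 1000
    seed: int = 0
    thin: int = 1
    range_grid_size: int = 16
    n_field_draws: int = 60  # thinned draws used for field/map reconstruction
    feedback: bool = True
    max_seconds: float | None = None
    rhat_threshold: float = 1.05
    ess_threshold: float = 200.0

    def __post_init__(self):
        if self.engine not in ("laplace", "mcmc"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.n_draws < 500:
            warnings.warn(
                f"n_draws={self.n_draws} < 500; reported summaries may be noisy",
                stacklevel=2,
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Pólya-Gamma augmentation
# ---------------------------------------------------------------------------

def sample_polya_gamma(
    z: np.ndarray, rng: np.random.Generator, n_terms: int = 100
) -> np.ndarray:
    """Draw ω ~ PG(1, z) elementwise via the truncated infinite sum.

    PG(1, z) = (1/2π²) Σ_k g_k / ((k − ½)² + z²/4π²) with g_k ~ Exp(1).
    The series is truncated at ``n_terms`` and the (deterministic) mean
    of the dropped tail is added back, so E[ω] = tanh(z/2)/(2z) holds
    exactly; the residual variance error is O(1/n_terms³) and
    negligible inside a Gibbs sweep.
    """
    z = np.abs(np.asarray(z, dtype=float))
    k = np.arange(1, n_terms + 1, dtype=float)[:, None]
    denom = (k - 0.5) ** 2 + (z[None, :] / (2.0 * np.pi)) ** 2
    g = rng.standard_exponential(size=(n_terms, z.size))
    omega = (g / denom).sum(axis=0) / (2.0 * np.pi**2)
    mean_full = np.where(z > 1e-12, np.tanh(z / 2.0) / (2.0 * np.maximum(z, 1e-12)), 0.25)
    mean_trunc = (1.0 / denom).sum(axis=0) / (2.0 * np.pi**2)
    return omega + (mean_full - mean_trunc)


# ---------------------------------------------------------------------------
# Discrete range grid for Matérn fields inside Gibbs samplers
# ---------------------------------------------------------------------------

class RangeGridCov:
    """Precomputed Matérn correlation inverses over a discrete range grid.

    Gibbs updates of a Matérn field's (σ², range) need the correlation
    inverse and log-determinant for every proposed range.  At desk scale
    the covariances are dense, so the range is restricted to a
    log-spaced grid spanning the data extent and R(r)⁻¹ / log|R(r)| are
    computed once per point set.  σ² remains continuous (it only scales
    R), as do the mean and noise parameters.
    """

    def __init__(self, points, ranges=None, n_grid: int = 16,
                 min_range: float | None = None):
        self.points = as_points(points)
        n = len(self.points)
        d = cdist(self.points, self.points)
        if ranges is None:
            extent = float(d.max())
            if extent <= 0:
                raise ValueError("degenerate point set: zero spatial extent")
            lo = 0.05 * extent
            if min_range is not None:
                lo = min(max(lo, min_range), 0.5 * extent)
            ranges = np.geomspace(lo, 2.0 * extent, n_grid)
        self.ranges = np.asarray(ranges, dtype=float)
        self.n = n
        self._d = d
        self._inv = []
        self._corr: dict[int, np.ndarray] = {}
        self._logdet = np.empty(len(self.ranges))
        eye = np.eye(n)
        for i, r in enumerate(self.ranges):
            R = matern_correlation_fast(d, r)
            np.fill_diagonal(R, 1.0)
            R += JITTER * eye
            L = np.linalg.cholesky(R)
            self._logdet[i] = 2.0 * np.sum(np.log(np.diag(L)))
            Linv = solve_triangular(L, eye, lower=True)
            self._inv.append(Linv.T @ Linv)

    def corr(self, idx: int) -> np.ndarray:
        """Correlation matrix R(r) for grid index ``idx``, lazily cached."""
        if idx not in self._corr:
            R = matern_correlation_fast(self._d, self.ranges[idx])
            np.fill_diagonal(R, 1.0 + JITTER)
            self._corr[idx] = R
        return self._corr[idx]

    def corr_chol(self, idx: int) -> np.ndarray:
        """Lower Cholesky factor of R(r), lazily cached."""
        if not hasattr(self, "_chol"):
            self._chol = {}
        if idx not in self._chol:
            self._chol[idx] = np.linalg.cholesky(self.corr(idx))
        return self._chol[idx]

    def index_of(self, range_value: float) -> int:
        return int(np.argmin(np.abs(np.log(self.ranges) - np.log(range_value))))

    def precision(self, idx: int, sigma2: float) -> np.ndarray:
        """Prior precision (σ² R(r))⁻¹ for grid index ``idx``."""
        return self._inv[idx] / sigma2

    def precision_into(self, idx: int, sigma2: float, out: np.ndarray) -> np.ndarray:
        """Write (σ² R(r))⁻¹ into a preallocated buffer (hot Gibbs path)."""
        return np.multiply(self._inv[idx], 1.0 / sigma2, out=out)

    def inv_dot_one(self, idx: int) -> np.ndarray:
        """R(r)⁻¹ · 1, cached per grid index."""
        if not hasattr(self, "_inv_one"):
            self._inv_one = {}
        if idx not in self._inv_one:
            self._inv_one[idx] = self._inv[idx] @ np.ones(self.n)
        return self._inv_one[idx]

    def quad_form(self, idx: int, resid: np.ndarray) -> float:
        """residᵀ R(r)⁻¹ resid for grid index ``idx``."""
        return float(resid @ (self._inv[idx] @ resid))

    def log_likelihood(
        self, idx: int, sigma2: float, resid: np.ndarray
    ) -> float:
        """log N(resid; 0, σ² R(r)) up to the 2π constant."""
        q = self.quad_form(idx, resid)
        return -0.5 * (self._logdet[idx] + self.n * np.log(sigma2) + q / sigma2)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def split_rhat(chains: np.ndarray) -> float:
    """Split-R̂ of Gelman et al. for draws shaped (n_chains, n_iter)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        chains = chains[None, :]
    half = chains.shape[1] // 2
    if half < 2:
        return np.nan
    parts = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = parts.shape
    means = parts.mean(axis=1)
    w = parts.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a single chain via initial-positive-sequence autocorrelation."""
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for k in range(1, n // 2):
        if acf[k] < 0.0:
            break
        tau += 2.0 * acf[k]
    return float(n / max(tau, 1.0))
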