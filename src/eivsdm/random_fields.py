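"""Matérn (ν = 1) Gaussian random fields on point sets.

The spatial building block of the whole package: stationary, isotropic
Gaussian random fields with a Matérn covariance of smoothness ν = 1,
parameterized by a marginal variance σ² and a *range* — the distance at
which the spatial correlation has decayed to ≈ 0.14, related to the
Matérn scale parameter by κ = √8 / range.

Also provides the confounded-covariate construction used by the
simulation study: two covariates X₁ = Z + Z₁ and X₂ = Z + Z₂ built from
three independent field realizations, giving Var = 1 and Cov = 0.5 when
each component field has variance 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import kv

__all__ = [
    "MaternParams",
    "FieldRealization",
    "as_points",
    "matern_correlation",
    "matern_covariance_matrix",
    "simulate_grf",
    "make_confounded_pair",
]

#: Relative jitter added to covariance diagonals before factorization.
JITTER = 1e-8


def as_points(points) -> np.ndarray:
    """Coerce to an (n, 2) float array of planar coordinates.

    Accepts anything array-like with two columns (or a single (x, y)
    pair).  Coordinates must be finite; units are whatever the caller
    uses (km for projected data, unit-square units in simulations).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be (n, 2), got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


@dataclass(frozen=True)
class MaternParams:
    """Matérn covariance parameters: variance σ², range r, smoothness ν.

    Only ν = 1 is supported; the scale parameter κ = √8 / range is
    derived, never stored.
    """

    variance: float
    range: float
    smoothness: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.variance) and self.variance > 0):
            raise ValueError(f"variance must be > 0, got {self.variance}")
        if not (np.isfinite(self.range) and self.range > 0):
            raise ValueError(f"range must be > 0, got {self.range}")
        if self.smoothness != 1.0:
            raise ValueError("only smoothness ν = 1 is supported")

    @property
    def kappa(self) -> float:
        """Matérn scale parameter κ = √8 / range (ν = 1 convention)."""
        return np.sqrt(8.0) / self.range


@dataclass
class FieldRealization:
    """Values of a spatial field at a point set.

    Used both for noise-free simulated truth and for noisy point
    observations of a covariate.
    """

    points: np.ndarray
    values: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.points = as_points(self.points)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.points):
            raise ValueError(
                f"{len(self.values)} values for {len(self.points)} points"
            )

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.points[:, 0], "y": self.points[:, 1], "value": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FieldRealization":
        df = pd.read_csv(path)
        missing = {"x", "y", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns in {path}: {sorted(missing)}")
        return cls(points=df[["x", "y"]].to_numpy(), values=df["value"].to_numpy())


def matern_correlation(d, range: float):
    """Matérn ν = 1 correlation at distance(s) ``d``.

    ρ(d) = (κ d) · K₁(κ d) with κ = √8 / range, where K₁ is the modified
    Bessel function of the second kind.  Equals 1 at d = 0 (as a limit)
    and decays to ≈ 0.14 at d = range.
    """
    if not (np.isfinite(range) and range > 0):
        raise ValueError(f"range must be > 0, got {range}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    kd = np.sqrt(8.0) / range * d
    with np.errstate(invalid="ignore"):
        rho = np.where(kd > 0, kd * kv(1, np.where(kd > 0, kd, 1.0)), 1.0)
    return rho if rho.ndim else float(rho)


# --- fast interpolated correlation for hot inference paths ----------------
# rho(u) = u K1(u) tabulated on a uniform grid; linear interpolation with
# direct indexing.  Max absolute error ~2.4e-7 (worst near u=0 where the
# curvature has a log singularity); used only inside likelihood evaluations
# and samplers, never in the public exact-correlation API.
_FAST_UMAX = 60.0
_FAST_N = 120_000
_fast_table: np.ndarray | None = None


def _matern1_fast(kd: np.ndarray) -> np.ndarray:
    global _fast_table
    if _fast_table is None:
        u = np.linspace(0.0, _FAST_UMAX, _FAST_N + 1)
        _fast_table = np.where(u > 0, u * kv(1, np.maximum(u, 1e-300)), 1.0)
    inv_du = _FAST_N / _FAST_UMAX
    x = np.clip(kd, 0.0, _FAST_UMAX) * inv_du
    i = x.astype(np.int64)
    np.clip(i, 0, _FAST_N - 1, out=i)
    f = x - i
    return _fast_table[i] * (1.0 - f) + _fast_table[i + 1] * f


def matern_correlation_fast(d, range: float) -> np.ndarray:
    """Interpolated Matérn ν = 1 correlation (abs. error ≤ ~2.4e-7)."""
    if not (np.isfinite(range) and range > 0):
        raise ValueError(f"range must be > 0, got {range}")
    return _matern1_fast(np.sqrt(8.0) / range * np.asarray(d, dtype=float))


def matern_covariance_fast(points_a, points_b, params: MaternParams) -> np.ndarray:
    """Interpolated covariance block; ``points_b=None`` gives the square
    matrix with exact σ² diagonal."""
    pts_a = as_points(points_a)
    if points_b is None:
        d = cdist(pts_a, pts_a)
        cov = params.variance * matern_correlation_fast(d, params.range)
        np.fill_diagonal(cov, params.variance)
        return cov
    d = cdist(pts_a, as_points(points_b))
    return params.variance * matern_correlation_fast(d, params.range)


def matern_covariance_matrix(points, params: MaternParams) -> np.ndarray:
    """Dense Matérn covariance matrix σ² ρ(‖aᵢ − aⱼ‖) over a point set.

    Duplicate points are allowed (identical rows); the diagonal is
    exactly σ².  No jitter is added here — factorization routines add
    ``JITTER · σ²`` themselves.
    """
    pts = as_points(points)
    d = cdist(pts, pts)
    cov = params.variance * matern_correlation(d, params.range)
    np.fill_diagonal(cov, params.variance)
    return cov


def matern_cross_covariance(points_a, points_b, params: MaternParams) -> np.ndarray:
    """Cross-covariance block σ² ρ(‖aᵢ − bⱼ‖) between two point sets."""
    d = cdist(as_points(points_a), as_points(points_b))
    return params.variance * matern_correlation(d, params.range)


def chol_with_jitter(cov: np.ndarray, scale: float) -> np.ndarray:
    """Lower Cholesky factor of ``cov + JITTER·scale·I``; loud failure."""
    n = cov.shape[0]
    try:
        return np.linalg.cholesky(cov + JITTER * scale * np.eye(n))
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"covariance factorization failed for n={n} even after adding "
            f"jitter {JITTER * scale:g}; smallest eigenvalue "
            f"{np.linalg.eigvalsh(cov).min():g}"
        ) from err


def simulate_grf(points, params: MaternParams, seed: int) -> FieldRealization:
    """Draw one zero-mean Gaussian random field realization at ``points``.

    Exact dense simulation: values ~ MVN(0, Σ(σ², range)) via Cholesky.
    Reproducible: the same (points, params, seed) give identical values.
    """
    pts = as_points(points)
    cov = matern_covariance_matrix(pts, params)
    L = chol_with_jitter(cov, params.variance)
    rng = np.random.default_rng(seed)
    values = L @ rng.standard_normal(len(pts))
    return FieldRealization(points=pts, values=values, seed=seed)


def make_confounded_pair(
    z: FieldRealization, z1: FieldRealization, z2: FieldRealization
) -> tuple[FieldRealization, FieldRealization]:
    """Build the confounded covariate pair X₁ = Z + Z₁, X₂ = Z + Z₂.

    With the three inputs independent realizations of variance-0.5
    fields on a shared point set, the implied moments are
    Var[X₁] = Var[X₂] = 1.0 and Cov[X₁, X₂] = 0.5.
    """
    if not (
        z.points.shape == z1.points.shape == z2.points.shape
        and np.array_equal(z.points, z1.points)
        and np.array_equal(z.points, z2.points)
    ):
        raise ValueError("all three realizations must share the same point set")
    x1 = FieldRealization(points=z.points, values=z.values + z1.values)
    x2 = FieldRealization(points=z.points, values=z.values + z2.values)
    return x1, x2
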