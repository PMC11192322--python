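"""Structured additive predictor for the species distribution model.

The SDM is a Bayesian logistic GAMM: presence/absence Y(sᵢ) ~
Bernoulli(μᵢ) with logit(μᵢ) = ηᵢ and

    ηᵢ = β₀ + Σⱼ βⱼ xⱼ(sᵢ) + Σⱼ fⱼ(zⱼ(sᵢ)) + W(sᵢ)

where xⱼ are (possibly uncertain) covariates entering linearly, the fⱼ
are second-order random-walk (RW2) splines over a discretized covariate
domain, and W is a Matérn spatial residual absorbing spatial pattern the
covariates miss.  This module owns the predictor algebra and the RW2
machinery; the fitters live in `eivsdm.fitting`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kriging import PriorConfig
from .random_fields import as_points

__all__ = [
    "SdmSpec",
    "SpeciesObservations",
    "linear_predictor",
    "logistic_link",
    "rw2_log_density",
    "rw2_structure",
    "bin_covariate",
]


@dataclass(frozen=True)
class SdmSpec:
    """Structure of the additive predictor.

    ``linear_terms`` name covariates with linear coefficients (these are
    the ones that may be uncertain/kriged); ``spline_terms`` name known
    covariates modelled through RW2 splines with ``n_bins`` equal-width
    bins each; ``spatial_residual`` toggles the Matérn W(s) term.  Each
    fitted spline is constrained to sum to zero across bins so the
    intercept stays identifiable.
    """

    linear_terms: tuple[str, ...] = ()
    spline_terms: tuple[str, ...] = ()
    n_bins: int = 20
    spatial_residual: bool = True
    intercept: bool = True
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self):
        object.__setattr__(self, "linear_terms", tuple(self.linear_terms))
        object.__setattr__(self, "spline_terms", tuple(self.spline_terms))
        if self.n_bins < 4:
            raise ValueError("spline bin count must be >= 4")
        if not (self.linear_terms or self.spline_terms or self.spatial_residual
                or self.intercept):
            raise ValueError("model needs at least one term (or an intercept)")
        overlap = set(self.linear_terms) & set(self.spline_terms)
        if overlap:
            raise ValueError(f"terms cannot be both linear and spline: {sorted(overlap)}")


@dataclass
class SpeciesObservations:
    """Presence/absence records with any co-located known covariates."""

    points: np.ndarray
    y: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.points = as_points(self.points)
        self.y = np.asarray(self.y)
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary 0/1")
        self.y = self.y.astype(float)
        if len(self.y) != len(self.points):
            raise ValueError("y length must match number of points")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(len(self.y)))
        elif len(self.covariates) != len(self.y):
            raise ValueError("covariate table length must match number of points")

    def __len__(self) -> int:
        return len(self.y)


def logistic_link(eta) -> np.ndarray:
    """μ = 1 / (1 + e^(−η)); numerically safe for large |η|."""
    eta = np.asarray(eta, dtype=float)
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out if out.ndim else float(out)


def linear_predictor(
    spec: SdmSpec,
    params: dict,
    covariates: pd.DataFrame,
) -> np.ndarray:
    """Evaluate ηᵢ = β₀ + Σ βⱼ xⱼ(sᵢ) + Σ fⱼ(zⱼ(sᵢ)) + W(sᵢ).

    ``params`` supplies "beta0" (scalar), "beta" (mapping term → value),
    "splines" (mapping term → per-observation spline values, i.e. the
    fitted fⱼ(zⱼ(sᵢ)) already evaluated at the observations), and "W"
    (per-observation spatial residual).  Missing covariate columns raise
    with the offending name.
    """
    n = len(covariates)
    eta = np.full(n, float(params.get("beta0", 0.0)) if spec.intercept else 0.0)
    beta = params.get("beta", {})
    for term in spec.linear_terms:
        if term not in covariates.columns:
            raise KeyError(f"covariate column {term!r} missing from table")
        eta = eta + float(beta.get(term, 0.0)) * covariates[term].to_numpy(dtype=float)
    splines = params.get("splines", {})
    for term in spec.spline_terms:
        if term not in covariates.columns:
            raise KeyError(f"covariate column {term!r} missing from table")
        f = np.asarray(splines.get(term, np.zeros(n)), dtype=float)
        if len(f) != n:
            raise ValueError(f"spline values for {term!r} have wrong length")
        eta = eta + f
    w = params.get("W")
    if w is not None:
        w = np.asarray(w, dtype=float)
        if len(w) != n:
            raise ValueError("spatial residual W has wrong length")
        eta = eta + w
    return eta


def rw2_structure(d: int) -> np.ndarray:
    """RW2 penalty (structure) matrix K = DᵀD, D the second-difference
    operator over d ordered bins.  Rank d − 2; null space spanned by
    constant and linear trends in the bin index."""
    if d < 4:
        raise ValueError("need at least 4 bins")
    D = np.zeros((d - 2, d))
    for i in range(d - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D.T @ D


def rw2_log_density(u, zeta2: float) -> float:
    """Improper RW2 log-density of spline values ``u`` (up to a constant).

    Second differences Δ²uᵢ = uᵢ − 2uᵢ₊₁ + uᵢ₊₂ are iid N(0, ζ²), so the
    density is invariant under adding any linear function of bin index.
    """
    if zeta2 <= 0:
        raise ValueError("zeta2 must be > 0")
    u = np.asarray(u, dtype=float).ravel()
    if len(u) < 4:
        raise ValueError("need at least 4 bins")
    d2 = np.diff(u, n=2)
    return float(
        -0.5 * len(d2) * np.log(2.0 * np.pi * zeta2) - 0.5 * np.sum(d2**2) / zeta2
    )


def bin_covariate(values, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width discretization of a covariate for its RW2 spline.

    Returns (bin assignment per observation, bin midpoints).  The bins
    span the observed range; the top edge is inclusive.  A constant
    covariate cannot support a spline and raises.
    """
    if d < 4:
        raise ValueError("need at least 4 bins")
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    if hi <= lo:
        raise ValueError(
            "covariate is constant; remove its spline term (no spread to smooth over)"
        )
    edges = np.linspace(lo, hi, d + 1)
    assignment = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, d - 1)
    midpoints = 0.5 * (edges[:-1] + edges[1:])
    return assignment, midpoints
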