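"""Spatial cross-validation, scoring, and prevalence prediction intervals.

Generalization to unseen areas is assessed by leave-one-region-out
cross-validation: field visits are partitioned into geographic regions,
each fold trains on all other regions and predicts the held-out one.
Accuracy is the root of the Brier score, RMSE(y, E[μ]).  Regional
prevalence prediction intervals come from sampling μ vectors from the
joint posterior, then sampling 0/1 occurrences from them — so the
interval carries both posterior and binomial uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import predict_eta_draws
from .inference import InferenceConfig
from .kriging import PriorConfig
from .random_fields import FieldRealization, as_points
from .sdm import SdmSpec, SpeciesObservations, logistic_link

__all__ = [
    "RegionPartition",
    "CvPredictions",
    "make_folds",
    "cross_validate",
    "rmse_score",
    "prevalence_intervals",
]


@dataclass
class RegionPartition:
    """Region label per species location; labels partition [N]."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")

    @property
    def regions(self) -> list:
        return sorted(pd.unique(self.labels).tolist())

    def indices(self, region) -> np.ndarray:
        return np.where(self.labels == region)[0]


@dataclass(frozen=True)
class Fold:
    region: object
    train: np.ndarray
    test: np.ndarray


def make_folds(points, labels) -> list[Fold]:
    """Leave-one-region-out folds from per-location region labels."""
    pts = as_points(points)
    part = RegionPartition(np.asarray(labels))
    if len(part.labels) != len(pts):
        raise ValueError("labels length must match number of points")
    regions = part.regions
    if len(regions) < 2:
        raise ValueError("need at least 2 regions to cross-validate")
    folds = []
    for region in regions:
        test = part.indices(region)
        if len(test) == 0:
            warnings.warn(f"region {region!r} has no locations; dropped", stacklevel=2)
            continue
        train = np.where(part.labels != region)[0]
        folds.append(Fold(region=region, train=train, test=test))
    return folds


@dataclass
class CvPredictions:
    """Held-out posterior predictive summaries per species location.

    ``mu_mean[i]`` is E[μᵢ] from the fold that held location i out;
    ``mu_draws`` holds per-location posterior draws of μᵢ (each column
    produced by its own fold, so no fold ever predicted its training
    region); ``fold_id[i]`` names that fold.  Failed folds leave NaNs.
    """

    mu_mean: np.ndarray
    mu_draws: np.ndarray
    fold_id: np.ndarray
    failed_folds: list = field(default_factory=list)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.mu_mean).sum())


def cross_validate(
    model_kind: str,
    species: SpeciesObservations,
    abiotic: dict[str, FieldRealization] | None,
    spec: SdmSpec,
    folds: list[Fold],
    priors: PriorConfig | None = None,
    inference: InferenceConfig | None = None,
    holdout_abiotic: bool = False,
    n_pred_draws: int = 200,
) -> CvPredictions:
    """Leave-region-out predictions with the requested fitter.

    By default only species field visits are held out; abiotic
    measurements stay available to every fold (abiotic surveys exist
    everywhere in the motivating setting).  ``holdout_abiotic=True``
    additionally removes abiotic observations falling in the held-out
    region.  The fold metadata records which behaviour was used.
    """
    from .fitting import fit_direct, fit_joint, fit_two_stage

    priors = priors or PriorConfig()
    inference = inference or InferenceConfig()
    N = len(species)
    mu_mean = np.full(N, np.nan)
    mu_draws = np.full((n_pred_draws, N), np.nan)
    fold_id = np.full(N, -1, dtype=object)
    failed = []
    base_seed = np.random.SeedSequence(inference.seed).generate_state(len(folds)) % (2**31)

    for k, fold in enumerate(folds):
        tr, te = fold.train, fold.test
        sp_tr = SpeciesObservations(
            points=species.points[tr],
            y=species.y[tr].astype(int),
            covariates=species.covariates.iloc[tr].reset_index(drop=True),
        )
        ab = abiotic
        if ab is not None and holdout_abiotic:
            te_pts = species.points[te]
            lo, hi = te_pts.min(axis=0), te_pts.max(axis=0)
            ab = {}
            for name, fr in abiotic.items():
                inside = np.all((fr.points >= lo) & (fr.points <= hi), axis=1)
                ab[name] = FieldRealization(
                    points=fr.points[~inside], values=fr.values[~inside])
        inf = InferenceConfig(**{**inference.__dict__, "seed": int(base_seed[k])})
        try:
            if model_kind == "direct":
                fit = fit_direct(sp_tr, spec, inference=inf, priors=priors)
            elif model_kind == "two_stage":
                fit = fit_two_stage(sp_tr, ab, spec, priors=priors, inference=inf)
            elif model_kind == "joint":
                fit = fit_joint(sp_tr, ab, spec, priors=priors, inference=inf)
            else:
                raise ValueError(f"unknown model kind {model_kind!r}")
            cov_te = species.covariates.iloc[te].reset_index(drop=True)
            eta = predict_eta_draws(
                fit, species.points[te],
                covariate_values=cov_te if len(cov_te.columns) else None,
                n_draws=n_pred_draws,
                rng=np.random.default_rng(int(base_seed[k]) + 1),
            )
        except ValueError:
            raise
        except Exception as err:
            warnings.warn(f"fold {fold.region!r} failed: {err}", stacklevel=2)
            failed.append(fold.region)
            continue
        mu = logistic_link(eta)
        mu_mean[te] = mu.mean(axis=0)
        take = np.resize(np.arange(len(mu)), n_pred_draws)
        mu_draws[:, te] = mu[take]
        fold_id[te] = fold.region
    return CvPredictions(
        mu_mean=mu_mean, mu_draws=mu_draws, fold_id=fold_id, failed_folds=failed
    )


def rmse_score(y, mu_mean) -> float:
    """√(Brier score): root mean squared error of E[μ] against binary y."""
    y = np.asarray(y, dtype=float).ravel()
    mu = np.asarray(mu_mean, dtype=float).ravel()
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(mu):
        raise ValueError("length mismatch")
    if np.any((mu < 0) | (mu > 1)):
        raise ValueError("mu values must lie in [0, 1]")
    return float(np.sqrt(np.mean((y - mu) ** 2)))


def prevalence_intervals(
    cv: CvPredictions,
    partition: RegionPartition,
    n_samples: int = 1000,
    seed: int = 0,
    y: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region predicted prevalence with 95% prediction intervals.

    For each posterior sample: draw a μ vector, then Bernoulli 0/1
    occurrences, then the region prevalence — the 2.5%/97.5% quantiles
    over samples are the interval.  ``y`` adds the observed (true)
    prevalence column when supplied.
    """
    if n_samples < 100:
        warnings.warn(f"n_samples={n_samples} < 100; intervals will be coarse",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    n_draws = len(cv.mu_draws)
    rows = []
    for region in partition.regions:
        idx = partition.indices(region)
        mu = cv.mu_draws[:, idx]
        if np.isnan(mu).all():
            rows.append({"region": region, "true_prevalence": np.nan,
                         "predicted_mean": np.nan, "q2.5": np.nan, "q97.5": np.nan})
            continue
        pick = rng.integers(0, n_draws, size=n_samples)
        occ = rng.uniform(size=(n_samples, len(idx))) < mu[pick]
        prev = occ.mean(axis=1)
        rows.append(
            {
                "region": region,
                "true_prevalence": float(np.mean(y[idx])) if y is not None else np.nan,
                "predicted_mean": float(prev.mean()),
                "q2.5": float(np.quantile(prev, 0.025)),
                "q97.5": float(np.quantile(prev, 0.975)),
            }
        )
    return pd.DataFrame(rows)
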