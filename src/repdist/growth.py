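"""Generative side of the dugong growth example.

Two growth models for dugong (*Dugong dugon*) length are used throughout:

* model 1 — linear regression of length on log-transformed age and weight,
  ``y = b0 + b1*log(x1) + b2*x2 + eps``;
* model 2 — nonlinear asymptotic growth on age only,
  ``y = alpha - beta3 * gamma**x1 + eps``;

with iid Gaussian errors of precision tau in both cases.  Age ``x1`` is
measured in half-years on (0, 70], weight ``x2`` in units of 100 kg on
[0.2, 9], length ``y`` in meters.  The scientific question is a binary
breeding-status classification of a newly adult animal: a dugong of age 17
years (34 half-years) and weight 250 kg (x2 = 2.5) is *certain to breed* iff
its predicted mean length strictly exceeds 2.50 m.

True parameters are drawn uniformly over biologically plausible boxes, by
default afresh for every Monte Carlo replicate, so reproducibility rates
integrate over the plausible parameter space rather than conditioning on a
single unknown truth.  Both choices (the boxes, the redraw policy) are
documented in docs/methods.md and togglable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "QueryPoint",
    "BreedingStatus",
    "BREEDING_THRESHOLD_M",
    "DEFAULT_QUERY",
    "classify_status",
    "LinearGrowthParams",
    "NonlinearGrowthParams",
    "GrowthModel",
    "LINEAR_MODEL",
    "NONLINEAR_MODEL",
    "growth_model",
    "PredictorDesign",
    "DataStructure",
    "Dataset",
    "draw_true_parameters",
    "mean_length",
    "simulate_dataset",
    "true_status",
]

#: Classification threshold on predicted mean length (meters, strict >).
BREEDING_THRESHOLD_M = 2.50


@dataclass(frozen=True)
class QueryPoint:
    """Covariate point at which predictions are made.

    Defaults are the example's constants: age 17 years = 34 half-years,
    weight 250 kg = 2.5 in units of 100 kg.
    """

    age_halfyears: float = 34.0
    weight_100kg: float = 2.5


DEFAULT_QUERY = QueryPoint()


class BreedingStatus:
    CERTAIN_TO_BREED = "certain_to_breed"
    NOT_CERTAIN_TO_BREED = "not_certain_to_breed"


def classify_status(mean_length_m: float) -> str:
    """Breeding status from a (predicted or true) mean length, strict > 2.50 m."""
    if mean_length_m > BREEDING_THRESHOLD_M:
        return BreedingStatus.CERTAIN_TO_BREED
    return BreedingStatus.NOT_CERTAIN_TO_BREED


@dataclass(frozen=True)
class LinearGrowthParams:
    beta0: float  # meters
    beta1: float  # meters per log(half-year)
    beta2: float  # meters per 100 kg
    tau: float  # error precision (1/variance)

    def validate(self) -> None:
        if not (0 < self.beta0 < 3 and 0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError(f"linear growth parameters outside plausible box: {self}")
        if not (50 <= self.tau <= 250):
            raise ValueError(f"precision tau outside [50, 250]: {self.tau}")


@dataclass(frozen=True)
class NonlinearGrowthParams:
    alpha: float  # asymptotic length, meters
    beta3: float  # meters
    gamma: float  # dimensionless decay in (0, 1)
    tau: float  # error precision

    def validate(self) -> None:
        if not (1 < self.alpha < 3 and 1 < self.beta3 < 3):
            raise ValueError(f"nonlinear growth parameters outside plausible box: {self}")
        if not (0 < self.gamma < 1):
            raise ValueError(f"gamma outside (0, 1): {self.gamma}")
        if not (50 <= self.tau <= 250):
            raise ValueError(f"precision tau outside [50, 250]: {self.tau}")


@dataclass(frozen=True)
class GrowthModel:
    """One of the two dugong growth models (the M component).

    ``bounds`` are the uniform sampling boxes for the true parameters;
    they can be overridden (e.g. collapsed to a point for tests) without
    touching the model structure.
    """

    version: int
    requires: frozenset
    param_names: tuple
    bounds: Mapping[str, tuple]

    def with_bounds(self, **overrides) -> "GrowthModel":
        new = dict(self.bounds)
        new.update(overrides)
        return GrowthModel(self.version, self.requires, self.param_names, new)

    def draw_params(self, rng: np.random.Generator):
        lo = np.array([self.bounds[p][0] for p in self.param_names])
        hi = np.array([self.bounds[p][1] for p in self.param_names])
        draw = rng.uniform(lo, hi)
        vals = dict(zip(self.param_names, draw))
        if self.version == 1:
            return LinearGrowthParams(**vals)
        return NonlinearGrowthParams(**vals)

    def mean(self, params, age_halfyears, weight_100kg=None):
        """Noiseless mean length at the given covariates (vectorized)."""
        age = np.asarray(age_halfyears, dtype=float)
        if self.version == 1:
            if np.any(age <= 0):
                raise ValueError("log-age model needs strictly positive age")
            if weight_100kg is None:
                raise ValueError("linear growth model requires a weight covariate")
            w = np.asarray(weight_100kg, dtype=float)
            return params.beta0 + params.beta1 * np.log(age) + params.beta2 * w
        if not (0 <= params.gamma <= 1):
            raise ValueError(f"gamma outside [0, 1]: {params.gamma}")
        return params.alpha - params.beta3 * params.gamma ** age

    def mean_at(self, params, query: QueryPoint) -> float:
        return float(self.mean(params, query.age_halfyears, query.weight_100kg))


LINEAR_MODEL = GrowthModel(
    version=1,
    requires=frozenset({"age", "weight"}),
    param_names=("beta0", "beta1", "beta2", "tau"),
    bounds={"beta0": (0, 3), "beta1": (0, 1), "beta2": (0, 1), "tau": (50, 250)},
)

NONLINEAR_MODEL = GrowthModel(
    version=2,
    requires=frozenset({"age"}),
    param_names=("alpha", "beta3", "gamma", "tau"),
    bounds={"alpha": (1, 3), "beta3": (1, 3), "gamma": (0, 1), "tau": (50, 250)},
)


def growth_model(version: int) -> GrowthModel:
    if version == 1:
        return LINEAR_MODEL
    if version == 2:
        return NONLINEAR_MODEL
    raise ValueError(f"unknown growth model version {version!r}")


@dataclass(frozen=True)
class PredictorDesign:
    """The Spre component: which predictors the study measures, and how.

    Age is sampled uniformly on (0.5, 70] half-years (the lower bound respects
    half-year measurement resolution and keeps log-age finite), weight
    uniformly on [0.2, 9] hundred kg, independently.
    """

    provides: frozenset
    age_range: tuple = (0.5, 70.0)
    weight_range: tuple = (0.2, 9.0)

    def sample_predictors(self, n: int, rng: np.random.Generator):
        age = rng.uniform(*self.age_range, size=n)
        weight = (
            rng.uniform(*self.weight_range, size=n)
            if "weight" in self.provides
            else None
        )
        return age, weight


@dataclass(frozen=True)
class DataStructure:
    """The Ds component: sample size and multiplicative recording biases."""

    n: int
    age_bias_factor: float = 1.0
    weight_bias_factor: float = 1.0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("sample size must be positive")


@dataclass(frozen=True)
class Dataset:
    """One simulated replicate: recorded predictors (post-bias) and responses."""

    recorded_age: np.ndarray
    recorded_weight: np.ndarray | None
    response: np.ndarray
    true_params: object
    model_version: int

    @property
    def n(self) -> int:
        return len(self.response)


def draw_true_parameters(model_version: int, rng: np.random.Generator):
    """Draw one true parameter set uniformly over the model's plausibility box."""
    return growth_model(model_version).draw_params(rng)


def mean_length(model_version: int, params, query: QueryPoint = DEFAULT_QUERY) -> float:
    """Noiseless mean length under the given model at the query point."""
    return growth_model(model_version).mean_at(params, query)


def simulate_dataset(
    model_version: int,
    params,
    design: PredictorDesign,
    dstruct: DataStructure,
    rng: np.random.Generator,
) -> Dataset:
    """Simulate one dataset: true predictors, Gaussian responses, biased records.

    Responses are generated from the *true* predictor values; the recording
    bias (a data-processing error) is applied only to the stored predictor
    columns that the analyst later sees.  Responses are never truncated.
    """
    model = growth_model(model_version)
    missing = model.requires - design.provides
    if missing:
        raise ValueError(
            f"design does not provide {sorted(missing)} required by model "
            f"{model_version} (non-permutable combination)"
        )
    age, weight = design.sample_predictors(dstruct.n, rng)
    mu = model.mean(params, age, weight)
    y = mu + rng.normal(0.0, 1.0 / np.sqrt(params.tau), size=dstruct.n)
    rec_age = age * dstruct.age_bias_factor
    rec_weight = None if weight is None else weight * dstruct.weight_bias_factor
    return Dataset(
        recorded_age=rec_age,
        recorded_weight=rec_weight,
        response=y,
        true_params=params,
        model_version=model_version,
    )


def true_status(model_version: int, params, query: QueryPoint = DEFAULT_QUERY) -> str:
    """Breeding status assigned under the true (generating) model and parameters."""
    return classify_status(mean_length(model_version, params, query))
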