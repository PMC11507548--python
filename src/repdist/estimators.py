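"""Post-data methods: frequentist and Bayesian fits of the growth models.

Each method maps a simulated :class:`~repdist.growth.Dataset` to a predicted
mean length at the query point, wrapped in a :class:`FitResult`.  A failed
fit carries no prediction — downstream rate estimation excludes failures
from the denominator rather than imputing anything.

* least-squares family: ordinary least squares for the linear model
  (normal equations via :func:`numpy.linalg.lstsq`), damped Gauss-Newton /
  Levenberg-Marquardt nonlinear least squares for the asymptotic growth
  model with gamma kept in (0, 1) by a logit transform and a small
  deterministic multi-start grid;
* Bayesian family: Metropolis-within-Gibbs with vague priors
  (Normal(0, precision 1e-6) on location/slope parameters, Uniform(0, 1)
  on gamma, Gamma(1e-3, 1e-3) on the error precision tau), one chain,
  1000 burn-in and 1000 retained draws, proposal adaptation during
  burn-in only.  The reported prediction is the posterior-predictive mean
  of the noiseless mean function at the query (additive noise has mean
  zero, so drawing predictive noise would only add Monte Carlo variance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares as _scipy_least_squares

from .growth import Dataset, DEFAULT_QUERY, GrowthModel, QueryPoint, growth_model

__all__ = [
    "FitResult",
    "PriorSpec",
    "McmcSettings",
    "EstimatorMethod",
    "least_squares_method",
    "bayesian_method",
    "fit_ols_linear",
    "fit_nls_nonlinear",
    "fit_bayes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitResult:
    predicted_length: float | None
    success: bool
    failure_reason: str = ""
    diagnostics: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.success and self.predicted_length is not None:
            raise ValueError("failed fits must not carry a prediction")


def _failure(reason: str, **diag) -> FitResult:
    return FitResult(None, False, reason, dict(diag))


@dataclass(frozen=True)
class PriorSpec:
    """Prior assignment policy for Bayesian fits.

    Vague priors (the default) transfer to any growth model's location and
    slope parameters; gamma always gets Uniform(0, 1) and tau always gets
    Gamma(tau_shape, tau_rate).  Normal priors are parameterized by
    *precision* (``location_precision`` = 1e-6 means variance 1e6).  If
    ``vague`` is False, only parameters named in ``declared_for`` have
    (informative) priors, and those do not transfer across model
    parameterizations — a model with any other parameter is then
    non-permutable with this method.
    """

    location_precision: float = 1e-6
    tau_shape: float = 1e-3
    tau_rate: float = 1e-3
    vague: bool = True
    declared_for: frozenset = frozenset()

    def assignable(self, model: GrowthModel) -> tuple[bool, str]:
        for name in model.param_names:
            if name in ("tau", "gamma"):
                continue
            if self.vague or name in self.declared_for:
                continue
            return False, (
                f"post-data method declares no prior assignable to model "
                f"parameter {name!r} (informative priors do not transfer)"
            )
        return True, ""


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 1
    burn_in: int = 1000
    samples: int = 1000
    thinning: int = 1
    adapt_during_burn_in: bool = True
    initial_proposal_sd: float = 0.5


@dataclass(frozen=True)
class EstimatorMethod:
    """The Spost component: a named analysis method applicable to the growth models."""

    family: str  # "least_squares" | "bayesian"
    label: str
    priors: PriorSpec | None = None
    settings: McmcSettings | None = None

    def priors_assignable(self, model: GrowthModel) -> tuple[bool, str]:
        if self.family != "bayesian":
            return True, ""
        return self.priors.assignable(model)

    def fit(
        self,
        dataset: Dataset,
        model: GrowthModel,
        query: QueryPoint = DEFAULT_QUERY,
        rng: np.random.Generator | None = None,
    ) -> FitResult:
        if self.family == "least_squares":
            if model.version == 1:
                return fit_ols_linear(dataset, query)
            return fit_nls_nonlinear(dataset, query)
        if self.family == "bayesian":
            if rng is None:
                raise ValueError("Bayesian fits need a seeded random generator")
            return fit_bayes(dataset, model, self.priors, self.settings, query, rng)
        raise ValueError(f"unknown estimator family {self.family!r}")


def least_squares_method(label: str = "least-squares") -> EstimatorMethod:
    return EstimatorMethod(family="least_squares", label=label)


def bayesian_method(
    label: str = "bayes-vague",
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
) -> EstimatorMethod:
    return EstimatorMethod(
        family="bayesian",
        label=label,
        priors=priors or PriorSpec(),
        settings=settings or McmcSettings(),
    )


# ---------------------------------------------------------------------------
# least squares


def fit_ols_linear(dataset: Dataset, query: QueryPoint = DEFAULT_QUERY) -> FitResult:
    """OLS fit of length on (log recorded age, recorded weight)."""
    if dataset.recorded_weight is None:
        return _failure("dataset has no weight column; linear model cannot be fit")
    X = np.column_stack(
        [
            np.ones(dataset.n),
            np.log(dataset.recorded_age),
            dataset.recorded_weight,
        ]
    )
    if dataset.n <= X.shape[1]:
        return _failure(f"too few observations (n={dataset.n}) for 3 coefficients")
    beta, _, rank, _ = np.linalg.lstsq(X, dataset.response, rcond=None)
    if rank < X.shape[1]:
        return _failure("singular design")
    pred = beta[0] + beta[1] * np.log(query.age_halfyears) + beta[2] * query.weight_100kg
    if not np.isfinite(pred):
        return _failure("non-finite prediction")
    return FitResult(float(pred), True, diagnostics={"rank": float(rank)})


from scipy.special import expit as _expit, logit as _logit


def fit_nls_nonlinear(dataset: Dataset, query: QueryPoint = DEFAULT_QUERY) -> FitResult:
    """Nonlinear least squares for y = alpha - beta3 * gamma**age.

    gamma is optimized on the logit scale so it stays inside (0, 1); the
    damped Gauss-Newton (Levenberg-Marquardt) solver is started from a small
    deterministic grid and the best converged optimum is kept.  If no start
    converges to a finite solution the fit fails (the "NA" case excluded
    from rate denominators downstream).
    """
    y = dataset.response
    x = dataset.recorded_age
    if dataset.n < 3:
        return _failure(f"too few observations (n={dataset.n}) for 3 parameters")

    def residuals(theta):
        alpha, beta3, u = theta
        return alpha - beta3 * _expit(u) ** x - y

    alpha0 = float(np.max(y))
    beta30 = max(float(np.max(y) - np.min(y)), 0.1)
    starts = [
        (alpha0, beta30, _logit(0.5)),
        (alpha0, beta30, _logit(0.9)),
    ]
    best = None
    for theta0 in starts:
        try:
            sol = _scipy_least_squares(residuals, theta0, method="lm")
        except Exception:  # singular Jacobian etc.
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        return _failure("nonlinear least squares did not converge from any start")
    rss, sol = best
    alpha, beta3, u = sol.x
    gamma = float(_expit(u))
    pred = alpha - beta3 * gamma ** query.age_halfyears
    if not np.isfinite(pred):
        return _failure("non-finite prediction")
    return FitResult(
        float(pred),
        True,
        diagnostics={
            "rss": rss,
            "alpha": float(alpha),
            "beta3": float(beta3),
            "gamma": gamma,
            "nfev": float(sol.nfev),
        },
    )


# ---------------------------------------------------------------------------
# Bayesian fits


def fit_bayes(
    dataset: Dataset,
    model: GrowthModel,
    priors: PriorSpec,
    settings: McmcSettings,
    query: QueryPoint = DEFAULT_QUERY,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Metropolis-within-Gibbs posterior sampling and posterior-predictive mean.

    Linear-in-likelihood coefficients get conjugate Gibbs updates (their
    conditionals are Gaussian under the vague normal priors), tau gets its
    conditional Gamma update, and gamma — the only non-conjugate parameter —
    gets a random-walk Metropolis update on the logit scale with step-size
    adaptation during burn-in only.
    """
    ok, why = priors.assignable(model)
    if not ok:
        raise ValueError(why)
    if rng is None:
        raise ValueError("fit_bayes needs a seeded random generator")
    if model.version == 1:
        return _bayes_linear(dataset, priors, settings, query, rng)
    return _bayes_nonlinear(dataset, priors, settings, query, rng)


def _draw_tau(rng, priors, rss, n):
    shape = priors.tau_shape + 0.5 * n
    rate = priors.tau_rate + 0.5 * rss
    return rng.gamma(shape, 1.0 / rate)


def _bayes_linear(dataset, priors, settings, query, rng):
    if dataset.recorded_weight is None:
        return _failure("dataset has no weight column; linear model cannot be fit")
    y = dataset.response
    n = dataset.n
    X = np.column_stack([np.ones(n), np.log(dataset.recorded_age), dataset.recorded_weight])
    XtX = X.T @ X
    Xty = X.T @ y
    P = priors.location_precision * np.eye(3)

    beta = np.linalg.lstsq(X, y, rcond=None)[0]  # start at OLS
    tau = 100.0
    keep = np.empty((settings.samples, 3))
    total = settings.burn_in + settings.samples
    for it in range(total):
        A = P + tau * XtX
        L = np.linalg.cholesky(A)
        m = np.linalg.solve(A, tau * Xty)
        z = rng.standard_normal(3)
        beta = m + np.linalg.solve(L.T, z)
        resid = y - X @ beta
        tau = _draw_tau(rng, priors, resid @ resid, n)
        if it >= settings.burn_in:
            keep[it - settings.burn_in] = beta
    if not np.all(np.isfinite(keep)):
        return _failure("sampler failure: non-finite posterior draws")
    qvec = np.array([1.0, np.log(query.age_halfyears), query.weight_100kg])
    draws = keep @ qvec
    return FitResult(
        float(draws.mean()),
        True,
        diagnostics={"posterior_sd": float(draws.std(ddof=1))},
    )


def _bayes_nonlinear(dataset, priors, settings, query, rng):
    y = dataset.response
    x = dataset.recorded_age
    n = dataset.n
    prec0 = priors.location_precision

    alpha = float(np.max(y)) + 0.05
    beta3 = max(float(np.max(y) - np.min(y)), 0.1)
    gamma = 0.8
    u = _logit(gamma)
    tau = 100.0
    sd = settings.initial_proposal_sd

    g = gamma ** x
    keep = np.empty((settings.samples, 3))
    accepted_burn = 0
    accepted_keep = 0
    total = settings.burn_in + settings.samples
    for it in range(total):
        # alpha | rest : y + beta3*g = alpha + eps
        prec = prec0 + tau * n
        m = tau * np.sum(y + beta3 * g) / prec
        alpha = m + rng.standard_normal() / np.sqrt(prec)
        # beta3 | rest : (alpha - y) = beta3*g + eps
        sgg = g @ g
        prec = prec0 + tau * sgg
        m = tau * (g @ (alpha - y)) / prec
        beta3 = m + rng.standard_normal() / np.sqrt(prec)
        # gamma | rest : random-walk Metropolis on logit scale, Uniform(0,1) prior
        resid = y - alpha + beta3 * g
        ll = -0.5 * tau * (resid @ resid)
        u_prop = u + sd * rng.standard_normal()
        gamma_prop = _expit(u_prop)
        g_prop = gamma_prop ** x
        resid_prop = y - alpha + beta3 * g_prop
        ll_prop = -0.5 * tau * (resid_prop @ resid_prop)
        # Jacobian of the logit transform: d(gamma)/d(u) = gamma(1-gamma);
        # computed on the log scale as -(log(1+e^u) + log(1+e^-u)) for stability
        log_jac = -(np.logaddexp(0.0, u) + np.logaddexp(0.0, -u))
        log_jac_prop = -(np.logaddexp(0.0, u_prop) + np.logaddexp(0.0, -u_prop))
        log_ratio = ll_prop - ll + log_jac_prop - log_jac
        if np.log(rng.uniform()) < log_ratio:
            u, gamma, g = u_prop, gamma_prop, g_prop
            if it < settings.burn_in:
                accepted_burn += 1
            else:
                accepted_keep += 1
        # tau | rest
        resid = y - alpha + beta3 * g
        tau = _draw_tau(rng, priors, resid @ resid, n)
        if settings.adapt_during_burn_in and it < settings.burn_in and (it + 1) % 100 == 0:
            acc = accepted_burn / (it + 1)
            if acc < 0.2:
                sd *= 0.7
            elif acc > 0.6:
                sd *= 1.4
        if it >= settings.burn_in:
            keep[it - settings.burn_in] = (alpha, beta3, gamma)
    if not np.all(np.isfinite(keep)):
        return _failure("sampler failure: non-finite posterior draws")
    acc_rate = accepted_keep / settings.samples
    if acc_rate == 0.0:
        return _failure("sampler failure: zero acceptance for gamma", proposal_sd=sd)
    draws = keep[:, 0] - keep[:, 1] * keep[:, 2] ** query.age_halfyears
    return FitResult(
        float(draws.mean()),
        True,
        diagnostics={
            "gamma_acceptance": acc_rate,
            "proposal_sd": sd,
            "posterior_sd": float(draws.std(ddof=1)),
        },
    )
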