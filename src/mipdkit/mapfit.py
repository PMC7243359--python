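"""Bayesian maximum a posteriori (MAP) individualization from measured levels.

Multiplicative correction factors on the random-effect-bearing parameters
(clearance and central volume) are estimated by minimizing the negative log
posterior

    -log p(f | y) = sum_j [ (y_j - yhat_j)^2 / (2 var_j) + log sqrt(2 pi var_j) ]
                  + sum_i (ln f_i)^2 / (2 omega_i^2)

where var_j follows the model's residual error (additive, proportional, or
combined) and omega_i is the model's IIV SD on the log scale — the lognormal
IIV prior has its mode at f = 1. The data term rewards individual goodness of
fit; the prior penalizes large excursions of the correction factors, and the
MAP estimate balances the two.

The search uses simulated annealing (a Metropolis-Hastings adaptation):
Gaussian proposals on the log-factors, geometric cooling, a fixed proposal
budget of 5,000 iterations (counted as proposals), and best-state return.
Log-factors are bounded to [-ln 10, ln 10] (factors 0.1-10x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .models import (
    CorrectionFactors,
    CovariateSet,
    PKModelSpec,
    compute_individual_parameters,
)
from .records import Observation, ObservationSet
from .simulate import ConcentrationTimeCourse, DoseEvent, rk4_solve, _make_plan, _run_plan

__all__ = [
    "SAConfig",
    "negative_log_posterior",
    "map_estimate",
    "Observation",
    "ObservationSet",
]

LOG_FACTOR_BOUND = math.log(10.0)


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing schedule (all values configurable)."""

    n_iter: int = 5000
    t0: float = 1.0
    cooling: float = 0.999
    proposal_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.t0 <= 0:
            raise ValueError("starting temperature must be > 0 (zero-temperature start "
                             "would reject all uphill proposals)")
        if not 0 < self.cooling <= 1:
            raise ValueError("cooling must be in (0, 1]")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be > 0")


def _free_factor_names(model: PKModelSpec) -> list[str]:
    """Parameters that carry correction factors: CL and V1 with IIV."""
    return [p for p in ("CL", "V1") if p in model.iiv and model.iiv[p] > 0]


class _Objective:
    """Negative log posterior over log-factors, with a pre-resolved dose grid."""

    def __init__(
        self,
        model: PKModelSpec,
        cov: CovariateSet,
        doses: Sequence[DoseEvent],
        obs: ObservationSet,
        step_min: float = 1.0,
    ) -> None:
        if len(obs) == 0:
            raise ValueError("observation set is empty")
        if not doses:
            raise ValueError("dose history is empty")
        self.model = model
        self.cov = cov
        self.free = _free_factor_names(model)
        self.omegas = np.array([model.iiv[p] for p in self.free])
        self.t0 = min(d.start_time for d in doses)
        last_obs_h = max((o.time - self.t0).total_seconds() / 3600.0 for o in obs)
        if last_obs_h <= 0:
            raise ValueError("observations precede the first dose")
        horizon_h = last_obs_h + step_min / 60.0
        # doses after the last observation cannot influence the likelihood
        in_span = [d for d in doses
                   if (d.start_time - self.t0).total_seconds() / 3600.0 <= horizon_h]
        self.plan = _make_plan(in_span, self.t0, horizon_h, step_min)
        times_h = np.array([(o.time - self.t0).total_seconds() / 3600.0 for o in obs])
        if np.any(times_h < 0):
            raise ValueError("observations precede the first dose")
        self.grid_h = np.arange(self.plan.n_steps + 1) * step_min / 60.0
        self.obs_times_h = times_h
        self.y = np.array([o.concentration_mg_L for o in obs])

    def factors_from_log(self, logf: np.ndarray) -> CorrectionFactors:
        d = dict(zip(self.free, np.exp(logf)))
        return CorrectionFactors(cl=d.get("CL", 1.0), v1=d.get("V1", 1.0))

    def predict(self, factors: CorrectionFactors) -> np.ndarray:
        params = compute_individual_parameters(self.model, self.cov, factors)
        amounts = _run_plan(params, self.plan)
        conc = np.clip(amounts[:, 0] / params.v1_L, 0.0, None)
        return np.interp(self.obs_times_h, self.grid_h, conc)

    def components(self, logf: np.ndarray) -> tuple[float, float, float]:
        """(data quadratic term, data normalization term, prior penalty)."""
        yhat = self.predict(self.factors_from_log(logf))
        var = np.array([self.model.residual_error.variance(float(p)) for p in yhat])
        quad = float(np.sum((self.y - yhat) ** 2 / (2.0 * var)))
        norm = float(np.sum(0.5 * np.log(2.0 * math.pi * var)))
        prior = float(np.sum(logf**2 / (2.0 * self.omegas**2)))
        return quad, norm, prior

    def __call__(self, logf: np.ndarray) -> float:
        quad, norm, prior = self.components(logf)
        return quad + norm + prior


def negative_log_posterior(
    factors: CorrectionFactors,
    model: PKModelSpec,
    cov: CovariateSet,
    doses: Sequence[DoseEvent],
    obs: ObservationSet,
    step_min: float = 1.0,
) -> float:
    """Negative log posterior density of the correction factors (up to a constant)."""
    objective = _Objective(model, cov, doses, obs, step_min)
    by_name = {"CL": factors.cl, "V1": factors.v1}
    logf = np.array([math.log(by_name[p]) for p in objective.free])
    return objective(logf)


def map_estimate(
    model: PKModelSpec,
    cov: CovariateSet,
    doses: Sequence[DoseEvent],
    obs: ObservationSet,
    seed: int,
    sa: SAConfig = SAConfig(),
    step_min: float = 1.0,
    fit_horizon_h: Optional[float] = None,
) -> tuple[CorrectionFactors, ConcentrationTimeCourse]:
    """MAP correction factors via seeded simulated annealing.

    With an empty observation set the prior mode (factors exactly 1.0) is
    returned without search. The same seed always yields bit-identical
    results.
    """
    if len(obs) == 0:
        factors = CorrectionFactors()
        tc = _fitted_course(model, cov, doses, factors, step_min, fit_horizon_h)
        return factors, tc

    objective = _Objective(model, cov, doses, obs, step_min)
    d = len(objective.free)
    rng = np.random.default_rng(seed)
    x = np.zeros(d)
    fx = objective(x)
    best_x, best_f = x.copy(), fx
    temp = sa.t0
    for _ in range(sa.n_iter):
        prop = np.clip(x + rng.normal(0.0, sa.proposal_sd, size=d),
                       -LOG_FACTOR_BOUND, LOG_FACTOR_BOUND)
        fp = objective(prop)
        if fp <= fx or rng.random() < math.exp(-(fp - fx) / temp):
            x, fx = prop, fp
            if fx < best_f:
                best_x, best_f = x.copy(), fx
        temp *= sa.cooling

    factors = objective.factors_from_log(best_x)
    tc = _fitted_course(model, cov, doses, factors, step_min, fit_horizon_h)
    return factors, tc


def _fitted_course(
    model: PKModelSpec,
    cov: CovariateSet,
    doses: Sequence[DoseEvent],
    factors: CorrectionFactors,
    step_min: float,
    horizon_h: Optional[float],
) -> ConcentrationTimeCourse:
    params = compute_individual_parameters(model, cov, factors)
    if not doses:
        raise ValueError("cannot build a fitted time course without dose events")
    t0 = min(d.start_time for d in doses)
    if horizon_h is None:
        last = max(d.start_time for d in doses)
        horizon_h = (last - t0).total_seconds() / 3600.0 + 24.0
    return rk4_solve(params, doses, horizon_h=horizon_h, start=t0, step_min=step_min)
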