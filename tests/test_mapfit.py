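"""MAP estimator: posterior construction, annealing search, consistency."""

import dataclasses
import math
from datetime import timedelta

import numpy as np
import pytest

import mipdkit as mk
from mipdkit.mapfit import SAConfig, _Objective


@pytest.fixture
def vanc():
    return mk.get_model("vancomycin")


@pytest.fixture
def doses():
    return mk.build_regimen("vancomycin", 1000.0, 12.0, 4, mk.EPOCH, 60.0)


def obs_at(hours, concs, drug="vancomycin"):
    return mk.ObservationSet(tuple(
        mk.Observation(time=mk.EPOCH + timedelta(hours=h), concentration_mg_L=c,
                       drug=drug)
        for h, c in zip(hours, concs)
    ))


def predictions(model, cov, doses, hours):
    params = mk.compute_individual_parameters(model, cov)
    last_dose_h = (max(d.start_time for d in doses) - mk.EPOCH).total_seconds() / 3600
    tc = mk.rk4_solve(params, doses, horizon_h=max(*hours, last_dose_h) + 1.0)
    return [tc.concentration_at(h) for h in hours]


class TestNegativeLogPosterior:
    def test_perfect_fit_at_prior_mode_has_zero_penalties(self, vanc, typical_cov, doses):
        hours = [2.0, 11.9, 26.0]
        obs = obs_at(hours, predictions(vanc, typical_cov, doses, hours))
        objective = _Objective(vanc, typical_cov, doses, obs)
        quad, norm, prior = objective.components(np.zeros(2))
        assert quad == pytest.approx(0.0, abs=1e-10)
        assert prior == 0.0
        total = mk.negative_log_posterior(mk.CorrectionFactors(), vanc, typical_cov,
                                          doses, obs)
        assert total == pytest.approx(norm)

    def test_additive_residual_is_quadratic(self, typical_cov, doses):
        model = mk.get_model("meropenem")
        mero_doses = mk.build_regimen("meropenem", 1000.0, 8.0, 3, mk.EPOCH, 30.0)
        hours = [2.0, 7.9, 15.0]
        base = predictions(model, typical_cov, mero_doses, hours)
        small = obs_at(hours, [base[0] + 1.0, base[1], base[2]], drug="meropenem")
        large = obs_at(hours, [base[0] + 2.0, base[1], base[2]], drug="meropenem")
        objective = _Objective(model, typical_cov, mero_doses, small)
        q_small = objective.components(np.zeros(2))[0]
        q_large = _Objective(model, typical_cov, mero_doses, large).components(
            np.zeros(2)
        )[0]
        assert q_large == pytest.approx(4.0 * q_small, rel=1e-9)

    def test_matches_independent_formula_on_three_point_fixture(
        self, vanc, typical_cov, doses
    ):
        """Direct re-implementation of the posterior on a fixed 3-observation set."""
        hours = [1.0, 11.9, 25.0]
        y = [22.0, 14.5, 19.0]
        obs = obs_at(hours, y)
        factors = mk.CorrectionFactors(cl=1.3, v1=0.9)
        value = mk.negative_log_posterior(factors, vanc, typical_cov, doses, obs)

        params = mk.compute_individual_parameters(vanc, typical_cov, factors)
        tc = mk.rk4_solve(params, doses, horizon_h=37.0)  # covers the whole regimen
        expected = 0.0
        for h, yi in zip(hours, y):
            pred = tc.concentration_at(h)
            var = 1.0**2 + (0.15 * pred) ** 2  # registry combined error
            expected += (yi - pred) ** 2 / (2 * var) + 0.5 * math.log(2 * math.pi * var)
        expected += math.log(1.3) ** 2 / (2 * vanc.iiv["CL"] ** 2)
        expected += math.log(0.9) ** 2 / (2 * vanc.iiv["V1"] ** 2)
        assert value == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_factor_rejected(self, vanc, typical_cov, doses):
        obs = obs_at([2.0], [10.0])
        with pytest.raises(ValueError):
            mk.negative_log_posterior(
                mk.CorrectionFactors(cl=-1.0), vanc, typical_cov, doses, obs
            )

    def test_empty_observations_rejected(self, vanc, typical_cov, doses):
        with pytest.raises(ValueError, match="empty"):
            mk.negative_log_posterior(
                mk.CorrectionFactors(), vanc, typical_cov, doses, mk.ObservationSet()
            )


class TestMapEstimate:
    def test_empty_observations_return_prior_mode(self, vanc, typical_cov, doses):
        factors, tc = mk.map_estimate(
            vanc, typical_cov, doses, mk.ObservationSet(), seed=1
        )
        assert (factors.cl, factors.v1) == (1.0, 1.0)
        assert len(tc.central_conc_mg_L) > 0

    def test_seed_reproducibility_bit_for_bit(self, vanc, typical_cov, doses):
        obs = obs_at([1.0, 11.9, 25.0], [25.0, 11.0, 17.0])
        f1, _ = mk.map_estimate(vanc, typical_cov, doses, obs, seed=123)
        f2, _ = mk.map_estimate(vanc, typical_cov, doses, obs, seed=123)
        assert (f1.cl, f1.v1) == (f2.cl, f2.v1)

    def test_matches_grid_search_on_one_factor_problem(self, typical_cov):
        """SA optimum vs a dense 1-d grid of the posterior (CL factor only)."""
        model = dataclasses.replace(mk.get_model("vancomycin"), iiv={"CL": 0.35})
        doses = mk.build_regimen("vancomycin", 1000.0, 12.0, 4, mk.EPOCH, 60.0)
        obs = obs_at([1.0, 11.9, 23.9, 35.9], [20.0, 8.0, 9.0, 8.5])
        objective = _Objective(model, typical_cov, doses, obs)
        grid = np.linspace(-math.log(10), math.log(10), 2001)
        values = [objective(np.array([g])) for g in grid]
        grid_mode = math.exp(grid[int(np.argmin(values))])
        factors, _ = mk.map_estimate(model, typical_cov, doses, obs, seed=5)
        resolution = math.exp(grid[1] - grid[0])
        assert factors.cl == pytest.approx(grid_mode, rel=2 * (resolution - 1.0))

    def test_informative_data_overrides_prior(self, typical_cov, doses):
        """sigma -> small pulls the mode to the data-implied factors."""
        model = dataclasses.replace(
            mk.get_model("vancomycin"),
            residual_error=mk.ResidualError(kind="additive", sigma_add_mg_L=0.01),
        )
        truth = mk.CorrectionFactors(cl=1.4, v1=0.85)
        params = mk.compute_individual_parameters(model, typical_cov, truth)
        tc = mk.rk4_solve(params, doses, horizon_h=48.0)
        hours = [1.0, 6.0, 11.9, 13.0, 18.0, 23.9, 25.0, 30.0, 35.9, 47.9]
        obs = obs_at(hours, [tc.concentration_at(h) for h in hours])
        sa = SAConfig(n_iter=8000, proposal_sd=0.03)
        factors, _ = mk.map_estimate(model, typical_cov, doses, obs, seed=11, sa=sa)
        assert factors.cl == pytest.approx(1.4, rel=0.02)
        assert factors.v1 == pytest.approx(0.85, rel=0.02)

    def test_vague_prior_data_balance_with_huge_sigma(self, typical_cov, doses):
        """sigma -> large leaves the factors at the prior mode."""
        model = dataclasses.replace(
            mk.get_model("vancomycin"),
            residual_error=mk.ResidualError(kind="additive", sigma_add_mg_L=1e6),
        )
        obs = obs_at([1.0, 11.9, 25.0], [40.0, 30.0, 35.0])
        factors, _ = mk.map_estimate(model, typical_cov, doses, obs, seed=3)
        assert factors.cl == pytest.approx(1.0, abs=0.02)
        assert factors.v1 == pytest.approx(1.0, abs=0.02)

    def test_zero_temperature_start_rejected(self):
        with pytest.raises(ValueError):
            SAConfig(t0=0.0)

    def test_best_objective_never_worse_than_start(self, vanc, typical_cov, doses):
        obs = obs_at([1.0, 11.9, 25.0], [25.0, 11.0, 17.0])
        factors, _ = mk.map_estimate(vanc, typical_cov, doses, obs, seed=9)
        start = mk.negative_log_posterior(mk.CorrectionFactors(), vanc, typical_cov,
                                          doses, obs)
        final = mk.negative_log_posterior(factors, vanc, typical_cov, doses, obs)
        assert final <= start + 1e-12
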