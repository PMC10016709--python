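"""MILP construction, solving, the outer grid search and the oracle."""

import math
from dataclasses import replace

import numpy as np
import pytest

import coralplan as cp
from coralplan.costs import FacilitySite, trip_cost_matrix
from coralplan.demand import Cluster
from coralplan.optimize import (
    ExcludedGrowthTimeError,
    InfeasibleSurvivalError,
    scale_costs,
)
from conftest import random_small_instance


def tiny_instance(demand=1e5, t_grid=(0.02, 1.0, 0.02), survival=None):
    cl = Cluster(
        id="c0", member_reef_ids=("r0",), centroid_lat=-18.0,
        centroid_lon=147.5, annual_demand=demand, intra_allowance_km=5.0,
    )
    fac = FacilitySite("f0", "F0", -19.0, 146.8)
    params = cp.CostParams()
    tc = trip_cost_matrix([fac], [cl], params)
    return cp.ProblemInstance(
        clusters=(cl,), facilities=(fac,), cost_params=params,
        survival=survival or cp.SurvivalSpec(),
        trip_costs=tc,
        solver_config=cp.SolverConfig(*t_grid),
    )


class TestBigM:
    def test_base_grid_value(self):
        inst = tiny_instance(demand=7.124e6)
        # grid minimum survival is at t_min = 0.02
        p_min = 0.1 - 1.0 / (25 * 0.02 + 10.0)
        assert cp.big_M(inst) == pytest.approx(7.124e6 / p_min, rel=1e-12)

    def test_flat_survival_demand_over_pmax(self):
        spec = cp.SurvivalSpec(form="logistic", c=50.0, t0=-1.0, pmax=0.3)
        inst = tiny_instance(demand=1e6, survival=spec)
        # sigmoid saturates at pmax across the whole grid
        assert cp.big_M(inst) == pytest.approx(1e6 / 0.3, rel=1e-3)

    def test_zero_demand_zero_M(self):
        assert cp.big_M(tiny_instance(demand=0.0)) == 0.0

    def test_all_excluded_raises(self):
        spec = cp.SurvivalSpec(form="linear", c=0.2, t0=0.5)
        inst = tiny_instance(survival=spec, t_grid=(0.02, 0.4, 0.02))
        with pytest.raises(InfeasibleSurvivalError):
            cp.big_M(inst)


class TestBuild:
    def test_variable_and_constraint_counts(self):
        model = cp.build_mip(tiny_instance(), 0.1)
        # 1 X + 1 T + 1 Y variables; capacity, frequency, demand, link rows
        assert model.c.shape == (3,)
        assert model.A.shape == (4, 3)
        assert model.integrality.tolist() == [0, 1, 1]

    def test_excluded_growth_time_rejected(self):
        spec = cp.SurvivalSpec(form="linear", c=0.2, t0=0.2)
        inst = tiny_instance(survival=spec)
        with pytest.raises(ExcludedGrowthTimeError):
            cp.build_mip(inst, 0.1)

    def test_zero_demand_solves_to_zero_with_all_closed(self):
        sol = cp.solve_mip(cp.build_mip(tiny_instance(demand=0.0), 0.1))
        assert sol.status == "optimal"
        assert sol.objective == pytest.approx(0.0, abs=1e-6)
        assert np.all(sol.Y == 0)


class TestSolve:
    def test_single_facility_closed_form(self):
        inst = tiny_instance(demand=2e5)
        t = 0.1
        sol = cp.solve_mip(cp.build_mip(inst, t))
        assert sol.status == "optimal"
        p = cp.evaluate_survival(inst.survival, t)
        x = 2e5 / p
        trips = max(math.ceil(x / inst.cost_params.s_c), math.ceil(1 / t))
        params = inst.cost_params
        expected = (
            params.crf * params.c_f_cap
            + inst.trip_costs[0, 0] * trips
            + x * t * params.unit_residence_cost()
        )
        assert sol.objective == pytest.approx(expected, rel=1e-9)
        oracle = cp.brute_force_oracle(inst, t)
        assert oracle.objective == pytest.approx(expected, rel=1e-9)

    def test_cost_homogeneity(self):
        inst = random_small_instance(seed=99)
        t = 0.28
        base = cp.solve_mip(cp.build_mip(inst, t))
        scaled = cp.solve_mip(cp.build_mip(scale_costs(inst, 3.0), t))
        assert scaled.objective == pytest.approx(3.0 * base.objective, rel=1e-9)
        assert np.array_equal(scaled.Y, base.Y)

    def test_solution_feasible_outside_solver(self):
        inst = random_small_instance(seed=5)
        sol = cp.solve_mip(cp.build_mip(inst, 0.28))
        cp.check_feasibility(inst, sol, 0.28)


class TestOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_equivalence_on_random_instances(self, seed):
        """MILP objective matches exhaustive enumeration at every grid t."""
        inst = random_small_instance(seed)
        cfg = inst.solver_config
        grid = cp.survival_grid(inst.survival, cfg.t_min, cfg.t_max, cfg.dt)
        for g in grid:
            if not g.included:
                continue
            mip = cp.solve_mip(cp.build_mip(inst, g.t))
            oracle = cp.brute_force_oracle(inst, g.t)
            assert mip.objective == pytest.approx(
                oracle.objective, rel=1e-6
            ), f"seed={seed}, t={g.t}"

    def test_oracle_solution_is_feasible(self):
        inst = random_small_instance(seed=17)
        sol = cp.brute_force_oracle(inst, 0.52)
        cp.check_feasibility(inst, sol, 0.52)

    def test_scale_guard(self):
        inst = random_small_instance(seed=0)
        big = replace(
            inst,
            clusters=inst.clusters * 8,
            trip_costs=np.tile(inst.trip_costs, (8, 1)),
        )
        with pytest.raises(ValueError):
            cp.brute_force_oracle(big, 0.5)


class TestTwoStage:
    def test_flat_survival_prefers_smallest_growth_time(self):
        # saturated sigmoid: survival = pmax on the whole grid, so residence
        # cost only grows with t and the smallest admissible t must win
        spec = cp.SurvivalSpec(form="logistic", c=200.0, t0=-0.5, pmax=0.3)
        inst = tiny_instance(demand=5e5, survival=spec,
                             t_grid=(0.1, 0.5, 0.1))
        res = cp.two_stage_solve(inst)
        assert res.t_star == pytest.approx(0.1)

    def test_incumbent_matches_trace_minimum(self):
        inst = random_small_instance(seed=23, t_grid=(0.06, 1.0, 0.16))
        res = cp.two_stage_solve(inst)
        objs = [z for _, z in res.per_t_trace if z is not None]
        assert res.objective == pytest.approx(min(objs), rel=1e-12)
        ts = [t for t, z in res.per_t_trace if z is not None]
        assert res.t_star in ts

    def test_excluded_points_traced_not_solved(self):
        spec = cp.SurvivalSpec(form="linear", c=2.0, t0=0.2, pmax=0.5)
        inst = tiny_instance(demand=1e5, survival=spec, t_grid=(0.1, 0.5, 0.1))
        res = cp.two_stage_solve(inst)
        trace = dict(res.per_t_trace)
        assert trace[0.1] is None  # below the ramp's x-intercept
        assert trace[0.5] is not None

    def test_all_excluded_raises(self):
        spec = cp.SurvivalSpec(form="linear", c=0.1, t0=0.9)
        inst = tiny_instance(survival=spec, t_grid=(0.02, 0.5, 0.02))
        with pytest.raises(InfeasibleSurvivalError):
            cp.two_stage_solve(inst)

    def test_breakdown_total_equals_objective(self):
        inst = random_small_instance(seed=31)
        res = cp.two_stage_solve(inst)
        assert res.breakdown["total"] == pytest.approx(res.objective, rel=1e-9)

    def test_demand_constraint_binding_at_optimum(self):
        inst = random_small_instance(seed=13)
        res = cp.two_stage_solve(inst)
        p = cp.evaluate_survival(inst.survival, res.t_star)
        supplied = p * res.solution.X.sum(axis=1)
        demands = inst.demands
        assert np.all(supplied >= demands * (1 - 1e-6) - 1e-6)
        positive = demands > 0
        if positive.any():
            # production is costly, so some cluster's demand binds exactly
            slack = supplied[positive] / demands[positive] - 1.0
            assert slack.min() == pytest.approx(0.0, abs=1e-6)
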