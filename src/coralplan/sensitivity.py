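"""Scenario sweeps over the core solver.

Four studies probe how the optimal facility plan responds to the inputs
a planner is least certain about:

* ``reef_subset_study`` — re-solve over many random reef subsets to see
  which candidate ports persist in optimal plans and how many facilities
  optimal plans open.
* ``cost_scaling_study`` — scale one cost parameter by powers of two
  (outward from the base case) until the optimal facility count or set
  changes in each direction.
* ``pmax_sweep`` — vary the survival ceiling (10%..100%) under the
  asymptotic curve; cost should fall as the ceiling rises since fewer
  units must be produced per survivor.
* ``survival_form_grid`` — joint grid over a survival form's scaling
  factor and horizontal shift, recording objective, growth time and
  facility count per cell.

Every study is deterministic given its seed and emits tidy records
(one row per scenario) convertible to a DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .costs import CostParams, FacilitySite
from .demand import DemandParams, Reef, select_reef_subset
from .optimize import (
    InfeasibleSurvivalError,
    ProblemInstance,
    SolveResult,
    SolverConfig,
    make_instance,
    two_stage_solve,
)
from .survival import SurvivalSpec

__all__ = [
    "ScenarioResult",
    "reef_subset_study",
    "cost_scaling_study",
    "pmax_sweep",
    "survival_form_grid",
    "scenarios_to_frame",
]

COST_PARAMETERS = ("c_f_cap", "c_v_cap", "c_f_op", "c_d_op")

# per-form (c_lo, c_hi) scaling-factor ranges; t0 spans 0..0.5 for all forms
FORM_C_RANGES = {
    "asymptotic": (5.0, 55.0),
    "linear": (0.0, 0.5),
    "logistic": (5.0, 55.0),
    "pseudo_gamma": (5.0, 30.0),
}


@dataclass(frozen=True)
class ScenarioResult:
    """One solved scenario, summarized for tabulation."""

    scenario_id: str
    perturbation: str
    t_star: float
    n_facilities: int
    facility_ids: tuple[str, ...]
    production_total: float
    objective: float
    feasible: bool = True


def _summarize(
    scenario_id: str, perturbation: str, result: SolveResult,
    instance: ProblemInstance,
) -> ScenarioResult:
    open_ids = tuple(
        instance.facilities[j].id
        for j, y in enumerate(result.solution.Y) if y > 0.5
    )
    return ScenarioResult(
        scenario_id=scenario_id,
        perturbation=perturbation,
        t_star=result.t_star,
        n_facilities=len(open_ids),
        facility_ids=open_ids,
        production_total=float(np.sum(result.solution.X)),
        objective=result.objective,
    )


def _infeasible(scenario_id: str, perturbation: str) -> ScenarioResult:
    return ScenarioResult(
        scenario_id=scenario_id, perturbation=perturbation,
        t_star=float("nan"), n_facilities=0, facility_ids=(),
        production_total=float("nan"), objective=float("nan"), feasible=False,
    )


def scenarios_to_frame(scenarios: Sequence[ScenarioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scenario_id": [s.scenario_id for s in scenarios],
            "perturbation": [s.perturbation for s in scenarios],
            "t_star": [s.t_star for s in scenarios],
            "n_facilities": [s.n_facilities for s in scenarios],
            "facility_ids": [";".join(s.facility_ids) for s in scenarios],
            "production_total": [s.production_total for s in scenarios],
            "objective": [s.objective for s in scenarios],
            "objective_millions": [s.objective / 1e6 for s in scenarios],
            "feasible": [s.feasible for s in scenarios],
        }
    )


def reef_subset_study(
    all_reefs: Sequence[Reef],
    facilities: Sequence[FacilitySite],
    n_subsets: int,
    subset_size: int,
    seed: int,
    cost_params: CostParams = CostParams(),
    survival: SurvivalSpec = SurvivalSpec(),
    demand_params: DemandParams = DemandParams(),
    solver_config: SolverConfig = SolverConfig(),
) -> tuple[pd.Series, pd.Series, list[ScenarioResult]]:
    """Solve over ``n_subsets`` random reef subsets.

    Returns (per-facility selection frequency as a fraction of subsets,
    facility-count histogram, per-subset scenario records).  Subset ``k``
    is drawn with seed ``seed + k`` so the study is reproducible and each
    subset independent.
    """
    freq = {f.id: 0 for f in facilities}
    counts: dict[int, int] = {}
    scenarios: list[ScenarioResult] = []
    for k in range(n_subsets):
        sub = select_reef_subset(all_reefs, subset_size, seed + k)
        instance = make_instance(
            sub, facilities, cost_params, survival, demand_params, solver_config
        )
        sid = f"subset_{k:03d}"
        try:
            res = two_stage_solve(instance)
        except InfeasibleSurvivalError as e:
            raise InfeasibleSurvivalError(f"{sid}: {e}") from e
        scen = _summarize(sid, f"seed={seed + k}", res, instance)
        scenarios.append(scen)
        for fid in scen.facility_ids:
            freq[fid] += 1
        counts[scen.n_facilities] = counts.get(scen.n_facilities, 0) + 1
    frequency = pd.Series(
        {fid: n / n_subsets for fid, n in freq.items()}, name="selection_frequency"
    )
    histogram = pd.Series(dict(sorted(counts.items())), name="n_solutions")
    return frequency, histogram, scenarios


def _scaled_instance(
    instance: ProblemInstance, parameter: str, factor: float
) -> ProblemInstance:
    if parameter not in COST_PARAMETERS:
        raise ValueError(
            f"unknown cost parameter {parameter!r}; expected one of {COST_PARAMETERS}"
        )
    p = instance.cost_params
    new_params = replace(p, **{parameter: getattr(p, parameter) * factor})
    trip_costs = instance.trip_costs
    if parameter == "c_d_op":
        trip_costs = trip_costs * factor
    return replace(instance, cost_params=new_params, trip_costs=trip_costs)


def cost_scaling_study(
    instance: ProblemInstance,
    parameter: str,
    exponents: Sequence[float],
) -> list[ScenarioResult]:
    """Scale one cost parameter by ``2**x`` for each exponent ``x``.

    ``x = -inf`` is supported and zeroes the parameter.  Records every
    scenario; the caller can locate the smallest |x| in each direction
    that changes the facility count or set.
    """
    scenarios = []
    for x in exponents:
        factor = 0.0 if x == float("-inf") else 2.0 ** x
        scaled = _scaled_instance(instance, parameter, factor)
        sid = f"{parameter}_x{x:g}"
        try:
            res = two_stage_solve(scaled)
        except InfeasibleSurvivalError:
            scenarios.append(_infeasible(sid, f"{parameter} *= 2^{x:g}"))
            continue
        scenarios.append(_summarize(sid, f"{parameter} *= 2^{x:g}", res, scaled))
    return scenarios


def pmax_sweep(
    instance: ProblemInstance,
    pmax_values: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
) -> list[ScenarioResult]:
    """Solve at each survival ceiling in ``pmax_values``."""
    scenarios = []
    for pmax in pmax_values:
        spec = replace(instance.survival, pmax=float(pmax))
        scaled = replace(instance, survival=spec)
        sid = f"pmax_{pmax:g}"
        try:
            res = two_stage_solve(scaled)
        except InfeasibleSurvivalError:
            scenarios.append(_infeasible(sid, f"pmax={pmax:g}"))
            continue
        scenarios.append(_summarize(sid, f"pmax={pmax:g}", res, scaled))
    return scenarios


def survival_form_grid(
    instance: ProblemInstance,
    form: str,
    c_values: Sequence[float] | None = None,
    t0_values: Sequence[float] | None = None,
    n_increments: int = 11,
) -> list[ScenarioResult]:
    """Joint (c, t0) grid for one survival functional form.

    Defaults to ``n_increments`` evenly spaced values per axis over the
    form's standard range (t0 in [0, 0.5] for every form).  Cells whose
    survival curve is excluded everywhere on the growth-time grid are
    recorded as infeasible scenarios rather than raising.
    """
    if c_values is None:
        lo, hi = FORM_C_RANGES[form]
        c_values = np.linspace(lo, hi, n_increments)
    if t0_values is None:
        t0_values = np.linspace(0.0, 0.5, n_increments)
    scenarios = []
    for c in c_values:
        for t0 in t0_values:
            sid = f"{form}_c{c:g}_t0{t0:g}"
            pert = f"form={form}, c={c:g}, t0={t0:g}"
            try:
                spec = replace(instance.survival, form=form, c=float(c), t0=float(t0))
            except ValueError:
                scenarios.append(_infeasible(sid, pert))
                continue
            cell = replace(instance, survival=spec)
            try:
                res = two_stage_solve(cell)
            except InfeasibleSurvivalError:
                scenarios.append(_infeasible(sid, pert))
                continue
            scenarios.append(_summarize(sid, pert, res, cell))
    return scenarios
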