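"""Facility location, sizing and growth-time optimization.

The planning problem: open facilities ``Y_j`` at candidate coastal sites,
produce ``X_ij`` units per year at facility ``j`` for demand cluster
``i``, and run ``T_ij`` vessel trips per year, choosing also the growth
time ``t`` each unit spends in its facility before deployment.  Survival
one year post-deployment is ``P(t)``, so meeting a surviving-unit demand
``d_i`` requires ``P(t) * Σ_j X_ij >= d_i``.

With ``t`` fixed the problem is a mixed-integer linear program:

    min  Σ_j [ CRF·c_f_cap·Y_j + Σ_i ( c_ij^T·T_ij
               + X_ij·t·(CRF·c_v_cap·a + c_f_op) ) ]
    s.t. X_ij <= s_c·T_ij                 (vessel capacity per trip)
         t·Σ_i T_ij >= Y_j               (deployment frequency: an open
                                          facility empties at least once
                                          per growth period)
         P(t)·Σ_j X_ij >= d_i            (survivors meet demand)
         Σ_i X_ij <= M·Y_j               (production only at open sites)
         X >= 0, T integer >= 0, Y binary

The growth time couples survival (nonlinear) to the linear stage, so the
full problem is solved by an outer grid search: fix ``t`` on an
arithmetic grid, solve the MILP, and keep the incumbent with the
strictly smallest objective (ties go to the smallest ``t``).  ``M`` is
the total demand divided by the smallest admissible survival value on
the grid — the largest production any single facility could ever need.

The MILP backend is a thin wrapper over :func:`scipy.optimize.milp`
(HiGHS); an exhaustive enumeration oracle is provided for independent
verification on small instances.
"""

from __future__ import annotations

import itertools
import math
import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .costs import CostParams, FacilitySite, annual_cost_breakdown, trip_cost_matrix
from .demand import Cluster, DemandParams, Reef, sweep_cluster
from .survival import SurvivalSpec, evaluate_survival, survival_grid

__all__ = [
    "SolverConfig",
    "ProblemInstance",
    "MipModel",
    "MipSolution",
    "SolveResult",
    "make_instance",
    "big_M",
    "build_mip",
    "solve_mip",
    "two_stage_solve",
    "brute_force_oracle",
    "check_feasibility",
]

_CEIL_TOL = 1e-9


class InfeasibleSurvivalError(RuntimeError):
    """No growth time on the grid has admissible survival."""


class ExcludedGrowthTimeError(ValueError):
    """A MIP was requested at a growth time excluded by the survival cutoff."""


@dataclass(frozen=True)
class SolverConfig:
    """Growth-time grid and inner-solver settings.

    The grid runs ``t_min, t_min+dt, ..., t_max`` (default 0.02..1.00 in
    steps of 0.02, i.e. roughly weekly increments up to one year).
    ``mip_gap`` 0 solves each inner MILP to proven optimality.
    """

    t_min: float = 0.02
    t_max: float = 1.0
    dt: float = 0.02
    mip_gap: float = 0.0
    time_limit: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.t_min <= self.t_max:
            raise ValueError(
                f"need 0 < t_min <= t_max, got t_min={self.t_min}, t_max={self.t_max}"
            )
        if self.dt <= 0.0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.mip_gap < 0.0:
            raise ValueError("mip_gap must be >= 0")

    def to_dict(self) -> dict:
        return {"t_min": self.t_min, "t_max": self.t_max, "dt": self.dt,
                "mip_gap": self.mip_gap, "time_limit": self.time_limit}

    @classmethod
    def from_dict(cls, d: dict) -> "SolverConfig":
        keys = ("t_min", "t_max", "dt", "mip_gap", "time_limit")
        return cls(**{
            k: (None if d[k] is None else float(d[k]))
            for k in keys if k in d
        })


@dataclass(frozen=True)
class ProblemInstance:
    """A fully specified siting problem: demand clusters, candidate sites,
    costs, the survival curve and the per-trip cost matrix."""

    clusters: tuple[Cluster, ...]
    facilities: tuple[FacilitySite, ...]
    cost_params: CostParams
    survival: SurvivalSpec
    trip_costs: np.ndarray  # (|I|, |J|) $/trip
    solver_config: SolverConfig = SolverConfig()

    def __post_init__(self) -> None:
        ni, nj = len(self.clusters), len(self.facilities)
        if self.trip_costs.shape != (ni, nj):
            raise ValueError(
                f"trip cost matrix shape {self.trip_costs.shape} != ({ni}, {nj})"
            )
        if any(c.annual_demand < 0 for c in self.clusters):
            raise ValueError("cluster demands must be non-negative")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_facilities(self) -> int:
        return len(self.facilities)

    @property
    def demands(self) -> np.ndarray:
        return np.array([c.annual_demand for c in self.clusters])

    @property
    def total_demand(self) -> float:
        return float(self.demands.sum())


def make_instance(
    reefs: Sequence[Reef],
    facilities: Sequence[FacilitySite],
    cost_params: CostParams = CostParams(),
    survival: SurvivalSpec = SurvivalSpec(),
    demand_params: DemandParams = DemandParams(),
    solver_config: SolverConfig = SolverConfig(),
) -> ProblemInstance:
    """Cluster reefs and assemble a :class:`ProblemInstance`."""
    clusters = sweep_cluster(reefs, cost_params.s_c, demand_params)
    trip_costs = trip_cost_matrix(facilities, clusters, cost_params)
    return ProblemInstance(
        clusters=tuple(clusters),
        facilities=tuple(facilities),
        cost_params=cost_params,
        survival=survival,
        trip_costs=trip_costs,
        solver_config=solver_config,
    )


@dataclass(frozen=True)
class MipSolution:
    """Inner-MILP solution at a fixed growth time."""

    X: np.ndarray          # (|I|, |J|) produced units/year
    Y: np.ndarray          # (|J|,) 0/1 open indicators
    T: np.ndarray          # (|I|, |J|) integer trips/year
    objective: float       # $/yr
    status: str            # "optimal" | "infeasible" | "limit"


@dataclass(frozen=True)
class MipModel:
    """Solver-ready MILP: ``min c·x`` s.t. ``A x <= b`` with mixed integrality.

    Variable layout: X (|I|·|J| continuous), then T (|I|·|J| integer),
    then Y (|J| binary), all row-major by (cluster, facility).

    Production variables are expressed internally in vessel loads
    (``x_scale = s_c`` units each) so constraint coefficients stay within
    a few orders of magnitude of 1 — raw unit counts reach 1e8-1e9 and
    wreck MILP solver numerics.  :meth:`split` maps back to units.
    """

    instance: ProblemInstance
    t_hat: float
    survival_at_t: float
    c: np.ndarray
    A: sp.csr_matrix
    b: np.ndarray
    integrality: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    x_scale: float = 1.0

    @property
    def n_x(self) -> int:
        return self.instance.n_clusters * self.instance.n_facilities

    def split(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Extract (X, T, Y) from a raw solver vector, X in units/year."""
        ni, nj = self.instance.n_clusters, self.instance.n_facilities
        X = x[: ni * nj].reshape(ni, nj) * self.x_scale
        T = x[ni * nj: 2 * ni * nj].reshape(ni, nj)
        Y = x[2 * ni * nj:]
        return X, T, Y


def _included_grid(instance: ProblemInstance):
    cfg = instance.solver_config
    grid = survival_grid(instance.survival, cfg.t_min, cfg.t_max, cfg.dt)
    return grid, [g for g in grid if g.included]


def big_M(instance: ProblemInstance) -> float:
    """Largest conceivable production at one facility: total demand over
    the smallest admissible survival value on the growth-time grid."""
    if instance.total_demand == 0.0:
        return 0.0
    _, included = _included_grid(instance)
    if not included:
        raise InfeasibleSurvivalError(
            "no growth time on the grid has survival above pmin_allow"
        )
    p_min = min(g.survival for g in included)
    return instance.total_demand / p_min


def build_mip(instance: ProblemInstance, t_hat: float) -> MipModel:
    """Assemble the MILP at fixed growth time ``t_hat``.

    Two solver-side transformations leave the optimum untouched but make
    the model tractable: production variables are scaled to vessel loads
    (see :class:`MipModel`), and the big-M linking coefficient is
    tightened from the grid-global :func:`big_M` to ``D / P(t_hat)`` —
    valid because any optimal plan produces exactly ``D / P(t_hat)``
    units in total, so no facility can optimally exceed it.
    """
    p_t = evaluate_survival(instance.survival, t_hat)
    if p_t <= instance.survival.pmin_allow:
        raise ExcludedGrowthTimeError(
            f"growth time {t_hat} has survival {p_t} <= pmin_allow "
            f"{instance.survival.pmin_allow}"
        )
    ni, nj = instance.n_clusters, instance.n_facilities
    nij = ni * nj
    nvar = 2 * nij + nj
    params = instance.cost_params
    s_c = params.s_c
    # per-t tightening of the grid-global big-M, in vessel loads
    M = min(big_M(instance), instance.total_demand / p_t) / s_c

    c = np.empty(nvar)
    c[:nij] = t_hat * params.unit_residence_cost() * s_c
    c[nij: 2 * nij] = instance.trip_costs.ravel()
    c[2 * nij:] = params.crf * params.c_f_cap

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b: list[float] = []
    row = 0

    def x_idx(i: int, j: int) -> int:
        return i * nj + j

    def t_idx(i: int, j: int) -> int:
        return nij + i * nj + j

    def y_idx(j: int) -> int:
        return 2 * nij + j

    # vessel capacity per (i, j): X'_ij - T_ij <= 0  (X' in vessel loads)
    for i in range(ni):
        for j in range(nj):
            rows += [row, row]
            cols += [x_idx(i, j), t_idx(i, j)]
            vals += [1.0, -1.0]
            b.append(0.0)
            row += 1

    # deployment frequency per j: Y_j - t Σ_i T_ij <= 0
    for j in range(nj):
        rows.append(row)
        cols.append(y_idx(j))
        vals.append(1.0)
        for i in range(ni):
            rows.append(row)
            cols.append(t_idx(i, j))
            vals.append(-t_hat)
        b.append(0.0)
        row += 1

    # demand per i: -Σ_j X'_ij <= -d_i / (P(t) s_c)
    demands = instance.demands
    for i in range(ni):
        for j in range(nj):
            rows.append(row)
            cols.append(x_idx(i, j))
            vals.append(-1.0)
        b.append(-demands[i] / (p_t * s_c))
        row += 1

    # big-M linking per j: Σ_i X'_ij - M Y_j <= 0
    for j in range(nj):
        for i in range(ni):
            rows.append(row)
            cols.append(x_idx(i, j))
            vals.append(1.0)
        rows.append(row)
        cols.append(y_idx(j))
        vals.append(-M)
        b.append(0.0)
        row += 1

    A = sp.csr_matrix((vals, (rows, cols)), shape=(row, nvar))
    integrality = np.zeros(nvar)
    integrality[nij:] = 1
    lb = np.zeros(nvar)
    ub = np.full(nvar, np.inf)
    ub[2 * nij:] = 1.0
    return MipModel(
        instance=instance, t_hat=t_hat, survival_at_t=p_t,
        c=c, A=A, b=np.asarray(b), integrality=integrality, lb=lb, ub=ub,
        x_scale=s_c,
    )


def solve_mip(model: MipModel) -> MipSolution:
    """Solve an assembled MILP with HiGHS via :func:`scipy.optimize.milp`.

    The reported objective is recomputed from the (integer-rounded)
    extracted variables so it agrees exactly with the cost breakdown.
    """
    cfg = model.instance.solver_config
    options: dict = {"mip_rel_gap": cfg.mip_gap}
    if cfg.time_limit is not None:
        options["time_limit"] = cfg.time_limit
    res = milp(
        c=model.c,
        constraints=LinearConstraint(model.A, ub=model.b),
        integrality=model.integrality,
        bounds=Bounds(model.lb, model.ub),
        options=options,
    )
    ni, nj = model.instance.n_clusters, model.instance.n_facilities
    if res.status == 2:  # infeasible
        zeros = np.zeros((ni, nj))
        return MipSolution(X=zeros, Y=np.zeros(nj), T=zeros.copy(),
                           objective=math.inf, status="infeasible")
    if res.x is None:
        return MipSolution(X=np.zeros((ni, nj)), Y=np.zeros(nj),
                           T=np.zeros((ni, nj)), objective=math.inf,
                           status="limit")
    X, T, Y = model.split(res.x)
    T = np.rint(T)
    Y = np.rint(Y)
    X = np.clip(X, 0.0, None)
    params = model.instance.cost_params
    objective = float(
        model.t_hat * params.unit_residence_cost() * X.sum()
        + np.sum(model.instance.trip_costs * T)
        + params.crf * params.c_f_cap * Y.sum()
    )
    status = "optimal" if res.status == 0 else "limit"
    return MipSolution(X=X, Y=Y, T=T, objective=objective, status=status)


def check_feasibility(
    instance: ProblemInstance,
    solution: MipSolution,
    t: float,
    rtol: float = 1e-6,
) -> None:
    """Re-check every constraint arithmetically, outside the solver.

    Raises ``AssertionError`` on the first violated constraint; used by
    tests and by the cost breakdown's feasibility contract.
    """
    p_t = evaluate_survival(instance.survival, t)
    params = instance.cost_params
    M = big_M(instance)
    X, T, Y = solution.X, solution.T, solution.Y
    scale = max(1.0, float(np.max(np.abs(X), initial=0.0)))
    atol = rtol * scale
    assert np.all(X >= -atol), "negative production"
    assert np.all(T >= -rtol), "negative trips"
    assert np.allclose(T, np.rint(T)), "fractional trips"
    assert np.all((np.isclose(Y, 0) | np.isclose(Y, 1))), "non-binary open flags"
    assert np.all(X <= params.s_c * T + atol), "trip capacity violated"
    assert np.all(t * T.sum(axis=0) >= Y - rtol), "deployment frequency violated"
    demands = instance.demands
    assert np.all(p_t * X.sum(axis=1) >= demands * (1 - rtol) - atol), \
        "demand not met"
    assert np.all(X.sum(axis=0) <= M * Y + atol), "production at closed facility"


@dataclass(frozen=True)
class SolveResult:
    """Outcome of the two-stage grid search."""

    t_star: float
    solution: MipSolution
    objective: float
    breakdown: dict[str, float]
    per_t_trace: tuple[tuple[float, float | None], ...] = field(default=())
    runtime_s: float = 0.0


def two_stage_solve(instance: ProblemInstance) -> SolveResult:
    """Outer grid search over growth time wrapping the inner MILP.

    Iterates the growth-time grid, skips survival-excluded points (traced
    with objective ``None``), solves the MILP at each admissible point,
    and keeps the incumbent under strict improvement so the smallest
    growth time attaining the minimum wins ties.  The returned ``t_star``
    is accurate to half a grid step.
    """
    start = time.perf_counter()
    grid, included = _included_grid(instance)
    if not included:
        raise InfeasibleSurvivalError(
            "every growth time on the grid is excluded by the survival cutoff"
        )
    best: MipSolution | None = None
    best_t = math.nan
    best_z = math.inf
    trace: list[tuple[float, float | None]] = []
    for g in grid:
        if not g.included:
            trace.append((g.t, None))
            continue
        sol = solve_mip(build_mip(instance, g.t))
        z = sol.objective if sol.status == "optimal" else math.inf
        trace.append((g.t, None if math.isinf(z) else z))
        if z < best_z:
            best, best_t, best_z = sol, g.t, z
    if best is None:
        raise InfeasibleSurvivalError("no admissible growth time yielded a solution")
    breakdown = annual_cost_breakdown(best, best_t, instance)
    return SolveResult(
        t_star=best_t,
        solution=best,
        objective=best_z,
        breakdown=breakdown,
        per_t_trace=tuple(trace),
        runtime_s=time.perf_counter() - start,
    )


def _ceil(x: float) -> int:
    return int(math.ceil(x - _CEIL_TOL))


def brute_force_oracle(instance: ProblemInstance, t_hat: float) -> MipSolution:
    """Exhaustive reference solution for small instances.

    Enumerates every open-facility subset and every single-facility
    assignment of demand clusters; each open facility short of the
    minimum trip count (one deployment event per growth period) buys
    top-up trips at its cheapest per-trip cost.  Splitting a cluster
    across facilities never helps: the per-unit residence cost is
    facility-independent, trip ceilings are superadditive, and any trip a
    split could contribute toward the frequency floor is available more
    cheaply as a top-up.
    """
    ni, nj = instance.n_clusters, instance.n_facilities
    if ni > 6 or nj > 6:
        raise ValueError(f"oracle limited to 6x6 instances, got {ni}x{nj}")
    p_t = evaluate_survival(instance.survival, t_hat)
    if p_t <= instance.survival.pmin_allow:
        raise ExcludedGrowthTimeError(f"growth time {t_hat} excluded")
    params = instance.cost_params
    demands = instance.demands
    cost_t = instance.trip_costs
    x_req = demands / p_t                             # production per cluster
    trips_req = np.array([_ceil(x / params.s_c) if x > 0 else 0 for x in x_req])
    unit_cost = t_hat * params.unit_residence_cost()
    residence = unit_cost * float(x_req.sum())        # assignment-independent
    fixed = params.crf * params.c_f_cap
    min_trips = _ceil(1.0 / t_hat)                    # per open facility
    cheapest_trip = cost_t.min(axis=0) if ni else np.zeros(nj)

    active = [i for i in range(ni) if demands[i] > 0]
    best_cost = math.inf
    best_plan: tuple[tuple[int, ...], tuple[int, ...]] | None = None

    for r in range(0 if not active else 1, nj + 1):
        for subset in itertools.combinations(range(nj), r):
            sub_fixed = fixed * r
            if sub_fixed + residence >= best_cost:
                continue
            for assign in itertools.product(subset, repeat=len(active)):
                transport = sum(
                    cost_t[i, j] * trips_req[i] for i, j in zip(active, assign)
                )
                topup = 0.0
                for j in subset:
                    got = sum(trips_req[i] for i, jj in zip(active, assign) if jj == j)
                    if got < min_trips:
                        topup += (min_trips - got) * cheapest_trip[j]
                total = sub_fixed + residence + transport + topup
                if total < best_cost:
                    best_cost = total
                    best_plan = (subset, assign)

    if best_plan is None:
        if active:
            return MipSolution(X=np.zeros((ni, nj)), Y=np.zeros(nj),
                               T=np.zeros((ni, nj)), objective=math.inf,
                               status="infeasible")
        return MipSolution(X=np.zeros((ni, nj)), Y=np.zeros(nj),
                           T=np.zeros((ni, nj)), objective=0.0, status="optimal")

    subset, assign = best_plan
    X = np.zeros((ni, nj))
    T = np.zeros((ni, nj))
    Y = np.zeros(nj)
    for j in subset:
        Y[j] = 1.0
    for i, j in zip(active, assign):
        X[i, j] = x_req[i]
        T[i, j] = trips_req[i]
    for j in subset:
        got = int(T[:, j].sum())
        if got < min_trips:
            i_cheap = int(np.argmin(cost_t[:, j]))
            T[i_cheap, j] += min_trips - got
    return MipSolution(X=X, Y=Y, T=T, objective=best_cost, status="optimal")


def scale_costs(instance: ProblemInstance, factor: float) -> ProblemInstance:
    """Return a copy with all four cost parameters scaled by ``factor``."""
    p = instance.cost_params
    new_params = replace(
        p,
        c_f_cap=p.c_f_cap * factor,
        c_v_cap=p.c_v_cap * factor,
        c_f_op=p.c_f_op * factor,
        c_d_op=p.c_d_op * factor,
    )
    return replace(
        instance,
        cost_params=new_params,
        trip_costs=instance.trip_costs * factor,
    )
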