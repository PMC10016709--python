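import numpy as np
import pytest

import coralplan as cp
from coralplan.costs import FacilitySite, trip_cost_matrix
from coralplan.demand import Cluster


@pytest.fixture(scope="session")
def base_spec() -> cp.SurvivalSpec:
    """Base-case asymptotic survival curve (c=25, t0=0, pmax=0.1)."""
    return cp.SurvivalSpec()


@pytest.fixture(scope="session")
def synthetic_field() -> list[cp.Reef]:
    """A full-size synthetic reef province (2816 reefs)."""
    return cp.generate_synthetic_reefs(cp.SyntheticFieldSpec(n_reefs=2816, seed=7))


@pytest.fixture(scope="session")
def base_instance(synthetic_field) -> cp.ProblemInstance:
    """Benchmark-scale instance: 50 random reefs, 7 candidate ports."""
    reefs = cp.select_reef_subset(synthetic_field, 50, seed=1)
    return cp.make_instance(reefs, cp.DEFAULT_PORTS)


def random_small_instance(
    seed: int,
    max_side: int = 4,
    t_grid: tuple[float, float, float] = (0.04, 1.0, 0.24),
) -> cp.ProblemInstance:
    """A random instance small enough for the exhaustive oracle."""
    rng = np.random.default_rng(seed)
    ni = int(rng.integers(1, max_side + 1))
    nj = int(rng.integers(1, max_side + 1))
    clusters = []
    for i in range(ni):
        demand = float(rng.uniform(0, 1.5e6)) if rng.random() > 0.1 else 0.0
        clusters.append(
            Cluster(
                id=f"c{i}",
                member_reef_ids=(f"r{i}",),
                centroid_lat=float(rng.uniform(-25, -10)),
                centroid_lon=float(rng.uniform(144, 153)),
                annual_demand=demand,
                intra_allowance_km=float(rng.uniform(0, 30)),
            )
        )
    facilities = [
        FacilitySite(f"f{j}", f"F{j}", float(rng.uniform(-25, -10)),
                     float(rng.uniform(144, 152)))
        for j in range(nj)
    ]
    params = cp.CostParams()
    trip_costs = trip_cost_matrix(facilities, clusters, params)
    t_min, t_max, dt = t_grid
    return cp.ProblemInstance(
        clusters=tuple(clusters),
        facilities=tuple(facilities),
        cost_params=params,
        survival=cp.SurvivalSpec(),
        trip_costs=trip_costs,
        solver_config=cp.SolverConfig(t_min=t_min, t_max=t_max, dt=dt),
    )
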