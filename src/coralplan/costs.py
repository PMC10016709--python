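"""Cost model: amortized capital, Little's-law facility sizing, trip costs.

Annualized cost of a production plan has four components:

fixed capital
    ``CRF * c_f_cap`` per open facility, where ``CRF`` is the capital
    recovery factor — the annuity rate converting a lump capital sum into
    a constant annual payment over the amortization horizon.
variable capital
    Facility floor area follows Little's law: average in-process
    inventory equals throughput times residence time, ``t * X`` units,
    each needing ``a`` m² of floor; the build cost ``c_v_cap`` $/m² is
    amortized the same way, giving ``CRF * c_v_cap * a * t * X`` per year.
operating
    ``c_f_op`` dollars per unit-year of residence applied to the same
    in-process inventory: ``c_f_op * t * X`` per year.
transport
    Per-trip cost ``c_ij^T`` = $/km rate times the return-trip distance
    facility→cluster-centroid→facility plus the cluster's intra-cluster
    allowance, summed over trips actually run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .demand import Cluster
from .geo import haversine_km

if TYPE_CHECKING:  # pragma: no cover
    from .optimize import MipSolution, ProblemInstance

__all__ = [
    "CostParams",
    "FacilitySite",
    "DEFAULT_PORTS",
    "capital_recovery_factor",
    "trip_cost_matrix",
    "annual_cost_breakdown",
]


@dataclass(frozen=True)
class CostParams:
    """Capital, operating and logistics cost parameters.

    Defaults are the expert-elicited case-study values: a $10M fixed
    build cost and $45,000/m² variable build cost per facility, both
    amortized at 5% p.a. over 25 years; $2.56 per coral unit per year of
    facility residence; $100 per km sailed; vessels carrying 432,000
    units per trip; and 8.05 m² of tank floor per 24,000 units.
    """

    c_f_cap: float = 10_000_000.0     # $ per facility opened
    c_v_cap: float = 45_000.0         # $ per m² of floor built
    c_f_op: float = 2.56              # $ per unit-year of residence
    c_d_op: float = 100.0             # $ per km travelled
    interest: float = 0.05            # periodic rate, fraction/yr
    horizon: float = 25.0             # amortization period, yr
    s_c: float = 432_000.0            # vessel capacity, units/trip
    a: float = 8.05 / 24_000.0        # m² of floor per unit

    def __post_init__(self) -> None:
        for name in ("c_f_cap", "c_v_cap", "c_f_op", "c_d_op", "horizon", "s_c", "a"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")
        if self.interest < 0.0:
            raise ValueError("interest must be >= 0")
        if self.horizon < 1.0:
            raise ValueError(f"horizon must be >= 1 year, got {self.horizon}")

    @property
    def crf(self) -> float:
        return capital_recovery_factor(self.interest, self.horizon)

    def unit_residence_cost(self) -> float:
        """$ per unit per year of residence: amortized floor + operating."""
        return self.crf * self.c_v_cap * self.a + self.c_f_op

    def to_dict(self) -> dict:
        return {
            "c_f_cap": self.c_f_cap, "c_v_cap": self.c_v_cap,
            "c_f_op": self.c_f_op, "c_d_op": self.c_d_op,
            "interest": self.interest, "horizon": self.horizon,
            "s_c": self.s_c, "a": self.a,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CostParams":
        keys = ("c_f_cap", "c_v_cap", "c_f_op", "c_d_op",
                "interest", "horizon", "s_c", "a")
        # YAML 1.1 reads exponent literals like 5.0e6 as strings
        return cls(**{k: float(d[k]) for k in keys if k in d})


@dataclass(frozen=True)
class FacilitySite:
    """A candidate coastal port where a facility may be opened."""

    id: str
    name: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"site {self.id}: latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"site {self.id}: longitude {self.lon} out of range")


# Approximate public coordinates for the seven Queensland candidate ports;
# override from config for a real siting study.
DEFAULT_PORTS: tuple[FacilitySite, ...] = (
    FacilitySite("bundaberg", "Bundaberg", -24.87, 152.35),
    FacilitySite("gladstone", "Gladstone", -23.85, 151.26),
    FacilitySite("rockhampton", "Rockhampton", -23.38, 150.51),
    FacilitySite("mackay", "Mackay", -21.14, 149.19),
    FacilitySite("airlie_beach", "Airlie Beach", -20.27, 148.72),
    FacilitySite("townsville", "Townsville", -19.26, 146.82),
    FacilitySite("cairns", "Cairns", -16.92, 145.78),
)


def capital_recovery_factor(interest: float, horizon: float) -> float:
    """Annuity rate turning a lump sum into equal annual payments.

    ``CRF = i / (1 - (1+i)^-n)`` for interest ``i > 0``; the zero-interest
    limit is straight-line ``1/n``.
    """
    if horizon < 1.0:
        raise ValueError(f"horizon must be >= 1 year, got {horizon}")
    if interest < 0.0:
        raise ValueError(f"interest must be >= 0, got {interest}")
    if interest == 0.0:
        return 1.0 / horizon
    return interest / (1.0 - (1.0 + interest) ** (-horizon))


def trip_cost_matrix(
    facilities: Sequence[FacilitySite],
    clusters: Sequence[Cluster],
    params: CostParams,
) -> np.ndarray:
    """Per-trip cost matrix ``c_ij^T`` ($/trip), shape (clusters, facilities).

    Each trip sails facility → cluster centroid → facility (twice the
    great-circle distance) plus the cluster's intra-cluster star-tour
    allowance, priced at ``c_d_op`` $/km.
    """
    cost = np.empty((len(clusters), len(facilities)))
    for i, cl in enumerate(clusters):
        for j, fac in enumerate(facilities):
            d = haversine_km(fac.lat, fac.lon, cl.centroid_lat, cl.centroid_lon)
            cost[i, j] = params.c_d_op * (2.0 * d + cl.intra_allowance_km)
    return cost


def annual_cost_breakdown(
    solution: "MipSolution",
    t: float,
    instance: "ProblemInstance",
) -> dict[str, float]:
    """Decompose a solution's annual cost into its four components.

    Returns ``{"fixed_capital", "variable_capital", "operating",
    "transport", "total"}`` in $/yr; ``total`` equals the MIP objective.
    """
    p = instance.cost_params
    crf = p.crf
    x_total = float(np.sum(solution.X))
    fixed_capital = crf * p.c_f_cap * float(np.sum(solution.Y))
    variable_capital = crf * p.c_v_cap * p.a * t * x_total
    operating = p.c_f_op * t * x_total
    transport = float(np.sum(instance.trip_costs * solution.T))
    total = fixed_capital + variable_capital + operating + transport
    return {
        "fixed_capital": fixed_capital,
        "variable_capital": variable_capital,
        "operating": operating,
        "transport": transport,
        "total": total,
    }
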