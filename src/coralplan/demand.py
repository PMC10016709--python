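"""Reef demand generation and capacity-respecting clustering.

Each reef is treated as a disc whose radius follows from its surveyed
area.  The restoration target is an atoll: an annular band of width
``r_width`` centred on the reef perimeter.  Planting density ``d_c``
(corals per m² restored) times the atoll area gives the reef's annual
demand in surviving corals.  Small reefs (radius at or below a threshold)
are restored across the whole disc plus the band.

Reefs are then aggregated into clusters by a north-to-south latitude
sweep: adjacent reefs join the current cluster while its cumulative
annual demand stays within one vessel load ``s_c``, so a single
deployment vessel can service a cluster.  Each cluster carries an
intra-cluster distance allowance — a round-trip star tour from the
cluster centroid to each member reef — added to every vessel trip that
serves it.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Sequence

from .geo import haversine_km

__all__ = [
    "Reef",
    "DemandParams",
    "Cluster",
    "reef_radius",
    "reef_demand",
    "sweep_cluster",
    "intra_cluster_allowance",
    "select_reef_subset",
]

_M2_PER_KM2 = 1e6


@dataclass(frozen=True)
class Reef:
    """A demand-generating reef site (WGS84 coordinates, area in km²)."""

    id: str
    lat: float
    lon: float
    area: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"reef {self.id}: latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"reef {self.id}: longitude {self.lon} out of range")
        if not self.area > 0.0:
            raise ValueError(f"reef {self.id}: area must be positive, got {self.area}")


@dataclass(frozen=True)
class DemandParams:
    """Restoration-atoll geometry and planting density.

    d_c: corals planted per m² restored (default 1).
    r_width: width of the restoration atoll band in metres (default 20).
    disc_threshold: reef radius (m) at or below which the whole disc is
        restored rather than only the annulus (default 100).
    """

    d_c: float = 1.0
    r_width: float = 20.0
    disc_threshold: float = 100.0

    def __post_init__(self) -> None:
        if self.d_c < 0.0:
            raise ValueError(f"d_c must be >= 0, got {self.d_c}")
        if not self.r_width > 0.0:
            raise ValueError(f"r_width must be positive, got {self.r_width}")
        if self.disc_threshold < 0.0:
            raise ValueError(f"disc_threshold must be >= 0, got {self.disc_threshold}")


@dataclass(frozen=True)
class Cluster:
    """A latitude-contiguous group of reefs serviced as one demand point."""

    id: str
    member_reef_ids: tuple[str, ...]
    centroid_lat: float
    centroid_lon: float
    annual_demand: float
    intra_allowance_km: float = 0.0


def reef_radius(area_km2: float) -> float:
    """Radius in metres of the disc with the given area in km²."""
    if not area_km2 > 0.0:
        raise ValueError(f"reef area must be positive, got {area_km2}")
    return math.sqrt(area_km2 * _M2_PER_KM2 / math.pi)


def reef_demand(reef: Reef, params: DemandParams = DemandParams()) -> float:
    """Annual demand (surviving corals/year) for one reef.

    Large reefs (radius above the disc threshold) demand the annulus of
    width ``r_width`` centred on the perimeter; small reefs demand the
    full disc out to the band's outer edge.
    """
    r = reef_radius(reef.area)
    half = params.r_width / 2.0
    if r <= params.disc_threshold:
        area_m2 = math.pi * (r + half) ** 2
    else:
        area_m2 = math.pi * ((r + half) ** 2 - (r - half) ** 2)
    return params.d_c * area_m2


def _sweep_key(reef: Reef) -> tuple[float, float, str]:
    # north→south: latitude descending; ties broken west→east, then id
    return (-reef.lat, reef.lon, reef.id)


def sweep_cluster(
    reefs: Sequence[Reef],
    s_c: float,
    params: DemandParams = DemandParams(),
    demands: Sequence[float] | None = None,
) -> list[Cluster]:
    """Greedy north-to-south sweep clustering under vessel capacity ``s_c``.

    Reefs are sorted by latitude descending and accumulated into the
    current cluster while its cumulative annual demand stays <= ``s_c``.
    A reef whose own demand exceeds ``s_c`` forms a singleton cluster.
    Cluster centroids are unweighted means of member coordinates, and each
    cluster's intra-cluster allowance is computed on construction.

    Pre-computed per-reef ``demands`` (aligned with ``reefs``) may be
    supplied; otherwise they are derived from ``params``.
    """
    if not s_c > 0.0:
        raise ValueError(f"vessel capacity must be positive, got {s_c}")
    if demands is None:
        demand_of = {r.id: reef_demand(r, params) for r in reefs}
    else:
        if len(demands) != len(reefs):
            raise ValueError("demands must align with reefs")
        demand_of = {r.id: d for r, d in zip(reefs, demands)}

    ordered = sorted(reefs, key=_sweep_key)
    clusters: list[Cluster] = []
    current: list[Reef] = []
    current_demand = 0.0

    def flush() -> None:
        nonlocal current, current_demand
        if not current:
            return
        cid = f"cluster_{len(clusters):03d}"
        lat = sum(r.lat for r in current) / len(current)
        lon = sum(r.lon for r in current) / len(current)
        allowance = 2.0 * sum(haversine_km(lat, lon, r.lat, r.lon) for r in current)
        clusters.append(
            Cluster(
                id=cid,
                member_reef_ids=tuple(r.id for r in current),
                centroid_lat=lat,
                centroid_lon=lon,
                annual_demand=current_demand,
                intra_allowance_km=allowance,
            )
        )
        current = []
        current_demand = 0.0

    for reef in ordered:
        d = demand_of[reef.id]
        if d > s_c:
            # oversize reef: close the running cluster, emit a singleton
            flush()
            current = [reef]
            current_demand = d
            flush()
            continue
        if current and current_demand + d > s_c:
            flush()
        current.append(reef)
        current_demand += d
    flush()
    return clusters


def intra_cluster_allowance(
    cluster: Cluster, reefs: Sequence[Reef]
) -> float:
    """Round-trip star-tour allowance (km): 2 × Σ centroid-to-member distance."""
    by_id = {r.id: r for r in reefs}
    try:
        members = [by_id[rid] for rid in cluster.member_reef_ids]
    except KeyError as e:
        raise ValueError(f"cluster {cluster.id} references unknown reef {e}") from e
    if not members:
        raise ValueError(f"cluster {cluster.id} has no members")
    return 2.0 * sum(
        haversine_km(cluster.centroid_lat, cluster.centroid_lon, r.lat, r.lon)
        for r in members
    )


def select_reef_subset(reefs: Sequence[Reef], n: int, seed: int) -> list[Reef]:
    """Uniform sample of ``n`` reefs without replacement, reproducible by seed."""
    if n > len(reefs):
        raise ValueError(f"cannot sample {n} reefs from {len(reefs)}")
    rng = random.Random(seed)
    return rng.sample(list(reefs), n)
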