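"""Reading and writing the package's file formats.

Reef registries come in as CSV (header columns ``id, lat, lon,
area_km2``, remappable); configuration as a YAML file with sections for
demand, survival, cost and solver parameters plus an optional port
registry; results go out as JSON (full solve summary), CSV (assignment
table) and GeoJSON (RFC 7946 Point features, lon-lat order).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .costs import DEFAULT_PORTS, CostParams, FacilitySite
from .demand import Cluster, DemandParams, Reef
from .optimize import ProblemInstance, SolveResult, SolverConfig
from .survival import SurvivalSpec

__all__ = [
    "ReefLoadError",
    "read_reefs_csv",
    "write_reefs_csv",
    "read_config",
    "write_clusters_csv",
    "clusters_geojson",
    "solve_result_dict",
    "write_result",
]

DEFAULT_COLUMNS = {"id": "id", "lat": "lat", "lon": "lon", "area": "area_km2"}


class ReefLoadError(ValueError):
    """Raised when a reef CSV is malformed; names the offending row."""


def read_reefs_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[Reef]:
    """Load and validate reef records from CSV.

    ``column_map`` maps the logical fields ``id, lat, lon, area`` onto
    the file's header names (defaults: ``id, lat, lon, area_km2``).
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    reefs: list[Reef] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [v for v in cols.values() if v not in header]
        if missing:
            raise ReefLoadError(f"{path}: missing column(s) {', '.join(missing)}")
        for rownum, row in enumerate(reader, start=2):
            try:
                reefs.append(
                    Reef(
                        id=str(row[cols["id"]]),
                        lat=float(row[cols["lat"]]),
                        lon=float(row[cols["lon"]]),
                        area=float(row[cols["area"]]),
                    )
                )
            except (TypeError, ValueError) as e:
                raise ReefLoadError(f"{path}: row {rownum}: {e}") from e
    return reefs


def write_reefs_csv(reefs: Sequence[Reef], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "lat", "lon", "area_km2"])
        for r in reefs:
            writer.writerow([r.id, repr(r.lat), repr(r.lon), repr(r.area)])


def _ports_from_config(entries) -> tuple[FacilitySite, ...]:
    ports = []
    for e in entries:
        ports.append(
            FacilitySite(
                id=str(e.get("id", e["name"]).lower().replace(" ", "_"))
                if isinstance(e, dict) else str(e[0]),
                name=str(e["name"]),
                lat=float(e["lat"]),
                lon=float(e["lon"]),
            )
        )
    return tuple(ports)


def read_config(path: str | Path) -> dict:
    """Parse a YAML config into typed parameter objects.

    Recognized top-level sections: ``demand``, ``survival``, ``costs``,
    ``solver``, ``ports`` (list of name/lat/lon mappings) and ``seed``.
    Absent sections fall back to package defaults.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    demand_raw = raw.get("demand", {})
    demand = DemandParams(**{
        k: float(demand_raw[k]) for k in ("d_c", "r_width", "disc_threshold")
        if k in demand_raw
    })
    return {
        "demand": demand,
        "survival": SurvivalSpec.from_dict(raw.get("survival", {})),
        "costs": CostParams.from_dict(raw.get("costs", {})),
        "solver": SolverConfig.from_dict(raw.get("solver", {})),
        "ports": _ports_from_config(raw["ports"]) if "ports" in raw else DEFAULT_PORTS,
        "seed": int(raw.get("seed", 0)),
    }


def write_clusters_csv(clusters: Sequence[Cluster], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "centroid_lat", "centroid_lon", "annual_demand",
             "intra_allowance_km", "n_reefs", "member_reef_ids"]
        )
        for c in clusters:
            writer.writerow(
                [c.id, repr(c.centroid_lat), repr(c.centroid_lon),
                 repr(c.annual_demand), repr(c.intra_allowance_km),
                 len(c.member_reef_ids), ";".join(c.member_reef_ids)]
            )


def clusters_geojson(clusters: Sequence[Cluster]) -> dict:
    """RFC 7946 FeatureCollection of cluster centroids (lon-lat order)."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [c.centroid_lon, c.centroid_lat],
                },
                "properties": {
                    "id": c.id,
                    "annual_demand": c.annual_demand,
                    "n_reefs": len(c.member_reef_ids),
                },
            }
            for c in clusters
        ],
    }


def solve_result_dict(result: SolveResult, instance: ProblemInstance) -> dict:
    """JSON-serializable summary of a two-stage solve."""
    open_idx = [j for j, y in enumerate(result.solution.Y) if y > 0.5]
    assignment = []
    for i, cl in enumerate(instance.clusters):
        for j in open_idx:
            x = float(result.solution.X[i, j])
            trips = int(result.solution.T[i, j])
            if x > 0 or trips > 0:
                assignment.append(
                    {
                        "cluster": cl.id,
                        "facility": instance.facilities[j].id,
                        "produced_units_per_year": x,
                        "trips_per_year": trips,
                    }
                )
    return {
        "t_star_years": result.t_star,
        "objective_per_year": result.objective,
        "breakdown_per_year": result.breakdown,
        "total_production_per_year": float(np.sum(result.solution.X)),
        "open_facilities": [instance.facilities[j].id for j in open_idx],
        "n_open_facilities": len(open_idx),
        "n_clusters": instance.n_clusters,
        "total_demand_per_year": instance.total_demand,
        "assignment": assignment,
        "per_t_trace": [
            {"t": t, "objective": z, "excluded": z is None}
            for t, z in result.per_t_trace
        ],
        "runtime_s": result.runtime_s,
    }


def write_result(
    result: SolveResult,
    instance: ProblemInstance,
    out_dir: str | Path,
    stem: str = "solution",
) -> dict[str, Path]:
    """Write a solve result as JSON + assignment CSV + GeoJSON.

    Returns the mapping of artifact kind to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = solve_result_dict(result, instance)
    paths = {
        "json": out / f"{stem}.json",
        "csv": out / f"{stem}_assignment.csv",
        "geojson": out / f"{stem}.geojson",
    }
    with open(paths["json"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    with open(paths["csv"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["cluster", "facility", "produced_units_per_year", "trips_per_year"]
        )
        for rec in summary["assignment"]:
            writer.writerow(
                [rec["cluster"], rec["facility"],
                 repr(rec["produced_units_per_year"]), rec["trips_per_year"]]
            )
    geo = clusters_geojson(instance.clusters)
    by_cluster = {}
    for rec in summary["assignment"]:
        by_cluster.setdefault(rec["cluster"], []).append(rec["facility"])
    for feat in geo["features"]:
        feat["properties"]["assigned_facilities"] = by_cluster.get(
            feat["properties"]["id"], []
        )
    with open(paths["geojson"], "w", encoding="utf-8") as fh:
        json.dump(geo, fh, indent=2)
    return paths
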