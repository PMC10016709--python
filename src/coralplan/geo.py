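"""Great-circle geometry on a spherical Earth (radius 6371 km)."""

from __future__ import annotations

import math

EARTH_RADIUS_KM = 6371.0

__all__ = ["EARTH_RADIUS_KM", "haversine_km"]


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two WGS84 points.

    Spherical approximation; the sub-percent error against an ellipsoidal
    geodesic is negligible next to cost-parameter uncertainty.
    """
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))
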