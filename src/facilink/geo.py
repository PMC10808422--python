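"""Great-circle geometry for geospatial conflict detection.

Coordinates are WGS84 decimal degrees.  Distances use the Haversine formula
on a sphere of mean Earth radius 6371 km; matched groups whose member
coordinates imply a separation above 1 km are review-flagged, and groups
with multiple distinct coordinates more than 2 km apart count as discordant
in the validation summary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "GeoConstants",
    "haversine_km",
    "max_pairwise_distance",
    "distinct_coordinates",
    "discordance_stats",
]

COORDINATE_DECIMALS = 5  # output/rounding precision for WGS84 decimal degrees


@dataclass(frozen=True)
class GeoConstants:
    earth_radius_km: float = 6371.0
    review_distance_km: float = 1.0
    discordance_distance_km: float = 2.0

    def __post_init__(self) -> None:
        if min(self.earth_radius_km, self.review_distance_km,
               self.discordance_distance_km) <= 0:
            raise ValueError("geo constants must be positive")


DEFAULT_GEO = GeoConstants()


def haversine_km(
    lat1: float, lon1: float, lat2: float, lon2: float,
    constants: GeoConstants = DEFAULT_GEO,
) -> float:
    """Great-circle distance between two points, in kilometres.

    ``2R·asin(√(sin²(Δφ/2) + cosφ₁·cosφ₂·sin²(Δλ/2)))`` with angles in
    radians; symmetric and non-negative.
    """
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * constants.earth_radius_km * math.asin(min(1.0, math.sqrt(a)))


def _member_coordinates(group) -> list[tuple[float, float]]:
    return [
        (m.latitude, m.longitude) for m in group.members if m.has_coords
    ]


def distinct_coordinates(group) -> list[tuple[float, float]]:
    """Unique member coordinate pairs after 5-decimal rounding.

    Coordinates that agree to the output precision count as a single set.
    """
    seen: dict[tuple[float, float], None] = {}
    for lat, lon in _member_coordinates(group):
        seen.setdefault((round(lat, COORDINATE_DECIMALS), round(lon, COORDINATE_DECIMALS)))
    return list(seen)


def max_pairwise_distance(group, constants: GeoConstants = DEFAULT_GEO) -> float | None:
    """Largest Haversine distance among geolocated members; None if < 2."""
    coords = _member_coordinates(group)
    if len(coords) < 2:
        return None
    return max(
        haversine_km(a[0], a[1], b[0], b[1], constants)
        for a, b in itertools.combinations(coords, 2)
    )


def discordance_stats(
    groups: Sequence, constants: GeoConstants = DEFAULT_GEO
) -> dict[str, float | int | None]:
    """Share of multi-coordinate groups whose points sit > 2 km apart.

    ``n_multi_gps`` counts groups with at least two *distinct* rounded
    coordinate sets; ``frac_exceeding`` is the share of those whose maximum
    pairwise distance exceeds ``discordance_distance_km`` (None when no
    group has multiple coordinates).
    """
    multi = [g for g in groups if len(distinct_coordinates(g)) >= 2]
    if not multi:
        return {"n_multi_gps": 0, "frac_exceeding": None}
    n_exceeding = sum(
        1
        for g in multi
        if (max_pairwise_distance(g, constants) or 0.0) > constants.discordance_distance_km
    )
    return {"n_multi_gps": len(multi), "frac_exceeding": n_exceeding / len(multi)}
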