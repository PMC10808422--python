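"""Single-coordinate assignment per facility group.

When a matched group carries coordinates from several sources, one pair is
chosen by an ordered source-preference hierarchy (government-associated
sources first).  The study's default order is COUS, then the non-2017
Service Provision Assessment frames (2016, 2015, 2014), then SPA 2017,
then ESRI, HDX, and the Maina et al. spatial database; the hierarchy is
configuration, not code, so other countries' priorities can be expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .geo import COORDINATE_DECIMALS
from .matching import MatchGroup

__all__ = ["SourceHierarchy", "DEFAULT_HIERARCHY", "assign_gps", "count_distinct_gps"]


@dataclass(frozen=True)
class SourceHierarchy:
    """Ordered preference tiers of source ids for GPS assignment.

    Within a tier the listed order breaks ties.  Sources absent from every
    tier rank after all listed sources, in run-configuration order.
    """

    tiers: tuple[tuple[str, ...], ...] = (
        ("cous",),
        ("spa2016", "spa2015", "spa2014"),
        ("spa2017",),
        ("esri",),
        ("hdx",),
        ("maina",),
    )

    def __post_init__(self) -> None:
        flat = [s for tier in self.tiers for s in tier]
        if len(flat) != len(set(flat)):
            raise ValueError("a source_id appears in more than one hierarchy tier")

    def rank(self, source_id: str, fallback_order: int = 0) -> tuple[int, int, int]:
        """Total preference order; lower sorts first.

        Listed sources rank by (tier, position); unlisted ones rank after
        everything listed, by their configured source order.
        """
        for t, tier in enumerate(self.tiers):
            if source_id in tier:
                return (0, t * 1000 + tier.index(source_id), 0)
        return (1, fallback_order, 0)


DEFAULT_HIERARCHY = SourceHierarchy()


def assign_gps(
    group: MatchGroup, hierarchy: SourceHierarchy = DEFAULT_HIERARCHY
) -> dict[str, float | str] | None:
    """Pick the group's authoritative coordinates.

    A single geolocated member is used directly; otherwise the member from
    the highest-ranked source wins, with row order breaking ties inside one
    source (that situation — one source contributing two coordinates to one
    group — is also flagged).  Coordinates are rounded to 5 decimals.
    Returns None when no member has coordinates.
    """
    geolocated = [m for m in group.members if m.has_coords]
    if not geolocated:
        return None
    chosen = min(
        geolocated,
        key=lambda m: (hierarchy.rank(m.source_id, m.source_order), m.row_index),
    )
    same_source = [m for m in geolocated if m.source_id == chosen.source_id]
    if len({(round(m.latitude, COORDINATE_DECIMALS), round(m.longitude, COORDINATE_DECIMALS))
            for m in same_source}) > 1:
        group.add_note(
            f"multiple coordinates within source {chosen.source_id}; "
            "first by row order used"
        )
    return {
        "latitude": round(chosen.latitude, COORDINATE_DECIMALS),
        "longitude": round(chosen.longitude, COORDINATE_DECIMALS),
        "gps_source": chosen.source_id,
    }


def count_distinct_gps(group: MatchGroup) -> int:
    """Number of unique coordinate pairs among members after 5-decimal
    rounding; coordinates that match precisely count once."""
    from .geo import distinct_coordinates

    return len(distinct_coordinates(group))
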