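"""Group-level conflict resolution and final list construction.

After clustering, each group's facility type is resolved (facilities are
frequently reported one tier lower by older sources because they were since
upgraded, e.g. a health hut become a health post), geospatial and same-name
ambiguities are flagged for human verification, and the consolidated
facility list (CFL) is emitted with one row per unique facility alongside a
full per-record list linkable through ``match_id``.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import pandas as pd

from .geo import DEFAULT_GEO, GeoConstants, haversine_km, max_pairwise_distance
from .gps import DEFAULT_HIERARCHY, SourceHierarchy, assign_gps, count_distinct_gps
from .ingest import TYPE_LADDER, FacilityType, NormalizedRecord
from .matching import MatchGroup, MatchingConfig, jaro_winkler_distance

__all__ = [
    "CFL_COLUMNS",
    "CFL_TYPE_LABELS",
    "resolve_fac_type",
    "assign_group_gps",
    "flag_geo_conflicts",
    "flag_same_name_conflicts",
    "near_threshold_report",
    "build_cfl",
    "build_full_list",
    "consolidate_groups",
]

logger = logging.getLogger(__name__)

# Exact output schema of the consolidated facility list.
CFL_COLUMNS = [
    "region",
    "match_id",
    "match_name",
    "group_fac_type",
    "group_latitude",
    "group_longitude",
    "group_gps_source",
    "n_gps",
    "n_source",
    "source_list",
    "data_flagged",
    "data_notes",
]

# Output labels (French, without special characters).
CFL_TYPE_LABELS: dict[FacilityType, str] = {
    FacilityType.HOPITAL: "hopital",
    FacilityType.CENTRE_DE_SANTE: "centre de sante",
    FacilityType.POSTE_DE_SANTE: "poste de sante",
    FacilityType.CASE_DE_SANTE: "case de sante",
    FacilityType.AUTRE: "autre",
    FacilityType.UNKNOWN: "unknown",
}

HEADLINE_TYPES = (
    FacilityType.HOPITAL,
    FacilityType.CENTRE_DE_SANTE,
    FacilityType.POSTE_DE_SANTE,
    FacilityType.CASE_DE_SANTE,
)


def _member_year(member: NormalizedRecord) -> int | None:
    return member.source_year


def resolve_fac_type(group: MatchGroup) -> FacilityType:
    """Resolve conflicting member types to a single group type.

    Rules, in order:

    * a single distinct reported type (ignoring unknown) stands as-is;
    * when all conflicting types sit on the upgrade ladder
      (hut < post < center < hospital) and at least one member is dated, the
      most recently dated report wins — upgrades/downgrades are resolved by
      recency and noted;
    * otherwise (off-ladder conflict, or no dated member) the majority type
      wins, ties going to the higher tier, and the group is flagged.

    Undated sources rank oldest.  The resolved type is stored on the group
    and returned.
    """
    typed = [m for m in group.members if m.fac_type_std is not FacilityType.UNKNOWN]
    distinct = {m.fac_type_std for m in typed}
    if not distinct:
        group.group_fac_type = FacilityType.UNKNOWN
        return group.group_fac_type
    if len(distinct) == 1:
        group.group_fac_type = next(iter(distinct))
        return group.group_fac_type

    labels = " vs ".join(sorted(CFL_TYPE_LABELS[t] for t in distinct))
    on_ladder = all(t in TYPE_LADDER for t in distinct)
    dated = [m for m in typed if _member_year(m) is not None]
    if on_ladder and dated:
        latest_year = max(_member_year(m) for m in dated)
        latest = [m for m in dated if _member_year(m) == latest_year]
        latest_types = {m.fac_type_std for m in latest}
        if len(latest_types) == 1:
            resolved = next(iter(latest_types))
        else:
            resolved = _majority_type(latest)
        earlier = {
            m.fac_type_std for m in typed if m.fac_type_std is not resolved
        }
        direction = (
            "upgrade"
            if all(TYPE_LADDER[t] < TYPE_LADDER[resolved] for t in earlier)
            else "downgrade"
            if all(TYPE_LADDER[t] > TYPE_LADDER[resolved] for t in earlier)
            else "change"
        )
        group.add_note(
            f"facility type conflict ({labels}) resolved to "
            f"{CFL_TYPE_LABELS[resolved]} by most recent source ({direction})"
        )
    else:
        resolved = _majority_type(typed)
        group.add_note(
            f"facility type conflict ({labels}): majority/higher-tier "
            f"assignment {CFL_TYPE_LABELS[resolved]}, needs verification"
        )
    group.group_fac_type = resolved
    return resolved


def _majority_type(members: Sequence[NormalizedRecord]) -> FacilityType:
    counts: dict[FacilityType, int] = {}
    for m in members:
        counts[m.fac_type_std] = counts.get(m.fac_type_std, 0) + 1
    best = max(counts.values())
    tied = [t for t, c in counts.items() if c == best]
    # tie -> higher ladder tier; off-ladder types rank below the ladder
    return max(tied, key=lambda t: TYPE_LADDER.get(t, 0))


def assign_group_gps(
    groups: Sequence[MatchGroup], hierarchy: SourceHierarchy = DEFAULT_HIERARCHY
) -> None:
    for g in groups:
        chosen = assign_gps(g, hierarchy)
        if chosen is not None:
            g.group_latitude = chosen["latitude"]
            g.group_longitude = chosen["longitude"]
            g.group_gps_source = chosen["gps_source"]
        g.n_gps = count_distinct_gps(g)


def flag_geo_conflicts(
    groups: Sequence[MatchGroup], constants: GeoConstants = DEFAULT_GEO
) -> None:
    """Flag groups whose member coordinates imply > 1 km separation."""
    for g in groups:
        dist = max_pairwise_distance(g, constants)
        if dist is not None and dist > constants.review_distance_km:
            g.add_note(
                f"GPS discordance: member coordinates up to {dist:.2f} km apart "
                f"(review threshold {constants.review_distance_km:g} km)"
            )


def flag_same_name_conflicts(
    groups: Sequence[MatchGroup], constants: GeoConstants = DEFAULT_GEO
) -> None:
    """Flag the two common same-name ambiguity patterns.

    (a) distinct groups sharing a match name and region with *different*
    types may be one facility recorded before and after an upgrade — both
    are flagged, unless their assigned coordinates sit more than the review
    distance apart, in which case they are noted as GPS-confirmed distinct
    facilities; (b) distinct groups sharing name, type and region but listed
    under different departments/districts stay separate and are flagged.
    """
    by_name_region: dict[tuple[str, str], list[MatchGroup]] = {}
    for g in groups:
        by_name_region.setdefault((g.match_name, g.region_std), []).append(g)
    for (name, _), bucket in by_name_region.items():
        if len(bucket) < 2 or not name:
            continue
        for a, b in itertools.combinations(bucket, 2):
            if a.group_fac_type is not b.group_fac_type:
                gps_known = (
                    a.group_latitude is not None and b.group_latitude is not None
                )
                far_apart = gps_known and haversine_km(
                    a.group_latitude, a.group_longitude,
                    b.group_latitude, b.group_longitude, constants,
                ) > constants.review_distance_km
                if far_apart:
                    note = (
                        f"same name, different type as {{other}} "
                        "(GPS-separated; treated as distinct facilities)"
                    )
                else:
                    note = (
                        f"same name, different type as {{other}}: possibly one "
                        "facility recorded before/after a type upgrade, needs "
                        "verification"
                    )
                a.add_note(note.format(other=b.match_id))
                b.add_note(note.format(other=a.match_id))
            else:
                admin_a = {(m.department_orig, m.district_orig) for m in a.members}
                admin_b = {(m.department_orig, m.district_orig) for m in b.members}
                if admin_a != admin_b:
                    note = (
                        "same name and type as {other} in different "
                        "departments/districts; treated as distinct facilities, "
                        "needs verification"
                    )
                else:
                    note = (
                        "same name and type as {other}; needs verification"
                    )
                a.add_note(note.format(other=b.match_id))
                b.add_note(note.format(other=a.match_id))


def near_threshold_report(
    groups: Sequence[MatchGroup],
    cfg: MatchingConfig = MatchingConfig(),
) -> pd.DataFrame:
    """List group pairs with similar but 'different enough' names.

    For each within-region pair of groups, the minimum Jaro-Winkler
    distance between member match names falling in
    ``(threshold, threshold + review_margin]`` produces a review row; these
    are candidate missed matches for manual verification.
    """
    rows = []
    by_region: dict[str, list[MatchGroup]] = {}
    for g in groups:
        by_region.setdefault(g.region_std, []).append(g)
    hi = cfg.threshold + cfg.review_margin
    for region, bucket in by_region.items():
        for a, b in itertools.combinations(bucket, 2):
            best = min(
                jaro_winkler_distance(ma.match_name, mb.match_name, cfg)
                for ma in a.members
                for mb in b.members
            )
            if cfg.threshold < best <= hi:
                rows.append(
                    {
                        "region": region,
                        "group_a": a.match_id,
                        "group_b": b.match_id,
                        "name_a": a.match_name,
                        "name_b": b.match_name,
                        "jw_distance": round(best, 6),
                    }
                )
    return pd.DataFrame(
        rows, columns=["region", "group_a", "group_b", "name_a", "name_b", "jw_distance"]
    )


def consolidate_groups(
    groups: Sequence[MatchGroup],
    hierarchy: SourceHierarchy = DEFAULT_HIERARCHY,
    constants: GeoConstants = DEFAULT_GEO,
) -> None:
    """Run every resolution/flagging pass in order (idempotent)."""
    for g in groups:
        resolve_fac_type(g)
        for m in g.members:
            for flag in m.flags:
                g.add_note(f"{m.ref}: {flag}")
    assign_group_gps(groups, hierarchy)
    flag_geo_conflicts(groups, constants)
    flag_same_name_conflicts(groups, constants)


def build_cfl(groups: Sequence[MatchGroup]) -> pd.DataFrame:
    """One output row per unique facility, in the published column order.

    Rows typed ``autre``/``unknown`` are carried in the file but excluded
    from headline counts by the reporting module.
    """
    rows = []
    for g in groups:
        rows.append(
            {
                "region": g.region_std,
                "match_id": g.match_id,
                "match_name": g.match_name,
                "group_fac_type": CFL_TYPE_LABELS[g.group_fac_type],
                "group_latitude": g.group_latitude,
                "group_longitude": g.group_longitude,
                "group_gps_source": g.group_gps_source,
                "n_gps": g.n_gps,
                "n_source": g.n_source,
                "source_list": "; ".join(g.source_list),
                "data_flagged": g.data_flagged,
                "data_notes": "; ".join(g.data_notes),
            }
        )
    return pd.DataFrame(rows, columns=CFL_COLUMNS)


def build_full_list(groups: Sequence[MatchGroup]) -> pd.DataFrame:
    """Per-record list linkable to the CFL through ``match_id``."""
    rows = []
    for g in groups:
        for m in g.members:
            rows.append(
                {
                    "match_id": g.match_id,
                    "region": g.region_std,
                    "source_id": m.source_id,
                    "row_index": m.row_index,
                    "fac_name_orig": m.fac_name_orig,
                    "match_name": m.match_name,
                    "fac_type_orig": m.fac_type_orig,
                    "fac_type_std": CFL_TYPE_LABELS[m.fac_type_std],
                    "ownership_orig": m.ownership_orig,
                    "region_orig": m.region_orig,
                    "department_orig": m.department_orig,
                    "district_orig": m.district_orig,
                    "latitude": None if m.latitude is None else round(m.latitude, 5),
                    "longitude": None if m.longitude is None else round(m.longitude, 5),
                    "source_year": m.source_year,
                }
            )
    return pd.DataFrame(rows)
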