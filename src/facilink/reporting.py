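"""Validation summaries over the consolidated list.

Covers facility counts and GPS coverage by region and type, prevalence of
multi-type matches, and side-by-side comparison against previously
published national count tables.  Headline counts include only the four
main facility tiers; ``autre``/``unknown`` rows are excluded.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

__all__ = [
    "HEADLINE_LABELS",
    "REFERENCE_COUNTS",
    "coverage_summary",
    "multitype_summary",
    "compare_counts",
]

HEADLINE_LABELS = (
    "hopital",
    "centre de sante",
    "poste de sante",
    "case de sante",
)

COUNT_COLUMNS = ["all", "hopital", "centre_de_sante", "poste_de_sante", "case_de_sante"]

# National facility totals as reported in previously published Senegal
# facility lists: the Service Provision Assessment (SPA) survey facility
# frames and the CSSDOS Health Map report.  Transcribed from those published
# reports for regression/comparison display only.
REFERENCE_COUNTS = pd.DataFrame(
    [
        ("SPA 2012-2013 facility frame", 3084, 86, 242, 1250, 1506),
        ("SPA 2017 facility frame", 3764, 68, 148, 1853, 1695),
        ("SPA 2019 facility frame", 3967, 80, 153, 1859, 1875),
        ("Health Map 2021 (public only)", 3964, 40, 110, 1531, 2283),
    ],
    columns=["list_name"] + COUNT_COLUMNS,
).set_index("list_name")


def _round_half_up(value: float, decimals: int = 1) -> float:
    scale = 10 ** decimals
    return math.floor(value * scale + 0.5) / scale


def _headline(cfl: pd.DataFrame) -> pd.DataFrame:
    return cfl[cfl["group_fac_type"].isin(HEADLINE_LABELS)]


def coverage_summary(cfl: pd.DataFrame) -> pd.DataFrame:
    """Facility counts and GPS coverage by region × type.

    Returns one row per (region, type) cell present in the list, plus
    per-region "all" rows and national rows, with
    ``pct_with_gps = 100·n_with_gps/n_facilities`` rounded half-up to one
    decimal.  Empty cells are omitted.
    """
    frame = _headline(cfl).copy()
    if frame.empty:
        return pd.DataFrame(
            columns=["region", "fac_type", "n_facilities", "n_with_gps", "pct_with_gps"]
        )
    frame["has_gps"] = frame["group_latitude"].notna() & frame["group_longitude"].notna()
    rows = []

    def add(region: str, fac_type: str, sub: pd.DataFrame) -> None:
        n = len(sub)
        if n == 0:
            return
        with_gps = int(sub["has_gps"].sum())
        rows.append(
            {
                "region": region,
                "fac_type": fac_type,
                "n_facilities": n,
                "n_with_gps": with_gps,
                "pct_with_gps": _round_half_up(100.0 * with_gps / n),
            }
        )

    for region, by_region in frame.groupby("region", sort=True):
        for fac_type in HEADLINE_LABELS:
            add(region, fac_type, by_region[by_region["group_fac_type"] == fac_type])
        add(region, "all", by_region)
    for fac_type in HEADLINE_LABELS:
        add("national", fac_type, frame[frame["group_fac_type"] == fac_type])
    add("national", "all", frame)
    return pd.DataFrame(rows)


def multitype_summary(full_list: pd.DataFrame, cfl: pd.DataFrame) -> dict:
    """Prevalence of matches whose sources disagreed on facility type.

    A group is multi-type when its member records carry at least two
    distinct standardized types (unknown ignored).  ``pct_of_cfl`` uses the
    headline facility count as denominator; ``n_resolved`` counts
    multi-type groups whose final type carries a recency-resolution note.
    """
    known = full_list[full_list["fac_type_std"] != "unknown"]
    n_types = known.groupby("match_id")["fac_type_std"].nunique()
    multitype_ids = set(n_types[n_types >= 2].index)
    headline = _headline(cfl)
    n_cfl = len(headline)
    multitype_rows = cfl[cfl["match_id"].isin(multitype_ids)]
    resolved = multitype_rows["data_notes"].str.contains(
        "resolved to", regex=False
    )
    per_type = (
        multitype_rows[multitype_rows["group_fac_type"].isin(HEADLINE_LABELS)]
        .groupby("group_fac_type")["match_id"]
        .count()
        .to_dict()
    )
    n_multi = len(multitype_rows)
    return {
        "n_multitype": n_multi,
        "pct_of_cfl": _round_half_up(100.0 * n_multi / n_cfl) if n_cfl else None,
        "per_type": per_type,
        "n_resolved": int(resolved.sum()),
    }


def compare_counts(cfl: pd.DataFrame, reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """CFL-minus-reference facility-count differences, by type.

    ``reference`` rows are list names and columns are
    ``all/hopital/centre_de_sante/poste_de_sante/case_de_sante``; defaults
    to the packaged published-report table.  The output shows the CFL
    counts, each reference row, and the per-cell differences.
    """
    if reference is None:
        reference = REFERENCE_COUNTS
    missing = [c for c in COUNT_COLUMNS if c not in reference.columns]
    if missing:
        raise ValueError(f"reference table is missing columns: {missing}")
    headline = _headline(cfl)
    label_to_col = {
        "hopital": "hopital",
        "centre de sante": "centre_de_sante",
        "poste de sante": "poste_de_sante",
        "case de sante": "case_de_sante",
    }
    cfl_counts = {"all": len(headline)}
    for label, col in label_to_col.items():
        cfl_counts[col] = int((headline["group_fac_type"] == label).sum())
    rows = [{"list_name": "Consolidated facility list", "kind": "count", **cfl_counts}]
    for name, ref_row in reference.iterrows():
        rows.append({"list_name": name, "kind": "count",
                     **{c: ref_row[c] for c in COUNT_COLUMNS}})
        rows.append(
            {
                "list_name": name,
                "kind": "difference",
                **{c: cfl_counts[c] - ref_row[c] for c in COUNT_COLUMNS},
            }
        )
    return pd.DataFrame(rows, columns=["list_name", "kind"] + COUNT_COLUMNS)
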