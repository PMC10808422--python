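"""Reading and standardizing per-source facility lists.

Each input is a delimited UTF-8 table with a header row; a
:class:`SourceSpec` maps its headers onto the canonical attributes
(name, region, and optionally type, ownership, department, district,
latitude, longitude).  Loading standardizes the four core attributes,
infers a facility type from the name string when the source reports none,
canonicalizes the region against Senegal's 14 first-level administrative
units, and removes exact within-source duplicates.
"""

from __future__ import annotations

import enum
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .normalize import (
    DEFAULT_LEXICON,
    NormalizationLexicon,
    normalize_name,
    strip_accents,
)

__all__ = [
    "FacilityType",
    "SourceSpec",
    "SourceRecord",
    "NormalizedRecord",
    "SENEGAL_REGIONS",
    "canonical_region",
    "infer_type_from_name",
    "load_source",
    "normalize_records",
    "dedupe_within_source",
    "pool_sources",
]

logger = logging.getLogger(__name__)


class FacilityType(str, enum.Enum):
    """Main facility tiers of the Senegalese formal health system.

    ``autre`` covers clinics/"doctors"/unspecified facilities; ``autre`` and
    ``unknown`` rows are carried through the pipeline but excluded from
    headline facility counts.
    """

    HOPITAL = "hopital"
    CENTRE_DE_SANTE = "centre_de_sante"
    POSTE_DE_SANTE = "poste_de_sante"
    CASE_DE_SANTE = "case_de_sante"
    AUTRE = "autre"
    UNKNOWN = "unknown"


# Position on the upgrade ladder (health hut -> post -> center -> hospital);
# autre/unknown sit off-ladder.
TYPE_LADDER: dict[FacilityType, int] = {
    FacilityType.CASE_DE_SANTE: 1,
    FacilityType.POSTE_DE_SANTE: 2,
    FacilityType.CENTRE_DE_SANTE: 3,
    FacilityType.HOPITAL: 4,
}

SENEGAL_REGIONS: tuple[str, ...] = (
    "Dakar",
    "Diourbel",
    "Fatick",
    "Kaffrine",
    "Kaolack",
    "Kédougou",
    "Kolda",
    "Louga",
    "Matam",
    "Saint-Louis",
    "Sédhiou",
    "Tambacounda",
    "Thiès",
    "Ziguinchor",
)

_REGION_LOOKUP = {
    strip_accents(r).lower().replace("-", " "): r for r in SENEGAL_REGIONS
}


def canonical_region(raw: str) -> tuple[str, bool]:
    """Case/accent-insensitive match against the 14 regions.

    Returns ``(canonical_name, True)`` on a hit, otherwise the verbatim
    input with ``False`` so the caller can flag it (blocking correctness
    depends on region identity, so unmatched regions are kept, not guessed).
    """
    key = strip_accents(raw).strip().lower().replace("-", " ")
    key = " ".join(key.split())
    hit = _REGION_LOOKUP.get(key)
    if hit is not None:
        return hit, True
    return raw.strip(), False


# Name-string vocabulary for inferring a type when the source reports none.
# Ordered: phrases before abbreviations, and checked in this priority.
_TYPE_VOCABULARY: tuple[tuple[str, FacilityType], ...] = (
    ("centre hospitalier universitaire", FacilityType.HOPITAL),
    ("centre hospitalier regional", FacilityType.HOPITAL),
    ("centre hospitalier", FacilityType.HOPITAL),
    ("case de sante", FacilityType.CASE_DE_SANTE),
    ("centre de sante", FacilityType.CENTRE_DE_SANTE),
    ("poste de sante", FacilityType.POSTE_DE_SANTE),
    ("health hut", FacilityType.CASE_DE_SANTE),
    ("health centre", FacilityType.CENTRE_DE_SANTE),
    ("health center", FacilityType.CENTRE_DE_SANTE),
    ("health post", FacilityType.POSTE_DE_SANTE),
    ("hopital", FacilityType.HOPITAL),
    ("hospital", FacilityType.HOPITAL),
    ("clinique", FacilityType.AUTRE),
    ("cabinet", FacilityType.AUTRE),
    ("docteur", FacilityType.AUTRE),
    ("doctors", FacilityType.AUTRE),
    ("chr", FacilityType.HOPITAL),
    ("chu", FacilityType.HOPITAL),
    ("eps", FacilityType.HOPITAL),
    ("cds", FacilityType.CASE_DE_SANTE),
    ("ps", FacilityType.POSTE_DE_SANTE),
    ("cs", FacilityType.CENTRE_DE_SANTE),
)

# Labels used when a source's type column is parsed.
_TYPE_LABEL_LOOKUP: dict[str, FacilityType] = {
    "hopital": FacilityType.HOPITAL,
    "hospital": FacilityType.HOPITAL,
    "centre hospitalier": FacilityType.HOPITAL,
    "eps": FacilityType.HOPITAL,
    "centre de sante": FacilityType.CENTRE_DE_SANTE,
    "health center": FacilityType.CENTRE_DE_SANTE,
    "health centre": FacilityType.CENTRE_DE_SANTE,
    "cs": FacilityType.CENTRE_DE_SANTE,
    "poste de sante": FacilityType.POSTE_DE_SANTE,
    "health post": FacilityType.POSTE_DE_SANTE,
    "ps": FacilityType.POSTE_DE_SANTE,
    "case de sante": FacilityType.CASE_DE_SANTE,
    "health hut": FacilityType.CASE_DE_SANTE,
    "cds": FacilityType.CASE_DE_SANTE,
    "clinique": FacilityType.AUTRE,
    "clinic": FacilityType.AUTRE,
    "cabinet": FacilityType.AUTRE,
    "autre": FacilityType.AUTRE,
    "other": FacilityType.AUTRE,
}


def infer_type_from_name(fac_name_orig: str) -> FacilityType:
    """Identify the facility type from the name string.

    >>> infer_type_from_name("PS Nemataba")
    <FacilityType.POSTE_DE_SANTE: 'poste_de_sante'>
    """
    text = strip_accents(fac_name_orig).lower()
    text = " ".join("".join(c if c.isalnum() else " " for c in text).split())
    tokens = set(text.split())
    for phrase, fac_type in _TYPE_VOCABULARY:
        if " " in phrase:
            if f" {phrase} " in f" {text} ":
                return fac_type
        elif phrase in tokens:
            return fac_type
    return FacilityType.UNKNOWN


def parse_type_label(label: str | None) -> FacilityType:
    """Map a source-reported type label onto the standard enumeration."""
    if label is None or not str(label).strip():
        return FacilityType.UNKNOWN
    key = strip_accents(str(label)).lower().strip()
    key = " ".join(key.replace("_", " ").split())
    hit = _TYPE_LABEL_LOOKUP.get(key)
    if hit is not None:
        return hit
    inferred = infer_type_from_name(str(label))
    return inferred if inferred is not FacilityType.UNKNOWN else FacilityType.AUTRE


@dataclass(frozen=True)
class SourceSpec:
    """How to read one source list.

    ``column_map`` maps canonical attribute names (``name``, ``region``,
    ``type``, ``ownership``, ``department``, ``district``, ``latitude``,
    ``longitude``) to the file's column headers; at least ``name`` and
    ``region`` are required.  ``hierarchy_tier`` is only informative here —
    GPS preference is configured in :mod:`facilink.gps`.
    """

    source_id: str
    column_map: Mapping[str, str]
    source_year: int | None = None
    has_gps: bool = True
    delimiter: str = ","

    def __post_init__(self) -> None:
        missing = {"name", "region"} - set(self.column_map)
        if missing:
            raise ValueError(
                f"source {self.source_id!r}: column_map must map {sorted(missing)}"
            )


@dataclass(frozen=True)
class SourceRecord:
    """One facility row exactly as reported by one source."""

    source_id: str
    row_index: int
    fac_name_orig: str
    region_orig: str
    fac_type_orig: str | None = None
    ownership_orig: str | None = None
    department_orig: str | None = None
    district_orig: str | None = None
    latitude: float | None = None
    longitude: float | None = None

    @property
    def ref(self) -> str:
        """Globally unique record reference, ``source_id:row_index``."""
        return f"{self.source_id}:{self.row_index}"

    @property
    def has_coords(self) -> bool:
        return self.latitude is not None and self.longitude is not None


@dataclass(frozen=True)
class NormalizedRecord(SourceRecord):
    """A source record plus standardized region, type and match name."""

    region_std: str = ""
    region_canonical: bool = True
    fac_type_std: FacilityType = FacilityType.UNKNOWN
    match_name: str = ""
    source_year: int | None = None
    source_order: int = 0
    flags: tuple[str, ...] = field(default=())


def _parse_coordinate(value, low: float, high: float) -> tuple[float | None, bool]:
    """Parse one coordinate; (None, True) flags a malformed/out-of-range value."""
    if value is None:
        return None, False
    text = str(value).strip()
    if not text or text.lower() in {"nan", "na", "none"}:
        return None, False
    try:
        parsed = float(text)
    except ValueError:
        return None, True
    if math.isnan(parsed):
        return None, False
    if not (low <= parsed <= high):
        return None, True
    return parsed, False


def load_source(
    source: "str | os.PathLike[str] | pd.DataFrame", spec: SourceSpec
) -> list[SourceRecord]:
    """Read one source list into :class:`SourceRecord`\\ s.

    ``source`` may be a CSV path or an already-loaded DataFrame.  Rows with
    an empty facility name are rejected (logged); malformed or out-of-range
    coordinates are set to missing with a warning, never dropped.
    """
    if isinstance(source, pd.DataFrame):
        frame = source
    else:
        frame = pd.read_csv(source, sep=spec.delimiter, dtype=str, encoding="utf-8")
    cmap = dict(spec.column_map)
    missing_cols = [col for col in cmap.values() if col not in frame.columns]
    if missing_cols:
        raise ValueError(
            f"source {spec.source_id!r}: columns {missing_cols} not found in file "
            f"(available: {list(frame.columns)})"
        )

    def cell(row, attr) -> str | None:
        col = cmap.get(attr)
        if col is None:
            return None
        value = row[col]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        text = str(value).strip()
        return text or None

    records: list[SourceRecord] = []
    n_rejected = 0
    n_coord_warnings = 0
    for pos, (_, row) in enumerate(frame.iterrows()):
        name = cell(row, "name")
        region = cell(row, "region")
        if not name or not region:
            n_rejected += 1
            logger.info(
                "%s: rejected row %d (empty %s)",
                spec.source_id, pos, "name" if not name else "region",
            )
            continue
        lat, bad_lat = _parse_coordinate(cell(row, "latitude"), -90.0, 90.0)
        lon, bad_lon = _parse_coordinate(cell(row, "longitude"), -180.0, 180.0)
        if bad_lat or bad_lon:
            n_coord_warnings += 1
            logger.warning(
                "%s row %d: malformed coordinate set to missing", spec.source_id, pos
            )
        if (lat is None) != (lon is None):  # half a coordinate is no coordinate
            lat = lon = None
        records.append(
            SourceRecord(
                source_id=spec.source_id,
                row_index=pos,
                fac_name_orig=name,
                region_orig=region,
                fac_type_orig=cell(row, "type"),
                ownership_orig=cell(row, "ownership"),
                department_orig=cell(row, "department"),
                district_orig=cell(row, "district"),
                latitude=lat,
                longitude=lon,
            )
        )
    logger.info(
        "%s: loaded %d rows (%d rejected, %d coordinate warnings)",
        spec.source_id, len(records), n_rejected, n_coord_warnings,
    )
    return records


def normalize_records(
    records: Iterable[SourceRecord],
    spec: SourceSpec,
    lexicon: NormalizationLexicon = DEFAULT_LEXICON,
    source_order: int = 0,
) -> list[NormalizedRecord]:
    """Attach canonical region, standardized type and match name."""
    out: list[NormalizedRecord] = []
    for rec in records:
        region_std, canonical = canonical_region(rec.region_orig)
        if rec.fac_type_orig:
            fac_type = parse_type_label(rec.fac_type_orig)
        else:
            fac_type = infer_type_from_name(rec.fac_name_orig)
        match_name = normalize_name(rec.fac_name_orig, lexicon)
        flags: list[str] = []
        if not canonical:
            flags.append("region not in canonical list")
        if not match_name:
            flags.append("name normalizes to empty string")
        out.append(
            NormalizedRecord(
                source_id=rec.source_id,
                row_index=rec.row_index,
                fac_name_orig=rec.fac_name_orig,
                region_orig=rec.region_orig,
                fac_type_orig=rec.fac_type_orig,
                ownership_orig=rec.ownership_orig,
                department_orig=rec.department_orig,
                district_orig=rec.district_orig,
                latitude=rec.latitude,
                longitude=rec.longitude,
                region_std=region_std,
                region_canonical=canonical,
                fac_type_std=fac_type,
                match_name=match_name,
                source_year=spec.source_year,
                source_order=source_order,
                flags=tuple(flags),
            )
        )
    return out


def dedupe_within_source(records: Sequence[NormalizedRecord]) -> list[NormalizedRecord]:
    """Collapse exact within-source duplicates.

    The duplicate key is (match name, canonical region, standardized type);
    among duplicates the record with coordinates wins, ties broken by file
    order, so the result is invariant to input ordering.
    """
    sources = {r.source_id for r in records}
    if len(sources) > 1:
        raise ValueError(f"records span multiple sources: {sorted(sources)}")
    best: dict[tuple, NormalizedRecord] = {}
    order: list[tuple] = []
    for rec in sorted(records, key=lambda r: r.row_index):
        key = (rec.match_name, rec.region_std, rec.fac_type_std)
        incumbent = best.get(key)
        if incumbent is None:
            best[key] = rec
            order.append(key)
        elif rec.has_coords and not incumbent.has_coords:
            best[key] = rec
    removed = len(records) - len(best)
    if removed:
        logger.info(
            "%s: removed %d within-source duplicates", next(iter(sources), "?"), removed
        )
    return [best[key] for key in order]


def pool_sources(
    per_source: Sequence[Sequence[NormalizedRecord]],
) -> list[NormalizedRecord]:
    """Concatenate per-source (already deduped) record lists.

    Record identity is the (source_id, row_index) pair; colliding source ids
    across lists are a configuration error.
    """
    seen_sources: set[str] = set()
    pooled: list[NormalizedRecord] = []
    for records in per_source:
        sources = {r.source_id for r in records}
        clash = sources & seen_sources
        if clash:
            raise ValueError(f"duplicate source_id across inputs: {sorted(clash)}")
        seen_sources |= sources
        pooled.extend(records)
    refs = {r.ref for r in pooled}
    if len(refs) != len(pooled):
        raise ValueError("record references are not globally unique")
    logger.info("pooled %d facility observations from %d sources",
                len(pooled), len(per_source))
    return pooled
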