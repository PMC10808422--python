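"""Run-configuration files.

A run is described by one YAML file listing the sources (path, year,
column map), plus optional ``matching``, ``geo``, ``hierarchy`` and
``lexicon`` blocks overriding the defaults::

    sources:
      - source_id: cous
        path: cous.csv
        year: 2021
        has_gps: true
        columns: {name: nom, region: region, latitude: lat, longitude: lon}
    matching: {threshold: 0.2}
    geo: {review_distance_km: 1.0}
    hierarchy: [[cous], [spa2016, spa2015, spa2014], [spa2017]]
    lexicon:
      extra_type_tokens: [dispensaire prive]
      acronyms: {st: saint}

Relative source paths resolve against the configuration file's directory.
"""

from __future__ import annotations

import os
from pathlib import Path

import yaml

from .geo import GeoConstants
from .gps import SourceHierarchy
from .ingest import SourceSpec
from .matching import MatchingConfig
from .normalize import DEFAULT_LEXICON, NormalizationLexicon

__all__ = ["load_run_config"]


def _build_lexicon(block: dict | None) -> NormalizationLexicon:
    if not block:
        return DEFAULT_LEXICON
    tokens = tuple(block.get("type_tokens", DEFAULT_LEXICON.type_tokens))
    tokens += tuple(block.get("extra_type_tokens", ()))
    acronyms = dict(DEFAULT_LEXICON.acronym_map)
    acronyms.update(block.get("acronyms", {}))
    return NormalizationLexicon(
        type_tokens=tokens,
        acronym_map=acronyms,
        roman_numeral_limit=block.get(
            "roman_numeral_limit", DEFAULT_LEXICON.roman_numeral_limit
        ),
    )


def load_run_config(path: "str | os.PathLike[str]"):
    """Parse a YAML run configuration into a ready :class:`FacilityLinkage`."""
    from .model import FacilityLinkage

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not raw or "sources" not in raw or not raw["sources"]:
        raise ValueError(f"{path}: configuration must list at least one source")
    sources = []
    for entry in raw["sources"]:
        spec = SourceSpec(
            source_id=entry["source_id"],
            column_map=entry["columns"],
            source_year=entry.get("year"),
            has_gps=entry.get("has_gps", True),
            delimiter=entry.get("delimiter", ","),
        )
        table = Path(entry["path"])
        if not table.is_absolute():
            table = path.parent / table
        sources.append((str(table), spec))
    matching = MatchingConfig(**raw.get("matching", {}))
    geo = GeoConstants(**raw.get("geo", {}))
    hierarchy = (
        SourceHierarchy(tuple(tuple(tier) for tier in raw["hierarchy"]))
        if raw.get("hierarchy")
        else None
    )
    lexicon = _build_lexicon(raw.get("lexicon"))
    return FacilityLinkage(
        sources, matching=matching, geo=geo, hierarchy=hierarchy, lexicon=lexicon
    )
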