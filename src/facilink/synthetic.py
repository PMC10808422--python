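"""Ground-truthed synthetic multi-source facility registries.

The generator builds a universe of facilities with plausible West-African
toponym names, a region, a true coordinate pair, a type drawn from shares
resembling the national mix (≈2% hospitals, 5% health centers, 50% health
posts, 43% health huts), and optional type-upgrade events.  It then emits K
overlapping source lists that exhibit the documented error modes of real
facility lists:

* partial coverage — each source samples facilities independently;
* name variants — type prefixes/suffixes ("PS X" / "X Poste de Santé"),
  accent stripping, acronym contraction ("Saint" → "St."), roman-numeral
  toggling ("2" → "II"), and character-level typos;
* stale types — sources dated before a facility's upgrade year report the
  pre-upgrade (one tier lower) type;
* per-source GPS missingness and metre-scale coordinate jitter;
* within-source duplicate rows.

Every emitted record maps to its true facility in a ground-truth table, so
entity-resolution quality is measurable without any download.  A fixed seed
fully determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gps import SourceHierarchy
from .ingest import SENEGAL_REGIONS, FacilityType, SourceSpec
from .matching import MatchingConfig, jaro_winkler_distance
from .normalize import normalize_name, strip_accents

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_universe",
           "emit_source_lists", "simulate", "write_dataset"]

# Generic Senegalese toponym fragments; composed names, not real facilities.
_NAME_PREFIXES = (
    "Keur", "Médina", "Ndiaye", "Touba", "Darou", "Sam", "Thiaroye", "Santhiaba",
    "Ngor", "Yoff", "Pikine", "Guédiawaye", "Diamaguène", "Mbao", "Sicap",
    "Grand", "Petit", "Sainte", "Saint", "Ndame", "Missirah", "Sare", "Vélingara",
    "Kothiary", "Diender", "Bambilor", "Sangalkam", "Niague", "Malika", "Yeumbeul",
    "Ouakam", "Hann", "Rufisque", "Bargny", "Sébikotane", "Pout", "Khombole",
    "Ndiaganiao", "Fissel", "Tattaguine", "Niakhar", "Ndoffane", "Gandiaye",
    "Nioro", "Koungheul", "Dianke", "Goudiry", "Kidira", "Bakel", "Kanel",
    "Ranérou", "Ogo", "Thilogne", "Agnam", "Dabia", "Orkadiéré", "Waoundé",
    "Semme", "Bokidiawé", "Nabadji", "Dodel", "Gamadji", "Guédé", "Méry",
    "Aéré", "Cascas", "Boké", "Démette", "Fanaye", "Galoya", "Mboumba",
    "Madina", "Pété", "Walaldé", "Taredji", "Niandane", "Guia", "Donaye",
)
_NAME_SUFFIXES = (
    "Massar", "Fall", "Diop", "Ndao", "Sarr", "Gueye", "Sy", "Ba", "Kane",
    "Niang", "Mbaye", "Fada", "Ndofane", "Coly", "Badji", "Sané", "Mané",
    "Dramé", "Cissé", "Diallo", "Sow", "Barry", "Camara", "Tall", "Seck",
    "Wade", "Faye", "Dione", "Ngom", "Thiam", "Bathily", "Konaté", "Sakho",
    "Soumaré", "Timéra", "Wagué", "Diawara", "Sylla", "Baldé", "Kandé",
    "Sabaly", "Mballo", "Diédhiou", "Goudiaby", "Sonko", "Sagna", "Manga",
    "Tendeng", "Bodian", "Niassy", "Diatta", "Himbane", "Bassène", "Preira",
)

_TYPE_PREFIX_FORMS: dict[FacilityType, tuple[str, ...]] = {
    FacilityType.POSTE_DE_SANTE: ("PS {name}", "{name} Poste de Santé", "Poste de Santé {name}"),
    FacilityType.CENTRE_DE_SANTE: ("CS {name}", "Centre de Santé {name}"),
    FacilityType.CASE_DE_SANTE: ("Case de Santé {name}", "CDS {name}"),
    FacilityType.HOPITAL: ("Hôpital {name}", "Hôpital de {name}"),
    FacilityType.AUTRE: ("Clinique {name}",),
}

_TYPE_LABELS: dict[FacilityType, str] = {
    FacilityType.HOPITAL: "Hôpital",
    FacilityType.CENTRE_DE_SANTE: "Centre de Santé",
    FacilityType.POSTE_DE_SANTE: "Poste de Santé",
    FacilityType.CASE_DE_SANTE: "Case de Santé",
    FacilityType.AUTRE: "Clinique",
}

_LADDER_DOWN: dict[FacilityType, FacilityType] = {
    FacilityType.POSTE_DE_SANTE: FacilityType.CASE_DE_SANTE,
    FacilityType.CENTRE_DE_SANTE: FacilityType.POSTE_DE_SANTE,
    FacilityType.HOPITAL: FacilityType.CENTRE_DE_SANTE,
}

_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}

_METRES_PER_DEGREE = 111_320.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic registry run.

    Defaults are the package's reference conditions: 500 facilities across
    the 14 regions, five overlapping sources with 70% inclusion and 80% GPS
    reporting each, 100 m coordinate jitter, mild name noise, 10% upgrade
    probability, and 2% within-source duplication.
    """

    seed: int = 1
    n_facilities: int = 500
    regions: tuple[str, ...] = SENEGAL_REGIONS
    type_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "hopital": 0.02,
            "centre_de_sante": 0.05,
            "poste_de_sante": 0.50,
            "case_de_sante": 0.43,
        }
    )
    n_sources: int = 5
    inclusion_prob: float = 0.7
    gps_prob: float = 0.8
    gps_jitter_sd_m: float = 100.0
    p_typo: float = 0.05
    p_accent_strip: float = 0.3
    p_type_prefix: float = 0.6
    p_acronym_contract: float = 0.5
    p_roman_toggle: float = 0.3
    p_numbered_name: float = 0.15
    upgrade_prob: float = 0.10
    within_source_dup_prob: float = 0.02
    # minimum pairwise Jaro-Winkler distance between canonical names within a
    # region (kept above the 0.2 matching threshold so truth is identifiable);
    # 0 disables the check
    min_name_separation: float = 0.22
    first_source_year: int = 2014
    year_step: int = 2

    def __post_init__(self) -> None:
        probs = (
            self.inclusion_prob, self.gps_prob, self.p_typo, self.p_accent_strip,
            self.p_type_prefix, self.p_acronym_contract, self.p_roman_toggle,
            self.p_numbered_name, self.upgrade_prob, self.within_source_dup_prob,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.type_shares.values()) - 1.0) > 1e-9:
            raise ValueError("type shares must sum to 1")

    @property
    def source_ids(self) -> list[str]:
        return [f"src{k + 1:02d}" for k in range(self.n_sources)]

    @property
    def source_years(self) -> list[int]:
        return [self.first_source_year + k * self.year_step for k in range(self.n_sources)]


@dataclass
class SyntheticDataset:
    """Everything one run emits: universe, per-source frames, specs, truth."""

    universe: pd.DataFrame
    frames: dict[str, pd.DataFrame]
    specs: list[SourceSpec]
    hierarchy: SourceHierarchy
    truth: pd.DataFrame  # columns: source_id, row_index, facility_id


def _region_boxes(regions: tuple[str, ...]) -> dict[str, tuple[float, float, float, float]]:
    """Non-overlapping per-region bounding boxes tiled over a Senegal-like
    extent (lat 12.4–16.4 N, lon 17.5–11.4 W)."""
    boxes = {}
    per_row = (len(regions) + 1) // 2
    for i, region in enumerate(regions):
        col, row = i % per_row, i // per_row
        lon0 = -17.5 + col * (6.1 / per_row)
        lat0 = 12.4 + row * 2.0
        boxes[region] = (lat0, lat0 + 1.8, lon0, lon0 + 6.1 / per_row - 0.05)
    return boxes


def _draw_name(rng: np.random.Generator, cfg: SyntheticConfig) -> str:
    name = f"{rng.choice(_NAME_PREFIXES)} {rng.choice(_NAME_SUFFIXES)}"
    if rng.random() < 0.25:  # occasional three-part toponym
        name = f"{name} {rng.choice(_NAME_SUFFIXES)}"
    if rng.random() < cfg.p_numbered_name:
        name = f"{name} {rng.integers(1, 4)}"
    return name


def generate_universe(cfg: SyntheticConfig) -> pd.DataFrame:
    """Build the ground-truth facility universe.

    Returns one row per facility: ``facility_id, name, region, fac_type,
    latitude, longitude, original_type, upgrade_year``.  Canonical names are
    unique (and, when ``min_name_separation`` > 0, mutually separated in
    Jaro-Winkler distance) within each region.
    """
    rng = np.random.default_rng(cfg.seed)
    boxes = _region_boxes(cfg.regions)
    types = list(cfg.type_shares)
    shares = np.array([cfg.type_shares[t] for t in types])
    jw_cfg = MatchingConfig()
    years = cfg.source_years
    taken: dict[str, list[str]] = {r: [] for r in cfg.regions}
    rows = []
    for fid in range(cfg.n_facilities):
        region = str(rng.choice(cfg.regions))
        fac_type = FacilityType(types[int(rng.choice(len(types), p=shares))])
        norm_names = taken[region]
        for _ in range(2000):
            name = _draw_name(rng, cfg)
            norm = normalize_name(name)
            if norm in norm_names:
                continue
            if cfg.min_name_separation > 0 and any(
                jaro_winkler_distance(norm, other, jw_cfg) <= cfg.min_name_separation
                for other in norm_names
            ):
                continue
            break
        else:  # pragma: no cover - name pool exhausted
            raise RuntimeError(f"could not draw a separable name in region {region}")
        norm_names.append(norm)
        lat0, lat1, lon0, lon1 = boxes[region]
        lat = float(rng.uniform(lat0, lat1))
        lon = float(rng.uniform(lon0, lon1))
        original = fac_type
        upgrade_year = None
        if fac_type in _LADDER_DOWN and rng.random() < cfg.upgrade_prob:
            original = _LADDER_DOWN[fac_type]
            # strictly after the first source year and no later than the last,
            # so both the old and the new type are observable
            upgrade_year = int(rng.integers(min(years) + 1, max(years) + 1))
        rows.append(
            {
                "facility_id": fid,
                "name": name,
                "region": region,
                "fac_type": fac_type.value,
                "latitude": round(lat, 6),
                "longitude": round(lon, 6),
                "original_type": original.value,
                "upgrade_year": upgrade_year,
            }
        )
    return pd.DataFrame(rows)


def _apply_typo(name: str, rng: np.random.Generator) -> str:
    positions = [i for i, ch in enumerate(name) if ch.isalpha()]
    if not positions:
        return name
    i = int(rng.choice(positions))
    chars = list(name)
    if rng.random() < 0.5 and i + 1 < len(chars) and chars[i + 1].isalpha():
        chars[i], chars[i + 1] = chars[i + 1], chars[i]  # adjacent transposition
    else:
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        repl = alphabet[int(rng.integers(len(alphabet)))]
        chars[i] = repl.upper() if chars[i].isupper() else repl
    return "".join(chars)


def _toggle_roman(name: str, rng: np.random.Generator) -> str:
    tokens = name.split()
    last = tokens[-1]
    if last.isdigit() and int(last) in _ROMAN:
        tokens[-1] = _ROMAN[int(last)]
    return " ".join(tokens)


def _render_name(
    canonical: str, reported_type: FacilityType, rng: np.random.Generator,
    cfg: SyntheticConfig,
) -> str:
    name = canonical
    if rng.random() < cfg.p_roman_toggle:
        name = _toggle_roman(name, rng)
    if "Saint" in name and rng.random() < cfg.p_acronym_contract:
        name = name.replace("Sainte", "Ste.").replace("Saint", "St.")
    if rng.random() < cfg.p_accent_strip:
        name = strip_accents(name)
    if rng.random() < cfg.p_typo:
        name = _apply_typo(name, rng)
    forms = _TYPE_PREFIX_FORMS.get(reported_type)
    if forms and rng.random() < cfg.p_type_prefix:
        name = forms[int(rng.integers(len(forms)))].format(name=name)
    return name


# Two header dialects so the column-mapping machinery is exercised.
_HEADERS_A = {
    "name": "nom", "type": "type_structure", "region": "region",
    "department": "departement", "latitude": "latitude", "longitude": "longitude",
}
_HEADERS_B = {
    "name": "fac_name", "type": "fac_type", "region": "region_name",
    "department": "department", "latitude": "lat", "longitude": "lon",
}


def emit_source_lists(universe: pd.DataFrame, cfg: SyntheticConfig) -> SyntheticDataset:
    """Emit K noisy overlapping source lists plus the ground-truth map."""
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    frames: dict[str, pd.DataFrame] = {}
    specs: list[SourceSpec] = []
    truth_rows = []
    for k, (source_id, year) in enumerate(zip(cfg.source_ids, cfg.source_years)):
        headers = _HEADERS_A if k % 2 == 0 else _HEADERS_B
        rows = []

        def emit(fac, rendered: str, reported: FacilityType, with_gps: bool) -> None:
            if with_gps:
                dlat = rng.normal(0.0, cfg.gps_jitter_sd_m) / _METRES_PER_DEGREE
                dlon = rng.normal(0.0, cfg.gps_jitter_sd_m) / (
                    _METRES_PER_DEGREE * math.cos(math.radians(fac.latitude))
                )
                lat = round(fac.latitude + dlat, 6)
                lon = round(fac.longitude + dlon, 6)
            else:
                lat = lon = None
            dept = f"{fac.region} departement {1 + fac.facility_id % 2}"
            rows.append(
                {
                    headers["name"]: rendered,
                    headers["type"]: _TYPE_LABELS[reported],
                    headers["region"]: fac.region,
                    headers["department"]: dept,
                    headers["latitude"]: lat,
                    headers["longitude"]: lon,
                }
            )
            truth_rows.append(
                {"source_id": source_id, "row_index": len(rows) - 1,
                 "facility_id": fac.facility_id}
            )

        for fac in universe.itertuples(index=False):
            if rng.random() >= cfg.inclusion_prob:
                continue
            reported = FacilityType(fac.fac_type)
            if fac.upgrade_year is not None and not pd.isna(fac.upgrade_year) \
                    and year < fac.upgrade_year:
                reported = FacilityType(fac.original_type)
            rendered = _render_name(fac.name, reported, rng, cfg)
            emit(fac, rendered, reported, rng.random() < cfg.gps_prob)
            if rng.random() < cfg.within_source_dup_prob:
                emit(fac, rendered, reported, False)  # duplicate row, GPS dropped

        frames[source_id] = pd.DataFrame(rows, columns=list(headers.values()))
        specs.append(
            SourceSpec(
                source_id=source_id,
                column_map=dict(headers),
                source_year=year,
                has_gps=cfg.gps_prob > 0,
            )
        )
    hierarchy = SourceHierarchy(tuple((sid,) for sid in cfg.source_ids))
    truth = pd.DataFrame(truth_rows, columns=["source_id", "row_index", "facility_id"])
    return SyntheticDataset(universe=universe, frames=frames, specs=specs,
                            hierarchy=hierarchy, truth=truth)


def simulate(cfg: SyntheticConfig | None = None, **overrides) -> SyntheticDataset:
    """Generate a universe and its source lists in one call."""
    if cfg is None:
        cfg = SyntheticConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    return emit_source_lists(generate_universe(cfg), cfg)


def write_dataset(dataset: SyntheticDataset, outdir: "str | Path") -> None:
    """Write source CSVs, a run-configuration file, and the truth table."""
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for source_id, frame in dataset.frames.items():
        frame.to_csv(out / f"{source_id}.csv", index=False, encoding="utf-8")
    dataset.truth.to_csv(out / "truth.csv", index=False)
    dataset.universe.to_csv(out / "universe.csv", index=False, encoding="utf-8")
    config = {
        "sources": [
            {
                "source_id": spec.source_id,
                "path": f"{spec.source_id}.csv",
                "year": spec.source_year,
                "has_gps": spec.has_gps,
                "columns": dict(spec.column_map),
            }
            for spec in dataset.specs
        ],
        "hierarchy": [list(tier) for tier in dataset.hierarchy.tiers],
    }
    with open(out / "run_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False, allow_unicode=True)
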