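"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from facilink.ingest import FacilityType, NormalizedRecord
from facilink.model import FacilityLinkage
from facilink.synthetic import SyntheticConfig, simulate


def jaro_bruteforce(s1: str, s2: str) -> float:
    """Independent brute-force Jaro: explicit matched-index bookkeeping.

    Enumerates match assignments directly from the definition (equal
    characters within the window, each position used once, leftmost-first)
    and recomputes transpositions from the two matched subsequences.
    """
    if s1 == s2:
        return 1.0
    if not s1 or not s2:
        return 0.0
    window = max(max(len(s1), len(s2)) // 2 - 1, 0)
    used: set[int] = set()
    assigned: list[tuple[int, int]] = []
    for i, ch in enumerate(s1):
        for j in range(len(s2)):
            if j in used or abs(i - j) > window or s2[j] != ch:
                continue
            used.add(j)
            assigned.append((i, j))
            break
    if not assigned:
        return 0.0
    seq1 = [s1[i] for i, _ in assigned]
    seq2 = [s2[j] for j in sorted(j for _, j in assigned)]
    t = sum(a != b for a, b in zip(seq1, seq2)) / 2.0
    m = len(assigned)
    return (m / len(s1) + m / len(s2) + (m - t) / m) / 3.0


def make_record(
    source_id: str = "src01",
    row_index: int = 0,
    match_name: str = "nemataba",
    region: str = "Kolda",
    fac_type: FacilityType = FacilityType.POSTE_DE_SANTE,
    lat: float | None = None,
    lon: float | None = None,
    source_year: int | None = None,
    source_order: int = 0,
    **kw,
) -> NormalizedRecord:
    """Compact builder for normalized records in unit tests."""
    return NormalizedRecord(
        source_id=source_id,
        row_index=row_index,
        fac_name_orig=kw.pop("fac_name_orig", match_name),
        region_orig=region,
        region_std=region,
        fac_type_std=fac_type,
        match_name=match_name,
        latitude=lat,
        longitude=lon,
        source_year=source_year,
        source_order=source_order,
        **kw,
    )


NOISE_OFF = dict(
    inclusion_prob=1.0,
    gps_prob=1.0,
    gps_jitter_sd_m=0.0,
    p_typo=0.0,
    p_accent_strip=0.0,
    p_type_prefix=0.0,
    p_acronym_contract=0.0,
    p_roman_toggle=0.0,
    upgrade_prob=0.0,
    within_source_dup_prob=0.0,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The reference synthetic conditions: 5 sources, 500 facilities,
    mild noise, seed 1."""
    return simulate(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def fitted(default_dataset):
    model = FacilityLinkage.from_frames(
        default_dataset.frames,
        default_dataset.specs,
        hierarchy=default_dataset.hierarchy,
    )
    return model.fit()
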