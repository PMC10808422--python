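"""Fuzzy matching of facility records within regions.

Candidate pairs are generated only *within* a region (blocking), scored with
the Jaro-Winkler string distance on the normalized match name, and accepted
when the distance is at or below the threshold (default 0.2, i.e. similarity
of at least 0.8).  Accepted pairs are clustered into unique-facility groups
by transitive closure (single linkage); a stricter complete-linkage mode is
available behind a configuration switch.  Manual review decisions (splits
and merges) are applied on top of the automatic clustering.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .ingest import FacilityType, NormalizedRecord
from .normalize import strip_accents

__all__ = [
    "MatchingConfig",
    "MatchCandidate",
    "MatchGroup",
    "ReviewDecision",
    "jaro_similarity",
    "jaro_winkler_similarity",
    "jaro_winkler_distance",
    "candidate_pairs",
    "cluster_matches",
    "apply_review_decisions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchingConfig:
    """Parameters of the pairwise matcher.

    ``threshold`` is the maximum Jaro-Winkler *distance* for an accepted
    pair.  ``prefix_weight`` (p) and ``prefix_max`` (ℓmax) are the standard
    Winkler prefix constants.
    """

    threshold: float = 0.2
    prefix_weight: float = 0.1
    prefix_max: int = 4
    block_key: str = "region_std"
    complete_linkage: bool = False
    review_margin: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if not 0.0 <= self.prefix_weight <= 0.25:
            raise ValueError("prefix_weight must be in [0, 0.25]")
        if self.prefix_max < 0:
            raise ValueError("prefix_max must be >= 0")


@dataclass(frozen=True)
class MatchCandidate:
    """A scored within-block record pair."""

    record_a: str
    record_b: str
    jw_distance: float
    accepted: bool
    review_reason: str | None = None


@dataclass
class MatchGroup:
    """A cluster of records asserted to be one real-world facility."""

    match_id: str
    region_std: str
    members: list[NormalizedRecord]
    group_fac_type: FacilityType = FacilityType.UNKNOWN
    group_latitude: float | None = None
    group_longitude: float | None = None
    group_gps_source: str | None = None
    n_gps: int = 0
    data_notes: list[str] = field(default_factory=list)

    @property
    def source_list(self) -> list[str]:
        """Distinct contributing sources, in configured source order."""
        seen: dict[str, int] = {}
        for m in sorted(self.members, key=lambda r: (r.source_order, r.row_index)):
            seen.setdefault(m.source_id, m.source_order)
        return list(seen)

    @property
    def n_source(self) -> int:
        return len({m.source_id for m in self.members})

    @property
    def data_flagged(self) -> int:
        return 1 if self.data_notes else 0

    @property
    def match_name(self) -> str:
        """Representative name: lexicographic minimum of member match names."""
        return min(m.match_name for m in self.members)

    def add_note(self, note: str) -> None:
        """Append a note once; repeated passes stay idempotent."""
        if note not in self.data_notes:
            self.data_notes.append(note)


def jaro_similarity(s1: str, s2: str) -> float:
    """Jaro similarity in [0, 1].

    Characters match when equal and within a window of
    ``floor(max(|s1|,|s2|)/2) - 1`` positions; with ``m`` matches and ``t``
    half the out-of-order matches, the score is
    ``(m/|s1| + m/|s2| + (m−t)/m) / 3`` (0 when ``m`` is 0, 1 when both
    strings are empty).
    """
    if s1 == s2:
        return 1.0
    len1, len2 = len(s1), len(s2)
    if len1 == 0 or len2 == 0:
        return 0.0
    window = max(max(len1, len2) // 2 - 1, 0)
    matched1 = [False] * len1
    matched2 = [False] * len2
    m = 0
    for i, ch in enumerate(s1):
        lo = max(0, i - window)
        hi = min(len2, i + window + 1)
        for j in range(lo, hi):
            if not matched2[j] and s2[j] == ch:
                matched1[i] = matched2[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    transposed = 0
    j = 0
    for i in range(len1):
        if matched1[i]:
            while not matched2[j]:
                j += 1
            if s1[i] != s2[j]:
                transposed += 1
            j += 1
    t = transposed / 2.0
    return (m / len1 + m / len2 + (m - t) / m) / 3.0


def jaro_winkler_similarity(
    s1: str, s2: str, cfg: MatchingConfig = MatchingConfig()
) -> float:
    """Jaro similarity boosted by the length of the common prefix."""
    jaro = jaro_similarity(s1, s2)
    prefix = 0
    for a, b in zip(s1, s2):
        if a != b or prefix >= cfg.prefix_max:
            break
        prefix += 1
    return jaro + prefix * cfg.prefix_weight * (1.0 - jaro)


def jaro_winkler_distance(
    s1: str, s2: str, cfg: MatchingConfig = MatchingConfig()
) -> float:
    """1 − Jaro-Winkler similarity; 0 iff the strings are identical."""
    return 1.0 - jaro_winkler_similarity(s1, s2, cfg)


def candidate_pairs(
    records: Sequence[NormalizedRecord], cfg: MatchingConfig = MatchingConfig()
) -> list[MatchCandidate]:
    """Score every unordered within-block record pair.

    Blocking is on ``cfg.block_key`` (canonical region by default); no
    cross-block pair is ever emitted.  Records whose region did not
    canonicalize are left in their own verbatim-named block.
    """
    blocks: dict[str, list[NormalizedRecord]] = {}
    for rec in records:
        blocks.setdefault(getattr(rec, cfg.block_key), []).append(rec)
    candidates: list[MatchCandidate] = []
    for block in blocks.values():
        block = sorted(block, key=lambda r: (r.source_order, r.row_index))
        for a, b in itertools.combinations(block, 2):
            dist = jaro_winkler_distance(a.match_name, b.match_name, cfg)
            candidates.append(
                MatchCandidate(a.ref, b.ref, dist, accepted=dist <= cfg.threshold)
            )
    n_accepted = sum(c.accepted for c in candidates)
    logger.info("scored %d candidate pairs, %d accepted", len(candidates), n_accepted)
    return candidates


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _region_slug(region: str) -> str:
    slug = strip_accents(region).lower()
    return "".join(ch for ch in slug if ch.isalnum()) or "x"


def assign_match_ids(groupings: Sequence[list[NormalizedRecord]]) -> list[MatchGroup]:
    """Wrap member lists into :class:`MatchGroup`\\ s with deterministic ids.

    Groups are ordered by (region, lexicographic minimum match name, first
    source order/row); ids are ``<region-slug>-NNNN`` with a per-region
    counter, so identical inputs in any order yield identical ids.
    """
    def sort_key(members: list[NormalizedRecord]):
        first = min((m.source_order, m.row_index) for m in members)
        return (
            _region_slug(members[0].region_std),
            min(m.match_name for m in members),
            first,
        )

    groups: list[MatchGroup] = []
    counters: dict[str, int] = {}
    for members in sorted(groupings, key=sort_key):
        members = sorted(members, key=lambda m: (m.source_order, m.row_index))
        slug = _region_slug(members[0].region_std)
        counters[slug] = counters.get(slug, 0) + 1
        groups.append(
            MatchGroup(
                match_id=f"{slug}-{counters[slug]:04d}",
                region_std=members[0].region_std,
                members=members,
            )
        )
    return groups


def _complete_linkage_components(
    block: list[NormalizedRecord], cfg: MatchingConfig
) -> list[list[str]]:
    """Complete-linkage clustering of one block via scipy's hierarchy."""
    import numpy as np
    from scipy.cluster.hierarchy import fcluster, linkage

    if len(block) == 1:
        return [[block[0].ref]]
    dists = [
        jaro_winkler_distance(a.match_name, b.match_name, cfg)
        for a, b in itertools.combinations(block, 2)
    ]
    z = linkage(np.asarray(dists), method="complete")
    labels = fcluster(z, t=cfg.threshold, criterion="distance")
    comps: dict[int, list[str]] = {}
    for rec, lab in zip(block, labels):
        comps.setdefault(int(lab), []).append(rec.ref)
    return list(comps.values())


def cluster_matches(
    records: Sequence[NormalizedRecord],
    candidates: Sequence[MatchCandidate],
    cfg: MatchingConfig = MatchingConfig(),
) -> list[MatchGroup]:
    """Cluster accepted pairs into unique-facility groups.

    Default is transitive closure over accepted pairs (union-find single
    linkage); ``cfg.complete_linkage`` switches to agglomerative complete
    linkage cut at the threshold.  Every record lands in exactly one group;
    singletons form their own.
    """
    by_ref = {r.ref: r for r in records}
    unknown = [c.record_a for c in candidates if c.record_a not in by_ref]
    unknown += [c.record_b for c in candidates if c.record_b not in by_ref]
    if unknown:
        raise ValueError(f"candidates reference unknown records: {sorted(set(unknown))[:5]}")

    if cfg.complete_linkage:
        blocks: dict[str, list[NormalizedRecord]] = {}
        for rec in records:
            blocks.setdefault(getattr(rec, cfg.block_key), []).append(rec)
        groupings = []
        for block in blocks.values():
            block = sorted(block, key=lambda r: (r.source_order, r.row_index))
            for refs in _complete_linkage_components(block, cfg):
                groupings.append([by_ref[ref] for ref in refs])
        return assign_match_ids(groupings)

    uf = _UnionFind(by_ref)
    for cand in candidates:
        if cand.accepted:
            uf.union(cand.record_a, cand.record_b)
    components: dict[str, list[NormalizedRecord]] = {}
    for ref, rec in by_ref.items():
        components.setdefault(uf.find(ref), []).append(rec)
    return assign_match_ids(list(components.values()))


@dataclass(frozen=True)
class ReviewDecision:
    """One manual verification action: split a record out, or merge groups."""

    action: str  # "split" | "merge"
    record_ref_a: str
    record_ref_b: str | None = None
    reason: str = ""

    def __post_init__(self) -> None:
        if self.action not in {"split", "merge"}:
            raise ValueError(f"unknown review action {self.action!r}")
        if self.action == "merge" and not self.record_ref_b:
            raise ValueError("merge decision needs two record references")


def apply_review_decisions(
    groups: Sequence[MatchGroup], decisions: Sequence[ReviewDecision]
) -> list[MatchGroup]:
    """Apply manual split/merge corrections to the automatic clustering.

    Splits move the named record into its own group; merges union the two
    groups containing the named records.  Actions are recorded in the group
    notes; applying the same decisions twice is a no-op.
    """
    membership: dict[str, int] = {}
    groupings: list[list[NormalizedRecord]] = []
    notes: list[set[str]] = []
    for g in groups:
        idx = len(groupings)
        groupings.append(list(g.members))
        notes.append(set(g.data_notes))
        for m in g.members:
            membership[m.ref] = idx

    for dec in decisions:
        if dec.record_ref_a not in membership:
            raise ValueError(f"review decision references unknown record {dec.record_ref_a!r}")
        if dec.action == "merge":
            if dec.record_ref_b not in membership:
                raise ValueError(
                    f"review decision references unknown record {dec.record_ref_b!r}"
                )
            ia, ib = membership[dec.record_ref_a], membership[dec.record_ref_b]
            if ia == ib:
                continue
            keep, drop = min(ia, ib), max(ia, ib)
            note = (
                f"manual merge of {dec.record_ref_a} and {dec.record_ref_b}"
                + (f": {dec.reason}" if dec.reason else "")
            )
            groupings[keep].extend(groupings[drop])
            notes[keep] |= notes[drop] | {note}
            for m in groupings[drop]:
                membership[m.ref] = keep
            groupings[drop] = []
            notes[drop] = set()
        else:  # split
            idx = membership[dec.record_ref_a]
            if len(groupings[idx]) == 1:
                continue
            record = next(m for m in groupings[idx] if m.ref == dec.record_ref_a)
            groupings[idx] = [m for m in groupings[idx] if m.ref != dec.record_ref_a]
            note = (
                f"manual split of {dec.record_ref_a}"
                + (f": {dec.reason}" if dec.reason else "")
            )
            notes[idx].add(note)
            new_idx = len(groupings)
            groupings.append([record])
            notes.append({note})
            membership[dec.record_ref_a] = new_idx

    kept = [(g, n) for g, n in zip(groupings, notes) if g]
    out = assign_match_ids([g for g, _ in kept])
    # assign_match_ids sorts; restore each group's accumulated notes by membership
    note_by_first_ref = {
        min(m.ref for m in g): sorted(n) for g, n in kept
    }
    for group in out:
        group.data_notes = note_by_first_ref[min(m.ref for m in group.members)]
    return out
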