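"""Jaro-Winkler scoring, blocking, clustering, review decisions."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facilink.matching import (
    MatchCandidate,
    MatchingConfig,
    ReviewDecision,
    apply_review_decisions,
    candidate_pairs,
    cluster_matches,
    jaro_similarity,
    jaro_winkler_distance,
)
from conftest import jaro_bruteforce, make_record

CFG = MatchingConfig()


@pytest.mark.parametrize(
    ("s1", "s2", "expected"),
    [
        ("abc", "abc", 1.0),
        ("abc", "xyz", 0.0),
        ("", "", 1.0),
        ("a", "", 0.0),
        ("martha", "marhta", 0.9444444444),
        ("dixon", "dicksonx", 0.7666666667),
    ],
)
def test_jaro_similarity_examples(s1, s2, expected):
    assert jaro_similarity(s1, s2) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize(
    ("s1", "s2", "expected"),
    [
        ("nemataba", "nemataba", 0.0),
        ("abc", "xyz", 1.0),
        # jaro 0.944444, common prefix 3 -> sim 0.9611111, distance 0.0388889
        ("martha", "marhta", 0.0388889),
    ],
)
def test_jaro_winkler_distance_examples(s1, s2, expected):
    assert jaro_winkler_distance(s1, s2, CFG) == pytest.approx(expected, abs=1e-6)


def test_jaro_agrees_with_bruteforce_exhaustively():
    """Exhaustive agreement with the independent oracle on short strings."""
    strings = [
        "".join(p)
        for n in range(4)
        for p in itertools.product("abc", repeat=n)
    ]
    for s1, s2 in itertools.combinations_with_replacement(strings, 2):
        assert jaro_similarity(s1, s2) == pytest.approx(jaro_bruteforce(s1, s2), abs=1e-12)


@settings(max_examples=500, derandomize=True)
@given(st.text(alphabet="abc", max_size=8), st.text(alphabet="abc", max_size=8))
def test_jaro_matches_oracle_and_is_symmetric(s1, s2):
    sim = jaro_similarity(s1, s2)
    assert sim == pytest.approx(jaro_bruteforce(s1, s2), abs=1e-12)
    assert sim == pytest.approx(jaro_similarity(s2, s1), abs=1e-12)
    assert 0.0 <= sim <= 1.0


@settings(max_examples=300, derandomize=True)
@given(st.text(alphabet="abcde ", max_size=12), st.text(alphabet="abcde ", max_size=12))
def test_jw_distance_is_symmetric_zero_iff_identical(s1, s2):
    d = jaro_winkler_distance(s1, s2, CFG)
    assert d == pytest.approx(jaro_winkler_distance(s2, s1, CFG), abs=1e-12)
    assert 0.0 <= d <= 1.0
    assert (d == 0.0) == (s1 == s2)


def test_candidate_pairs_respect_region_blocking():
    same = [
        make_record("a", 0, "nemataba", "Kolda"),
        make_record("b", 0, "nemataba", "Kolda", source_order=1),
    ]
    cands = candidate_pairs(same, CFG)
    assert len(cands) == 1 and cands[0].accepted and cands[0].jw_distance == 0.0

    cross = [
        make_record("a", 0, "nemataba", "Kolda"),
        make_record("b", 0, "nemataba", "Fatick", source_order=1),
    ]
    assert candidate_pairs(cross, CFG) == []


def test_identical_block_pair_count():
    n = 6
    block = [make_record("a", i, "nemataba", "Kolda") for i in range(n)]
    cands = candidate_pairs(block, CFG)
    assert len(cands) == n * (n - 1) // 2
    assert all(c.accepted for c in cands)


def test_acceptances_monotone_in_threshold():
    rng = random.Random(13)
    names = ["".join(rng.choice("abcdef") for _ in range(rng.randint(3, 9)))
             for _ in range(30)]
    records = [make_record("a", i, name, "Kolda") for i, name in enumerate(names)]
    accepted = []
    for t in (0.0, 0.1, 0.2, 0.4, 1.0):
        cfg = MatchingConfig(threshold=t)
        accepted.append(sum(c.accepted for c in candidate_pairs(records, cfg)))
    assert accepted == sorted(accepted)
    assert accepted[-1] == 30 * 29 // 2  # threshold 1 accepts everything


def _three_records():
    return [
        make_record("a", 0, "alpha", "Kolda"),
        make_record("b", 0, "alphq", "Kolda", source_order=1),
        make_record("c", 0, "alpxq", "Kolda", source_order=2),
    ]


def test_transitive_closure_merges_chains():
    records = _three_records()
    refs = [r.ref for r in records]
    cands = [
        MatchCandidate(refs[0], refs[1], 0.05, True),
        MatchCandidate(refs[1], refs[2], 0.05, True),
    ]
    (group,) = cluster_matches(records, cands, CFG)
    assert {m.ref for m in group.members} == set(refs)


def test_singletons_without_accepted_pairs():
    records = _three_records()[:2]
    cands = [MatchCandidate(records[0].ref, records[1].ref, 0.5, False)]
    groups = cluster_matches(records, cands, CFG)
    assert sorted(len(g.members) for g in groups) == [1, 1]


def test_clustering_is_order_invariant():
    records = _three_records()
    cands = candidate_pairs(records, CFG)
    baseline = cluster_matches(records, cands, CFG)
    for perm in itertools.permutations(records):
        shuffled_cands = candidate_pairs(list(perm), CFG)
        groups = cluster_matches(list(perm), shuffled_cands, CFG)
        assert [(g.match_id, sorted(m.ref for m in g.members)) for g in groups] == [
            (g.match_id, sorted(m.ref for m in g.members)) for g in baseline
        ]


def test_complete_linkage_is_stricter_than_single_on_chains():
    # chain a~b~c (near pairs at distance 0.1, far pair at 0.2): with a
    # 0.15 threshold single linkage merges all three through b, while
    # complete linkage keeps the far end out
    records = [
        make_record("a", 0, "fannhock", "Dakar"),
        make_record("b", 0, "fannhoqq", "Dakar", source_order=1),
        make_record("c", 0, "fannqqqq", "Dakar", source_order=2),
    ]
    single_cfg = MatchingConfig(threshold=0.15)
    complete_cfg = MatchingConfig(threshold=0.15, complete_linkage=True)
    far = jaro_winkler_distance("fannhock", "fannqqqq", single_cfg)
    assert far > single_cfg.threshold  # the chain's far pair is no match
    single = cluster_matches(records, candidate_pairs(records, single_cfg), single_cfg)
    complete = cluster_matches(
        records, candidate_pairs(records, complete_cfg), complete_cfg
    )
    assert len(single) == 1
    assert len(complete) == 2
    # both modes still partition the records
    for groups in (single, complete):
        assert sum(len(g.members) for g in groups) == len(records)


def test_cluster_rejects_unknown_candidate_refs():
    records = _three_records()[:1]
    with pytest.raises(ValueError, match="unknown records"):
        cluster_matches(records, [MatchCandidate("ghost:0", records[0].ref, 0.0, True)], CFG)


class TestReviewDecisions:
    def _groups(self):
        records = [
            make_record("a", 0, "alpha", "Kolda"),
            make_record("b", 0, "beta", "Kolda", source_order=1),
            make_record("c", 0, "gamma", "Kolda", source_order=2),
        ]
        return cluster_matches(records, [], CFG)

    def test_merge_two_singletons(self):
        groups = self._groups()
        merged = apply_review_decisions(
            groups, [ReviewDecision("merge", "a:0", "b:0", "field confirmation")]
        )
        sizes = sorted(len(g.members) for g in merged)
        assert sizes == [1, 2]
        big = next(g for g in merged if len(g.members) == 2)
        assert any("manual merge" in note for note in big.data_notes)

    def test_split_from_group_of_three(self):
        records = [
            make_record("a", 0, "alpha", "Kolda"),
            make_record("b", 0, "alpha", "Kolda", source_order=1),
            make_record("c", 0, "alpha", "Kolda", source_order=2),
        ]
        groups = cluster_matches(records, candidate_pairs(records, CFG), CFG)
        assert len(groups) == 1
        split = apply_review_decisions(
            groups, [ReviewDecision("split", "c:0", reason="distinct facility")]
        )
        assert sorted(len(g.members) for g in split) == [1, 2]

    def test_empty_decisions_are_identity(self):
        groups = self._groups()
        unchanged = apply_review_decisions(groups, [])
        assert [(g.match_id, [m.ref for m in g.members]) for g in unchanged] == [
            (g.match_id, [m.ref for m in g.members]) for g in groups
        ]

    def test_idempotent_under_reapplication(self):
        groups = self._groups()
        decisions = [ReviewDecision("merge", "a:0", "b:0")]
        once = apply_review_decisions(groups, decisions)
        twice = apply_review_decisions(once, decisions)
        assert [(g.match_id, sorted(m.ref for m in g.members), sorted(g.data_notes))
                for g in once] == [
            (g.match_id, sorted(m.ref for m in g.members), sorted(g.data_notes))
            for g in twice
        ]

    def test_unknown_record_is_an_error(self):
        with pytest.raises(ValueError, match="ghost:9"):
            apply_review_decisions(self._groups(), [ReviewDecision("split", "ghost:9")])

    def test_merge_requires_two_refs(self):
        with pytest.raises(ValueError, match="two record references"):
            ReviewDecision("merge", "a:0")
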