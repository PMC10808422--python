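"""Type resolution, conflict flagging, and CFL construction."""

import pytest

from facilink.consolidate import (
    CFL_COLUMNS,
    build_cfl,
    build_full_list,
    consolidate_groups,
    flag_geo_conflicts,
    flag_same_name_conflicts,
    near_threshold_report,
    resolve_fac_type,
)
from facilink.ingest import FacilityType
from facilink.matching import MatchGroup, MatchingConfig
from conftest import make_record


def _group(members, match_id="kolda-0001", region="Kolda"):
    return MatchGroup(match_id=match_id, region_std=region, members=list(members))


def _typed(fac_type, year, idx=0, source="a"):
    return make_record(source, idx, "alpha", fac_type=fac_type, source_year=year)


class TestResolveFacType:
    def test_upgrade_resolved_by_most_recent_source(self):
        group = _group(
            [
                _typed(FacilityType.CASE_DE_SANTE, 2014, 0, "old"),
                _typed(FacilityType.POSTE_DE_SANTE, 2021, 0, "new"),
            ]
        )
        assert resolve_fac_type(group) is FacilityType.POSTE_DE_SANTE
        assert any("upgrade" in n for n in group.data_notes)

    def test_downgrade_recency_beats_majority_of_old_reports(self):
        # a facility reopened at a lower tier: older sources say hospital,
        # recent ones say health post — recency wins
        group = _group(
            [
                _typed(FacilityType.HOPITAL, 2015, 0, "spa2015"),
                _typed(FacilityType.POSTE_DE_SANTE, 2017, 0, "spa2017"),
                _typed(FacilityType.POSTE_DE_SANTE, 2021, 0, "cous"),
            ]
        )
        assert resolve_fac_type(group) is FacilityType.POSTE_DE_SANTE
        assert group.data_flagged == 1
        assert any("downgrade" in n for n in group.data_notes)

    def test_single_type_is_unchanged_and_unflagged(self):
        group = _group([_typed(FacilityType.HOPITAL, 2015)])
        assert resolve_fac_type(group) is FacilityType.HOPITAL
        assert group.data_notes == []

    def test_unknown_members_do_not_create_conflicts(self):
        group = _group(
            [
                _typed(FacilityType.POSTE_DE_SANTE, 2015, 0, "a"),
                _typed(FacilityType.UNKNOWN, 2021, 0, "b"),
            ]
        )
        assert resolve_fac_type(group) is FacilityType.POSTE_DE_SANTE
        assert group.data_notes == []

    def test_undated_conflict_falls_back_to_majority_with_flag(self):
        group = _group(
            [
                _typed(FacilityType.CASE_DE_SANTE, None, 0, "a"),
                _typed(FacilityType.CASE_DE_SANTE, None, 0, "b"),
                _typed(FacilityType.POSTE_DE_SANTE, None, 0, "c"),
            ]
        )
        assert resolve_fac_type(group) is FacilityType.CASE_DE_SANTE
        assert any("needs verification" in n for n in group.data_notes)

    def test_undated_tie_goes_to_higher_tier(self):
        group = _group(
            [
                _typed(FacilityType.CASE_DE_SANTE, None, 0, "a"),
                _typed(FacilityType.POSTE_DE_SANTE, None, 0, "b"),
            ]
        )
        assert resolve_fac_type(group) is FacilityType.POSTE_DE_SANTE
        assert group.data_flagged == 1

    def test_off_ladder_conflict_uses_majority(self):
        group = _group(
            [
                _typed(FacilityType.AUTRE, 2015, 0, "a"),
                _typed(FacilityType.AUTRE, 2016, 0, "b"),
                _typed(FacilityType.POSTE_DE_SANTE, 2021, 0, "c"),
            ]
        )
        assert resolve_fac_type(group) is FacilityType.AUTRE
        assert group.data_flagged == 1


class TestGeoFlags:
    def test_far_pair_flagged_with_distance(self):
        group = _group(
            [
                make_record("a", 0, "alpha", lat=14.0, lon=-17.0),
                make_record("b", 0, "alpha", lat=14.0135, lon=-17.0, source_order=1),
            ]
        )  # ~1.5 km apart
        flag_geo_conflicts([group])
        assert group.data_flagged == 1
        assert any("1.50 km" in n for n in group.data_notes)

    def test_near_pair_and_single_gps_not_flagged(self):
        near = _group(
            [
                make_record("a", 0, "alpha", lat=14.0, lon=-17.0),
                make_record("b", 0, "alpha", lat=14.0045, lon=-17.0, source_order=1),
            ]
        )  # ~0.5 km
        single = _group([make_record("a", 0, "alpha", lat=14.0, lon=-17.0)])
        flag_geo_conflicts([near, single])
        assert near.data_flagged == 0
        assert single.data_flagged == 0


class TestSameNameFlags:
    def test_same_name_different_type_cross_flagged(self):
        a = _group(
            [make_record("a", 0, "fatick", "Fatick",
                         fac_type=FacilityType.CENTRE_DE_SANTE)],
            "fatick-0001", "Fatick",
        )
        b = _group(
            [make_record("b", 0, "fatick", "Fatick", fac_type=FacilityType.HOPITAL,
                         source_order=1)],
            "fatick-0002", "Fatick",
        )
        a.group_fac_type = FacilityType.CENTRE_DE_SANTE
        b.group_fac_type = FacilityType.HOPITAL
        flag_same_name_conflicts([a, b])
        assert a.data_flagged == 1 and b.data_flagged == 1
        assert any("fatick-0002" in n for n in a.data_notes)

    def test_gps_separated_same_name_noted_as_distinct(self):
        a = _group(
            [make_record("a", 0, "fatick", "Fatick",
                         fac_type=FacilityType.CENTRE_DE_SANTE)],
            "fatick-0001", "Fatick",
        )
        b = _group(
            [make_record("b", 0, "fatick", "Fatick", fac_type=FacilityType.HOPITAL,
                         source_order=1)],
            "fatick-0002", "Fatick",
        )
        a.group_fac_type, b.group_fac_type = (
            FacilityType.CENTRE_DE_SANTE, FacilityType.HOPITAL
        )
        a.group_latitude, a.group_longitude = 14.0, -16.0
        b.group_latitude, b.group_longitude = 14.1, -16.0  # ~11 km away
        flag_same_name_conflicts([a, b])
        assert any("distinct" in n for n in a.data_notes)
        assert not any("upgrade" in n for n in a.data_notes)

    def test_same_name_and_type_across_districts_flagged(self):
        a = _group(
            [make_record("a", 0, "mlomp", "Ziguinchor", district_orig="Oussouye")],
            "ziguinchor-0001", "Ziguinchor",
        )
        b = _group(
            [make_record("b", 0, "mlomp", "Ziguinchor",
                         district_orig="Thionk Essyl", source_order=1)],
            "ziguinchor-0002", "Ziguinchor",
        )
        for g in (a, b):
            g.group_fac_type = FacilityType.POSTE_DE_SANTE
        flag_same_name_conflicts([a, b])
        assert a.data_flagged == 1 and b.data_flagged == 1
        assert any("departments/districts" in n for n in a.data_notes)

    def test_unique_names_are_never_flagged(self):
        groups = [
            _group([make_record("a", i, name)], f"kolda-{i:04d}")
            for i, name in enumerate(["alpha", "beta", "gamma"])
        ]
        for g in groups:
            g.group_fac_type = FacilityType.POSTE_DE_SANTE
        flag_same_name_conflicts(groups)
        assert all(g.data_flagged == 0 for g in groups)


def test_near_threshold_pairs_reported():
    cfg = MatchingConfig()
    a = _group([make_record("a", 0, "boukitingho")], "kolda-0001")
    b = _group([make_record("b", 0, "bakitongha", source_order=1)], "kolda-0002")
    c = _group([make_record("c", 0, "zzzzz", source_order=2)], "kolda-0003")
    report = near_threshold_report([a, b, c], cfg)
    pairs = set(zip(report["group_a"], report["group_b"]))
    assert ("kolda-0001", "kolda-0002") in pairs
    assert all("zzzzz" not in n for n in report["name_b"])
    ok = (report["jw_distance"] > cfg.threshold) & (
        report["jw_distance"] <= cfg.threshold + cfg.review_margin
    )
    assert ok.all()


class TestBuildCfl:
    def _groups(self):
        groups = [
            _group([make_record("a", 0, "alpha", fac_type=FacilityType.HOPITAL,
                                lat=14.0, lon=-17.0)], "kolda-0001"),
            _group([make_record("a", 1, "beta", fac_type=FacilityType.AUTRE)],
                   "kolda-0002"),
            _group([make_record("a", 2, "gamma",
                                fac_type=FacilityType.POSTE_DE_SANTE)], "kolda-0003"),
        ]
        consolidate_groups(groups)
        return groups

    def test_schema_and_row_count(self):
        groups = self._groups()
        cfl = build_cfl(groups)
        assert list(cfl.columns) == CFL_COLUMNS
        assert len(cfl) == len(groups)

    def test_flag_invariant_matches_notes(self):
        cfl = build_cfl(self._groups())
        assert ((cfl["data_notes"] != "") == (cfl["data_flagged"] == 1)).all()

    def test_autre_rows_carried_but_excluded_from_headline(self):
        from facilink.reporting import HEADLINE_LABELS

        cfl = build_cfl(self._groups())
        assert len(cfl) == 3
        assert (cfl["group_fac_type"] == "autre").sum() == 1
        headline = cfl[cfl["group_fac_type"].isin(HEADLINE_LABELS)]
        assert len(headline) == 2

    def test_full_list_reconciles_with_pool(self):
        groups = self._groups()
        full = build_full_list(groups)
        assert len(full) == sum(len(g.members) for g in groups)
        assert set(full["match_id"]) == {g.match_id for g in groups}


def test_consolidation_is_idempotent(fitted):
    """Re-running every resolution/flagging pass is a no-op."""
    before = build_cfl(fitted.groups)
    consolidate_groups(fitted.groups, fitted.model.hierarchy, fitted.model.geo)
    after = build_cfl(fitted.groups)
    assert before.equals(after)
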