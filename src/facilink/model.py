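"""Top-level modelling interface.

:class:`FacilityLinkage` bundles the source tables and tuning parameters;
``fit()`` runs ingestion → normalization → within-source dedup → pooling →
blocked fuzzy matching → clustering → (optional) review decisions →
type/GPS resolution → conflict flagging, and returns a
:class:`LinkageResults` carrying the consolidated facility list, the full
per-record list, diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import consolidate as _consolidate
from . import evaluation as _evaluation
from . import geo as _geo
from . import ingest as _ingest
from . import reporting as _reporting
from .gps import DEFAULT_HIERARCHY, SourceHierarchy
from .matching import (
    MatchingConfig,
    ReviewDecision,
    candidate_pairs,
    cluster_matches,
    apply_review_decisions,
)
from .normalize import DEFAULT_LEXICON, NormalizationLexicon

__all__ = ["FacilityLinkage", "LinkageResults", "read_review_file"]


def read_review_file(path: "str | os.PathLike[str]") -> list[ReviewDecision]:
    """Read manual review decisions from a delimited file.

    Expected columns: ``action`` (split|merge), ``record_ref_a``,
    ``record_ref_b`` (blank for splits), ``reason``.
    """
    frame = pd.read_csv(path, dtype=str).fillna("")
    decisions = []
    for _, row in frame.iterrows():
        decisions.append(
            ReviewDecision(
                action=row["action"].strip(),
                record_ref_a=row["record_ref_a"].strip(),
                record_ref_b=row.get("record_ref_b", "").strip() or None,
                reason=row.get("reason", "").strip(),
            )
        )
    return decisions


class FacilityLinkage:
    """Entity-resolution model over one or more facility source lists.

    Parameters
    ----------
    sources
        Sequence of ``(table, spec)`` pairs, where ``table`` is a CSV path
        or a DataFrame and ``spec`` an :class:`~facilink.ingest.SourceSpec`.
    matching, geo, hierarchy, lexicon
        Tuning parameter blocks; defaults follow the reference pipeline
        (Jaro-Winkler threshold 0.2 within regions, 1 km review / 2 km
        discordance distances, government-first GPS preference).
    """

    def __init__(
        self,
        sources: Sequence[tuple],
        *,
        matching: MatchingConfig | None = None,
        geo: _geo.GeoConstants | None = None,
        hierarchy: SourceHierarchy | None = None,
        lexicon: NormalizationLexicon | None = None,
    ) -> None:
        self.sources = list(sources)
        ids = [spec.source_id for _, spec in self.sources]
        if len(ids) != len(set(ids)):
            raise ValueError("source_ids must be unique")
        self.matching = matching or MatchingConfig()
        self.geo = geo or _geo.GeoConstants()
        self.hierarchy = hierarchy or DEFAULT_HIERARCHY
        self.lexicon = lexicon or DEFAULT_LEXICON

    @classmethod
    def from_frames(
        cls, frames: Mapping[str, pd.DataFrame], specs: Sequence[_ingest.SourceSpec], **kw
    ) -> "FacilityLinkage":
        """Build from in-memory tables keyed by source_id."""
        return cls([(frames[s.source_id], s) for s in specs], **kw)

    @classmethod
    def from_config(cls, path: "str | os.PathLike[str]") -> "FacilityLinkage":
        """Build from a YAML run-configuration file (see docs/methods.md)."""
        from .config import load_run_config

        return load_run_config(path)

    def fit(
        self, review: "Sequence[ReviewDecision] | str | os.PathLike[str] | None" = None
    ) -> "LinkageResults":
        """Run the full consolidation pipeline."""
        per_source = []
        load_log = {}
        for order, (table, spec) in enumerate(self.sources):
            raw = _ingest.load_source(table, spec)
            normed = _ingest.normalize_records(raw, spec, self.lexicon, source_order=order)
            deduped = _ingest.dedupe_within_source(normed)
            load_log[spec.source_id] = {
                "loaded": len(raw),
                "after_dedup": len(deduped),
                "duplicates_removed": len(raw) - len(deduped),
            }
            per_source.append(deduped)
        pooled = _ingest.pool_sources(per_source)
        candidates = candidate_pairs(pooled, self.matching)
        groups = cluster_matches(pooled, candidates, self.matching)
        if review is not None:
            if not isinstance(review, (list, tuple)):
                review = read_review_file(review)
            groups = apply_review_decisions(groups, review)
        _consolidate.consolidate_groups(groups, self.hierarchy, self.geo)
        review_report = _consolidate.near_threshold_report(groups, self.matching)
        return LinkageResults(
            model=self,
            groups=groups,
            cfl=_consolidate.build_cfl(groups),
            full_list=_consolidate.build_full_list(groups),
            review_report=review_report,
            n_pooled=len(pooled),
            load_log=load_log,
        )


@dataclass
class LinkageResults:
    """Fitted consolidation output.

    Attributes
    ----------
    cfl
        Consolidated facility list, one row per unique facility.
    full_list
        Per-record list linkable to the CFL via ``match_id``.
    groups
        The underlying :class:`~facilink.matching.MatchGroup` objects.
    review_report
        Near-threshold group pairs suggested for manual verification.
    """

    model: FacilityLinkage
    groups: list
    cfl: pd.DataFrame
    full_list: pd.DataFrame
    review_report: pd.DataFrame
    n_pooled: int
    load_log: dict = field(default_factory=dict)

    # -- diagnostics ----------------------------------------------------
    def coverage(self) -> pd.DataFrame:
        return _reporting.coverage_summary(self.cfl)

    def multitype(self) -> dict:
        return _reporting.multitype_summary(self.full_list, self.cfl)

    def discordance(self) -> dict:
        return _geo.discordance_stats(self.groups, self.model.geo)

    def compare_counts(self, reference: pd.DataFrame | None = None) -> pd.DataFrame:
        return _reporting.compare_counts(self.cfl, reference)

    def assignment(self) -> dict[str, str]:
        """Record reference → match_id mapping for evaluation."""
        return {m.ref: g.match_id for g in self.groups for m in g.members}

    def evaluate(self, truth) -> _evaluation.LinkageMetrics:
        """Score against a ground-truth record→facility mapping."""
        return _evaluation.pairwise_linkage_metrics(self.assignment(), truth)

    # -- presentation ---------------------------------------------------
    def headline_counts(self) -> dict[str, int]:
        headline = self.cfl[
            self.cfl["group_fac_type"].isin(_reporting.HEADLINE_LABELS)
        ]
        counts = {"all": len(headline)}
        for label in _reporting.HEADLINE_LABELS:
            counts[label] = int((headline["group_fac_type"] == label).sum())
        return counts

    def summary(self) -> str:
        counts = self.headline_counts()
        headline = self.cfl[self.cfl["group_fac_type"].isin(_reporting.HEADLINE_LABELS)]
        n_gps = int(headline["group_latitude"].notna().sum())
        disc = self.discordance()
        lines = [
            "Facility list consolidation results",
            "=" * 51,
            f"{'Sources':<38}{len(self.model.sources):>13}",
            f"{'Pooled facility observations':<38}{self.n_pooled:>13}",
            f"{'Unique facilities (headline types)':<38}{counts['all']:>13}",
            f"{'  hopital':<38}{counts['hopital']:>13}",
            f"{'  centre de sante':<38}{counts['centre de sante']:>13}",
            f"{'  poste de sante':<38}{counts['poste de sante']:>13}",
            f"{'  case de sante':<38}{counts['case de sante']:>13}",
            f"{'Other/unknown rows carried':<38}{len(self.cfl) - counts['all']:>13}",
        ]
        pct = 100.0 * n_gps / counts["all"] if counts["all"] else 0.0
        lines += [
            f"{'With at least one GPS':<38}{n_gps:>13}",
            f"{'GPS coverage (%)':<38}{pct:>13.1f}",
            f"{'Groups with multiple distinct GPS':<38}{disc['n_multi_gps']:>13}",
        ]
        if disc["frac_exceeding"] is not None:
            over = 100.0 * disc["frac_exceeding"]
            km = self.model.geo.discordance_distance_km
            lines.append(f"{f'  of which > {km:g} km apart (%)':<38}{over:>13.1f}")
        n_flagged = int(self.cfl["data_flagged"].sum())
        lines += [
            f"{'Rows flagged for verification':<38}{n_flagged:>13}",
            "=" * 51,
        ]
        return "\n".join(lines)

    def to_csv(self, outdir: "str | os.PathLike[str]") -> None:
        """Write the CFL, full list, review report and coverage summary."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cfl.to_csv(out / "consolidated_facility_list.csv", index=False,
                        encoding="utf-8")
        self.full_list.to_csv(out / "full_facility_list.csv", index=False,
                              encoding="utf-8")
        self.review_report.to_csv(out / "review_report.csv", index=False)
        self.coverage().to_csv(out / "coverage_summary.csv", index=False)
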