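"""Scoring predicted match groups against ground truth.

Linkage quality is summarized with pairwise precision/recall/F1: a record
pair counts as predicted when the two records share a match group, and as
true when they share a true facility identity.  Pairwise metrics are the
primary view because manual-review workflows operate on pairs; a
cluster-level exact-match rate is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["LinkageMetrics", "pairwise_linkage_metrics", "cluster_exact_match_rate",
           "threshold_sweep"]


@dataclass(frozen=True)
class LinkageMetrics:
    """Pairwise linkage scores.

    Precision is 1 by convention when no pair is predicted, recall is 1
    when no true pair exists; F1 is the harmonic mean (0 when both
    components are 0).
    """

    pairwise_precision: float
    pairwise_recall: float
    f1: float
    n_pred_pairs: int
    n_true_pairs: int


def _pair_count(sizes) -> int:
    return int(sum(n * (n - 1) // 2 for n in sizes))


def _as_mapping(assignment) -> dict[str, object]:
    if isinstance(assignment, pd.DataFrame):
        if {"source_id", "row_index"}.issubset(assignment.columns):
            refs = assignment["source_id"].astype(str) + ":" + assignment["row_index"].astype(str)
        else:
            refs = assignment.iloc[:, 0].astype(str)
        label_col = [c for c in ("match_id", "facility_id", "label") if c in assignment.columns]
        if not label_col:
            raise ValueError("assignment frame needs a match_id/facility_id column")
        return dict(zip(refs, assignment[label_col[0]]))
    return dict(assignment)


def pairwise_linkage_metrics(
    predicted: "Mapping[str, object] | pd.DataFrame",
    truth: "Mapping[str, object] | pd.DataFrame",
) -> LinkageMetrics:
    """Score a predicted record→group assignment against record→entity truth.

    Both arguments map record references (``source_id:row_index``) to
    labels; DataFrames with (source_id, row_index, match_id/facility_id)
    columns are accepted.  Every predicted record must exist in truth.
    Counting uses the group×entity contingency table, so it scales linearly
    in the number of records rather than quadratically in pairs.
    """
    pred = _as_mapping(predicted)
    true = _as_mapping(truth)
    unknown = sorted(set(pred) - set(true))
    if unknown:
        raise ValueError(f"records missing from ground truth: {unknown[:5]}")

    pred_sizes: dict[object, int] = {}
    true_sizes: dict[object, int] = {}
    joint: dict[tuple, int] = {}
    for ref, g in pred.items():
        e = true[ref]
        pred_sizes[g] = pred_sizes.get(g, 0) + 1
        true_sizes[e] = true_sizes.get(e, 0) + 1
        joint[(g, e)] = joint.get((g, e), 0) + 1
    n_pred = _pair_count(pred_sizes.values())
    n_true = _pair_count(true_sizes.values())
    n_both = _pair_count(joint.values())
    precision = 1.0 if n_pred == 0 else n_both / n_pred
    recall = 1.0 if n_true == 0 else n_both / n_true
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return LinkageMetrics(precision, recall, f1, n_pred, n_true)


def cluster_exact_match_rate(
    predicted: "Mapping[str, object] | pd.DataFrame",
    truth: "Mapping[str, object] | pd.DataFrame",
) -> float:
    """Share of true entities recovered as exactly one predicted group."""
    pred = _as_mapping(predicted)
    true = _as_mapping(truth)
    by_entity: dict[object, set] = {}
    by_group: dict[object, int] = {}
    for ref, g in pred.items():
        by_entity.setdefault(true[ref], set()).add(g)
        by_group[g] = by_group.get(g, 0) + 1
    entity_counts: dict[object, int] = {}
    for ref in pred:
        e = true[ref]
        entity_counts[e] = entity_counts.get(e, 0) + 1
    if not by_entity:
        return 1.0
    exact = sum(
        1
        for e, gs in by_entity.items()
        if len(gs) == 1 and by_group[next(iter(gs))] == entity_counts[e]
    )
    return exact / len(by_entity)


def threshold_sweep(
    records: Sequence,
    truth: "Mapping[str, object] | pd.DataFrame",
    thresholds: Sequence[float],
    base_cfg=None,
) -> pd.DataFrame:
    """Re-cluster the same pooled records at each threshold and score.

    With single-linkage clustering, raising the threshold can only add
    accepted pairs, so recall is non-decreasing across thresholds; that
    invariant is asserted.  Returns one row of metrics per threshold.
    """
    from dataclasses import replace

    from .matching import MatchingConfig, candidate_pairs, cluster_matches

    if base_cfg is None:
        base_cfg = MatchingConfig()
    if any(not 0.0 <= t <= 1.0 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    rows = []
    last_recall = -1.0
    for t in sorted(thresholds):
        cfg = replace(base_cfg, threshold=t)
        groups = cluster_matches(records, candidate_pairs(records, cfg), cfg)
        assignment = {m.ref: g.match_id for g in groups for m in g.members}
        metrics = pairwise_linkage_metrics(assignment, truth)
        if not cfg.complete_linkage:
            assert metrics.pairwise_recall >= last_recall - 1e-12, (
                "recall decreased while raising the threshold"
            )
        last_recall = metrics.pairwise_recall
        rows.append(
            {
                "threshold": t,
                "pairwise_precision": metrics.pairwise_precision,
                "pairwise_recall": metrics.pairwise_recall,
                "f1": metrics.f1,
                "n_pred_pairs": metrics.n_pred_pairs,
                "n_true_pairs": metrics.n_true_pairs,
            }
        )
    return pd.DataFrame(rows)
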