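"""Rank-aggregation of inference methods into a community network.

Each method contributes a ranked prediction list; an interaction's
community score is the mean of its 1-based rank positions across lists,
with a missing-list penalty of (list length + 1).  Lower mean rank means
higher confidence.  The aggregated list is finally pruned to the expected
size of the complete GRN (23,908 interactions for *S. coelicolor*).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .assess import RankedPredictions
from .core import GRNError


@dataclass(frozen=True)
class CommunityScore:
    interaction: tuple[str, str]
    mean_rank: float
    support: int

    def __post_init__(self) -> None:
        if self.mean_rank < 1:
            raise GRNError("mean rank must be >= 1")
        if self.support < 1:
            raise GRNError("support must be >= 1")


def _rank_positions(predictions: RankedPredictions) -> dict[tuple[str, str], int]:
    """1-based rank of each pair after deterministic lexicographic
    tie-breaking within equal-score groups."""
    ranks: dict[tuple[str, str], int] = {}
    position = 1
    for group in predictions.tie_groups():
        for reg, tgt, _score in sorted(group, key=lambda e: (e[0], e[1])):
            ranks[(reg, tgt)] = position
            position += 1
    return ranks


def integrate_scores(lists: Sequence[RankedPredictions]) -> list[CommunityScore]:
    """Community scores (mean rank, support) sorted by ascending mean rank,
    ties broken lexicographically by (regulator, target)."""
    if not lists:
        raise GRNError("need at least one prediction list")
    per_list_ranks = [_rank_positions(pl) for pl in lists]
    penalties = [len(pl) + 1 for pl in lists]
    union: set[tuple[str, str]] = set()
    for ranks in per_list_ranks:
        union.update(ranks)
    scores = []
    for pair in union:
        positions = [
            ranks.get(pair, penalty)
            for ranks, penalty in zip(per_list_ranks, penalties)
        ]
        scores.append(
            CommunityScore(
                interaction=pair,
                mean_rank=sum(positions) / len(positions),
                support=sum(1 for ranks in per_list_ranks if pair in ranks),
            )
        )
    scores.sort(key=lambda s: (s.mean_rank, s.interaction))
    return scores


def integrate(
    lists: Sequence[RankedPredictions], method_label: str = "community"
) -> RankedPredictions:
    """Aggregate prediction lists by average rank position.

    The returned ranking is sorted ascending by mean rank; its score field
    is the negated mean rank so that the ``RankedPredictions`` convention
    (higher score = higher confidence, non-increasing along the order)
    holds.  Only interactions present in at least one input list appear.
    """
    scores = integrate_scores(lists)
    entries = [
        (pair[0], pair[1], -s.mean_rank)
        for s in scores
        for pair in (s.interaction,)
    ]
    return RankedPredictions(entries=entries, method_label=method_label)


def prune_top(predictions: RankedPredictions, k: int) -> RankedPredictions:
    """Keep the first min(k, len) entries of an already tie-broken ranking."""
    if k < 0:
        raise GRNError("k must be >= 0")
    return RankedPredictions(
        entries=list(predictions.entries[:k]),
        method_label=predictions.method_label,
    )
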