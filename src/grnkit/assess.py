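"""Assessment of inferred networks against a curated gold standard.

Ranked interaction predictions are scored with the area under the
precision-recall curve (AUPR) and the receiver operating characteristic
curve (AUROC), with

    precision = TP / (TP + FP)
    recall    = TPR = TP / (TP + FN)
    FPR       = FP / (FP + TN)

computed by walking the ranked list in tie groups (all entries sharing a
score form one curve point, so the curves are deterministic).  The negative
universe for the ROC is the TF -> gene search space of the gold standard:
all ordered pairs whose source is a gold regulator, self-loops included.

Set-valued predictions (e.g. global-regulator calls) are scored with MCC,
precision and F1; class overlap uses the Simpson similarity index
|A n B| / min(|A|, |B|).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import GRN, GRNError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise GRNError("confusion counts must be non-negative")


@dataclass
class RankedPredictions:
    """An ordered list of scored candidate interactions (best first).

    Scores must be non-increasing along the order and (regulator, target)
    pairs unique.  Use :meth:`from_scores` to sort and tie-break
    lexicographically from unordered input.
    """

    entries: list[tuple[str, str, float]]
    method_label: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        prev = math.inf
        for reg, tgt, score in self.entries:
            key = (reg, tgt)
            if key in seen:
                raise GRNError(f"duplicate prediction for pair {key}")
            seen.add(key)
            if score > prev + 1e-12:
                raise GRNError("prediction scores must be non-increasing")
            prev = score

    @classmethod
    def from_scores(
        cls,
        entries: Iterable[tuple[str, str, float]],
        method_label: str = "",
    ) -> "RankedPredictions":
        ordered = sorted(entries, key=lambda e: (-e[2], e[0], e[1]))
        return cls(entries=list(ordered), method_label=method_label)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def pairs(self) -> list[tuple[str, str]]:
        return [(r, t) for r, t, _s in self.entries]

    def tie_groups(self) -> list[list[tuple[str, str, float]]]:
        """Consecutive entries sharing a score, in rank order."""
        groups: list[list[tuple[str, str, float]]] = []
        for entry in self.entries:
            if groups and math.isclose(
                groups[-1][0][2], entry[2], rel_tol=0.0, abs_tol=1e-12
            ):
                groups[-1].append(entry)
            else:
                groups.append([entry])
        return groups


def read_ranked_tsv(path: str | os.PathLike, method_label: str = "") -> RankedPredictions:
    """Read a ``regulator target score`` TSV, sorting on load."""
    entries: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GRNError(f"{path}:{lineno}: expected 3 fields")
            try:
                score = float(parts[2])
            except ValueError:
                raise GRNError(f"{path}:{lineno}: bad score {parts[2]!r}") from None
            entries.append((parts[0], parts[1], score))
    return RankedPredictions.from_scores(
        entries, method_label=method_label or os.path.basename(str(path))
    )


def write_ranked_tsv(predictions: RankedPredictions, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#regulator\ttarget\tscore\n")
        for reg, tgt, score in predictions:
            handle.write(f"{reg}\t{tgt}\t{score:.10g}\n")


def restrict_to_gold(predictions: RankedPredictions, gold: GRN) -> RankedPredictions:
    """Drop entries with either endpoint absent from the gold gene set.

    Interactions among genes outside the gold standard cannot be judged
    (the gold standard is incomplete, not exhaustive), so they are excluded
    from scoring rather than counted as false positives.
    """
    kept = [
        (r, t, s)
        for r, t, s in predictions
        if r in gold and t in gold
    ]
    return RankedPredictions(entries=kept, method_label=predictions.method_label)


def _gold_keys(gold: GRN) -> set[tuple[str, str]]:
    return set(gold.interactions.keys())


def gold_universe_size(gold: GRN) -> int:
    """Default ROC universe: ordered regulator -> gene pairs of the gold
    standard (self-loops included)."""
    return len(gold.regulators()) * len(gold)


@dataclass
class CurveResult:
    auc: float
    points: list[tuple[float, float]]


def pr_curve(predictions: RankedPredictions, gold: GRN) -> CurveResult:
    """Precision-recall curve and AUPR by trapezoidal integration over recall.

    Predictions should already be restricted to gold genes (see
    :func:`restrict_to_gold`); the gold standard must contain at least one
    positive interaction.
    """
    positives = _gold_keys(gold)
    n_pos = len(positives)
    if n_pos == 0:
        raise GRNError("gold standard has no positive interactions")
    tp = fp = 0
    points: list[tuple[float, float]] = []
    for group in predictions.tie_groups():
        for reg, tgt, _s in group:
            if (reg.casefold(), tgt.casefold()) in positives:
                tp += 1
            else:
                fp += 1
        precision = tp / (tp + fp)
        recall = tp / n_pos
        points.append((recall, precision))
    if not points:
        return CurveResult(auc=0.0, points=[])
    # anchor at zero recall with the first observed precision
    recalls = np.array([0.0] + [p[0] for p in points])
    precisions = np.array([points[0][1]] + [p[1] for p in points])
    aupr = float(np.trapezoid(precisions, recalls))
    return CurveResult(auc=aupr, points=points)


def roc_curve(
    predictions: RankedPredictions,
    gold: GRN,
    universe_size: int | None = None,
) -> CurveResult:
    """ROC curve and AUROC over the TF -> gene universe of the gold standard.

    Pairs never ranked by the method are appended as one tied block at the
    end of the list (equivalent to random ordering of the remainder).
    """
    positives = _gold_keys(gold)
    n_pos = len(positives)
    if n_pos == 0:
        raise GRNError("gold standard has no positive interactions")
    if universe_size is None:
        universe_size = gold_universe_size(gold)
    n_neg = universe_size - n_pos
    if n_neg <= 0:
        raise GRNError("ROC universe has no negatives")
    tp = fp = 0
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    for group in predictions.tie_groups():
        for reg, tgt, _s in group:
            if (reg.casefold(), tgt.casefold()) in positives:
                tp += 1
            else:
                fp += 1
        points.append((fp / n_neg, tp / n_pos))
    if tp < n_pos or fp < n_neg:
        points.append((1.0, 1.0))  # unranked remainder as one tied block
    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auroc = float(np.trapezoid(tprs, fprs))
    return CurveResult(auc=auroc, points=points[1:])


@dataclass(frozen=True)
class SetScores:
    mcc: float
    precision: float
    f1: float
    counts: ConfusionCounts


def gr_prediction_scores(
    predicted: set[str], gold: set[str], universe: set[str]
) -> SetScores:
    """Score a predicted gene set against a reference set over a universe.

    MCC is defined as 0 whenever any marginal of the 2x2 table is zero
    (the coefficient is otherwise indeterminate).
    """
    if not universe:
        raise GRNError("universe must be non-empty")
    if not predicted <= universe or not gold <= universe:
        raise GRNError("predicted and gold sets must be subsets of the universe")
    tp = len(predicted & gold)
    fp = len(predicted - gold)
    fn = len(gold - predicted)
    tn = len(universe) - tp - fp - fn
    counts = ConfusionCounts(tp, fp, fn, tn)
    denom = (
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return SetScores(mcc=mcc, precision=precision, f1=f1, counts=counts)


def simpson_index(a: set, b: set) -> float:
    """Simpson similarity |A n B| / min(|A|, |B|).

    Equals 1 whenever one set is a subset of the other and 0 for disjoint
    sets; undefined (error) when both sets are empty.
    """
    if not a and not b:
        raise GRNError("Simpson index undefined for two empty sets")
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))
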