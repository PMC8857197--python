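"""Expression-based GRN inference: mutual information, CLR, and MRNET.

Mutual information between gene expression profiles is estimated with the
maximum-likelihood plug-in estimator on equal-frequency discretized data
(bins = floor(sqrt(conditions)) by default).  Two rankings are derived
from the symmetric MI matrix, both constrained so that only genes from a
supplied TF list can appear as regulators (the causal direction cannot be
read off MI alone):

* **CLR** -- each MI value is converted to a z-score against the row
  backgrounds of both genes, z = max(0, (MI - mu) / sigma), and the edge
  score is sqrt(z_i^2 + z_j^2).
* **MRNET** -- per target, greedy maximum-relevance / minimum-redundancy
  forward selection over the TF candidates; the edge score is the MRMR
  score at selection time.

Rankings produced by external tools (GENIE3, TIGRESS, Inferelator, ...)
are ingested through :func:`import_external_ranking`.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assess import RankedPredictions, read_ranked_tsv
from .core import GRNError


@dataclass
class ExpressionMatrix:
    """Genes x conditions real-valued expression matrix."""

    values: np.ndarray
    gene_ids: list[str]
    condition_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise GRNError("expression matrix shape mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise GRNError("gene ids must be unique")
        if len(self.condition_ids) < 2:
            raise GRNError("need >= 2 conditions")
        if np.isnan(self.values).any():
            raise GRNError("expression matrix contains missing values")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(g) for g in df.index],
            condition_ids=[str(c) for c in df.columns],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.condition_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)


def load_expression_tsv(path: str | os.PathLike) -> ExpressionMatrix:
    from .io import read_expression_tsv

    return ExpressionMatrix.from_dataframe(read_expression_tsv(path))


@dataclass
class MIMatrix:
    """Symmetric gene x gene mutual-information estimates (nats)."""

    values: np.ndarray
    gene_ids: list[str]
    bins: int
    method: str = "ml-plugin-equal-frequency"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise GRNError("MI matrix must be square over the gene ids")
        if np.any(self.values < -1e-12):
            raise GRNError("MI estimates must be non-negative")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise GRNError("MI matrix must be symmetric")


def _equal_frequency_bins(row: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based equal-frequency discretization into ``bins`` symbols."""
    order = np.argsort(row, kind="mergesort")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(row.size)
    return (ranks * bins) // row.size


def default_bins(n_conditions: int) -> int:
    return max(2, int(math.floor(math.sqrt(n_conditions))))


def mutual_information(
    expr: ExpressionMatrix, bins: int | None = None
) -> MIMatrix:
    """Plug-in MI for every gene pair on equal-frequency discretized data.

    Constant genes cannot be discretized informatively; their pairs get
    MI = 0 with a warning.
    """
    if bins is None:
        bins = default_bins(expr.n_conditions)
    if bins < 2:
        raise GRNError("bins must be >= 2")
    if bins > expr.n_conditions:
        raise GRNError("bins cannot exceed the number of conditions")
    n_genes, n_cond = expr.values.shape
    disc = np.zeros((n_genes, n_cond), dtype=np.int64)
    constant = np.zeros(n_genes, dtype=bool)
    for i in range(n_genes):
        row = expr.values[i]
        if np.ptp(row) == 0:
            constant[i] = True
        disc[i] = _equal_frequency_bins(row, bins)
    if constant.any():
        warnings.warn(
            "constant expression rows get MI = 0: "
            + ", ".join(np.array(expr.gene_ids)[constant][:10])
        )
    mi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        if constant[i]:
            continue
        joint_index = disc[i] * bins
        for j in range(i + 1, n_genes):
            if constant[j]:
                continue
            counts = np.bincount(joint_index + disc[j], minlength=bins * bins)
            joint = counts.reshape(bins, bins) / n_cond
            pi = joint.sum(axis=1)
            pj = joint.sum(axis=0)
            outer = np.outer(pi, pj)
            mask = joint > 0
            value = float(np.sum(joint[mask] * np.log(joint[mask] / outer[mask])))
            mi[i, j] = mi[j, i] = max(value, 0.0)
    return MIMatrix(values=mi, gene_ids=list(expr.gene_ids), bins=bins)


def _tf_indices(mi: MIMatrix, tf_list: Sequence[str]) -> list[int]:
    index = {g.casefold(): i for i, g in enumerate(mi.gene_ids)}
    missing = [tf for tf in tf_list if tf.casefold() not in index]
    if missing:
        raise GRNError("TF list contains unknown genes: " + ", ".join(missing[:10]))
    return sorted({index[tf.casefold()] for tf in tf_list})


def clr(mi: MIMatrix, tf_list: Sequence[str]) -> RankedPredictions:
    """Context-likelihood-of-relatedness ranking restricted to TF sources.

    Each gene's MI row (diagonal excluded) defines a background mean and
    SD; z = max(0, (MI - mu) / sigma) with z = 0 where sigma = 0, and the
    score of TF->gene is sqrt(z_TF^2 + z_gene^2).  Self-loops are never
    emitted.
    """
    tf_idx = _tf_indices(mi, tf_list)
    n = len(mi.gene_ids)
    off_diag = ~np.eye(n, dtype=bool)
    mu = np.array([mi.values[i][off_diag[i]].mean() for i in range(n)])
    sd = np.array([mi.values[i][off_diag[i]].std() for i in range(n)])
    entries: list[tuple[str, str, float]] = []
    for i in tf_idx:
        for j in range(n):
            if j == i:
                continue
            zi = (mi.values[i, j] - mu[i]) / sd[i] if sd[i] > 0 else 0.0
            zj = (mi.values[i, j] - mu[j]) / sd[j] if sd[j] > 0 else 0.0
            zi, zj = max(zi, 0.0), max(zj, 0.0)
            entries.append(
                (mi.gene_ids[i], mi.gene_ids[j], math.sqrt(zi * zi + zj * zj))
            )
    return RankedPredictions.from_scores(entries, method_label="CLR")


def mrnet(mi: MIMatrix, tf_list: Sequence[str]) -> RankedPredictions:
    """Maximum-relevance / minimum-redundancy ranking restricted to TFs.

    Per target gene, TFs are greedily selected: the first pick maximizes
    MI with the target; each later candidate is scored MI(candidate,
    target) - mean MI(candidate, selected) and selection stops when the
    best score is no longer positive.  The edge score is the MRMR score at
    selection.
    """
    tf_idx = _tf_indices(mi, tf_list)
    n = len(mi.gene_ids)
    entries: list[tuple[str, str, float]] = []
    for target in range(n):
        candidates = [i for i in tf_idx if i != target]
        if not candidates:
            continue
        selected: list[int] = []
        remaining = list(candidates)
        while remaining:
            scores = []
            for c in remaining:
                relevance = mi.values[c, target]
                redundancy = (
                    float(np.mean([mi.values[c, s] for s in selected]))
                    if selected
                    else 0.0
                )
                scores.append(relevance - redundancy)
            best_pos = int(np.argmax(scores))
            best_score = scores[best_pos]
            if selected and best_score <= 0:
                break
            chosen = remaining.pop(best_pos)
            if best_score > 0 or not selected:
                entries.append(
                    (mi.gene_ids[chosen], mi.gene_ids[target], float(best_score))
                )
            selected.append(chosen)
            if best_score <= 0:
                break
    return RankedPredictions.from_scores(entries, method_label="MRNET")


def import_external_ranking(
    path: str | os.PathLike, method_label: str
) -> RankedPredictions:
    """Load a ``regulator target score`` TSV from an external inference tool."""
    return read_ranked_tsv(path, method_label=method_label)
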