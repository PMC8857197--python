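"""Binding-site inference: PWMs, exact-p-value scanning, regulon extension.

Regulons of TFs with at least three strong-evidence targets are extended
by sequence analysis: the upstream regions (up to -300..+50 relative to
the translation start, truncated so they never overlap the neighboring
gene's annotated extent) of the known targets yield a position weight
matrix, every candidate upstream region is scanned with the PWM on both
strands, and hits with p < 1e-4 become predicted interactions.

P-values are *exact* under the 0-order background model: the log-odds
scores are discretized to a fixed granularity and the distribution of the
total score of a random width-w word is computed by dynamic programming,
so a hit's p-value is the true probability that a random word scores at
least as high (up to the stated discretization bound).

The same machinery supports statistical validation of ChIP-supported weak
interactions (intersection of ChIP evidence with motif hits) and regulogs
transfer of interactions between organisms constrained to strict 1:1
orthologs of both TF and target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assess import RankedPredictions
from .core import (
    Effect,
    EvidenceLevel,
    GRN,
    GRNError,
    RegulatoryInteraction,
)
from .io import validate_one_to_one

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: Log-odds floor (bits); keeps zero-probability columns finite while far
#: below any attainable match score.
LOGODDS_FLOOR = -30.0
#: Discretization granularity for exact p-values (log-odds units).
SCORE_GRANULARITY = 1e-3

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class UpstreamRegion:
    """Upstream regulatory region of a gene, on the coding strand."""

    gene: str
    sequence: str
    genomic_span: tuple[str, int, int, str]  # replicon, start, end, strand

    def __post_init__(self) -> None:
        if len(self.sequence) > 351:
            raise GRNError("upstream region exceeds the 351-bp window")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise GRNError(f"non-ACGTN characters in region of {self.gene}")


def extract_upstream(
    gene_table: pd.DataFrame,
    genome: Mapping[str, str],
    window: tuple[int, int] = (-300, 50),
) -> list[UpstreamRegion]:
    """Extract non-overlapping upstream regions for every gene.

    Coordinates are 1-based inclusive; the translation start is the
    strand-aware annotated gene start.  For a + strand gene starting at s
    the candidate span is [s-300, s+50], truncated at the nearest annotated
    boundary of the adjacent upstream gene (regardless of its strand) and
    at the replicon ends; - strand genes are mirrored and the sequence
    reverse-complemented.
    """
    lo_off, hi_off = window
    regions: list[UpstreamRegion] = []
    for replicon, group in gene_table.groupby("replicon", sort=True):
        if replicon not in genome:
            raise GRNError(f"replicon {replicon!r} absent from genome FASTA")
        seq = genome[replicon]
        length = len(seq)
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        for _idx, row in group.iterrows():
            if row["strand"] == "+":
                tss = int(row["start"])
                lo = tss + lo_off
                hi = min(tss + hi_off, length)
                others = ends[(ends < tss) & (group["locus_tag"] != row["locus_tag"]).to_numpy()]
                if others.size:
                    lo = max(lo, int(others.max()) + 1)
                lo = max(lo, 1)
                if hi < lo:
                    warnings.warn(f"empty upstream region for {row['locus_tag']}")
                    continue
                regions.append(
                    UpstreamRegion(
                        gene=row["locus_tag"],
                        sequence=seq[lo - 1 : hi].upper(),
                        genomic_span=(replicon, lo, hi, "+"),
                    )
                )
            elif row["strand"] == "-":
                tss = int(row["end"])
                hi = tss - lo_off  # -(-300) = +300 downstream on genome
                lo = max(tss - hi_off, 1)
                others = starts[(starts > tss) & (group["locus_tag"] != row["locus_tag"]).to_numpy()]
                if others.size:
                    hi = min(hi, int(others.min()) - 1)
                hi = min(hi, length)
                if hi < lo:
                    warnings.warn(f"empty upstream region for {row['locus_tag']}")
                    continue
                regions.append(
                    UpstreamRegion(
                        gene=row["locus_tag"],
                        sequence=revcomp(seq[lo - 1 : hi].upper()),
                        genomic_span=(replicon, lo, hi, "-"),
                    )
                )
            else:
                raise GRNError(f"unknown strand for {row['locus_tag']}")
    return regions


UNIFORM_BACKGROUND = np.full(4, 0.25)


@dataclass
class PWM:
    """Position weight matrix: per-position probabilities over ACGT."""

    tf: str
    matrix: np.ndarray  # shape (width, 4), rows sum to 1
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    source_sites: int = 3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise GRNError("PWM matrix must have shape (width, 4)")
        if self.width < 4:
            raise GRNError("PWM width must be >= 4")
        if self.source_sites < 3:
            raise GRNError("PWM must derive from >= 3 sites")
        if np.any(np.abs(self.matrix.sum(axis=1) - 1.0) > 1e-9):
            raise GRNError("PWM columns must each sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise GRNError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2(p / background), floored for zero probabilities."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix / self.background[None, :])
        return np.maximum(lo, LOGODDS_FLOOR)

    def information_content(self) -> float:
        """Total IC in bits against a uniform background."""
        p = np.maximum(self.matrix, 1e-12)
        return float(np.sum(p * np.log2(p)) + 2.0 * self.width)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def build_pwm(
    tf: str,
    site_sequences: Sequence[str],
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
) -> PWM:
    """Build a PWM from >= 3 equal-width aligned binding sites.

    Column probabilities are (count + pseudocount * background) /
    (n_sites + pseudocount).
    """
    if len(site_sequences) < 3:
        raise GRNError("PWM construction requires at least 3 binding sites")
    widths = {len(s) for s in site_sequences}
    if len(widths) != 1:
        raise GRNError(f"binding sites have mixed widths: {sorted(widths)}")
    width = widths.pop()
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    counts = np.zeros((width, 4))
    for site in site_sequences:
        codes = encode(site.upper())
        if np.any(codes > 3):
            raise GRNError(f"binding site contains non-ACGT characters: {site}")
        counts[np.arange(width), codes] += 1.0
    matrix = (counts + pseudocount * bg[None, :]) / (len(site_sequences) + pseudocount)
    return PWM(tf=tf, matrix=matrix, background=bg, source_sites=len(site_sequences))


@dataclass(frozen=True)
class MotifHit:
    tf: str
    gene: str
    position: int  # 0-based offset within the region, forward coordinates
    strand: str
    score: float  # log-odds (bits)
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise GRNError("p-value must lie in (0, 1]")


class _ScoreModel:
    """Integer-discretized log-odds scores with an exact DP null distribution."""

    def __init__(self, pwm: PWM, granularity: float = SCORE_GRANULARITY):
        self.granularity = granularity
        logodds = pwm.log_odds()
        self.int_scores = np.round(logodds / granularity).astype(np.int64)
        self.rc_int_scores = self.int_scores[::-1, ::-1].copy()
        self.background = pwm.background
        self.width = pwm.width
        self._tail = self._null_tail()

    def _null_tail(self) -> tuple[int, np.ndarray]:
        mins = self.int_scores.min(axis=1)
        maxs = self.int_scores.max(axis=1)
        lo, hi = int(mins.sum()), int(maxs.sum())
        pmf = np.zeros(hi - lo + 1)
        pmf[0] = 1.0
        offset = 0  # current pmf[i] = P(sum == lo_partial + i)
        cur_lo = 0
        span = 1
        for pos in range(self.width):
            new_lo = cur_lo + int(mins[pos])
            new_span = span + int(maxs[pos] - mins[pos])
            new = np.zeros(new_span)
            for b in range(4):
                shift = int(self.int_scores[pos, b] - mins[pos])
                new[shift : shift + span] += pmf[:span] * self.background[b]
            pmf = new
            cur_lo = new_lo
            span = new_span
        # tail[i] = P(score_int >= cur_lo + i)
        tail = np.cumsum(pmf[::-1])[::-1]
        return cur_lo, tail

    def p_value(self, int_score: int) -> float:
        lo, tail = self._tail
        idx = int_score - lo
        if idx <= 0:
            return 1.0
        if idx >= tail.size:
            return float(tail[-1]) if tail.size else 1.0
        return float(tail[idx])

    def window_scores(self, codes: np.ndarray, reverse: bool = False) -> np.ndarray:
        """Integer score of every width-w window (N bases poison a window)."""
        w = self.width
        if codes.size < w:
            return np.empty(0, dtype=np.int64)
        mat = self.rc_int_scores if reverse else self.int_scores
        padded = np.column_stack([mat, np.full(w, np.iinfo(np.int32).min // w, dtype=np.int64)])
        windows = np.lib.stride_tricks.sliding_window_view(codes, w)
        return padded[np.arange(w)[None, :], windows].sum(axis=1)


def scan(
    pwm: PWM,
    regions: Sequence[UpstreamRegion],
    p_threshold: float = 1e-4,
    granularity: float = SCORE_GRANULARITY,
) -> list[MotifHit]:
    """Scan regions on both strands, keeping the best hit per gene.

    A hit's p-value is the exact probability, under the 0-order background,
    that a random width-w word scores at least as high; hits with
    p < ``p_threshold`` are returned.  Regions shorter than the PWM are
    skipped with a log entry.
    """
    if not 0.0 < p_threshold < 1.0:
        raise GRNError("p_threshold must lie in (0, 1)")
    model = _ScoreModel(pwm, granularity)
    hits: list[MotifHit] = []
    for region in regions:
        codes = encode(region.sequence.upper())
        if codes.size < pwm.width:
            logger.info(
                "region for %s shorter than PWM width %d; skipped",
                region.gene,
                pwm.width,
            )
            continue
        fwd = model.window_scores(codes, reverse=False)
        rev = model.window_scores(codes, reverse=True)
        best_fwd = int(fwd.max())
        best_rev = int(rev.max())
        if best_fwd >= best_rev:
            best, pos, strand = best_fwd, int(fwd.argmax()), "+"
        else:
            best, pos, strand = best_rev, int(rev.argmax()), "-"
        p = model.p_value(best)
        if p < p_threshold:
            hits.append(
                MotifHit(
                    tf=pwm.tf,
                    gene=region.gene,
                    position=pos,
                    strand=strand,
                    score=best * granularity,
                    p_value=p,
                )
            )
    return hits


def estimate_background(regions: Sequence[UpstreamRegion]) -> np.ndarray:
    """0-order nucleotide frequencies over a region set (N excluded)."""
    counts = np.zeros(4)
    for region in regions:
        codes = encode(region.sequence.upper())
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        return UNIFORM_BACKGROUND.copy()
    freqs = counts / total
    return np.maximum(freqs, 1e-3) / np.maximum(freqs, 1e-3).sum()


def discover_motif(
    tf: str,
    regions: Sequence[UpstreamRegion],
    width: int = 12,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
) -> PWM:
    """Information-content-maximizing common-window motif search.

    A deliberately simple seed-and-align procedure: every width-w window of
    the first region (both strands) seeds an alignment; for each seed, the
    best-matching window (minimum mismatches, either strand) is chosen in
    every region; the alignment with the highest total information content
    yields the PWM.  External MEME-format motifs can be imported instead
    for parity with published discovery tools.
    """
    if len(regions) < 3:
        raise GRNError("motif discovery requires >= 3 regions")
    seqs = [r.sequence.upper() for r in regions]
    if any(len(s) < width for s in seqs):
        raise GRNError("all regions must be at least as long as the motif width")
    window_sets = []
    for s in seqs:
        codes = encode(s)
        fwd = np.lib.stride_tricks.sliding_window_view(codes, width)
        rc_codes = encode(revcomp(s))
        rev = np.lib.stride_tricks.sliding_window_view(rc_codes, width)
        window_sets.append(np.vstack([fwd, rev]))

    seeds = window_sets[0]
    valid_seed = ~np.any(seeds > 3, axis=1)
    best_sites: list[np.ndarray] | None = None
    best_ic = -np.inf
    for seed in seeds[valid_seed]:
        chosen: list[np.ndarray] = []
        total_matches = 0
        for windows in window_sets:
            matches = np.sum(windows == seed[None, :], axis=1)
            matches[np.any(windows > 3, axis=1)] = -1
            idx = int(matches.argmax())
            chosen.append(windows[idx])
            total_matches += int(matches[idx])
        counts = np.zeros((width, 4))
        for site in chosen:
            counts[np.arange(width), site] += 1.0
        probs = counts / len(chosen)
        with np.errstate(divide="ignore", invalid="ignore"):
            col_ic = 2.0 + np.nansum(
                np.where(probs > 0, probs * np.log2(probs), 0.0), axis=1
            )
        ic = float(col_ic.sum())
        if ic > best_ic:
            best_ic = ic
            best_sites = chosen
    if best_sites is None:
        raise GRNError("no valid seed windows (regions all contain N runs)")
    sites = ["".join(BASES[c] for c in site) for site in best_sites]
    return build_pwm(tf, sites, background=background, pseudocount=pseudocount)


def extend_regulons(
    prior: GRN,
    regions: Sequence[UpstreamRegion],
    p_threshold: float = 1e-4,
    width: int = 12,
    min_targets: int = 3,
    background: np.ndarray | None = None,
    pwms: Mapping[str, PWM] | None = None,
) -> RankedPredictions:
    """Extend the regulons of a strong-evidence prior network by scanning.

    For every TF with >= ``min_targets`` prior targets that have upstream
    regions, a PWM is obtained (built-in discovery, or imported motifs via
    ``pwms``) and all regions are scanned; hits become predictions ranked
    by ascending p-value (score = -log10 p).  TFs below the target floor
    are skipped with a log entry; an empty prior yields an empty ranking.
    """
    region_of = {r.gene.casefold(): r for r in regions}
    if background is None:
        background = estimate_background(regions)
    targets_of: dict[str, list[str]] = {}
    for (rkey, tkey), inter in prior.interactions.items():
        targets_of.setdefault(prior.genes[rkey].locus_tag, []).append(tkey)
    entries: list[tuple[str, str, float]] = []
    for tf in sorted(targets_of):
        target_regions = [
            region_of[t] for t in sorted(set(targets_of[tf])) if t in region_of
        ]
        if len(target_regions) < min_targets:
            logger.info(
                "TF %s has %d prior targets with regions (< %d); skipped",
                tf,
                len(target_regions),
                min_targets,
            )
            continue
        if pwms is not None and tf in pwms:
            pwm = pwms[tf]
        else:
            pwm = discover_motif(tf, target_regions, width=width, background=background)
        for hit in scan(pwm, regions, p_threshold=p_threshold):
            entries.append((tf, region_of[hit.gene.casefold()].gene, -np.log10(hit.p_value)))
    return RankedPredictions.from_scores(entries, method_label="binding-sites")


def chip_validate(
    weak_chip: Iterable[RegulatoryInteraction],
    motif_hits: Iterable[MotifHit],
) -> list[RegulatoryInteraction]:
    """Reclassify ChIP-supported weak interactions confirmed by motif hits.

    Returns the interactions present in both inputs with evidence upgraded
    to strong; the caller merges them back into the network.
    """
    hit_keys = {(h.tf.casefold(), h.gene.casefold()) for h in motif_hits}
    validated = []
    for inter in weak_chip:
        if inter.key in hit_keys:
            validated.append(
                RegulatoryInteraction(
                    regulator=inter.regulator,
                    target=inter.target,
                    effect=inter.effect,
                    evidence=EvidenceLevel.STRONG,
                    experiments=inter.experiments | {"motif statistical validation"},
                    sources=inter.sources,
                )
            )
    return validated


def regulogs_transfer(
    source_strong: GRN,
    source_regions: Sequence[UpstreamRegion],
    target_regions: Sequence[UpstreamRegion],
    orthologs: Mapping[str, str] | Iterable[tuple[str, str]],
    p_threshold: float = 1e-4,
    width: int = 12,
    min_targets: int = 3,
    target_strong: GRN | None = None,
    label: str = "regulogs",
) -> GRN:
    """Transfer regulons across organisms through strict 1:1 orthologs.

    PWMs built from the source organism's strong regulons scan the target
    organism's upstream regions; a predicted interaction is kept only when
    both the TF and the hit gene have a one-to-one ortholog in the other
    organism.  Predictions are sorted by p-value with one best-scoring
    record per pair, and the target organism's original strong interactions
    (when provided) are placed ahead of the predictions in the complemented
    network.
    """
    if not isinstance(orthologs, Mapping):
        orthologs = validate_one_to_one(list(orthologs))
    else:
        orthologs = validate_one_to_one(list(orthologs.items()))
    fwd = {a.casefold(): b for a, b in orthologs.items()}
    back = {b.casefold() for b in orthologs.values()}

    source_map = {r.gene.casefold(): r for r in source_regions}
    background = estimate_background(source_regions)
    targets_of: dict[str, list[str]] = {}
    for (rkey, tkey), _inter in source_strong.interactions.items():
        targets_of.setdefault(source_strong.genes[rkey].locus_tag, []).append(tkey)

    predictions: list[tuple[str, str, float]] = []
    for tf in sorted(targets_of):
        if tf.casefold() not in fwd:
            continue
        tf_ortholog = fwd[tf.casefold()]
        prior_regions = [
            source_map[t] for t in sorted(set(targets_of[tf])) if t in source_map
        ]
        if len(prior_regions) < min_targets:
            logger.info("TF %s below the %d-target floor; skipped", tf, min_targets)
            continue
        pwm = discover_motif(tf, prior_regions, width=width, background=background)
        for hit in scan(pwm, target_regions, p_threshold=p_threshold):
            if hit.gene.casefold() in back:
                predictions.append((tf_ortholog, hit.gene, hit.p_value))

    best: dict[tuple[str, str], float] = {}
    for reg, tgt, p in predictions:
        key = (reg.casefold(), tgt.casefold())
        if key not in best or p < best[key][2]:
            best[key] = (reg, tgt, p)
    ordered = sorted(best.values(), key=lambda e: (e[2], e[0], e[1]))

    complemented = GRN(label=label)
    if target_strong is not None:
        for inter in target_strong.interactions.values():
            complemented.add_interaction(inter)
    for reg, tgt, p in ordered:
        complemented.add_interaction(
            RegulatoryInteraction(
                regulator=reg,
                target=tgt,
                effect=Effect.UNKNOWN,
                evidence=EvidenceLevel.WEAK,
                experiments=frozenset({"regulog-transfer"}),
                sources=frozenset({f"p={p:.3g}"}),
            )
        )
    return complemented


def grn_wide_orthologs(
    net_a: GRN, net_b: GRN, orthologs: Mapping[str, str]
) -> set[tuple[str, str]]:
    """Ortholog pairs whose members are both present in their GRNs."""
    return {
        (a, b)
        for a, b in orthologs.items()
        if a in net_a and b in net_b
    }
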