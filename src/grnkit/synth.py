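"""Synthetic data with the statistical structure the analysis assumes.

Every generator is a pure function of its configuration (seed included),
so fixtures are reproducible and no external downloads are needed.  The
generators emulate, at configurable scale:

* directed scale-free GRNs: TF out-degrees drawn from a discrete power
  law (target exponent ``target_alpha``), targets attached preferentially,
  interactions labeled strong/weak at a configurable strong fraction,
* expression data from a known network: a linear-Gaussian structural
  equation model (roots ~ N(0,1); each target is the signed weighted sum
  of its regulators plus Gaussian noise; cycles resolved by damped
  fixed-point iteration),
* genomes with planted binding sites: i.i.d. background at a given GC
  content, one PWM per strong TF at a target per-column information
  content, one sampled site embedded in each true target's upstream
  window,
* a paired "orthologous organism": a relabeled copy with a random
  fraction of genes deleted and the surviving 1:1 correspondence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Effect,
    EvidenceLevel,
    GRN,
    GRNError,
    Gene,
    RegulatoryInteraction,
)
from .expression import ExpressionMatrix
from .motifs import BASES, PWM, revcomp


@dataclass
class SynthConfig:
    """Study conditions for the synthetic test bed.

    Defaults mirror the analysed organism where the analysis fixes them:
    137 expression conditions (the transcriptome compendium size), ~6%
    strong-evidence interactions (the curated strong fraction), GC-rich
    genomes (0.72, Streptomyces-like), and a scale-free exponent inside
    the (2, 3] band typical of bacterial GRNs.
    """

    n_genes: int = 500
    n_tfs: int = 50
    target_alpha: float = 2.5
    n_conditions: int = 137
    noise_sd: float = 0.5
    strong_fraction: float = 0.06
    motif_width: int = 12
    motif_ic_per_column: float = 1.5
    gc_content: float = 0.72
    ortholog_retention_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 1 or self.n_tfs > self.n_genes:
            raise GRNError("need 1 <= n_tfs <= n_genes")
        if not 2.0 < self.target_alpha <= 3.5:
            raise GRNError("target_alpha expected in (2, 3.5]")
        if not 0.0 < self.ortholog_retention_fraction <= 1.0:
            raise GRNError("retention fraction must lie in (0, 1]")
        if self.seed is None:
            raise GRNError("seed is mandatory")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), stream))


def _sample_power_law(rng: np.random.Generator, alpha: float, size: int,
                      kmax: int) -> np.ndarray:
    """Discrete power-law draws P(k) ~ k^-alpha on 1..kmax (inverse CDF)."""
    ks = np.arange(1, kmax + 1, dtype=float)
    pmf = ks ** (-alpha)
    pmf /= pmf.sum()
    cdf = np.cumsum(pmf)
    u = rng.random(size)
    return np.searchsorted(cdf, u) + 1


def gene_tag(i: int, prefix: str = "SG") -> str:
    return f"{prefix}{i:05d}"


def sample_grn(config: SynthConfig, label: str = "synthetic") -> GRN:
    """Scale-free directed GRN with a designated TF subset.

    TF out-degrees follow a discrete power law with exponent
    ``target_alpha`` (capped at the number of available targets, with a
    warning on infeasible demand); targets are attached preferentially by
    in-degree, evidence labels are strong with probability
    ``strong_fraction``, and the draw is deterministic under the seed.
    """
    rng = config.rng(1)
    n, m = config.n_genes, config.n_tfs
    tags = [gene_tag(i) for i in range(n)]
    tf_tags = tags[:m]
    kmax = n  # self-loops permitted, so a TF can regulate up to n genes
    out_degrees = _sample_power_law(rng, config.target_alpha, m, kmax)
    if out_degrees.sum() > m * n:
        warnings.warn("degree demand exceeds capacity; capping at n_genes")
        out_degrees = np.minimum(out_degrees, n)
    # hubs first so preferential attachment has mass to work with
    out_degrees = np.sort(out_degrees)[::-1]
    attractiveness = np.ones(n)
    interactions: list[RegulatoryInteraction] = []
    for tf_i, k in enumerate(out_degrees):
        k = int(min(k, n))
        weights = attractiveness / attractiveness.sum()
        targets = rng.choice(n, size=k, replace=False, p=weights)
        attractiveness[targets] += 1.0
        strong = rng.random(k) < config.strong_fraction
        effects = rng.random(k) < 0.5
        for j, tgt in enumerate(targets):
            interactions.append(
                RegulatoryInteraction(
                    regulator=tf_tags[tf_i],
                    target=tags[tgt],
                    effect=Effect.ACTIVATION if effects[j] else Effect.REPRESSION,
                    evidence=EvidenceLevel.STRONG if strong[j] else EvidenceLevel.WEAK,
                    experiments=frozenset(
                        {"EMSA"} if strong[j] else {"microarray"}
                    ),
                    sources=frozenset({"synthetic"}),
                )
            )
    genes = [Gene(t, replicon="chr") for t in tags]
    net = GRN(interactions=interactions, genes=genes, label=label)
    return net


def simulate_expression(network: GRN, config: SynthConfig) -> ExpressionMatrix:
    """Linear-Gaussian SEM expression for every gene of the network.

    Per condition, root genes (no regulators) draw from N(0, 1); every
    regulated gene is the sum of (+/- w) times its regulators' values
    (w ~ U(0.5, 1.5), sign from the annotated effect) plus N(0, noise_sd)
    noise.  The coupled system (feedback loops included) is solved exactly
    as x = (I - W)^-1 e; an ill-conditioned system (a loop with weight
    product ~1) is an error naming the affected genes.
    """
    rng = config.rng(2)
    tags = network.gene_tags()
    index = {t.casefold(): i for i, t in enumerate(tags)}
    n = len(tags)
    weight_matrix = np.zeros((n, n))  # W[i, j]: effect of regulator j on i
    for (rkey, tkey), inter in network.interactions.items():
        w = rng.uniform(0.5, 1.5)
        if inter.effect == Effect.REPRESSION:
            w = -w
        elif inter.effect not in (Effect.ACTIVATION, Effect.REPRESSION):
            w = w if rng.random() < 0.5 else -w
        weight_matrix[index[tkey], index[rkey]] = w
    regulated = weight_matrix.any(axis=1)
    noise = rng.normal(0.0, 1.0, size=(n, config.n_conditions))
    noise[regulated] *= config.noise_sd

    # exact SEM solution x = (I - W)^-1 e; feedback loops are handled by
    # the solve rather than iteration (the fixed point exists whenever
    # no loop has weight product exactly 1)
    system = np.eye(n) - weight_matrix
    if np.linalg.cond(system) > 1e10:
        cycles = np.nonzero(regulated)[0]
        raise GRNError(
            "expression simulation has no stable solution for: "
            + ", ".join(tags[i] for i in cycles[:10])
        )
    values = np.linalg.solve(system, noise)
    conditions = [f"cond{j:03d}" for j in range(config.n_conditions)]
    return ExpressionMatrix(values=values, gene_ids=tags, condition_ids=conditions)


def _consensus_probability(ic_per_column: float) -> float:
    """Consensus-base probability p giving per-column IC (uniform bg),
    with the remaining mass split over the other three bases."""

    def ic(p: float) -> float:
        q = (1.0 - p) / 3.0
        entropy = -(p * math.log2(p) + 3 * q * math.log2(q)) if q > 0 else 0.0
        return 2.0 - entropy

    lo, hi = 0.2500001, 0.9999999
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if ic(mid) < ic_per_column:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def plant_genome(
    network: GRN,
    config: SynthConfig,
    prefix: str = "chr",
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame, dict[str, PWM]]:
    """Genome FASTA, gene table, true-site table, and the planted PWMs.

    Genes are laid out in tandem on one replicon with 400-bp intergenic
    gaps (so each full -300..+50 upstream window is available); the
    background is i.i.d. with the configured GC content.  One PWM per
    regulator of ``network`` is drawn at ``motif_ic_per_column`` bits per
    column, and a site sampled from it is embedded at a random offset and
    strand in the upstream window of each of its targets.
    """
    if config.motif_width < 6:
        raise GRNError("motif_width must be >= 6")
    window = 351
    if config.motif_width > window - 51:
        raise GRNError("motif width does not fit the upstream window")
    rng = config.rng(3)
    tags = network.gene_tags()
    gene_len, gap = 600, 400
    rows = []
    pos = gap + 1
    for tag in tags:
        rows.append((tag, prefix, pos, pos + gene_len - 1, "+"))
        pos += gene_len + gap
    table = pd.DataFrame(rows, columns=["locus_tag", "replicon", "start", "end", "strand"])
    length = pos
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome_codes = rng.choice(4, size=length, p=probs)

    p_cons = _consensus_probability(config.motif_ic_per_column)
    pwms: dict[str, PWM] = {}
    site_rows = []
    starts = dict(zip(table["locus_tag"], table["start"]))
    for tf in network.regulators():
        consensus = rng.integers(0, 4, size=config.motif_width)
        matrix = np.full((config.motif_width, 4), (1 - p_cons) / 3)
        matrix[np.arange(config.motif_width), consensus] = p_cons
        pwms[tf] = PWM(tf=tf, matrix=matrix, background=probs.copy(), source_sites=3)
        for (rkey, tkey), _inter in network.interactions.items():
            if network.genes[rkey].locus_tag != tf:
                continue
            target = network.genes[tkey].locus_tag
            site_codes = np.array(
                [rng.choice(4, p=matrix[i]) for i in range(config.motif_width)]
            )
            tss = starts[target]
            lo = max(tss - 300, 1)
            hi = min(tss + 50, length)
            offset = int(rng.integers(lo, hi - config.motif_width + 2))
            strand = "+" if rng.random() < 0.5 else "-"
            planted = site_codes if strand == "+" else (3 - site_codes)[::-1]
            genome_codes[offset - 1 : offset - 1 + config.motif_width] = planted
            site_rows.append((tf, target, offset, strand,
                              "".join(BASES[c] for c in site_codes)))
    genome = {prefix: "".join(BASES[c] for c in genome_codes)}
    sites = pd.DataFrame(
        site_rows, columns=["tf", "gene", "genomic_start", "strand", "site"]
    )
    return genome, table, sites, pwms


def make_ortholog_pair(
    network: GRN, config: SynthConfig, prefix: str = "OG"
) -> tuple[GRN, dict[str, str]]:
    """A paired "organism B": relabeled copy with random gene loss.

    A random (1 - retention) fraction of genes is deleted (edges dropped
    accordingly); the returned map contains only the surviving 1:1 pairs.
    """
    rng = config.rng(4)
    tags = network.gene_tags()
    n_keep = int(round(config.ortholog_retention_fraction * len(tags)))
    keep = set(rng.choice(len(tags), size=n_keep, replace=False))
    mapping = {
        tag: f"{prefix}{i:05d}" for i, tag in enumerate(tags) if i in keep
    }
    interactions = []
    for inter in network.interactions.values():
        reg = network.genes[inter.key[0]].locus_tag
        tgt = network.genes[inter.key[1]].locus_tag
        if reg in mapping and tgt in mapping:
            interactions.append(
                RegulatoryInteraction(
                    regulator=mapping[reg],
                    target=mapping[tgt],
                    effect=inter.effect,
                    evidence=inter.evidence,
                    experiments=inter.experiments,
                    sources=inter.sources,
                )
            )
    genes = [Gene(mapping[t], replicon="chr") for t in tags if t in mapping]
    net_b = GRN(interactions=interactions, genes=genes, label=f"{network.label}_orthoB")
    if not any(net_b.regulators()):
        warnings.warn("no TF survived the ortholog deletion")
    return net_b, mapping
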