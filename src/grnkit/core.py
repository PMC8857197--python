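"""Core data model for evidence-graded gene regulatory networks.

A GRN is a directed graph whose nodes are genes (keyed by locus tag) and
whose edges are regulatory interactions between a regulator (a transcription
factor or sigma factor) and a target gene.  Each interaction carries the
effect of the regulation (activation / repression / dual / unknown), the set
of experiment types that support it, provenance strings, and a two-level
evidence grade:

* ``strong`` -- at least one supporting experiment demonstrates physical
  binding of the regulator upstream of the target (e.g. EMSA with purified
  protein, in vitro transcription, DNase footprinting).
* ``weak`` -- the regulatory effect may be indirect or the binding site is
  only hypothesized (e.g. ChIP methods, transcriptomics, RT-PCR).

This module also implements meta-curation: merging several curated networks
into one non-redundant network on locus-tag keys, resolving evidence to the
maximum grade and conflicting effects to ``dual``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class GRNError(ValueError):
    """Raised on contract violations in network construction or queries."""


class EvidenceClassificationError(GRNError):
    """Raised when an experiment type is absent from the catalog."""


@enum.unique
class EvidenceLevel(enum.IntEnum):
    """Two-level evidence grade; ``STRONG > WEAK`` so ``max()`` resolves merges."""

    WEAK = 0
    STRONG = 1

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name.lower()

    @classmethod
    def parse(cls, text: str) -> "EvidenceLevel":
        try:
            return cls[text.strip().upper()]
        except KeyError:
            raise GRNError(f"unknown evidence level: {text!r}") from None


@enum.unique
class Effect(enum.Enum):
    ACTIVATION = "activation"
    REPRESSION = "repression"
    DUAL = "dual"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "Effect":
        key = text.strip().lower()
        # common curation shorthands
        aliases = {"+": "activation", "-": "repression", "?": "unknown",
                   "+-": "dual", "-+": "dual", "activator": "activation",
                   "repressor": "repression"}
        key = aliases.get(key, key)
        try:
            return cls(key)
        except ValueError:
            raise GRNError(f"unknown effect: {text!r}") from None


def combine_effects(a: Effect, b: Effect) -> Effect:
    """Resolve the effect of a merged interaction.

    ``unknown`` defers to any informative effect; an activation/repression
    conflict (or anything involving ``dual``) resolves to ``dual``.
    """
    if a == b:
        return a
    if a == Effect.UNKNOWN:
        return b
    if b == Effect.UNKNOWN:
        return a
    return Effect.DUAL


@dataclass(frozen=True)
class Gene:
    """A gene identified by its locus tag (the canonical key)."""

    locus_tag: str
    name: str | None = None
    replicon: str | None = None

    def __post_init__(self) -> None:
        if not self.locus_tag:
            raise GRNError("locus_tag must be non-empty")

    @property
    def key(self) -> str:
        """Case-insensitive comparison key (locus tags are case-preserved)."""
        return self.locus_tag.casefold()


@dataclass
class RegulatoryInteraction:
    """A directed regulatory interaction identified by (regulator, target)."""

    regulator: str
    target: str
    effect: Effect = Effect.UNKNOWN
    evidence: EvidenceLevel = EvidenceLevel.WEAK
    experiments: frozenset[str] = frozenset()
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.regulator or not self.target:
            raise GRNError("interaction endpoints must be non-empty locus tags")
        self.experiments = frozenset(self.experiments)
        self.sources = frozenset(self.sources)

    @property
    def key(self) -> tuple[str, str]:
        return (self.regulator.casefold(), self.target.casefold())

    def merged_with(self, other: "RegulatoryInteraction") -> "RegulatoryInteraction":
        if self.key != other.key:
            raise GRNError("cannot merge interactions with different keys")
        return RegulatoryInteraction(
            regulator=self.regulator,
            target=self.target,
            effect=combine_effects(self.effect, other.effect),
            evidence=max(self.evidence, other.evidence),
            experiments=self.experiments | other.experiments,
            sources=self.sources | other.sources,
        )


#: Seed experiment-type catalog.  Experiments proving physical TF binding
#: upstream of the target are graded strong; ChIP-family and purely
#: transcriptomic read-outs are weak.  User catalogs extend/override this.
DEFAULT_CATALOG: dict[str, EvidenceLevel] = {
    "EMSA": EvidenceLevel.STRONG,
    "in vitro transcription": EvidenceLevel.STRONG,
    "footprinting": EvidenceLevel.STRONG,
    "DNase footprinting": EvidenceLevel.STRONG,
    "ChIP": EvidenceLevel.WEAK,
    "ChIP-chip": EvidenceLevel.WEAK,
    "ChIP-seq": EvidenceLevel.WEAK,
    "ChIP-qPCR": EvidenceLevel.WEAK,
    "ChIP-exo": EvidenceLevel.WEAK,
    "microarray": EvidenceLevel.WEAK,
    "RNA-seq": EvidenceLevel.WEAK,
    "RT-PCR": EvidenceLevel.WEAK,
    "qRT-PCR": EvidenceLevel.WEAK,
    "DACA": EvidenceLevel.WEAK,
    "knockout": EvidenceLevel.WEAK,
    "regulog-transfer": EvidenceLevel.WEAK,
}


class ExperimentCatalog:
    """Total mapping experiment-type string -> :class:`EvidenceLevel`.

    Lookups are case-insensitive on a normalized key; unknown experiment
    strings are rejected rather than silently defaulted to weak.
    """

    def __init__(self, mapping: Mapping[str, EvidenceLevel] | None = None):
        source = dict(DEFAULT_CATALOG) if mapping is None else dict(mapping)
        self._mapping: dict[str, EvidenceLevel] = {}
        self._display: dict[str, str] = {}
        for name, level in source.items():
            self.add(name, level)

    @staticmethod
    def _norm(name: str) -> str:
        return " ".join(name.split()).casefold()

    def add(self, name: str, level: EvidenceLevel | str) -> None:
        if isinstance(level, str):
            level = EvidenceLevel.parse(level)
        key = self._norm(name)
        self._mapping[key] = level
        self._display[key] = name

    def __contains__(self, name: str) -> bool:
        return self._norm(name) in self._mapping

    def __getitem__(self, name: str) -> EvidenceLevel:
        try:
            return self._mapping[self._norm(name)]
        except KeyError:
            raise EvidenceClassificationError(
                f"experiment type not in catalog: {name!r}"
            ) from None

    def items(self):
        return ((self._display[k], v) for k, v in self._mapping.items())

    @classmethod
    def default(cls) -> "ExperimentCatalog":
        return cls()


def classify_evidence(
    experiments: Iterable[str], catalog: ExperimentCatalog | None = None
) -> EvidenceLevel:
    """Grade an interaction from its supporting experiment types.

    Returns ``STRONG`` iff at least one experiment maps to strong; the empty
    set is vacuously ``WEAK``.  Unknown experiment strings raise
    :class:`EvidenceClassificationError` naming the offender.
    """
    catalog = catalog or ExperimentCatalog.default()
    level = EvidenceLevel.WEAK
    for exp in experiments:
        level = max(level, catalog[exp])
    return level


class GRN:
    """A gene regulatory network: genes plus keyed regulatory interactions.

    Interaction identity is the (regulator, target) locus-tag pair, compared
    case-insensitively; self-loops (autoregulation) are permitted.  Genes
    without any incident interaction are not tracked unless explicitly added.
    """

    def __init__(
        self,
        interactions: Iterable[RegulatoryInteraction] = (),
        genes: Iterable[Gene] = (),
        label: str = "",
    ):
        self.label = label
        self._genes: dict[str, Gene] = {}
        self._interactions: dict[tuple[str, str], RegulatoryInteraction] = {}
        for gene in genes:
            self.add_gene(gene)
        for inter in interactions:
            self.add_interaction(inter)

    # -- construction -----------------------------------------------------
    def add_gene(self, gene: Gene) -> None:
        existing = self._genes.get(gene.key)
        if existing is None:
            self._genes[gene.key] = gene
        else:
            # keep the record with the most annotation
            if existing.replicon is None and gene.replicon is not None:
                self._genes[gene.key] = Gene(
                    existing.locus_tag, gene.name or existing.name, gene.replicon
                )

    def add_interaction(self, inter: RegulatoryInteraction) -> None:
        for tag in (inter.regulator, inter.target):
            if tag.casefold() not in self._genes:
                self._genes[tag.casefold()] = Gene(tag)
        key = inter.key
        if key in self._interactions:
            self._interactions[key] = self._interactions[key].merged_with(inter)
        else:
            self._interactions[key] = inter

    # -- queries ----------------------------------------------------------
    @property
    def genes(self) -> dict[str, Gene]:
        return self._genes

    @property
    def interactions(self) -> dict[tuple[str, str], RegulatoryInteraction]:
        return self._interactions

    def gene_tags(self) -> list[str]:
        return sorted(g.locus_tag for g in self._genes.values())

    def __len__(self) -> int:
        return len(self._genes)

    @property
    def n_interactions(self) -> int:
        return len(self._interactions)

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag.casefold() in self._genes

    def regulators(self) -> list[str]:
        """Genes with out-degree > 0, sorted by locus tag."""
        regs = {i.key[0] for i in self._interactions.values()}
        return sorted(self._genes[k].locus_tag for k in regs)

    def out_degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for (rkey, _t), inter in self._interactions.items():
            tag = self._genes[rkey].locus_tag
            deg[tag] = deg.get(tag, 0) + 1
        return deg

    def to_networkx(self, directed: bool = True, self_loops: bool = True):
        import networkx as nx

        graph = nx.DiGraph() if directed else nx.Graph()
        graph.add_nodes_from(g.locus_tag for g in self._genes.values())
        for inter in self._interactions.values():
            u = self._genes[inter.key[0]].locus_tag
            v = self._genes[inter.key[1]].locus_tag
            if not self_loops and u == v:
                continue
            graph.add_edge(u, v)
        return graph

    def copy(self, label: str | None = None) -> "GRN":
        return GRN(
            interactions=list(self._interactions.values()),
            genes=list(self._genes.values()),
            label=self.label if label is None else label,
        )


def merge_networks(networks: Sequence[GRN], label: str = "merged") -> GRN:
    """Meta-curation: union of genes and interactions over several networks.

    Interactions sharing a (regulator, target) key collapse to one record:
    experiments and sources are unioned, evidence resolves to the maximum
    level, and conflicting effects resolve to ``dual``.  An empty input list
    yields an empty network.
    """
    merged = GRN(label=label)
    for net in networks:
        for gene in net.genes.values():
            merged.add_gene(gene)
        for inter in net.interactions.values():
            merged.add_interaction(inter)
    return merged


def filter_strong(network: GRN, label: str | None = None) -> GRN:
    """Keep only strong-evidence interactions; drop genes left without edges."""
    strong = [
        i for i in network.interactions.values() if i.evidence == EvidenceLevel.STRONG
    ]
    kept_tags = {k for i in strong for k in i.key}
    genes = [g for key, g in network.genes.items() if key in kept_tags]
    return GRN(
        interactions=strong,
        genes=genes,
        label=label if label is not None else f"{network.label}(strong)",
    )


def restrict_to_replicon(network: GRN, replicon: str) -> GRN:
    """Drop genes (and incident interactions) not on the named replicon."""
    if not replicon:
        raise GRNError("replicon name must be non-empty")
    missing = [
        g.locus_tag for g in network.genes.values() if g.replicon is None
    ]
    if missing:
        raise GRNError(
            "genes missing replicon annotation: " + ", ".join(sorted(missing)[:20])
        )
    keep = {
        key for key, g in network.genes.items() if g.replicon == replicon
    }
    inters = [
        i
        for i in network.interactions.values()
        if i.key[0] in keep and i.key[1] in keep
    ]
    genes = [network.genes[k] for k in keep]
    kept_tags = {k for i in inters for k in i.key}
    genes = [g for g in genes if g.key in kept_tags]
    return GRN(interactions=inters, genes=genes, label=network.label)


@dataclass(frozen=True)
class NetworkSummary:
    genes: int
    interactions: int
    regulators: int
    strong_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.strong_fraction <= 1.0:
            raise GRNError("strong_fraction outside [0, 1]")


def network_summary(network: GRN) -> NetworkSummary:
    """Headline counts: genes, interactions, regulators, strong fraction."""
    n_int = network.n_interactions
    n_strong = sum(
        1
        for i in network.interactions.values()
        if i.evidence == EvidenceLevel.STRONG
    )
    return NetworkSummary(
        genes=len(network),
        interactions=n_int,
        regulators=len(network.regulators()),
        strong_fraction=(n_strong / n_int) if n_int else 0.0,
    )


def interaction_coverage_pct(n_interactions: int, expected_total: int) -> float:
    """Completeness of a reconstruction against the expected full-GRN size,
    as a percentage (e.g. 9707 curated of 23908 expected -> 40.6)."""
    if expected_total <= 0:
        raise GRNError("expected_total must be positive")
    return 100.0 * n_interactions / expected_total
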