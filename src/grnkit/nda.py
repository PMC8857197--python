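"""Natural Decomposition Approach: system-level classes of a GRN.

The NDA reads the diamond-shaped hierarchy of bacterial regulatory networks
off the graph structure alone, assigning every gene exactly one of four
classes:

* **global regulators (GR)** -- highly connected TFs coordinating genes
  across pathways; removing them fragments the network,
* **modular genes** -- genes grouped into the connected pieces (modules)
  that remain after GR removal,
* **intermodular genes** -- non-TF genes whose promoters integrate
  regulation coming from two or more different modules,
* **basal machinery** -- genes whose only regulation (if any) comes from
  the global regulators themselves.

Global regulators are found by default with an elbow rule on the ranked
out-degree curve: regulators are sorted by decreasing out-degree and the
cut is placed at the point of maximum perpendicular distance between the
rank-connectivity curve and its chord.  A fixed, externally curated GR set
can be injected instead to reproduce published decompositions.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import networkx as nx

from .core import GRN, GRNError


@enum.unique
class NDAClass(enum.Enum):
    GLOBAL_REGULATOR = "global_regulator"
    MODULAR = "modular"
    INTERMODULAR = "intermodular"
    BASAL_MACHINERY = "basal_machinery"


@dataclass
class NDAResult:
    """Partition of network genes into the four NDA classes.

    ``modules`` maps module id -> gene set (pairwise disjoint);
    ``submodules`` maps module id -> the list of parts the module splits
    into after removing its internal multi-input bridge genes (a single
    part when the module does not split).
    """

    class_of: dict[str, NDAClass]
    modules: dict[int, set[str]]
    submodules: dict[int, list[set[str]]]
    gr_set: list[str]

    def genes_in_class(self, cls: NDAClass) -> set[str]:
        return {g for g, c in self.class_of.items() if c is cls}

    def counts(self) -> dict[NDAClass, int]:
        out = {cls: 0 for cls in NDAClass}
        for cls in self.class_of.values():
            out[cls] += 1
        return out

    def module_of(self, gene: str) -> int | None:
        for mid, members in self.modules.items():
            if gene in members:
                return mid
        return None


def identify_global_regulators(
    network: GRN,
    strategy: str = "elbow",
    fixed: list[str] | None = None,
    min_out_degree: int | None = None,
) -> list[str]:
    """Select the global-regulator set among the network's regulators.

    strategy="elbow" (default): rank regulators by out-degree descending
    and cut at the point of maximum perpendicular distance between the
    rank-connectivity curve and its chord; the cut is extended to include
    degree ties.  strategy="fixed_set" injects a user list; "threshold"
    keeps all regulators with out-degree >= ``min_out_degree``.
    """
    if len(network) == 0:
        raise GRNError("network is empty")
    out_deg = network.out_degree()
    regulators = sorted(out_deg, key=lambda g: (-out_deg[g], g))
    if not regulators:
        warnings.warn("network has no regulators; GR set is empty")
        return []

    if strategy == "fixed_set":
        if fixed is None:
            raise GRNError("fixed_set strategy requires a gene list")
        reg_keys = {r.casefold(): r for r in regulators}
        missing = [g for g in fixed if g.casefold() not in reg_keys]
        if missing:
            raise GRNError(
                "fixed GR set contains non-regulators: " + ", ".join(missing)
            )
        return [reg_keys[g.casefold()] for g in fixed]

    if strategy == "threshold":
        if min_out_degree is None:
            raise GRNError("threshold strategy requires min_out_degree")
        return [g for g in regulators if out_deg[g] >= min_out_degree]

    if strategy != "elbow":
        raise GRNError(f"unknown GR strategy: {strategy!r}")

    m = len(regulators)
    if m == 1:
        return list(regulators)
    ks = [out_deg[g] for g in regulators]
    if ks[0] == ks[-1]:
        warnings.warn("all regulators share one out-degree; no elbow, GR set empty")
        return []
    # perpendicular distance from (i, k_i) to the chord (1,k_1)-(m,k_m)
    x1, y1, x2, y2 = 1.0, float(ks[0]), float(m), float(ks[-1])
    dx, dy = x2 - x1, y2 - y1
    norm = (dx * dx + dy * dy) ** 0.5
    best_i, best_d = 1, -1.0
    for i, k in enumerate(ks, start=1):
        d = abs(dy * (i - x1) - dx * (k - y1)) / norm
        if d > best_d + 1e-12:
            best_d, best_i = d, i
    cut = best_i - 1  # regulators strictly before the elbow point
    if cut < 1:
        cut = 1
    # extend across out-degree ties so equal hubs are all-in or all-out
    while cut < m and ks[cut] == ks[cut - 1]:
        cut += 1
    return regulators[:cut]


def nda_classify(network: GRN, gr_set: list[str]) -> NDAResult:
    """Classify every gene given a GR set and derive modules/submodules.

    Procedure: remove GRs and incident edges; genes left without residual
    edges (regulated only by GRs, isolated, or only self-regulating) form
    the basal machinery.  Pure-target genes fed by >= 2 residual regulators
    are intermodular candidates: weak components are computed with the
    candidates removed, a candidate whose regulators span >= 2 components
    is intermodular, otherwise it rejoins its component.  The resulting
    components are the modules.
    """
    regs = {r.casefold() for r in network.regulators()}
    gr_keys: list[str] = []
    for g in gr_set:
        if g.casefold() not in regs:
            raise GRNError(f"GR set member is not a regulator: {g}")
        gr_keys.append(g.casefold())
    gr_key_set = set(gr_keys)

    tag_of = {key: gene.locus_tag for key, gene in network.genes.items()}
    class_of: dict[str, NDAClass] = {}
    for key in gr_key_set:
        class_of[tag_of[key]] = NDAClass.GLOBAL_REGULATOR

    # residual graph: drop GRs (and their edges) and self-loops
    residual = nx.DiGraph()
    for key in network.genes:
        if key not in gr_key_set:
            residual.add_node(key)
    for (rkey, tkey), _inter in network.interactions.items():
        if rkey in gr_key_set or tkey in gr_key_set or rkey == tkey:
            continue
        residual.add_edge(rkey, tkey)

    basal = {n for n in residual.nodes if residual.degree(n) == 0}
    for key in basal:
        class_of[tag_of[key]] = NDAClass.BASAL_MACHINERY
    residual.remove_nodes_from(basal)

    candidates = {
        n
        for n in residual.nodes
        if residual.out_degree(n) == 0 and residual.in_degree(n) >= 2
    }
    stripped = residual.subgraph(set(residual.nodes) - candidates)
    components = [set(c) for c in nx.weakly_connected_components(stripped)]
    components.sort(key=lambda c: min(c))
    comp_of = {n: i for i, comp in enumerate(components) for n in comp}

    intermodular: set[str] = set()
    for cand in sorted(candidates):
        feeder_comps = {comp_of[p] for p in residual.predecessors(cand)}
        if len(feeder_comps) >= 2:
            intermodular.add(cand)
        else:
            components[feeder_comps.pop()].add(cand)
    for key in intermodular:
        class_of[tag_of[key]] = NDAClass.INTERMODULAR

    modules: dict[int, set[str]] = {}
    for i, comp in enumerate(components, start=1):
        modules[i] = {tag_of[k] for k in comp}
        for key in comp:
            class_of[tag_of[key]] = NDAClass.MODULAR

    submodules = {
        mid: _split_submodules(residual, {k for k in network.genes
                                          if tag_of[k] in members})
        for mid, members in modules.items()
    }
    submodules = {
        mid: [{tag_of[k] for k in part} for part in parts]
        for mid, parts in submodules.items()
    }

    missing = set(tag_of.values()) - set(class_of)
    if missing:  # pragma: no cover - partition safety net
        raise GRNError("genes left unclassified: " + ", ".join(sorted(missing)[:10]))
    return NDAResult(
        class_of=class_of,
        modules=modules,
        submodules=submodules,
        gr_set=[tag_of[k] for k in gr_keys],
    )


def _split_submodules(residual: nx.DiGraph, member_keys: set[str]) -> list[set[str]]:
    """Split one module by removing its internal integrator bridge genes.

    Bridges are module members fed by >= 2 regulators inside the module
    whose removal disconnects it (articulation points of the undirected
    induced subgraph).  If removing them splits the module, the weak
    components are its submodules -- subparts held together through
    integrator genes, mirroring at module scale how intermodular genes
    connect modules; otherwise the module is its own single part.
    """
    sub = residual.subgraph(member_keys & set(residual.nodes)).copy()
    articulation = set(nx.articulation_points(sub.to_undirected()))
    bridges = {
        n for n in articulation if sub.in_degree(n) >= 2
    }
    sub.remove_nodes_from(bridges)
    parts = [set(c) for c in nx.weakly_connected_components(sub)]
    parts.sort(key=lambda c: min(c))
    if len(parts) <= 1:
        return [set(member_keys)]
    return parts


@dataclass(frozen=True)
class NDASummary:
    counts: dict
    percentages: dict


def nda_summary(result: NDAResult, n_genes: int) -> NDASummary:
    """Per-class counts and percentages (100 * count / n_genes, 2 decimals)."""
    if n_genes <= 0:
        raise GRNError("n_genes must be positive")
    counts = result.counts()
    total = sum(counts.values())
    if total != n_genes:
        raise GRNError(
            f"classes do not partition the gene set: {total} classified, "
            f"{n_genes} expected"
        )
    pct = {cls: round(100.0 * n / n_genes, 2) for cls, n in counts.items()}
    return NDASummary(counts=dict(counts), percentages=pct)


def class_percentages(counts: dict[NDAClass, int] | list[int], n_genes: int) -> list[float]:
    """Percentages (2 decimals) for per-class counts over ``n_genes``."""
    if n_genes <= 0:
        raise GRNError("n_genes must be positive")
    values = list(counts.values()) if isinstance(counts, dict) else list(counts)
    return [round(100.0 * c / n_genes, 2) for c in values]
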