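"""Size-robust pairwise network dissimilarity (Schieber-style D-measure).

D compares two graphs on their undirected simple projections through three
bounded terms weighted by (w1, w2, w3), default (0.45, 0.45, 0.1):

1. the Jensen-Shannon divergence between the graphs' *averaged*
   node-distance distributions (how far apart, on average, nodes sit),
2. the difference of the square roots of the network node dispersions
   (NND), i.e. how heterogeneous the per-node distance distributions are,
3. an alpha-centrality-based comparison averaged over each graph and its
   complement, which discriminates networks of different size.

D(g, g) = 0, D is symmetric, and with weights summing to 1 it is bounded
in [0, 1].  Disconnected node pairs are assigned the "unreachable" distance
bin so disconnected graphs are handled uniformly.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .core import GRN, GRNError

DEFAULT_WEIGHTS = (0.45, 0.45, 0.1)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Two-way Jensen-Shannon divergence (natural log)."""
    size = max(p.size, q.size)
    pp = np.zeros(size)
    qq = np.zeros(size)
    pp[: p.size] = p
    qq[: q.size] = q
    m = (pp + qq) / 2.0
    return _entropy(m) - (_entropy(pp) + _entropy(qq)) / 2.0


def _as_undirected(graph) -> nx.Graph:
    if isinstance(graph, GRN):
        g = graph.to_networkx(directed=False, self_loops=False)
    else:
        g = nx.Graph(graph)
        g.remove_edges_from(nx.selfloop_edges(g))
    return g


def node_distance_distributions(g: nx.Graph) -> np.ndarray:
    """Per-node distributions over distance bins 1..n (bin n = unreachable)."""
    n = g.number_of_nodes()
    if n < 2:
        raise GRNError("need >= 2 nodes for distance distributions")
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), n, dtype=float)  # n encodes "unreachable"
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        i = index[source]
        for tgt, d in lengths.items():
            dist[i, index[tgt]] = d
    rows = np.zeros((n, n))  # bins 1..n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rows[i, int(dist[i, j]) - 1] += 1
    return rows / (n - 1)


def network_node_dispersion(g: nx.Graph) -> tuple[float, np.ndarray]:
    """NND and the averaged node-distance distribution.

    NND is the multi-way JS divergence of the per-node distance
    distributions, normalized by log(d + 1) with d the number of occupied
    distance bins.
    """
    rows = node_distance_distributions(g)
    mu = rows.mean(axis=0)
    js = _entropy(mu) - float(np.mean([_entropy(r) for r in rows]))
    occupied = int(np.max(np.nonzero(mu)[0])) + 1 if np.any(mu > 0) else 1
    norm = math.log(occupied + 1)
    return (js / norm if norm > 0 else 0.0), mu


def _alpha_centrality_pdf(g: nx.Graph) -> np.ndarray:
    """Normalized, sorted alpha-centrality vector treated as a pdf."""
    n = g.number_of_nodes()
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    alpha = 1.0 / n
    centrality = np.linalg.solve(np.eye(n) - alpha * a.T, np.ones(n))
    centrality = np.abs(centrality)
    total = centrality.sum()
    if total == 0:
        return np.full(n, 1.0 / n)
    return np.sort(centrality / total)[::-1]


def network_dissimilarity(
    g1,
    g2,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Dissimilarity D in [0, 1] between two non-empty networks."""
    w1, w2, w3 = weights
    if abs(w1 + w2 + w3 - 1.0) > 1e-9:
        raise GRNError("dissimilarity weights must sum to 1")
    ga = _as_undirected(g1)
    gb = _as_undirected(g2)
    if ga.number_of_nodes() == 0 or gb.number_of_nodes() == 0:
        raise GRNError("both networks must be non-empty")

    nnd_a, mu_a = network_node_dispersion(ga)
    nnd_b, mu_b = network_node_dispersion(gb)
    term1 = math.sqrt(max(_js_divergence(mu_a, mu_b), 0.0) / math.log(2))
    term2 = abs(math.sqrt(max(nnd_a, 0.0)) - math.sqrt(max(nnd_b, 0.0)))

    d = w1 * term1 + w2 * term2
    if w3 > 0:
        pa, pb = _alpha_centrality_pdf(ga), _alpha_centrality_pdf(gb)
        pac = _alpha_centrality_pdf(nx.complement(ga))
        pbc = _alpha_centrality_pdf(nx.complement(gb))
        term3 = math.sqrt(max(_js_divergence(pa, pb), 0.0) / math.log(2)) + math.sqrt(
            max(_js_divergence(pac, pbc), 0.0) / math.log(2)
        )
        d += (w3 / 2.0) * term3
    return float(d)
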