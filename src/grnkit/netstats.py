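"""Structural properties, degree-distribution fits, and profile clustering.

Scale-free GRNs follow a degree distribution P(k) ~ k^-alpha with
2 < alpha < 3, show the ultra-small-world effect (average path length
proportional to ln(ln(N))), and are hierarchically modular, with the
degree-dependent clustering coefficient scaling as C(k) ~ k^-1.  The
exponent alpha is estimated two ways: a robust (Huber-IRLS) linear
regression on the log-log complementary cumulative degree distribution
(reported alpha = |slope| + 1), and a discrete maximum-likelihood fit with
the lower cutoff xmin chosen by Kolmogorov-Smirnov minimization, compared
against alternative fat-tailed distributions by KS distance.

A network's 15-property structural profile (the global properties reported
for GRNs by the Abasy Atlas database) supports Pearson/Ward clustering of
networks and complements edge-wise assessment metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import optimize, special
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import GRN, GRNError

PROFILE_FIELDS = [
    "regulators_pct",
    "direct_interactions",
    "self_regulation_pct",
    "max_out_connectivity_pct",
    "density",
    "weakly_connected_components",
    "giant_component_pct",
    "feedforward_circuits",
    "complex_feedforward_circuits",
    "feedback_loops_3",
    "avg_shortest_path",
    "diameter",
    "avg_clustering_coefficient",
    "r2adj_Pk",
    "r2adj_Ck",
]


@dataclass
class StructuralProfile:
    """Fixed-order vector of the 15 global network properties."""

    regulators_pct: float
    direct_interactions: float
    self_regulation_pct: float
    max_out_connectivity_pct: float
    density: float
    weakly_connected_components: float
    giant_component_pct: float
    feedforward_circuits: float
    complex_feedforward_circuits: float
    feedback_loops_3: float
    avg_shortest_path: float
    diameter: float
    avg_clustering_coefficient: float
    r2adj_Pk: float
    r2adj_Ck: float
    label: str = ""

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PROFILE_FIELDS], dtype=float)


@dataclass
class PowerLawFit:
    alpha: float
    r2adj: float | None = None
    xmin: int | None = None
    ks_distance: float | None = None
    model_comparison: dict[str, float] | None = None
    slope: float | None = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise GRNError("power-law exponent must be positive")

    @property
    def preferred_model(self) -> str | None:
        if not self.model_comparison:
            return None
        return min(self.model_comparison, key=self.model_comparison.get)


@dataclass
class DegreeStats:
    degrees: np.ndarray
    ck: dict[int, float]
    ccdf: list[tuple[int, float]]

    def __post_init__(self) -> None:
        vals = [v for _k, v in self.ccdf]
        if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
            raise GRNError("CCDF must be non-increasing")


def count_motifs(network: GRN) -> tuple[int, int, int]:
    """(feedforward circuits, complex FFCs, 3-feedback loops).

    An FFC is an ordered triple of distinct genes (A, B, C) with edges
    A->B, A->C and B->C; a *complex* FFC additionally has at least one of
    its three edges reciprocated (this counter stands behind the profile
    slot and can be swapped by users with their own definition).
    3-feedback loops are directed 3-cycles counted once per node set.
    Self-loops are excluded throughout.
    """
    g = network.to_networkx(directed=True, self_loops=False)
    succ = {n: set(g.successors(n)) for n in g.nodes}
    ffc = cffc = 0
    for a in g.nodes:
        for b in succ[a]:
            if b == a:
                continue
            for c in succ[b]:
                if c == a or c == b:
                    continue
                if c in succ[a]:
                    ffc += 1
                    if a in succ[b] or b in succ[c] or a in succ[c]:
                        cffc += 1
    return ffc, cffc, count_feedback_loops_3(network)


def _count_loop_sets(succ: dict, a, b, c) -> bool:
    return (b in succ[a] and c in succ[b] and a in succ[c]) or (
        c in succ[a] and b in succ[c] and a in succ[b]
    )


def count_feedback_loops_3(network: GRN) -> int:
    """Directed 3-cycles counted once per node set (either orientation)."""
    g = network.to_networkx(directed=True, self_loops=False)
    succ = {n: set(g.successors(n)) for n in g.nodes}
    und: dict = {n: set() for n in g.nodes}
    for u, v in g.edges:
        und[u].add(v)
        und[v].add(u)
    order = {n: i for i, n in enumerate(sorted(g.nodes))}
    count = 0
    for a in g.nodes:
        for b in und[a]:
            if order[b] <= order[a]:
                continue
            for c in und[a] & und[b]:
                if order[c] <= order[b]:
                    continue
                if _count_loop_sets(succ, a, b, c):
                    count += 1
    return count


def degree_sequence(network: GRN, kind: str = "total") -> np.ndarray:
    """Degrees on the directed simple graph: 'total' (default), 'in', 'out'."""
    g = network.to_networkx(directed=True, self_loops=True)
    if kind == "total":
        deg = dict(g.degree())
    elif kind == "in":
        deg = dict(g.in_degree())
    elif kind == "out":
        deg = dict(g.out_degree())
    else:
        raise GRNError(f"unknown degree kind: {kind!r}")
    return np.array(sorted(deg.values()), dtype=int)


def degree_stats(network: GRN, kind: str = "total") -> DegreeStats:
    degrees = degree_sequence(network, kind)
    g = network.to_networkx(directed=False, self_loops=False)
    clustering = nx.clustering(g)
    per_degree: dict[int, list[float]] = {}
    for node in g.nodes:
        per_degree.setdefault(g.degree(node), []).append(clustering[node])
    ck = {k: float(np.mean(v)) for k, v in sorted(per_degree.items())}
    pos = degrees[degrees > 0]
    ccdf = []
    if pos.size:
        ks = np.unique(pos)
        ccdf = [(int(k), float(np.mean(pos >= k))) for k in ks]
    return DegreeStats(degrees=degrees, ck=ck, ccdf=ccdf)


def ultra_small_world_reference(n: int) -> float:
    """Reference path length ln(ln(n)) of ultra-small-world networks,
    rounded to 2 decimals for reporting."""
    if n < 3:
        raise GRNError("ln(ln(n)) reference requires n >= 3")
    return round(math.log(math.log(n)), 2)


def _adjusted_r2(y: np.ndarray, fitted: np.ndarray, n_params: int = 2) -> float:
    resid = y - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    r2 = 1.0 - ss_res / ss_tot
    n = len(y)
    if n <= n_params:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)


def fit_powerlaw_regression(degrees: Sequence[int]) -> PowerLawFit:
    """Robust log-log regression of the degree CCDF.

    Fits log P(K >= k) ~ log k with Huber-weighted iteratively reweighted
    least squares (50 iterations, tol 1e-8) and reports
    alpha = |slope| + 1 (the CCDF of P(k) ~ k^-alpha falls as k^-(alpha-1))
    together with the adjusted R^2 of the robust line.
    """
    import statsmodels.api as sm

    degrees = np.asarray(degrees, dtype=float)
    pos = degrees[degrees > 0]
    ks = np.unique(pos)
    if ks.size < 3:
        raise GRNError("need >= 3 distinct positive degrees for regression")
    ccdf = np.array([np.mean(pos >= k) for k in ks])
    x = np.log(ks)
    y = np.log(ccdf)
    exog = sm.add_constant(x)
    rlm = sm.RLM(y, exog, M=sm.robust.norms.HuberT())
    res = rlm.fit(maxiter=50, tol=1e-8)
    slope = float(res.params[1])
    fitted = res.params[0] + slope * x
    return PowerLawFit(
        alpha=abs(slope) + 1.0,
        r2adj=_adjusted_r2(y, fitted),
        slope=slope,
    )


# -- discrete MLE fits ----------------------------------------------------

CANDIDATE_DISTRIBUTIONS = (
    "power_law",
    "exponential",
    "stretched_exponential",
    "lognormal",
    "truncated_power_law",
)


def _tail_grid(xmin: int, kmax: int) -> np.ndarray:
    return np.arange(xmin, kmax + 1, dtype=float)


def _pmf_from_weights(weights: np.ndarray) -> np.ndarray:
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        return np.full_like(weights, np.nan)
    return weights / total


def _ks_distance(tail: np.ndarray, grid: np.ndarray, pmf: np.ndarray) -> float:
    cdf = np.cumsum(pmf)
    ecdf_at = np.searchsorted(np.sort(tail), grid, side="right") / tail.size
    return float(np.max(np.abs(ecdf_at - cdf)))


def _fit_candidate(name: str, tail: np.ndarray, xmin: int) -> tuple[float, dict]:
    """KS distance and parameters for one candidate tail model."""
    kmax = int(max(tail.max() * 5, xmin + 1000))
    grid = _tail_grid(xmin, kmax)
    log_grid = np.log(grid)

    if name == "power_law":
        def nll(alpha: float) -> float:
            z = special.zeta(alpha, xmin)
            if not np.isfinite(z) or z <= 0:
                return np.inf
            return tail.size * math.log(z) + alpha * np.sum(np.log(tail))

        res = optimize.minimize_scalar(nll, bounds=(1.05, 8.0), method="bounded")
        alpha = float(res.x)
        pmf = _pmf_from_weights(grid ** (-alpha))
        return _ks_distance(tail, grid, pmf), {"alpha": alpha}

    if name == "exponential":
        # discrete (geometric-type) exponential: closed-form MLE
        mean_excess = float(tail.mean()) - xmin
        q = mean_excess / (mean_excess + 1.0) if mean_excess > 0 else 1e-9
        lam = -math.log(q)
        pmf = _pmf_from_weights(np.exp(-lam * (grid - xmin)))
        return _ks_distance(tail, grid, pmf), {"lambda": lam}

    if name == "truncated_power_law":
        def nll(params: np.ndarray) -> float:
            alpha, lam = params
            if alpha <= 0 or lam <= 0:
                return np.inf
            weights = grid ** (-alpha) * np.exp(-lam * grid)
            total = weights.sum()
            if total <= 0:
                return np.inf
            return tail.size * math.log(total) + alpha * np.sum(
                np.log(tail)
            ) + lam * np.sum(tail)

        res = optimize.minimize(
            nll, x0=np.array([1.5, 0.01]), method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-6},
        )
        alpha, lam = map(float, res.x)
        pmf = _pmf_from_weights(grid ** (-alpha) * np.exp(-lam * grid))
        return _ks_distance(tail, grid, pmf), {"alpha": alpha, "lambda": lam}

    if name == "stretched_exponential":
        def nll(params: np.ndarray) -> float:
            beta, gamma = params
            if beta <= 0 or not 0.05 < gamma <= 3.0:
                return np.inf
            logw = -((grid / beta) ** gamma)
            total = np.exp(logw).sum()
            if total <= 0:
                return np.inf
            return tail.size * math.log(total) + np.sum((tail / beta) ** gamma)

        res = optimize.minimize(
            nll, x0=np.array([float(max(tail.mean(), 1.0)), 0.7]),
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-6},
        )
        beta, gamma = map(float, res.x)
        pmf = _pmf_from_weights(np.exp(-((grid / beta) ** gamma)))
        return _ks_distance(tail, grid, pmf), {"beta": beta, "gamma": gamma}

    if name == "lognormal":
        logs = np.log(tail)

        def nll(params: np.ndarray) -> float:
            mu, sigma = params
            if sigma <= 0:
                return np.inf
            logw = -((log_grid - mu) ** 2) / (2 * sigma**2) - log_grid
            total = np.exp(logw).sum()
            if total <= 0:
                return np.inf
            return tail.size * math.log(total) + np.sum(
                (logs - mu) ** 2 / (2 * sigma**2) + logs
            )

        res = optimize.minimize(
            nll, x0=np.array([float(logs.mean()), float(max(logs.std(), 0.3))]),
            method="Nelder-Mead",
            options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-6},
        )
        mu, sigma = map(float, res.x)
        pmf = _pmf_from_weights(
            np.exp(-((log_grid - mu) ** 2) / (2 * sigma**2)) / grid
        )
        return _ks_distance(tail, grid, pmf), {"mu": mu, "sigma": sigma}

    raise GRNError(f"unknown candidate distribution: {name!r}")


def fit_powerlaw_mle(
    degrees: Sequence[int],
    candidates: Sequence[str] = CANDIDATE_DISTRIBUTIONS,
    xmin: int | None = None,
    min_tail: int = 10,
    max_xmin_candidates: int = 40,
) -> PowerLawFit:
    """Discrete power-law MLE with KS-minimizing xmin and model comparison.

    The lower cutoff xmin is scanned over the distinct observed degrees
    (keeping tails of at least ``min_tail`` observations) and chosen to
    minimize the KS distance of the power-law fit; every candidate
    distribution is then fitted on the same tail and reported with its KS
    distance.  The preferred model is the one with minimum KS distance.
    """
    unknown = set(candidates) - set(CANDIDATE_DISTRIBUTIONS)
    if unknown:
        raise GRNError(f"unknown candidate distributions: {sorted(unknown)}")
    if not candidates:
        raise GRNError("candidate set must be non-empty")
    degrees = np.asarray(degrees, dtype=float)
    degrees = degrees[degrees > 0]
    if degrees.size < 50:
        raise GRNError("need >= 50 positive-degree observations for MLE")

    if xmin is None:
        options = [
            int(k)
            for k in np.unique(degrees)
            if np.sum(degrees >= k) >= min_tail
        ]
        if len(options) > max_xmin_candidates:
            idx = np.linspace(0, len(options) - 1, max_xmin_candidates).astype(int)
            options = [options[i] for i in idx]
        best = None
        for xm in options:
            tail = degrees[degrees >= xm]
            ks, params = _fit_candidate("power_law", tail, xm)
            if best is None or ks < best[0]:
                best = (ks, xm, params)
        ks_pl, xmin, pl_params = best
    else:
        tail = degrees[degrees >= xmin]
        ks_pl, pl_params = _fit_candidate("power_law", tail, xmin)

    tail = degrees[degrees >= xmin]
    comparison: dict[str, float] = {}
    for name in candidates:
        if name == "power_law":
            comparison[name] = ks_pl
        else:
            ks, _params = _fit_candidate(name, tail, xmin)
            comparison[name] = ks
    return PowerLawFit(
        alpha=pl_params["alpha"],
        xmin=int(xmin),
        ks_distance=ks_pl,
        model_comparison=comparison,
    )


def fit_ck_scaling(stats: DegreeStats) -> tuple[float, float]:
    """Exponent (positive magnitude) and adjusted R^2 of C(k) ~ k^-gamma.

    Ordinary least squares of log C(k) on log k over degrees with positive
    mean clustering; hierarchical modularity predicts gamma ~ 1.
    """
    pts = [(k, c) for k, c in stats.ck.items() if k > 0 and c > 0]
    if not any(c > 0 for c in stats.ck.values()):
        raise GRNError("all C(k) values are zero; scaling undefined")
    if len(pts) < 3:
        raise GRNError("need >= 3 degrees with positive mean clustering")
    x = np.log([k for k, _c in pts])
    y = np.log([c for _k, c in pts])
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    return abs(float(slope)), _adjusted_r2(y, fitted)


def structural_profile(network: GRN, degree_kind: str = "total") -> StructuralProfile:
    """The 15-property structural profile of a network.

    Path metrics (average shortest path, diameter) are computed on the
    undirected giant component; clustering on the undirected simple graph;
    motif counts exclude self-loops.  The two goodness-of-fit entries come
    from the CCDF regression of P(k) and the C(k) scaling regression, and
    are NaN when a fit is undefined (e.g. too few distinct degrees on toy
    networks).
    """
    n = len(network)
    if n == 0:
        raise GRNError("cannot profile an empty network")
    directed = network.to_networkx(directed=True, self_loops=True)
    undirected = network.to_networkx(directed=False, self_loops=False)

    out_deg = network.out_degree()
    n_self = sum(1 for (r, t) in network.interactions if r == t)
    ffc, cffc, _ = count_motifs(network)
    loops3 = count_feedback_loops_3(network)

    simple_edges = sum(1 for (r, t) in network.interactions if r != t)
    density = simple_edges / (n * (n - 1)) if n > 1 else 0.0

    components = list(nx.weakly_connected_components(directed))
    giant_nodes = max(components, key=len)
    giant = undirected.subgraph(giant_nodes)
    if giant.number_of_edges() > 0 and len(giant_nodes) > 1:
        giant_connected = giant.subgraph(
            max(nx.connected_components(giant), key=len)
        )
        avg_path = nx.average_shortest_path_length(giant_connected)
        diameter = nx.diameter(giant_connected)
    else:
        avg_path = 0.0
        diameter = 0.0

    stats = degree_stats(network, degree_kind)
    try:
        r2_pk = fit_powerlaw_regression(stats.degrees).r2adj
    except GRNError:
        r2_pk = float("nan")
    try:
        _gamma, r2_ck = fit_ck_scaling(stats)
    except GRNError:
        r2_ck = float("nan")

    return StructuralProfile(
        regulators_pct=100.0 * len(network.regulators()) / n,
        direct_interactions=float(network.n_interactions),
        self_regulation_pct=100.0 * n_self / n,
        max_out_connectivity_pct=100.0 * (max(out_deg.values()) if out_deg else 0) / n,
        density=density,
        weakly_connected_components=float(len(components)),
        giant_component_pct=100.0 * len(giant_nodes) / n,
        feedforward_circuits=float(ffc),
        complex_feedforward_circuits=float(cffc),
        feedback_loops_3=float(loops3),
        avg_shortest_path=float(avg_path),
        diameter=float(diameter),
        avg_clustering_coefficient=float(nx.average_clustering(undirected))
        if undirected.number_of_nodes()
        else 0.0,
        r2adj_Pk=float(r2_pk),
        r2adj_Ck=float(r2_ck),
        label=network.label,
    )


@dataclass
class ProfileClustering:
    labels: list[str]
    correlation: np.ndarray
    linkage: np.ndarray

    def newick(self) -> str:
        """Dendrogram as a Newick-like nested string."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return f"({render(node.left)},{render(node.right)}):{node.dist:.4f}"

        return render(tree) + ";"


def cluster_profiles(
    profiles: Sequence[StructuralProfile], scaling: str = "none"
) -> ProfileClustering:
    """Pearson-correlate structural profiles and Ward-cluster the networks.

    Features that are NaN in any profile or constant across all profiles
    are dropped before correlating (they carry no comparative signal);
    optional min-max feature scaling is applied first.  A profile with zero
    variance across the remaining features is rejected by name.
    """
    if len(profiles) < 2:
        raise GRNError("need >= 2 profiles to cluster")
    if scaling not in ("none", "minmax"):
        raise GRNError(f"unknown scaling: {scaling!r}")
    matrix = np.vstack([p.as_vector() for p in profiles])
    labels = [p.label or f"profile_{i}" for i, p in enumerate(profiles)]
    keep = ~np.any(np.isnan(matrix), axis=0)
    matrix = matrix[:, keep]
    if scaling == "minmax":
        lo = matrix.min(axis=0)
        span = matrix.max(axis=0) - lo
        span[span == 0] = 1.0
        matrix = (matrix - lo) / span
    variable = matrix.std(axis=0) > 0
    matrix = matrix[:, variable]
    if matrix.shape[1] < 2:
        raise GRNError("fewer than 2 informative features across profiles")
    row_sd = matrix.std(axis=1)
    flat = [labels[i] for i in np.nonzero(row_sd == 0)[0]]
    if flat:
        raise GRNError("constant profile(s): " + ", ".join(flat))
    corr = np.corrcoef(matrix)
    linkage = hierarchy.ward(pdist(corr, metric="euclidean"))
    return ProfileClustering(labels=labels, correlation=corr, linkage=linkage)
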