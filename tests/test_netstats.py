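"""Structural profiles, degree-distribution fits, clustering, dissimilarity."""

import itertools

import networkx as nx
import numpy as np
import pytest

from grnkit.core import GRN, GRNError, RegulatoryInteraction
from grnkit.dissimilarity import network_dissimilarity
from grnkit.netstats import (
    DegreeStats,
    PROFILE_FIELDS,
    cluster_profiles,
    count_feedback_loops_3,
    count_motifs,
    degree_stats,
    fit_ck_scaling,
    fit_powerlaw_mle,
    fit_powerlaw_regression,
    structural_profile,
    ultra_small_world_reference,
)
from conftest import make_grn


def grn_from_digraph(g):
    return GRN([RegulatoryInteraction(str(u), str(v)) for u, v in g.edges])


def enumerate_motifs_bruteforce(g):
    """Exhaustive ordered-triple enumeration of FFCs and 3-loop node sets."""
    nodes = list(g.nodes)
    edges = set(g.edges)
    ffc = 0
    for a, b, c in itertools.permutations(nodes, 3):
        if (a, b) in edges and (a, c) in edges and (b, c) in edges:
            ffc += 1
    loops = 0
    for trio in itertools.combinations(nodes, 3):
        a, b, c = trio
        if ((a, b) in edges and (b, c) in edges and (c, a) in edges) or (
            (a, c) in edges and (c, b) in edges and (b, a) in edges
        ):
            loops += 1
    return ffc, loops


class TestMotifCounts:
    def test_three_cycle(self):
        tri = make_grn([("A", "B"), ("B", "C"), ("C", "A")])
        ffc, _cffc, loops = count_motifs(tri)
        assert (ffc, loops) == (0, 1)
        assert structural_profile(tri).density == pytest.approx(0.5)

    def test_feedforward_instance(self):
        ffl = make_grn([("A", "B"), ("A", "C"), ("B", "C")])
        ffc, cffc, loops = count_motifs(ffl)
        assert (ffc, cffc, loops) == (1, 0, 0)

    def test_complex_ffc_requires_reciprocated_edge(self):
        net = make_grn([("A", "B"), ("A", "C"), ("B", "C"), ("C", "B")])
        ffc, cffc, _ = count_motifs(net)
        assert ffc == 2 and cffc == 2

    def test_matches_bruteforce_on_random_digraphs(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 6))
            g = nx.gnp_random_graph(n, 0.5, directed=True,
                                    seed=int(rng.integers(1 << 30)))
            net = grn_from_digraph(g)
            ffc, _cffc, loops = count_motifs(net)
            bf_ffc, bf_loops = enumerate_motifs_bruteforce(g)
            assert (ffc, loops) == (bf_ffc, bf_loops)


class TestUltraSmallWorld:
    @pytest.mark.parametrize("n, expected", [(6263, 2.17), (5386, 2.15),
                                             (4739, 2.14), (4763, 2.14), (3804, 2.11)])
    def test_published_network_sizes(self, n, expected):
        assert ultra_small_world_reference(n) == expected

    def test_small_n_errors(self):
        with pytest.raises(GRNError):
            ultra_small_world_reference(2)


class TestPowerLawRegression:
    def test_exact_ccdf_slope_minus_one_gives_alpha_two(self):
        degs = []
        n = 2520
        for k in range(1, 10):
            degs += [k] * (n // k - n // (k + 1))
        degs += [10] * (n // 10)
        fit = fit_powerlaw_regression(degs)
        assert fit.alpha == pytest.approx(2.0, abs=1e-6)
        assert fit.r2adj == pytest.approx(1.0, abs=1e-9)

    def test_too_few_distinct_degrees_errors(self):
        with pytest.raises(GRNError):
            fit_powerlaw_regression([3, 3, 5, 5])

    def test_recovers_alpha_on_synthetic_sequences(self):
        """100-rep median estimate within +-0.15 for alpha in {2, 2.5, 3}."""
        for alpha in (2.0, 2.5, 3.0):
            rng = np.random.default_rng(int(alpha * 10))
            ks = np.arange(1, 10000)
            pmf = ks ** (-alpha)
            pmf /= pmf.sum()
            estimates = [
                fit_powerlaw_regression(rng.choice(ks, size=2000, p=pmf)).alpha
                for _rep in range(100)
            ]
            assert abs(float(np.median(estimates)) - alpha) <= 0.15


class TestPowerLawMLE:
    def test_parametric_recovery(self):
        rng = np.random.default_rng(11)
        ks = np.arange(1, 100000)
        pmf = ks ** (-2.5)
        pmf /= pmf.sum()
        sample = rng.choice(ks, size=10000, p=pmf)
        fit = fit_powerlaw_mle(sample, candidates=("power_law",))
        assert fit.alpha == pytest.approx(2.5, abs=0.1)

    def test_geometric_sample_prefers_exponential(self):
        rng = np.random.default_rng(3)
        sample = rng.geometric(0.25, size=3000)
        fit = fit_powerlaw_mle(sample)
        assert fit.preferred_model == "exponential"
        assert fit.model_comparison["exponential"] < fit.model_comparison["power_law"]

    def test_empty_candidates_errors(self):
        with pytest.raises(GRNError):
            fit_powerlaw_mle(np.ones(100, dtype=int) * 2, candidates=())

    def test_too_few_observations_errors(self):
        with pytest.raises(GRNError):
            fit_powerlaw_mle([1, 2, 3])


class TestCkScaling:
    def test_exact_inverse_law(self):
        stats = DegreeStats(
            degrees=np.array([1, 2, 3]),
            ck={k: 1.0 / k for k in (2, 4, 8, 16)},
            ccdf=[(1, 1.0)],
        )
        gamma, r2 = fit_ck_scaling(stats)
        assert gamma == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_single_degree_errors(self):
        stats = DegreeStats(np.array([2]), {2: 0.5}, [(2, 1.0)])
        with pytest.raises(GRNError):
            fit_ck_scaling(stats)

    def test_all_zero_ck_errors(self):
        stats = DegreeStats(np.array([1, 2, 3]), {1: 0.0, 2: 0.0}, [(1, 1.0)])
        with pytest.raises(GRNError):
            fit_ck_scaling(stats)


class TestStructuralProfile:
    def test_fixed_order_and_length(self):
        net = make_grn([("A", "B"), ("B", "C"), ("A", "A")])
        vec = structural_profile(net).as_vector()
        assert vec.shape == (15,)
        assert len(PROFILE_FIELDS) == 15

    def test_counts_on_toy(self):
        net = make_grn([("A", "B"), ("A", "A"), ("C", "D")])
        p = structural_profile(net)
        assert p.direct_interactions == 3
        assert p.self_regulation_pct == pytest.approx(25.0)
        assert p.weakly_connected_components == 2
        assert p.giant_component_pct == pytest.approx(50.0)
        assert p.regulators_pct == pytest.approx(50.0)

    def test_empty_network_errors(self):
        with pytest.raises(GRNError):
            structural_profile(GRN())


class TestClusterProfiles:
    def _profiles(self, vectors, labels):
        from grnkit.netstats import StructuralProfile

        out = []
        for vec, label in zip(vectors, labels):
            out.append(StructuralProfile(*vec, label=label))
        return out

    def test_identical_profiles_merge_first(self, rng):
        base = rng.uniform(1, 10, 15)
        other = rng.uniform(1, 10, 15)
        profiles = self._profiles([base, base, other], ["a", "b", "c"])
        clustering = cluster_profiles(profiles)
        assert clustering.correlation[0, 1] == pytest.approx(1.0)
        first_merge = clustering.linkage[0, :2].astype(int)
        assert set(first_merge) == {0, 1}

    def test_order_invariance(self, rng):
        vecs = [rng.uniform(1, 10, 15) for _ in range(4)]
        labels = ["a", "b", "c", "d"]
        c1 = cluster_profiles(self._profiles(vecs, labels))
        c2 = cluster_profiles(self._profiles(vecs[::-1], labels[::-1]))
        # same pairwise correlation structure regardless of input order
        idx = [c2.labels.index(l) for l in c1.labels]
        assert np.allclose(c1.correlation, c2.correlation[np.ix_(idx, idx)])

    def test_single_profile_errors(self, rng):
        with pytest.raises(GRNError):
            cluster_profiles(self._profiles([rng.uniform(1, 10, 15)], ["a"]))

    def test_constant_profile_rejected_by_name(self, rng):
        vecs = [np.full(15, 3.0), rng.uniform(1, 10, 15)]
        with pytest.raises(GRNError, match="flatline"):
            cluster_profiles(self._profiles(vecs, ["flatline", "ok"]))


class TestDissimilarity:
    def test_self_dissimilarity_is_zero(self):
        g = nx.erdos_renyi_graph(12, 0.3, seed=1)
        assert network_dissimilarity(g, g) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_vs_path_positive(self):
        assert network_dissimilarity(nx.cycle_graph(3), nx.path_graph(3)) > 0

    def test_term1_only_on_identical_distance_distributions(self):
        # two disjoint unions with identical averaged distance histograms
        g1 = nx.path_graph(3)
        g2 = nx.path_graph(3)
        assert network_dissimilarity(g1, g2, weights=(1.0, 0.0, 0.0)) == pytest.approx(0.0)

    def test_symmetry_and_bounds_on_random_family(self, rng):
        graphs = [
            nx.gnp_random_graph(int(rng.integers(8, 20)), float(rng.uniform(0.15, 0.5)),
                                seed=int(rng.integers(1 << 30)))
            for _ in range(20)
        ]
        for i in range(0, 20, 3):
            for j in range(i + 1, 20, 4):
                d_ij = network_dissimilarity(graphs[i], graphs[j])
                d_ji = network_dissimilarity(graphs[j], graphs[i])
                assert d_ij == pytest.approx(d_ji, abs=1e-12)
                assert 0.0 <= d_ij <= 1.0

    def test_bad_weights_error(self):
        with pytest.raises(GRNError):
            network_dissimilarity(nx.path_graph(3), nx.path_graph(3),
                                  weights=(0.5, 0.5, 0.5))
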