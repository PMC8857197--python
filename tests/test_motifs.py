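"""PWM construction, exact-p-value scanning, regulon extension, regulogs."""

import itertools

import numpy as np
import pandas as pd
import pytest

from grnkit.core import (
    EvidenceLevel,
    GRN,
    GRNError,
    Gene,
    RegulatoryInteraction,
)
from grnkit.motifs import (
    BASES,
    MotifHit,
    PWM,
    UpstreamRegion,
    _ScoreModel,
    build_pwm,
    chip_validate,
    discover_motif,
    extend_regulons,
    extract_upstream,
    grn_wide_orthologs,
    regulogs_transfer,
    revcomp,
    scan,
)
from grnkit.synth import SynthConfig, plant_genome


def gene_table(rows):
    return pd.DataFrame(rows, columns=["locus_tag", "replicon", "start", "end", "strand"])


def one_hot_pwm(word, tf="T"):
    mat = np.zeros((len(word), 4))
    for i, base in enumerate(word):
        mat[i, BASES.index(base)] = 1.0
    return PWM(tf=tf, matrix=mat)


def enumeration_pvalue(pwm, observed_int, model):
    """Exhaustive p-value over all 4^w words under the background."""
    w = pwm.width
    total = 0.0
    for word in itertools.product(range(4), repeat=w):
        score = int(sum(model.int_scores[i, b] for i, b in enumerate(word)))
        if score >= observed_int:
            prob = 1.0
            for b in word:
                prob *= pwm.background[b]
            total += prob
    return total


class TestExtractUpstream:
    def test_truncation_at_upstream_neighbor(self):
        genome = {"chr": "A" * 2000}
        table = gene_table(
            [("up", "chr", 700, 850, "+"), ("g", "chr", 1000, 1500, "+")]
        )
        regions = {r.gene: r for r in extract_upstream(table, genome)}
        assert regions["g"].genomic_span == ("chr", 851, 1050, "+")
        assert len(regions["g"].sequence) == 200

    def test_full_window_when_no_neighbor(self):
        genome = {"chr": "C" * 2000}
        table = gene_table([("g", "chr", 1000, 1500, "+")])
        region = extract_upstream(table, genome)[0]
        assert len(region.sequence) == 351
        assert region.genomic_span == ("chr", 700, 1050, "+")

    def test_minus_strand_is_reverse_complemented(self):
        seq = "".join("ACGT"[i % 4] for i in range(2000))
        genome = {"chr": seq}
        table = gene_table([("g", "chr", 500, 1000, "-")])
        region = extract_upstream(table, genome)[0]
        assert region.genomic_span == ("chr", 950, 1300, "-")
        assert region.sequence == revcomp(seq[949:1300])

    def test_replicon_boundary_truncates(self):
        genome = {"chr": "G" * 400}
        table = gene_table([("g", "chr", 100, 300, "+")])
        region = extract_upstream(table, genome)[0]
        assert region.genomic_span == ("chr", 1, 150, "+")

    def test_unknown_strand_errors(self):
        genome = {"chr": "A" * 100}
        table = gene_table([("g", "chr", 10, 50, ".")])
        with pytest.raises(GRNError):
            extract_upstream(table, genome)


class TestBuildPWM:
    def test_columns_sum_to_one_with_pseudocount(self):
        pwm = build_pwm("T", ["ACGT", "ACGT", "ACGT", "ACGT"])
        assert np.allclose(pwm.matrix.sum(axis=1), 1.0)
        assert pwm.matrix[0, 0] > 0.95  # near one-hot after smoothing
        assert pwm.matrix[0, 1] > 0.0  # pseudocount keeps others positive

    def test_fewer_than_three_sites_refused(self):
        with pytest.raises(GRNError):
            build_pwm("T", ["ACGT", "ACGT"])

    def test_mixed_widths_error(self):
        with pytest.raises(GRNError):
            build_pwm("T", ["ACGT", "ACGTA", "ACGT"])

    def test_information_content_of_sharp_motif(self):
        pwm = build_pwm("T", ["ACGTACGTACGT"] * 10)
        assert pwm.information_content() > 1.8 * pwm.width


class TestExactPValues:
    def test_one_hot_width8_exact_match(self):
        pwm = one_hot_pwm("ACGTACGT")
        model = _ScoreModel(pwm)
        best = int(model.int_scores.max(axis=1).sum())
        assert model.p_value(best) == pytest.approx(0.25**8)
        region = UpstreamRegion("g", "TTTT" + "ACGTACGT" + "TTTT", ("chr", 1, 16, "+"))
        hits = scan(pwm, [region], p_threshold=1e-4)
        assert len(hits) == 1 and hits[0].position == 4

    def test_width4_best_p_cannot_pass_1e4(self):
        pwm = one_hot_pwm("ACGT")
        region = UpstreamRegion("g", "AAACGTAAA", ("chr", 1, 9, "+"))
        assert scan(pwm, [region], p_threshold=1e-4) == []
        model = _ScoreModel(pwm)
        assert model.p_value(int(model.int_scores.max(axis=1).sum())) == pytest.approx(
            0.25**4
        )

    def test_p_at_minimum_score_is_one(self):
        pwm = build_pwm("T", ["ACGT", "AGGT", "ACTT"])
        model = _ScoreModel(pwm)
        assert model.p_value(int(model.int_scores.min(axis=1).sum())) == 1.0

    @pytest.mark.parametrize("width", [4, 5, 6])
    def test_dp_equals_exhaustive_enumeration(self, width, rng):
        """DP tail probabilities equal full 4^w enumeration, for smoothed
        PWMs under uniform and skewed backgrounds."""
        for bg in (np.full(4, 0.25), np.array([0.14, 0.36, 0.36, 0.14])):
            sites = [
                "".join(rng.choice(list(BASES), width)) for _ in range(5)
            ]
            pwm = build_pwm("T", sites, background=bg)
            model = _ScoreModel(pwm)
            for _ in range(4):
                word = rng.integers(0, 4, width)
                observed = int(sum(model.int_scores[i, b] for i, b in enumerate(word)))
                assert model.p_value(observed) == pytest.approx(
                    enumeration_pvalue(pwm, observed, model), rel=1e-9
                )

    def test_scan_strand_symmetry(self, rng):
        """Reverse-complementing every region leaves the hit set unchanged."""
        sites = ["ACGGTTCAACGG"] * 4
        pwm = build_pwm("T", sites)
        seqs = [
            "".join(rng.choice(list(BASES), 60)) + "ACGGTTCAACGG"
            + "".join(rng.choice(list(BASES), 60))
            for _ in range(5)
        ]
        fwd_regions = [
            UpstreamRegion(f"g{i}", s, ("chr", 1, len(s), "+"))
            for i, s in enumerate(seqs)
        ]
        rc_regions = [
            UpstreamRegion(f"g{i}", revcomp(s), ("chr", 1, len(s), "+"))
            for i, s in enumerate(seqs)
        ]
        fwd_hits = {(h.gene, round(h.score, 6)) for h in scan(pwm, fwd_regions)}
        rc_hits = {(h.gene, round(h.score, 6)) for h in scan(pwm, rc_regions)}
        assert fwd_hits == rc_hits

    def test_bad_threshold_errors(self):
        pwm = one_hot_pwm("ACGTAC")
        with pytest.raises(GRNError):
            scan(pwm, [], p_threshold=1.5)


class TestDiscovery:
    def test_recovers_planted_consensus(self, rng):
        consensus = "TTGACAGCTAGC"
        regions = []
        for i in range(8):
            flank = "".join(rng.choice(list("ACGT"), 100))
            flank2 = "".join(rng.choice(list("ACGT"), 100))
            regions.append(
                UpstreamRegion(f"g{i}", flank + consensus + flank2,
                               ("chr", 1, 212, "+"))
            )
        pwm = discover_motif("T", regions, width=12)
        assert pwm.consensus() in (consensus, revcomp(consensus))

    def test_too_few_regions_errors(self):
        region = UpstreamRegion("g", "ACGTACGTACGT", ("chr", 1, 12, "+"))
        with pytest.raises(GRNError):
            discover_motif("T", [region, region], width=8)


class TestExtendRegulons:
    def _bundle(self, seed, n_prior=10, n_unseen=5, n_decoys=14):
        tf = "SG00000"
        prior_tgs = [f"SG{i:05d}" for i in range(1, n_prior + 1)]
        unseen = [f"SG{i:05d}" for i in range(n_prior + 1, n_prior + n_unseen + 1)]
        decoys = [
            f"SG{i:05d}"
            for i in range(n_prior + n_unseen + 1, n_prior + n_unseen + n_decoys + 1)
        ]
        inter = [
            RegulatoryInteraction(tf, t, evidence=EvidenceLevel.STRONG)
            for t in prior_tgs + unseen
        ]
        full = GRN(
            inter,
            genes=[Gene(g, replicon="chr") for g in [tf] + prior_tgs + unseen + decoys],
        )
        cfg = SynthConfig(
            n_genes=1 + n_prior + n_unseen + n_decoys, n_tfs=1, seed=seed,
            motif_width=12, motif_ic_per_column=1.5,
        )
        genome, table, _sites, _pwms = plant_genome(full, cfg)
        prior = GRN([i for i in inter if i.target in prior_tgs])
        regions = extract_upstream(table, genome)
        return prior, regions, set(prior_tgs), set(unseen)

    def test_recovers_planted_unseen_targets(self):
        prior, regions, _prior_tgs, unseen = self._bundle(seed=11)
        ranking = extend_regulons(prior, regions, p_threshold=1e-4, width=12)
        predicted = {t for _r, t, _s in ranking}
        assert len(predicted & unseen) >= 4

    def test_tf_below_three_targets_is_skipped(self):
        prior, regions, prior_tgs, _ = self._bundle(seed=3)
        two_targets = GRN(
            [v for k, v in list(prior.interactions.items())[:2]]
        )
        ranking = extend_regulons(two_targets, regions)
        assert len(ranking) == 0

    def test_empty_prior_gives_empty_ranking(self):
        _prior, regions, _p, _u = self._bundle(seed=4)
        assert len(extend_regulons(GRN(), regions)) == 0

    def test_never_emits_unknown_tf(self):
        prior, regions, _p, _u = self._bundle(seed=5)
        ranking = extend_regulons(prior, regions)
        prior_tfs = set(prior.regulators())
        assert {r for r, _t, _s in ranking} <= prior_tfs


class TestChipValidate:
    def test_intersection_is_relabeled_strong(self):
        weak = [
            RegulatoryInteraction("T", "a", experiments={"ChIP-seq"}),
            RegulatoryInteraction("T", "b", experiments={"ChIP-seq"}),
            RegulatoryInteraction("T", "c", experiments={"ChIP-chip"}),
        ]
        hits = [
            MotifHit("T", "a", 5, "+", 12.0, 1e-6),
            MotifHit("T", "b", 9, "-", 10.0, 5e-5),
        ]
        validated = chip_validate(weak, hits)
        assert {(v.regulator, v.target) for v in validated} == {("T", "a"), ("T", "b")}
        assert all(v.evidence is EvidenceLevel.STRONG for v in validated)

    def test_disjoint_inputs_give_empty_set(self):
        weak = [RegulatoryInteraction("T", "a", experiments={"ChIP-seq"})]
        assert chip_validate(weak, [MotifHit("T", "z", 0, "+", 5.0, 1e-5)]) == []


class TestRegulogs:
    def test_self_transfer_recovers_detectable_regulons(self):
        prior, regions, prior_tgs, unseen = TestExtendRegulons()._bundle(seed=21)
        identity = {g: g for g in {r.gene for r in regions}}
        out = regulogs_transfer(
            prior, regions, regions, identity, p_threshold=1e-4
        )
        transferred = {
            (i.regulator, i.target) for i in out.interactions.values()
        }
        detectable = {
            (r, t)
            for r, t, _s in extend_regulons(prior, regions, p_threshold=1e-4)
        }
        assert detectable <= transferred | set()
        # prior regulon should be among the detectable-and-transferred pairs
        assert sum(1 for (_r, t) in transferred if t in prior_tgs) >= 8

    def test_missing_tf_ortholog_blocks_transfer(self):
        prior, regions, _p, _u = TestExtendRegulons()._bundle(seed=22)
        mapping = {
            g: g for g in {r.gene for r in regions} if g not in prior.regulators()
        }
        out = regulogs_transfer(prior, regions, regions, mapping)
        assert out.n_interactions == 0

    def test_non_one_to_one_map_errors(self):
        prior, regions, _p, _u = TestExtendRegulons()._bundle(seed=23)
        with pytest.raises(GRNError):
            regulogs_transfer(
                prior, regions, regions, [("a", "x"), ("a", "y")]
            )

    def test_target_strong_placed_ahead(self):
        prior, regions, _p, _u = TestExtendRegulons()._bundle(seed=24)
        identity = {g: g for g in {r.gene for r in regions}}
        target_strong = GRN(
            [RegulatoryInteraction("SG00001", "SG00002",
                                   evidence=EvidenceLevel.STRONG)]
        )
        out = regulogs_transfer(
            prior, regions, regions, identity, target_strong=target_strong
        )
        assert ("sg00001", "sg00002") in out.interactions
        assert out.interactions[("sg00001", "sg00002")].evidence is EvidenceLevel.STRONG


class TestGrnWideOrthologs:
    def test_identity_map_identical_networks(self):
        net = GRN([RegulatoryInteraction("A", "B")])
        mapping = {"A": "A", "B": "B"}
        assert grn_wide_orthologs(net, net, mapping) == {("A", "A"), ("B", "B")}

    def test_empty_map(self):
        net = GRN([RegulatoryInteraction("A", "B")])
        assert grn_wide_orthologs(net, net, {}) == set()

    def test_pairs_require_membership_on_both_sides(self):
        net_a = GRN([RegulatoryInteraction("A", "B")])
        net_b = GRN([RegulatoryInteraction("X", "Y")])
        mapping = {"A": "X", "B": "Q"}
        assert grn_wide_orthologs(net_a, net_b, mapping) == {("A", "X")}
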