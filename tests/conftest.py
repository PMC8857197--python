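import numpy as np
import pytest

from grnkit.core import (
    EvidenceLevel,
    Effect,
    GRN,
    Gene,
    RegulatoryInteraction,
)


def make_grn(edges, label="toy", genes=None, replicon=None):
    """Build a GRN from (reg, tgt[, evidence[, effect]]) tuples."""
    interactions = []
    for edge in edges:
        reg, tgt = edge[0], edge[1]
        evidence = edge[2] if len(edge) > 2 else EvidenceLevel.WEAK
        effect = edge[3] if len(edge) > 3 else Effect.UNKNOWN
        interactions.append(
            RegulatoryInteraction(reg, tgt, evidence=evidence, effect=effect)
        )
    gene_objs = []
    if genes:
        gene_objs = [Gene(g, replicon=replicon) for g in genes]
    elif replicon is not None:
        tags = {t for e in edges for t in e[:2]}
        gene_objs = [Gene(g, replicon=replicon) for g in tags]
    return GRN(interactions, genes=gene_objs, label=label)


@pytest.fixture
def diamond_grn():
    """The hand-traced NDA fixture: one GR, two modules, one intermodular."""
    return make_grn(
        [("G", "A"), ("G", "B"), ("G", "Z"), ("A", "X"), ("A", "W"),
         ("B", "Y"), ("B", "W")]
    )


@pytest.fixture
def mixed_evidence_grn():
    return make_grn(
        [
            ("A", "B", EvidenceLevel.STRONG),
            ("A", "C", EvidenceLevel.STRONG),
            ("B", "C", EvidenceLevel.STRONG),
            ("B", "D", EvidenceLevel.WEAK),
            ("C", "E", EvidenceLevel.WEAK),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
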