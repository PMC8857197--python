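"""Cross-species regulon transfer through 1:1 orthologs.

Creates a paired "organism B" by deleting 20% of organism A's genes,
plants A's binding sites in both genomes, and transfers A's strong
regulons to B: a prediction is kept only when both the TF and the target
have a strict one-to-one ortholog.
"""

from grnkit import (
    EvidenceLevel,
    GRN,
    RegulatoryInteraction,
    SynthConfig,
    grn_wide_orthologs,
    make_ortholog_pair,
    regulogs_transfer,
)
from grnkit.core import Gene
from grnkit.motifs import extract_upstream
from grnkit.synth import plant_genome

tf = "SG00000"
targets = [f"SG{i:05d}" for i in range(1, 13)]
others = [f"SG{i:05d}" for i in range(13, 25)]
net_a = GRN(
    [RegulatoryInteraction(tf, t, evidence=EvidenceLevel.STRONG) for t in targets],
    genes=[Gene(g, replicon="chr") for g in [tf] + targets + others],
    label="organism_A",
)
config = SynthConfig(n_genes=25, n_tfs=1, seed=5, motif_width=12,
                     ortholog_retention_fraction=0.8)

net_b, orthologs = make_ortholog_pair(net_a, config)
print(f"organism B keeps {len(orthologs)}/{len(net_a)} genes "
      f"({net_b.n_interactions} surviving interactions)")

genome_a, table_a, _sites_a, _ = plant_genome(net_a, config)
# organism B's genome: same layout under B's locus tags for surviving genes
table_b = table_a[table_a["locus_tag"].isin(orthologs)].copy()
table_b["locus_tag"] = table_b["locus_tag"].map(orthologs)
regions_a = extract_upstream(table_a, genome_a)
regions_b = extract_upstream(table_b, {"chr": genome_a["chr"]})

# organism B's own curation only knows a few of its interactions
known_b = GRN(list(net_b.interactions.values())[:3], label="B_strong")
complemented = regulogs_transfer(
    net_a, regions_a, regions_b, orthologs, p_threshold=1e-4,
    target_strong=known_b,
)
novel = [
    (i.regulator, i.target)
    for i in complemented.interactions.values()
    if i.evidence is not EvidenceLevel.STRONG
]
print(f"complemented B network: {complemented.n_interactions} interactions "
      f"({len(novel)} transferred beyond B's own strong set)")
shared = grn_wide_orthologs(net_a, complemented, orthologs)
print(f"GRN-wide orthologs between A and complemented B: {len(shared)}")
# Only targets whose ortholog survives in B receive transferred
# interactions; B's own strong interactions stay at the head of the list.
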