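"""System-level decomposition of a GRN with the NDA.

Samples a synthetic scale-free network, identifies global regulators with
the elbow rule on the ranked out-degree curve, and partitions every gene
into the four system-level classes.
"""

from grnkit import (
    SynthConfig,
    identify_global_regulators,
    nda_classify,
    nda_summary,
    sample_grn,
)

config = SynthConfig(n_genes=300, n_tfs=30, seed=42)
network = sample_grn(config)
print(f"network: {len(network)} genes, {network.n_interactions} interactions")

grs = identify_global_regulators(network)  # elbow strategy (default)
print(f"global regulators (elbow cut): {grs}")

result = nda_classify(network, grs)
summary = nda_summary(result, len(network))
for cls, count in summary.counts.items():
    print(f"  {cls.value:>18}: {count:4d} ({summary.percentages[cls]:.2f}%)")
print(f"modules: {len(result.modules)}")
# Every gene lands in exactly one class; genes regulated only by the
# global regulators form the basal machinery, the weakly connected pieces
# left after GR removal are the functional modules, and multi-module
# integrator targets are the intermodular genes.
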