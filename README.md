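# grnkit

Curation, inference, and assessment of bacterial gene regulatory networks
(GRNs), built for organisms like *Streptomyces coelicolor* whose regulatory
knowledge is scattered across decades of literature and several databases.
The package is an importable Python library (with a thin `grn` command-line
wrapper) for the full reconstruction loop:

1. **Meta-curation** — merge curated interaction lists on locus-tag keys,
   grading every interaction *strong* (an experiment proves the TF binds
   upstream of the target: EMSA, in vitro transcription, footprinting) or
   *weak* (possibly indirect: ChIP, transcriptomics, RT-PCR), and resolving
   conflicts (evidence → maximum level, effect → *dual*).
2. **System-level decomposition (NDA)** — partition the genes of a GRN into
   global regulators, modular genes, intermodular genes, and basal
   machinery from graph structure alone, and derive the functional modules.
3. **Inference from binding sites** — build a position weight matrix (PWM)
   for every TF with ≥ 3 strong targets from the −300..+50 bp
   non-overlapping upstream regions of its targets, scan all upstream
   regions on both strands with *exact* p-values (dynamic programming over
   discretized log-odds scores), and extend regulons at p < 10⁻⁴.
4. **Inference from expression** — mutual information on equal-frequency
   discretized profiles, ranked by CLR (z-scores against row backgrounds,
   edge score √(z_i² + z_j²)) and MRNET (greedy max-relevance /
   min-redundancy), restricted to a supplied TF list for causality.
5. **Community networks** — aggregate ranked prediction lists by mean rank
   position (missing entries penalized with list length + 1) and prune to
   the expected size of the complete GRN.
6. **Assessment** — AUPR/AUROC against a curated gold standard
   (precision = TP/(TP+FP), recall = TP/(TP+FN), FPR = FP/(FP+TN));
   MCC/precision/F1 for global-regulator calls; Simpson similarity
   |A∩B|/min(|A|,|B|) between gene classes; 15-property structural
   profiles with power-law fits of P(k) ~ k^−α (robust CCDF regression
   and discrete MLE with KS model comparison), C(k) ~ k^−1 scaling,
   Pearson/Ward profile clustering, and a size-robust network
   dissimilarity D built from node-distance distributions.
7. **Regulogs transfer** — extrapolate strong regulons between organisms by
   PWM scanning, keeping only predictions where both TF and target have a
   strict 1:1 ortholog.

A synthetic-data module (`grnkit.synth`) generates scale-free GRNs,
linear-SEM expression compendia, genomes with planted binding sites, and
paired "orthologous organisms", so the entire pipeline is testable offline.

## Worked example

Recover a known network from simulated expression data
(`examples/04_expression_inference.py`):

```python
from grnkit import (SynthConfig, clr, mrnet, mutual_information,
                    pr_curve, restrict_to_gold, roc_curve,
                    sample_grn, simulate_expression)

config = SynthConfig(n_genes=50, n_tfs=10, seed=3, noise_sd=0.5)
network = sample_grn(config)                 # scale-free GRN, alpha = 2.5
expression = simulate_expression(network, config)   # 137 conditions
mi = mutual_information(expression)          # bins = floor(sqrt(137)) = 11
ranking = restrict_to_gold(clr(mi, network.gene_tags()[:10]), network)
print(roc_curve(ranking, network).auc, pr_curve(ranking, network).auc)
```

prints

```
    CLR: AUROC=0.908  AUPR=0.597 (23.0x random expectation 0.026)
  MRNET: AUROC=0.860  AUPR=0.600 (23.1x random expectation 0.026)
```

i.e. both mutual-information methods rank the true TF→gene edges far above
the random baseline (the fraction of the TF×gene search space that is a
true edge, here 0.026). The other `examples/` scripts demonstrate
meta-curation, NDA decomposition (e.g. a 300-gene synthetic network splits
into 2 global regulators, 49 modular genes in 23 modules, 5 intermodular
genes, and 244 basal-machinery genes), planted-motif regulon extension
(5/5 held-out targets recovered at p < 10⁻⁴ with no decoy hits),
community integration, structural comparison, and regulogs transfer.

The `grn` CLI exposes the same operations from a shell
(`grn merge`, `grn filter-strong`, `grn summary`, `grn nda`, `grn assess`,
`grn community`, `grn structure`, `grn compare`, `grn infer-expr`,
`grn simulate`, `grn recipe`).

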