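# Methods

This note records the models, conventions, and numerical choices behind
grnkit, and what the synthetic test bed does and does not establish.

## Data model and evidence grading

A GRN is a directed graph over genes keyed by locus tag (case-preserved,
compared case-insensitively); interaction identity is the (regulator,
target) pair, and sigma-factor and TF interactions are not distinguished
structurally. Evidence has exactly two levels with strong > weak; an
interaction is strong iff at least one supporting experiment type maps to
strong in the experiment catalog. The shipped seed catalog grades EMSA,
in vitro transcription, and footprinting as strong, and the ChIP family,
microarray, RNA-seq, RT-PCR, DACA, and knockout read-outs as weak; it is
user-extensible, and unknown experiment strings are rejected rather than
silently defaulted (silent weak-grading would corrupt gold standards).
Merging unions genes, experiments, and sources; evidence resolves to the
maximum level and an activation/repression conflict to *dual*. Genes
without any incident interaction are dropped from curated networks, so
gene counts mean "genes participating in the network".

## Natural Decomposition Approach

Given a global-regulator (GR) set, classification proceeds on the
*residual* graph obtained by deleting the GRs, their incident edges, and
self-loops:

1. genes with no residual edges (regulated only by GRs, isolated, or only
   self-regulating) are **basal machinery** — a self-loop alone creates no
   module structure;
2. pure-target genes (residual out-degree 0) with ≥ 2 distinct residual
   regulators are *integrator candidates*; weak components are computed
   with the candidates removed;
3. a candidate whose regulators fall in ≥ 2 components is **intermodular**
   and belongs to no module; otherwise it rejoins its single component;
4. the resulting components are the **modules** (weak connectivity, since
   modules contain non-TF targets reachable only along edge direction),
   and their members are **modular** genes.

Intermodular detection is a single pass after the initial components; the
procedure is deterministic (components ordered by smallest member).

**Submodules.** Within each module, members that integrate ≥ 2 internal
inputs *and* are articulation points of the module's undirected induced
subgraph are removed; if the module then splits, the weak components are
its submodules (subparts held together through integrator genes, mirroring
at module scale how intermodular genes connect modules). This rule is the
package's own declared stand-in: the original submodule derivation is not
published in an implementable form. An earlier draft removed rejoined
multi-input *sinks* instead, but a sink's removal can never disconnect its
component, so that rule is vacuous by construction.

**GR identification.** The exact published GR criterion is likewise not
available in implementable form, so the default is a documented elbow
rule: regulators are ranked by out-degree and the cut placed at the point
of maximum perpendicular distance between the rank–connectivity curve and
its chord, extended across out-degree ties so equal hubs are all-in or
all-out. When every regulator has the same out-degree there is no elbow
and the GR set is empty (with a warning). A `fixed_set` strategy injects
an externally curated GR list (for reproducing published decompositions)
and `threshold` keeps all regulators above an out-degree floor.

## Assessment

Ranked predictions are walked in tie groups — all entries sharing a score
form one PR/ROC point — so curves are deterministic and no optimistic
within-tie ordering is assumed. AUPR integrates precision over recall by
the trapezoid rule, anchored at (0, first-precision); AUROC likewise over
FPR, with never-ranked universe pairs appended as one tied block (the
random-ordering equivalent). The negative universe is the TF → gene
search space of the gold standard — all ordered pairs whose source is a
gold regulator, self-loops included, matching how inference methods are
given a TF list — not all gene pairs. Predictions with an endpoint
outside the gold gene set are excluded from scoring rather than counted
as false positives, because the gold standard is incomplete. MCC is
defined 0 when any margin of the 2×2 table is zero.

## Binding-site engine

Upstream regions span −300..+50 relative to the strand-aware annotated
gene start, truncated at the nearest annotated boundary of the adjacent
upstream gene regardless of its strand ("non-overlapping"), and clipped at
replicon ends (coordinates 1-based inclusive throughout). PWMs require
≥ 3 binding sites; columns are (count + 0.1·background)/(n + 0.1).
Scanning scores log₂(p/background) on both strands, keeps the best hit
per gene, and computes the p-value — the probability that a random
width-w word under the 0-order background scores at least as high —
*exactly* by dynamic programming over integer-discretized scores
(granularity 10⁻³ log-odds units, which is also the exactness bound;
zero-probability cells are floored at −30 bits, far below any attainable
match score). The background is estimated from the scanned region set by
default (switchable to uniform).

Motif discovery is a deliberately simple information-content-maximizing
common-window search (each window of the first region seeds an alignment;
the best-matching window per region, either strand, is selected; the
highest-IC alignment wins). External discovery tools can be substituted
by importing MEME-format motifs. ChIP statistical validation intersects
ChIP-only weak interactions with motif hits and upgrades the intersection
to strong. Regulogs transfer builds PWMs from the source organism's
strong regulons, scans the target organism, keeps predictions where both
TF and target have strict 1:1 orthologs, deduplicates to the best p-value
per pair, and places the target organism's own strong interactions ahead
of the predictions.

## Expression-based inference

Mutual information uses equal-frequency (rank-based) discretization with
bins = ⌊√conditions⌋ by default and the maximum-likelihood plug-in
estimator; estimates are therefore invariant under strictly monotone
per-gene transforms. Constant genes get MI = 0 with a warning. CLR and
MRNET follow their standard definitions with the TF constraint supplying
edge direction; MRNET selection stops when the best
relevance-minus-redundancy score is no longer positive. The Friedman and
Statmodel method variants are not implemented (no public definition);
their rankings, like GENIE3/TIGRESS/Inferelator output, enter through the
external-ranking adapter. Expression preprocessing (normalization, batch
correction) is upstream of this package; the loader only validates
completeness.

## Community integration

Ranks are 1-based positions after per-list lexicographic tie-breaking;
an interaction absent from a list contributes that list's length + 1; the
community score is the plain mean (no method weighting), and the
aggregate is pruned to the expected complete-GRN size (23,908 for the
default organism). The returned ranking stores the *negated* mean rank so
the package-wide "higher score = higher confidence" convention holds.
A community of communities is built by re-running the same integration.

## Structural statistics

The 15-property profile: regulators (%), direct interactions,
self-regulation (%), maximum out-connectivity (%), density (simple
directed graph, self-loops excluded), weakly connected components, giant
component (%), feed-forward circuits (ordered triples A→B, A→C, B→C),
complex FFCs, 3-feedback loops (directed 3-cycles counted once per node
set), average shortest path and diameter (undirected giant component),
average clustering coefficient (undirected simple graph), and the
adjusted R² of the P(k) and C(k) fits (NaN when a fit is undefined on
toy networks; NaN features are dropped before profile clustering).
"Complex FFC" is not defined in the public record; the shipped counter
(an FFC with at least one reciprocated edge) preserves the profile slot
and can be swapped. Degree for P(k) is total degree on the simple graph
(switchable to in/out).

Power-law exponents are estimated two independent ways: (1) Huber-IRLS
robust regression (50 iterations, tol 10⁻⁸) of log CCDF on log k with
α = |slope| + 1; (2) discrete maximum likelihood with xmin chosen by KS
minimization over observed degrees (tails of ≥ 10 observations, at most
40 xmin candidates), compared by KS distance against exponential,
stretched-exponential, lognormal, and truncated power-law alternatives
normalized by direct summation of the tail grid. C(k) scaling is OLS of
log mean-clustering on log degree over degrees with positive clustering.

Profile clustering Pearson-correlates profile vectors (optional min–max
feature scaling first) and Ward-links the Euclidean distances between
correlation rows. The dissimilarity D uses weights (0.45, 0.45, 0.1):
Jensen–Shannon divergence between averaged node-distance distributions
(disconnected pairs in an "unreachable" bin), the √NND difference, and an
α-centrality comparison (α = 1/n, sorted normalized centrality vectors as
distributions) averaged over each graph and its complement — the term
that discriminates network size. All terms operate on the undirected
simple projection, for which the measure is defined.

## Synthetic data (study conditions)

Defaults are fixed once as the study conditions: 137 expression
conditions (the compendium size of the motivating organism), noise SD
0.5, strong fraction 0.06 (the curated strong share), GC content 0.72
(Streptomyces-like), motif width 12 at 1.5 bits/column, scale-free target
exponent 2.5 (inside the (2,3) band of bacterial GRNs), ortholog
retention 0.8. Every generator is a pure function of (config, seed).

TF out-degrees are drawn from a discrete power law (inverse CDF) and
targets attached preferentially by in-degree. Expression follows a
linear-Gaussian SEM — roots ~ N(0,1), each regulated gene the signed
weighted sum (w ~ U(0.5, 1.5)) of its regulators plus noise — solved
*exactly* as x = (I − W)⁻¹e: a damped fixed-point iteration was
considered and rejected because it diverges whenever a feedback loop has
|weight product| > 1 even though the SEM solution exists; an
ill-conditioned system (loop product ≈ 1) raises an error naming the
genes. Genomes lay genes in tandem with 400-bp gaps so every full
−300..+50 window exists; one site per true target is embedded at a random
offset/strand. The paired organism is a relabeled copy with a random
gene fraction deleted.

What the generators do *not* emulate: operon structure and shared
promoters, condition-specific regulation, sigma-factor competition,
nonlinear or saturating kinetics, and the heavy inter-study heterogeneity
of real compendia. Passing recovery tests therefore demonstrates that the
inference machinery is correct and well-calibrated under its own model
assumptions, not that it attains the same accuracy on real expression or
sequence data.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run exhaustively where exhaustion is cheap
(all ≤ 6-pair ranking instances; all 4ʷ words for widths ≤ 8; all 4-node
digraphs) and on seeded 5-node samples for motif counts. Parameter
recovery uses the 50-gene/10-TF/137-condition SEM benchmark (20 seeds),
discrete power-law samples of n = 2000 (20 seeds per exponent), and
planted-motif genomes of 30 genes — 1 TF, 10 prior targets, 5 held-out
targets, 14 decoys — for 50 replicates; the elbow-robustness check uses a
300-gene network and 100 edge-removal trials. The acceptance script runs
10-seed versions of the stochastic recoveries and 5-seed power-law fits.
These sizes are the package's chosen benchmark conditions; recoveries are
stable across seeds at these sizes.

## Known limitations

- The GR elbow rule and the submodule rule are declared stand-ins for
  unpublished criteria; `fixed_set` injection exists precisely so
  published GR lists can reproduce published decompositions downstream.
- Exact motif p-values are exact only up to the score-discretization
  granularity; ties created by discretization are resolved conservatively
  (tail probability at the discretized score).
- The built-in motif discovery is seed-and-align, not EM or Gibbs
  sampling; weak or gapped motifs that published discovery tools find may
  be missed. Import MEME motifs for parity.
- MRNET emits only edges selected with positive MRMR scores, so its
  ranking is typically shorter than CLR's on the same input.
- The dissimilarity measure is O(n²)–O(n³) per pair (all-pairs shortest
  paths, dense solve for α-centrality) and is intended for networks up to
  a few thousand nodes.
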