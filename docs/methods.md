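# Methods

This note documents the models implemented in `lrgat`, the parameters that
matter, what the synthetic data generator does and does not emulate, and the
design choices made where the design was genuinely open.

## Pipeline overview

Input: a genes × cells count matrix; a prior-knowledge bundle of curated
ligand–receptor (LR) pairs, protein–protein interactions, protein complexes
and pathway memberships keyed by gene symbol; optionally per-cell spatial
coordinates. Output: a ranked list of candidate LR interactions with
source/destination cluster assignments, plus validation metrics.

Stages: QC filtering → per-cell normalisation → PCA → kNN graph → Leiden
clustering → per-cluster profiles → prior LR graph + Node2Vec position
matrix → inference graph + feature matrix → GATv2 link scorer → ranking →
evaluation (and spatial proximity when coordinates exist).

## Preprocessing and clustering

Counts are scaled per cell to a common target and log1p-transformed.
`target_sum=1e4` is the genome-wide scRNA-seq convention; passing `None`
scales to the median per-cell total instead, which keeps the post-log
dynamic range sensible for small gene panels (the small-dataset preset uses
this). Cells/genes failing `min_genes_per_cell` (default 200) or
`min_cells_per_gene` (default 3) are dropped; the small preset relaxes both
to 1.

The cell graph is an exact k-nearest-neighbour graph (default k = 15,
union-symmetrised, no self-loops) on deterministic full-SVD PCA coordinates
(default 30 components, capped at min(genes, cells) − 1). PCA + kNN was
chosen over approximate/fuzzy neighbour schemes so the adjacency is exactly
reproducible and testable against a brute-force O(n²) oracle.

Leiden optimises the resolution-parameterised configuration-model quality

    θ = (1/2J) Σ_c [ e_c − γ K_c² / (2J) ],

with J the edge count, e_c the within-community adjacency sum and K_c the
community degree sum (γ default 1.0). The quality attached to a partition is
re-evaluated directly from this formula, never taken from the optimiser's
internal bookkeeping.

A ligand/receptor gene counts as *expressed* in a cluster when its mean
normalised expression there exceeds τ (default 0, strict), so genes never
detected in a cluster cannot acquire cluster→gene edges. τ is one knob and
deliberately also serves as the "upregulated" rule — no separate test
statistic is introduced.

## Prior model

Nodes are the LR genes present both in the dataset and in at least one
curated pair; edges are the curated pairs with both endpoints present. The
annotation `W[m,n]` counts complexes plus pathways containing both genes
(computed as a sum of membership Gram matrices; the diagonal is the number
of groups containing the single gene — a convention, since a self-pair has
no external definition).

Node2Vec runs second-order biased random walks (p = q = 1 by default,
walk length 20, 10 walks per node, window 5) along edge direction, with
transition weights `1 + W[m,n]` so annotation-supported edges are favoured
but unannotated edges remain walkable; walks restart at their start node at
dead ends (pure receptors). Skip-gram with negative sampling (2 negatives,
unigram^0.75 noise) is optimised by full-batch gradient descent for 100
epochs at learning rate 0.5 — full-batch gradients are averaged over the
walk-pair corpus, so the step size is larger than per-pair SGD conventions
would suggest. Embeddings are 2-D; the position matrix is the ligand ×
receptor block of the embedding Gram matrix. Everything is deterministic
under the seed; isolated nodes keep their random initial coordinates.

## Inference graph and features

Nodes are clusters plus LR genes. Directed edges: cluster → gene for every
expressed LR gene, ligand → receptor for curated pairs. The pairwise
feature matrix X is filled case-wise:

* gene–gene: `Y_m·Y_n + A[m,n]`, with Y the overall mean normalised
  expression; for curated pairs A is the prior position value (default) or
  the raw annotation W (config switch `a_source` — the referent is ambiguous
  and both are implemented); for other gene pairs A = W.
* cluster–gene: the within-cluster mean expression (filled symmetrically).
* cluster–cluster: the minimum spatial distance between the clusters when
  coordinates were supplied, else 0. The raw distance is used (smaller =
  closer), not a transformed similarity.

Per-node input features are the node's row of X compressed by truncated SVD
to `feature_dim` (default 8) and rescaled by a single global RMS factor.
The rows are deliberately *not* centred: X entries are non-negative
magnitudes whose zero is meaningful, and centring would make "both silent"
gene pairs look spuriously similar (empirically this destroyed the
feature-level separation of co-expressed pairs).

## GATv2 link scorer

Single-head GATv2 layers: attention score
`l(h_m,h_n) = bᵀ LeakyReLU(O[h_m‖h_n])` (slope 0.2), max-stabilised softmax
over in-neighbourhoods (self-loops added so none is empty), aggregation
`σ(Σ α O h_n)` with ELU between layers and identity output. Two additions,
both standard GAT options: a per-layer residual projection and an
input-skip projection `emb += P h_input`. Because one projection applies to
every node, the inner-product decoder acquires a positive semi-definite
term `h_mᵀPᵀP h_n` and feature similarity can reach the score for node
pairs the supervision never saw.

Defaults: 2 layers, hidden 16, output 2-D, Adam at 0.01 for 200 epochs.
The final layer and skip are initialised at 0.1 scale so edge scores start
near zero and the balanced binary cross-entropy starts at log 2. Loss:
BCE on `σ(⟨emb_l, emb_r⟩)` with curated pairs labelled 1 and shuffled
negatives 0 (the Bernoulli negative log-likelihood; cross-entropy and NLL
coincide here). Gradients are analytic and checked against central
differences in the tests. Training aborts on non-finite loss.

The communication score of a pair is the raw inner product (the ranking
statistic); a sigmoid column is provided for readability. Ties are broken
lexicographically. Source/destination clusters are argmaxes of
cluster-embedding inner products with the ligand/receptor embedding — note
these assignments can be degenerate (one dominant cluster claiming most
genes), which is a property of the inner-product assignment rule, not a
bug.

## Supervision and evaluation protocol

Positives are the curated edges present in the data; negatives are fresh
shuffled pairings (1:1 by default) drawn from the same gene vocabulary,
restricted to the rankable ligand × receptor grid and never colliding with
curated pairs. An 80/20 stratified split defines training and validation
pairs; the GAT trains on the training split only, the ACC threshold is
chosen on the training split, and ACC/AUC are reported on validation
(ties get half credit in AUC).

`fit(holdout_pairs=...)` removes named pairs from supervision (both as
positives and as permissible negatives) while keeping their curated edges
in the graphs — the analogue of a database train/validation split.
`holdout_edges=True` additionally strips them from the prior graph and
message passing (strict link-prediction protocol).

## Synthetic worlds

The generator emulates a clustered scRNA-seq experiment with an
OmniPath-style prior: negative-binomial counts (dispersion 0.5, so
var = μ + 0.5 μ², matching droplet-data overdispersion) with per-(gene,
cluster) lognormal mean heterogeneity (σ = 0.5) that makes clusters
separable; a curated LR table whose first `n_planted` pairs are planted —
ligand mean multiplied by `effect_size` in a source cluster, receptor in a
destination cluster; random complexes/pathways; optional Gaussian-blob
spatial layout matching the generative clusters. Defaults: 60 genes, 240
cells, 3 clusters, 6 LR pairs, 2 planted, effect size 8.

Planted pairs receive no preferential complex/pathway co-membership by
default (`co_membership_enrichment = background = 0`): annotation sharing
is a property of curation databases, which cannot know which pairs are
active in a given tissue, and any differential annotation would make
planted pairs separable from negatives at *every* effect size, destroying
the effect-size-1 null that the recovery experiment relies on. The knob
exists for experiments that want enriched priors.

Not emulated: batch effects, dropout beyond NB sampling, realistic gene
vocabularies, multi-subunit complexes acting as receptors, hub structure in
the LR network (each gene appears in exactly one curated pair). Passing
tests on these worlds therefore show the machinery is correct and the
pipeline can rank strongly co-expressed curated pairs highly; they do not
show performance on real tissues.

## Recovery experiment and its honest limits

`recovery_experiment` measures, across generator seeds and effect sizes,
the AUC of planted pairs against 20 shuffled negatives under three
protocols (planted pairs in supervision; excluded from supervision;
excluded from supervision and graphs). The default is the
excluded-from-supervision protocol.

Measured behaviour (20 seeds): the training loss always falls from ≈log 2
to near zero, and median recovery AUC rises from ≈0.55–0.66 at effect size
1 to ≈0.64–0.68 at effect size 8, with large per-seed variance. The
ceiling is informational, not a bug: the supervision (curated vs shuffled
pairs, neither class co-expressed) contains no example connecting
co-expression to the positive label, so the trained 2-D decoder transmits
the — clearly present — feature-level signal (the X entry alone separates
planted pairs from negatives at AUC ≈ 1.0 at effect 8) only partially and
with seed-dependent sign noise. Under the strict protocol the signal does
not transmit at all; with planted pairs in supervision the AUC at effect 8
reaches ≈0.8 but curated pairs then outrank negatives at every effect
size, so there is no null. Users should treat the ranking as an
integration of prior evidence and expression, not as a detector of novel
links absent from the prior.

## Numerical and degenerate-input choices

All-zero cells are left as zeros with a warning. Softmax attention is
max-stabilised. AUC ties take half credit. Population variance (divide by
k) in spatial proximity summaries. Unknown spatial types raise named
errors; pairs with unresolvable clusters are skipped and counted. Empty
neighbourhoods cannot occur (self-loops). Seeds: one integer drives the
whole pipeline; internal stages derive fixed offsets from it.
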