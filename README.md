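# lrgat

Ligand–receptor cell–cell communication inference from scRNA-seq, combining
curated prior knowledge with expression data through graph embeddings and a
graph attention (GATv2) link scorer.

## The problem and the approach

Cells signal to each other through ligand–receptor (LR) binding. Most
computational tools score candidate LR pairs from expression of the two genes
alone; this package additionally exploits protein–protein interactions,
protein-complex membership and pathway co-membership, on the premise that an
interaction supported by independent protein-level evidence is more likely to
be real.

The pipeline has two models:

1. **Prior model.** Curated LR pairs present in the dataset form a directed
   ligand→receptor graph. Every node pair `(m, n)` is annotated with
   `W[m,n] = z(m,n) + a(m,n)` — the number of protein complexes plus the
   number of pathways containing both genes. Node2Vec random walks (biased by
   `1 + W` edge weights) embed each node in 2-D, and the inner products of
   these coordinates form a ligand × receptor *position matrix* summarising
   prior-network proximity.
2. **Communication model.** Cells are clustered with Leiden on a PCA/kNN
   graph, optimising the resolution-parameterised quality
   `θ = (1/2J) Σ_c [e_c − γ K_c²/(2J)]`. A second graph over clusters ∪
   ligands ∪ receptors is built: each cluster points to the LR genes it
   expresses, curated LR edges connect genes, and a pairwise feature matrix
   `X` mixes mean-expression products, the prior position values, and (when
   spatial coordinates exist) minimum inter-cluster distances. A GATv2
   network — attention `l(h_m,h_n) = bᵀ LeakyReLU(O[h_m‖h_n])`, softmax
   normalisation, weighted aggregation — is trained with binary cross-entropy
   to score curated pairs above shuffled-pair negatives. The final 2-D node
   embeddings give every ligand × receptor pair a communication score
   `⟨emb_l, emb_r⟩`; pairs are ranked, and each side is assigned the cluster
   whose embedding best matches the ligand (source) or receptor (destination).

Evaluation follows the standard protocol: negatives are shuffled pairings
disjoint from the curated set, an 80/20 stratified split separates training
from validation pairs, and performance is reported as ACC (threshold chosen
on the training split) and tie-aware AUC.

GATv2, its backpropagation, and Node2Vec are implemented in numpy inside the
package; clustering uses `leidenalg`, linear algebra and kNN use
numpy/scikit-learn, and all file formats go through scipy/pandas.

## Worked example

Everything runs on generated data — no downloads. The canned tiny world has
20 genes, 60 cells in 3 clusters, 6 curated LR pairs of which 2 are
"planted": their ligand is 8-fold elevated in a source cluster and their
receptor in a destination cluster.

```python
from lrgat import CellCommunication, RunConfig, fixture_small

fx = fixture_small(seed=0)
res = CellCommunication(fx.data, fx.bundle, RunConfig.small()).fit(seed=0)
print(res.summary())
```

```
Cell-cell communication (GATv2 link scorer)
=======================================================
clusters:            3 (resolution 1.0, quality 0.4940)
prior LR edges:      6 over 12 genes
candidate pairs:     36
held-out pairs:      0
training loss:       0.6931 -> 0.0000 (200 epochs)
validation ACC:      1.000 (threshold 15.732)
validation AUC:      1.000 (1 pos / 1 neg)

top 10 interactions:
 rank ligand receptor     score  probability  source_cluster  dest_cluster
    1   G003     G011 44.148992          1.0               2             2
    2   G002     G007 43.238664          1.0               1             1
    ...
```

The header reports the Leiden partition (3 clusters recovered, quality is the
resolution-parameterised modularity of the returned partition), the size of
the usable prior (6 curated edges over the 12 LR genes present), the
training-loss trajectory (from log 2 ≈ 0.693 at balanced initialisation to
~0 after 200 epochs), and validation metrics on the held-out 20% of
curated-vs-shuffled pairs (a single pair each way on a world this small —
see `scripts/acceptance.py` for better-powered estimates). Each ranked row
is one candidate interaction: its inner-product score, a sigmoid-transformed
probability column, and the argmax source/destination clusters. One planted
pair (`G002→G008`, planted route cluster 1 → 2) appears in the top ten.

`res.save(outdir)` writes the ranking, score matrix, cluster labels, metrics
and config; `lrgat run ... --outdir out/` does the same from the shell and
adds chord/Sankey JSON exports of the top-10 interactions. With spatial
coordinates (`fixture_small(spatial=True)` or a `cell_id,x,y` CSV),
`res.proximity()` summarises the minimum inter-cluster distances of the
top-ranked predictions.

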