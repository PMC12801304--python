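# Methods

## Problem

Given a peptide of 8–20 amino acids, predict whether it induces
interferon-gamma (IFN-γ) secretion in T-cell assays. Sequence alone
under-determines immunogenicity: the peptide's biological context — which
host it was assayed in, which protein and organism it derives from —
carries additional signal. `epifuse` therefore combines three stages:

1. **Per-residue embedding.** Each peptide is represented as an L×D
   matrix (one row per residue). The intended production embedder is a
   pretrained protein language model producing D = 1280 dimensions per
   residue; the package ships a deterministic synthetic embedder (any
   D ≥ 4) so the full pipeline runs without model weights. All matrices
   are standardized to L = 20 rows: zero rows appended after the last
   residue (C-terminal padding), longer peptides truncated to their
   N-terminal 20 rows. The pad/truncate convention is a deliberate,
   documented choice — the data-handling convention itself, not its exact
   orientation, is what downstream stages rely on.

2. **Knowledge-graph-weighted retrieval fusion.** A reference set of
   annotated epitopes (embeddings plus a knowledge graph of typed nodes
   Epitope/Molecule/MoleculeParent/Organism and relations DERIVED_FROM /
   ORIGINATES_FROM / BELONGS_TO / IS_VARIANT_OF) acts as a retrieval
   database. For a query embedding *q*:

   - the k = 5 nearest reference embeddings *e₁…e₅* are found by
     Euclidean distance between flattened matrices,
     d_i = √Σ_j (q_j − e_ij)²; an entry with the query's own id is
     excluded first, and ties break by ascending database index so the
     ranking is a total order;
   - each retrieved epitope starts with score S = 1.0; for every
     unordered pair (i, j) and every category c ∈ {host, source molecule,
     source organism, molecule parent} on which both carry the same
     non-absent value, the relationship-map increment M[c] is added to
     both scores (at most once per category per pair);
   - weights w_i = S_i / Σ S; with no queryable properties anywhere this
     is uniform (w_i = 1/k = 0.2);
   - the context embedding is W_avg = Σ w_i e_i, and the fused
     representation is 0.9·q + 0.1·W_avg (a convex combination dominated
     by the query, ratio configurable).

   Built-in relationship maps: human M = {host 1.0, source_molecule 0.5,
   source_organism 0.6, molecule_parent 0.4}; mouse M = {host 1.0,
   source_molecule 0.6, source_organism 0.5, molecule_parent 0.4}.
   A shared host is the strongest contextual cue; molecule parent the
   weakest. The epitope's own inducing/noninducing label is stored in the
   graph but excluded from weighting by default — sharing the predicted
   quantity would leak labels from the reference set into the features.
   An explicit `include_label_increment` opt-in exists for studying
   exactly that leakage effect.

3. **Multi-scale separable-convolution classifier.** The fused L×D map
   feeds parallel branches with window sizes {2, 4, 6, 8} (human profile)
   or {2, 4, 6} (mouse). Each branch is a separable convolution — a
   depthwise kernel spanning w positions per input channel
   (Depthwise(x) = Σᵢ Kᵢ·x₍:,:,i₎), then a pointwise 1×1 kernel mixing
   the D channels into 1024 filters with one bias per filter — followed
   by max-pooling over all L−w+1 valid positions, making each branch
   position-invariant to where a motif fires. Branch outputs concatenate
   to a 4096-vector (human), then dropout 0.7, a 500-unit hidden dense
   layer, and a 2-class softmax. Exact trainable-parameter counts:
   Σ_w (wD + DF + F) = 5,272,576 for the conv block, 4096·500+500 =
   2,048,500 for the hidden layer, 500·2+2 = 1,002 for the output layer;
   total 7,322,078 (mouse: 5,488,094). The closed form is asserted equal
   to the instantiated model's array sizes.

   Training: categorical cross-entropy + L2 (1e-3) on the dense-layer
   weights, Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8), batch 256, 20
   epochs, no early stopping. Forward, backward and the optimiser are
   implemented directly on NumPy arrays; the backward pass is verified
   against central finite differences in the test suite.

## Design choices where the design was open

- **Activation functions.** The separable-convolution equations and the
  layer table are written without nonlinearities. ReLU is applied after
  the pointwise convolution and after the hidden dense layer, the
  conventional default for this architecture family; parameter counts
  are unaffected.
- **L2 placement.** The penalty applies to the two dense layers only
  (`l2_include_conv=True` extends it to conv weights).
- **Dropout placement.** One dropout layer after concatenation, before
  the hidden dense layer, matching the layer table's order.
- **Distance operand.** The L2 distance treats the 20×D matrix as a
  flattened vector; averaging and fusion act elementwise on matrices, so
  positional structure is preserved for the classifier.
- **Database contents.** The retrieval database stores raw (standardized)
  embeddings; knowledge enters only through the weighting. Pre-fusing the
  database is a possible alternative reading of the workflow; storing raw
  embeddings is the default here because it keeps retrieval geometry
  independent of the relationship map.
- **Molecule parent resolution.** Direct per-epitope metadata is
  authoritative, including explicit absence; the transitive hop
  Epitope→Molecule→MoleculeParent is a fallback used only for graphs
  imported from bare triples.
- **Pairwise increments** apply at most once per category per pair; a
  category with either value absent contributes nothing.
- **Decision threshold** 0.5 on the inducing-class softmax probability.
- **Cross-validation** is stratified with seeded shuffling; each fold's
  retrieval database is restricted to training-fold embeddings so a
  validation query can never retrieve itself or fold-mates.
- **Graph backend.** An in-process `networkx` property graph rather than
  a graph-database server: the weighting needs only a four-property
  lookup, and the triple/Cypher exporters preserve interoperability with
  external graph stores.

## Synthetic data: what it emulates and what it does not

The generator plants the class signal the method is designed to exploit:

- inducing peptides carry a short motif (default "LP" at the N-terminus,
  a motif enriched among human inducing epitopes) with probability
  `motif_strength`; noninducing peptides never carry it at the planted
  position;
- host, source molecule and source organism are drawn from
  class-preferred pools; `kg_informativeness` ∈ [0,1] interpolates from
  label-independent metadata to maximally class-informative metadata
  (each molecule belongs to a fixed parent family, so molecule-parent
  sharing is informative exactly when molecule sharing is);
- embeddings are synthetic-embedder rows (fixed per-letter base vector
  plus a small positional term) standardized to 20 rows plus Gaussian
  noise (`noise_scale`, default 0.1 — small relative to the unit-scale
  base vectors, so the planted signal dominates);
- the reference knowledge set keeps the 169:554 inducing:noninducing
  imbalance of the curated reference collection and is id-disjoint from
  query sets.

It does **not** emulate MHC-binding biology, realistic amino-acid
composition, sequence redundancy structure, or the geometry of real
protein-language-model embeddings. Passing the end-to-end tests therefore
shows that the pipeline recovers the kind of signal it assumes —
positional sequence motifs plus class-correlated context — not that it
attains any particular accuracy on curated immunology data, which
requires the real embeddings and datasets.

## Problem sizes and numerics

Desk-scale studies (tests and the acceptance script) use embedding
dimension 32, 64 filters and 128 hidden units — the architecture is
unchanged, only widths shrink; the full-scale defaults remain
1280/1024/500. The end-to-end study trains on 1000 peptides and evaluates
on a held-out 400, averaged over 5 seeds, comparing KG-fused against
query-only (unfused) embeddings; a matched no-signal run (motif strength
0, uninformative metadata) checks the chance baseline. Retrieval is exact
(no approximate indexing). Zero-denominator metrics report 0 with a
logged warning; AUC is the rank estimator with half-credit ties, which
equals the trapezoidal ROC area to within 1e-9 by construction. All
randomness flows through seeded NumPy generators; training is
reproducible to the float on one machine.

## Known limitations

- The NumPy trainer targets desk-scale widths; at the full 1280×1024
  configuration it is correct but slow compared to GPU frameworks.
- The pretrained-embedder adapter requires the optional `esm`/`torch`
  stack and downloads model weights; it is untested in environments
  without them and raises a capability error pointing to the synthetic
  backend.
- The contextual weighting scores neighbours only against each other,
  not against the query; a query's own metadata never influences weights.
  This mirrors the reference design but means context selection is
  purely retrieval-driven.
- Uniform weights arise both from the explicit no-property fallback and
  from normalising untouched scores; the two are indistinguishable by
  output, which is intended.
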