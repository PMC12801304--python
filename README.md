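# epifuse

Context-aware prediction of interferon-gamma-inducing epitopes.

Short peptides (8–20 residues) presented by MHC molecules can trigger
IFN-γ secretion by T-cells — a property central to vaccine and
immunotherapy design. Sequence-only classifiers ignore the biological
context that shapes immunogenicity: the assay host, the source protein,
the source organism. `epifuse` enriches a peptide's per-residue
protein-language-model embedding with that context before classifying it:

1. **Retrieve** — the query's k = 5 nearest reference epitopes by L2
   distance between flattened L×D embedding matrices,
   d_i = √Σ_j (q_j − e_ij)².
2. **Reweight** — each retrieved epitope starts at score S = 1.0; every
   pair sharing a knowledge-graph property (host, source molecule,
   source organism, molecule parent) adds that category's increment from
   a relationship map M (human: host 1.0, source_molecule 0.5,
   source_organism 0.6, molecule_parent 0.4) to both scores. Weights are
   normalised scores, w_i = S_i / ΣS; without any properties they fall
   back to uniform 0.2.
3. **Fuse** — W_avg = Σ w_i e_i, then 0.9·q + 0.1·W_avg.
4. **Classify** — a multi-scale separable-convolution network: parallel
   depthwise+pointwise branches with windows {2,4,6,8}, 1024 filters,
   max-pooling over all positions, a 500-unit dense layer and a 2-class
   softmax (7,322,078 trainable parameters at the default human
   configuration), trained with Adam on categorical cross-entropy.

The package is aimed at computational immunologists who want to
experiment with retrieval-augmented embedding fusion: every stage
(embedding, knowledge graph, retrieval weighting, classifier, metrics,
synthetic benchmark data) is an importable module, plus an `epifuse` CLI
chaining them.

## Worked example: contextual weighting

Two of five retrieved epitopes share both host and source molecule;
under the human relationship map each of the pair gains +1.0 (host) and
+0.5 (source molecule):

```python
from epifuse import KnowledgeGraph, M_HUMAN, PeptideRecord, compute_context_weights

reference = [
    PeptideRecord("E1", "LPRQRAYL", host="human", source_molecule="spike"),
    PeptideRecord("E2", "LPGQRAYA", host="human", source_molecule="spike"),
    PeptideRecord("E3", "AAAAAAAA", host="h3", source_molecule="m3"),
    PeptideRecord("E4", "CCCCCCCC", host="h4", source_molecule="m4"),
    PeptideRecord("E5", "DDDDDDDD", host="h5", source_molecule="m5"),
]
kg = KnowledgeGraph.from_records(reference)
cw = compute_context_weights(["E1", "E2", "E3", "E4", "E5"], kg, M_HUMAN)
print("scores: ", cw.scores)
print("weights:", cw.weights)
```

```
scores:  [2.5 2.5 1.  1.  1. ]
weights: [0.3125 0.3125 0.125  0.125  0.125 ]
```

The contextually similar pair ends up carrying 62.5% of the averaged
context embedding; the three unrelated neighbours share the rest.

## Worked example: does the knowledge graph help?

The synthetic benchmark plants a sequence motif in inducing peptides and
makes metadata class-informative, then trains the classifier on fused
versus raw query embeddings (1000 training / 400 held-out peptides,
32-dimensional embeddings):

```python
from epifuse.experiments import signal_recovery

result = signal_recovery(seed=1)
print(f"fused AUC      {result['auc_fused']:.3f}")
print(f"query-only AUC {result['auc_query_only']:.3f}")
```

```
fused AUC      0.989
query-only AUC 0.974
```

Both models recover the planted signal; fusing knowledge-graph context
improves held-out ranking, the direction of effect the pipeline exists
to deliver.

## Command line

```bash
epifuse run --seed 1 --out run/          # simulate → fuse → train → evaluate
epifuse simulate --seed 1 --out data/
epifuse embed --in peptides.fasta --backend synthetic --dim 32 --out emb.npz
epifuse build-kg --in peptides.csv --out kg.tsv
epifuse fuse --queries emb.npz --database db.npz --kg kg.tsv --rel-map human --out fused.npz
epifuse train --fused fused.npz --labels labels.csv --host human --out model.npz
epifuse predict --model model.npz --fused test.npz --out preds.csv
epifuse evaluate --preds preds.csv --labels labels.csv --out report.json
```

Every run writes a `manifest.json` (config hash, seed, artifact list)
sufficient to replay it.

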