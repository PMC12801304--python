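"""Desk-scale experiment harnesses.

These drive the full pipeline (synthetic data -> retrieval fusion ->
classifier -> metrics) at sizes that run in seconds on one CPU, for
studying the direction of effect of knowledge-graph fusion and for
ablating relationship-map weights.  The classifier here is dimensioned
down (32-dimensional embeddings, 64 filters, 128 hidden units) while the
architecture and every pipeline stage are identical to the full-scale
configuration.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from epifuse.metrics import compute_metrics, confusion
from epifuse.mscnn import MSCNN, MSCNNConfig, predict, train
from epifuse.rag_fusion import M_HUMAN, RelationshipMap, enrich_dataset
from epifuse.synthetic_data import (
    SyntheticSpec,
    generate,
    generate_knowledge_db,
    labels_of,
)

#: classifier settings for desk-scale runs; architecture identical, smaller.
DESK_CONFIG = MSCNNConfig(
    filters=64,
    hidden_units=128,
    input_dim=32,
    batch_size=256,
    epochs=20,
)


def signal_recovery(
    seed: int,
    n_train: int = 1000,
    n_test: int = 400,
    dim: int = 32,
    motif_strength: float = 1.0,
    kg_informativeness: float = 1.0,
    noise_scale: float = 0.1,
    n_db: int = 723,
    rel_map: RelationshipMap = M_HUMAN,
    config: MSCNNConfig | None = None,
) -> dict[str, float]:
    """Train on a held-out synthetic split with and without KG fusion.

    Generates a balanced labelled set of ``n_train + n_test`` peptides and
    a reference knowledge set of ``n_db`` epitopes (169:554 imbalance),
    fuses every query against the reference set, then trains one
    classifier on the fused embeddings and one on the raw query
    embeddings, evaluating both on the same held-out split.

    Returns held-out ``auc_fused`` and ``auc_query_only``.
    """
    n_total = n_train + n_test
    spec = SyntheticSpec(
        n_inducing=n_total // 2,
        n_noninducing=n_total - n_total // 2,
        embedding_dim=dim,
        motif_strength=motif_strength,
        kg_informativeness=kg_informativeness,
        noise_scale=noise_scale,
        seed=seed,
    )
    records, _, embeddings = generate(spec)
    _, db_kg, db_embeddings = generate_knowledge_db(spec, n_db)
    y = labels_of(records)

    fused = enrich_dataset(embeddings, db_embeddings, db_kg, rel_map)
    rng = np.random.default_rng([seed, 31])
    perm = rng.permutation(n_total)
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    base = config or DESK_CONFIG
    base = dataclasses.replace(base, input_dim=dim, seed=seed)
    out = {}
    for name, data in (("auc_fused", fused), ("auc_query_only", embeddings)):
        model = train(MSCNN(base), [data[i] for i in train_idx], y[train_idx])
        preds = predict(model, [data[i] for i in test_idx])
        report = compute_metrics(
            confusion(y[test_idx], preds.labels_pred),
            scores=preds.scores,
            labels_true=y[test_idx],
        )
        out[name] = float(report.auc)
    return out


def relationship_map_ablation(
    seed: int,
    maps: dict[str, RelationshipMap],
    **kwargs,
) -> dict[str, float]:
    """Held-out fused AUC under each candidate relationship map."""
    return {
        name: signal_recovery(seed, rel_map=rel_map, **kwargs)["auc_fused"]
        for name, rel_map in maps.items()
    }
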