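"""Retrieval-augmented, knowledge-graph-weighted embedding fusion.

For each query peptide the pipeline (1) retrieves the ``k`` reference
epitopes with smallest L2 distance between flattened embedding matrices,
(2) scores each retrieved epitope by the biological context it shares with
the other retrieved epitopes — every unordered pair that agrees on a
property category (host, source molecule, source organism, molecule
parent) adds that category's increment from the relationship map to both
scores, starting from 1.0 — (3) normalises scores to convex weights and
averages the retrieved embeddings, and (4) fuses query and context with a
convex combination dominated by the query (default 9:1).

The relationship-map increments encode how predictive a shared property is
of shared immunogenic behaviour; a shared host counts the most, a shared
molecule parent the least.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from epifuse.io_formats import EmbeddingMatrix, ValidationError
from epifuse.kg_store import PROPERTY_CATEGORIES, EpitopeProperties, KnowledgeGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelationshipMap:
    """Category -> non-negative score increment for shared properties."""

    increments: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.increments:
            raise ValidationError("relationship map needs at least one category")
        unknown = set(self.increments) - set(PROPERTY_CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown relationship categories {sorted(unknown)}")
        for category, value in self.increments.items():
            if value < 0:
                raise ValidationError(f"negative increment for {category!r}: {value}")
        object.__setattr__(self, "increments", dict(self.increments))

    @classmethod
    def from_name(cls, name: str) -> "RelationshipMap":
        key = name.strip().lower()
        if key == "human":
            return M_HUMAN
        if key == "mouse":
            return M_MOUSE
        raise ValueError(f"unknown relationship map {name!r}; use 'human' or 'mouse'")

    @classmethod
    def from_file(cls, path) -> "RelationshipMap":
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle)
        return cls({str(k): float(v) for k, v in data.items()})


#: Map tuned on the human training set: shared host matters most.
M_HUMAN = RelationshipMap(
    {"host": 1.0, "source_molecule": 0.5, "source_organism": 0.6, "molecule_parent": 0.4}
)
#: Map tuned on the mouse training set (source molecule and organism swap rank).
M_MOUSE = RelationshipMap(
    {"host": 1.0, "source_molecule": 0.6, "source_organism": 0.5, "molecule_parent": 0.4}
)


@dataclass
class RetrievalResult:
    """Top-k neighbours of one query, nearest first."""

    neighbour_ids: list[str]
    distances: list[float]

    def __post_init__(self) -> None:
        if len(self.neighbour_ids) != len(self.distances):
            raise ValidationError("neighbour_ids and distances differ in length")


@dataclass
class ContextWeights:
    """Normalised contextual weights (and raw accumulated scores) for k neighbours."""

    weights: np.ndarray
    scores: np.ndarray


@dataclass
class FusedEmbedding:
    """Convex combination of a query embedding and its retrieved context."""

    epitope_id: str
    values: np.ndarray = field(repr=False)
    query_fraction: float = 0.9


def l2_distance(q: EmbeddingMatrix, e: EmbeddingMatrix) -> float:
    """Euclidean distance between two embedding matrices, flattened."""
    if q.values.shape != e.values.shape:
        raise ValueError(
            f"shape mismatch: {q.values.shape} vs {e.values.shape}"
        )
    return float(np.sqrt(np.sum((q.values - e.values) ** 2)))


def _stack(database: Sequence[EmbeddingMatrix]) -> np.ndarray:
    shapes = {e.values.shape for e in database}
    if len(shapes) != 1:
        raise ValidationError(f"database embeddings have mixed shapes: {sorted(shapes)}")
    return np.stack([e.values.reshape(-1) for e in database])


def retrieve_top_k(
    q: EmbeddingMatrix,
    database: Sequence[EmbeddingMatrix],
    k: int = 5,
    _flat_db: np.ndarray | None = None,
) -> RetrievalResult:
    """Return the k database entries nearest to ``q`` in L2, ascending.

    A database entry whose epitope_id equals the query's is excluded before
    ranking (self-retrieval guard against label leakage).  Ties are broken
    by ascending database index, giving a reproducible total order.
    """
    keep = [i for i, e in enumerate(database) if e.epitope_id != q.epitope_id]
    if len(keep) < k:
        raise ValueError(
            f"database holds {len(keep)} candidates after self-exclusion; need k={k}"
        )
    flat = _flat_db if _flat_db is not None else _stack(database)
    if flat.shape[1] != q.values.size:
        raise ValueError("query and database embedding shapes differ")
    diffs = flat[keep] - q.values.reshape(-1)
    dists = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
    order = np.argsort(dists, kind="stable")[:k]
    return RetrievalResult(
        neighbour_ids=[database[keep[i]].epitope_id for i in order],
        distances=[float(dists[i]) for i in order],
    )


def compute_context_weights(
    neighbour_ids: Sequence[str],
    kg: KnowledgeGraph,
    rel_map: RelationshipMap,
    include_label_increment: float | None = None,
) -> ContextWeights:
    """Score retrieved epitopes by shared KG context and normalise to weights.

    Every epitope starts at score 1.0.  For each unordered pair and each
    relationship-map category on which both epitopes carry the same
    non-absent value, the category increment is added to both scores (at
    most once per category per pair).  Weights are scores divided by their
    sum; with no queryable properties anywhere this reduces to uniform
    weights 1/k.

    ``include_label_increment`` opts in to treating a shared class label as
    an additional category.  It is off by default: label sharing leaks the
    quantity being predicted.
    """
    k = len(neighbour_ids)
    if k < 2:
        raise ValueError("contextual weighting needs at least 2 retrieved epitopes")
    props: list[EpitopeProperties] = []
    labels: list[int | None] = []
    for eid in neighbour_ids:
        if kg.has_epitope(eid):
            props.append(kg.get_properties(eid))
            labels.append(kg.get_label(eid))
        else:
            props.append(EpitopeProperties())
            labels.append(None)

    scores = np.ones(k, dtype=np.float64)
    for i in range(k):
        for j in range(i + 1, k):
            for category, increment in rel_map.increments.items():
                a = getattr(props[i], category)
                b = getattr(props[j], category)
                if a is not None and a == b:
                    scores[i] += increment
                    scores[j] += increment
            if include_label_increment is not None:
                if labels[i] is not None and labels[i] == labels[j]:
                    scores[i] += include_label_increment
                    scores[j] += include_label_increment
    weights = scores / scores.sum()
    return ContextWeights(weights=weights, scores=scores)


def weighted_average(
    neighbours: Sequence[EmbeddingMatrix], weights: ContextWeights
) -> EmbeddingMatrix:
    """Elementwise convex combination of the retrieved embeddings."""
    if len(neighbours) != len(weights.weights):
        raise ValueError("number of neighbours and weights differ")
    shapes = {e.values.shape for e in neighbours}
    if len(shapes) != 1:
        raise ValueError(f"neighbour embeddings have mixed shapes: {sorted(shapes)}")
    stacked = np.stack([e.values for e in neighbours])
    values = np.tensordot(weights.weights, stacked, axes=1)
    return EmbeddingMatrix("context", values)


def fuse(
    query: EmbeddingMatrix, context: EmbeddingMatrix, query_fraction: float = 0.9
) -> FusedEmbedding:
    """Convex combination query_fraction * query + (1 - query_fraction) * context."""
    if not 0.0 <= query_fraction <= 1.0:
        raise ValueError(f"query_fraction must lie in [0, 1], got {query_fraction}")
    if query.values.shape != context.values.shape:
        raise ValueError(
            f"shape mismatch: {query.values.shape} vs {context.values.shape}"
        )
    values = query_fraction * query.values + (1.0 - query_fraction) * context.values
    return FusedEmbedding(query.epitope_id, values, query_fraction)


def enrich_dataset(
    queries: Sequence[EmbeddingMatrix],
    database: Sequence[EmbeddingMatrix],
    kg: KnowledgeGraph,
    rel_map: RelationshipMap,
    k: int = 5,
    query_fraction: float = 0.9,
    audit_path=None,
) -> list[FusedEmbedding]:
    """Apply retrieve -> weight -> average -> fuse to every query.

    When ``audit_path`` is given, a per-query TSV audit trail is written
    with columns query_id, neighbour_id, rank, distance, score, weight.
    """
    if not queries:
        return []
    flat_db = _stack(database)
    by_id = {e.epitope_id: e for e in database}
    fused: list[FusedEmbedding] = []
    audit_rows: list[str] = []
    for query in queries:
        result = retrieve_top_k(query, database, k=k, _flat_db=flat_db)
        weights = compute_context_weights(result.neighbour_ids, kg, rel_map)
        context = weighted_average(
            [by_id[i] for i in result.neighbour_ids], weights
        )
        fused.append(fuse(query, context, query_fraction))
        logger.debug(
            "query %s -> neighbours %s weights %s",
            query.epitope_id,
            result.neighbour_ids,
            np.round(weights.weights, 4).tolist(),
        )
        if audit_path is not None:
            for rank, (nid, dist, score, weight) in enumerate(
                zip(result.neighbour_ids, result.distances, weights.scores, weights.weights),
                start=1,
            ):
                audit_rows.append(
                    f"{query.epitope_id}\t{nid}\t{rank}\t{dist:.6g}\t{score:.6g}\t{weight:.6g}"
                )
    if audit_path is not None:
        header = "query_id\tneighbour_id\trank\tdistance\tscore\tweight"
        Path(audit_path).write_text("\n".join([header, *audit_rows]) + "\n", encoding="utf-8")
    return fused
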