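"""Seeded synthetic peptides, metadata and embeddings for pipeline testing.

The generator emulates, at desk scale, the statistical structure the
method assumes in real epitope data:

* class signal in sequence — inducing peptides carry a short planted motif
  (default "LP" at the N-terminus, a motif enriched in human inducing
  epitopes) with probability ``motif_strength``; noninducing peptides
  never carry it at the planted position;
* class-correlated knowledge-graph context — host, source molecule and
  source organism are drawn from class-preferred pools, with the
  correlation strength set by ``kg_informativeness`` (0 = metadata
  independent of class, 1 = maximally class-informative), so contextual
  reweighting of retrieved neighbours can be informative;
* a reference knowledge set with the 169:554 inducing:noninducing
  imbalance of the curated reference collection, disjoint by id from any
  query set.

Embeddings come from the deterministic synthetic embedder, standardized to
20 rows, plus Gaussian noise of scale ``noise_scale``.  Everything derives
from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from epifuse.embedder import _ALPHABET, synthetic_embed
from epifuse.io_formats import EmbeddingMatrix, PeptideRecord, standardize_length
from epifuse.kg_store import KnowledgeGraph

#: inducing:total ratio of the reference knowledge set (169 of 723).
KNOWLEDGE_DB_POSITIVE_FRACTION = 169 / 723


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the generator; defaults give a strongly learnable problem."""

    n_inducing: int = 500
    n_noninducing: int = 500
    length_range: tuple[int, int] = (8, 20)
    motif: str = "LP"
    motif_strength: float = 1.0
    kg_informativeness: float = 1.0
    n_molecules: int = 12
    n_organisms: int = 8
    hosts: tuple[str, ...] = ("human", "mouse")
    embedding_dim: int = 32
    noise_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inducing < 1 or self.n_noninducing < 1:
            raise ValueError("class counts must be >= 1")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must lie in [0, 1]")
        if not 0.0 <= self.kg_informativeness <= 1.0:
            raise ValueError("kg_informativeness must lie in [0, 1]")
        if len(self.motif) > self.length_range[0]:
            raise ValueError("motif longer than the minimum peptide length")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def _sample_sequence(rng: np.random.Generator, spec: SyntheticSpec, label: int) -> str:
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    letters = rng.choice(list(_ALPHABET), size=length)
    seq = "".join(letters)
    m = len(spec.motif)
    if label == 1 and rng.random() < spec.motif_strength:
        seq = spec.motif + seq[m:]
    else:
        # the planted position must never spell the motif in any other case
        while seq[:m] == spec.motif:
            seq = "".join(rng.choice(list(_ALPHABET), size=m)) + seq[m:]
    return seq


def _pick_pool(rng: np.random.Generator, names: list[str], label: int, mix: float) -> str:
    """Draw from the class-preferred half of a name pool.

    ``mix`` = kg_informativeness.  The preferred half is used with
    probability (1 + mix) / 2; at mix = 0 both halves are equally likely
    and the draw is independent of the class.
    """
    half = len(names) // 2
    preferred = names[:half] if label == 1 else names[half:]
    other = names[half:] if label == 1 else names[:half]
    pool = preferred if rng.random() < (1.0 + mix) / 2.0 else other
    return pool[int(rng.integers(len(pool)))]


def _generate_set(
    spec: SyntheticSpec,
    n_pos: int,
    n_neg: int,
    prefix: str,
    stream: int,
) -> tuple[list[PeptideRecord], KnowledgeGraph, list[EmbeddingMatrix]]:
    rng = np.random.default_rng([spec.seed, stream])
    molecules = [f"mol{i:02d}" for i in range(spec.n_molecules)]
    organisms = [f"org{i:02d}" for i in range(spec.n_organisms)]
    # each molecule belongs to one fixed parent family (3 molecules per family)
    parent_of = {m: f"family{i // 3}" for i, m in enumerate(molecules)}

    labels = np.array([1] * n_pos + [0] * n_neg)
    records: list[PeptideRecord] = []
    embeddings: list[EmbeddingMatrix] = []
    target_len = spec.length_range[1]
    for i, label in enumerate(labels):
        seq = _sample_sequence(rng, spec, int(label))
        preferred_host = spec.hosts[0] if label == 1 else spec.hosts[min(1, len(spec.hosts) - 1)]
        other_hosts = [h for h in spec.hosts if h != preferred_host] or [preferred_host]
        if rng.random() < (1.0 + spec.kg_informativeness) / 2.0:
            host = preferred_host
        else:
            host = other_hosts[int(rng.integers(len(other_hosts)))]
        molecule = _pick_pool(rng, molecules, int(label), spec.kg_informativeness)
        organism = _pick_pool(rng, organisms, int(label), spec.kg_informativeness)
        record = PeptideRecord(
            epitope_id=f"{prefix}{i:05d}",
            sequence=seq,
            host=host,
            label=int(label),
            source_molecule=molecule,
            molecule_parent=parent_of[molecule],
            source_organism=organism,
        )
        records.append(record)
        emb = standardize_length(
            synthetic_embed(seq, spec.embedding_dim, seed=spec.seed), target_len
        )
        noise = spec.noise_scale * rng.standard_normal(emb.values.shape)
        embeddings.append(EmbeddingMatrix(record.epitope_id, emb.values + noise))
    kg = KnowledgeGraph.from_records(records)
    return records, kg, embeddings


def generate(
    spec: SyntheticSpec,
) -> tuple[list[PeptideRecord], KnowledgeGraph, list[EmbeddingMatrix]]:
    """Generate a labelled query/training set under the spec's conditions."""
    return _generate_set(spec, spec.n_inducing, spec.n_noninducing, "q", stream=1)


def generate_knowledge_db(
    spec: SyntheticSpec, n_db: int
) -> tuple[list[PeptideRecord], KnowledgeGraph, list[EmbeddingMatrix]]:
    """Generate the reference knowledge set used as the retrieval database.

    Ids are disjoint from :func:`generate` output ("kg" prefix vs "q");
    class counts follow the 169:554 reference imbalance, rounded to the
    nearest integers.
    """
    if n_db < 1:
        raise ValueError("n_db must be >= 1")
    n_pos = int(round(n_db * KNOWLEDGE_DB_POSITIVE_FRACTION))
    n_pos = min(max(n_pos, 1), n_db - 1)
    return _generate_set(spec, n_pos, n_db - n_pos, "kg", stream=2)


def labels_of(records: Sequence[PeptideRecord]) -> np.ndarray:
    """Convenience: the label vector of a generated record list."""
    return np.array([r.label for r in records], dtype=int)
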