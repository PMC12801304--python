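import numpy as np
import pytest

from epifuse import EmbeddingMatrix, KnowledgeGraph, PeptideRecord


def make_emb(epitope_id: str, values) -> EmbeddingMatrix:
    return EmbeddingMatrix(epitope_id, np.asarray(values, dtype=float))


def random_embs(n: int, L: int, D: int, seed: int, prefix: str = "e") -> list:
    rng = np.random.default_rng(seed)
    return [make_emb(f"{prefix}{i}", rng.standard_normal((L, D))) for i in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def worked_example_kg():
    """Five epitopes: E1 and E2 share host and source molecule, E3-E5 share
    nothing with anybody."""
    records = [
        PeptideRecord("E1", "LPRQRAYL", host="human", source_molecule="spike"),
        PeptideRecord("E2", "LPGQRAYA", host="human", source_molecule="spike"),
        PeptideRecord("E3", "AAAAAAAA", host="h3", source_molecule="m3"),
        PeptideRecord("E4", "CCCCCCCC", host="h4", source_molecule="m4"),
        PeptideRecord("E5", "DDDDDDDD", host="h5", source_molecule="m5"),
    ]
    return KnowledgeGraph.from_records(records)
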