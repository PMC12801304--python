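"""Pluggable per-residue embedders.

Two backends: a deterministic synthetic embedder (each residue row is a
fixed per-letter base vector plus a small positional perturbation), and an
optional adapter for the ESM2 protein language model (esm2_t33_650M_UR50D,
1280 dimensions per residue) when the ``esm``/``torch`` stack is
installed.  The synthetic backend keeps the full pipeline runnable and
reproducible at any dimension without model weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from epifuse.io_formats import EmbeddingMatrix, PeptideRecord

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_MAX_POS = 64
_POS_SCALE = 0.1


class CapabilityError(RuntimeError):
    """A requested embedding backend is not available in this installation."""


@dataclass(frozen=True)
class EmbedderSpec:
    """Which backend to use and what it should produce.

    ``dimension`` is 1280 for the pretrained model; the synthetic backend
    accepts any dimension >= 4 so tests can run small.  ``layer`` selects
    the transformer representation layer for the pretrained backend (final
    layer by default).  ``seed`` parameterises the synthetic backend only.
    """

    name: str = "synthetic"
    dimension: int = 1280
    layer: int | None = None
    seed: int = 0


def synthetic_embed(sequence: str, dimension: int, seed: int = 0) -> EmbeddingMatrix:
    """Deterministic stand-in embedding: one row per residue.

    Row(letter, position) = base[letter] + 0.1 * pos[position], with base
    and positional vectors drawn once from seeded generators.  Identical
    (letter, position, seed) triples always map to identical rows, distinct
    letters at the same position to distinct rows.
    """
    if dimension < 4:
        raise ValueError("synthetic embedder needs dimension >= 4")
    if len(sequence) > _MAX_POS:
        raise ValueError(f"sequence longer than {_MAX_POS} residues")
    base = np.random.default_rng([seed, 101]).standard_normal((len(_ALPHABET), dimension))
    pos = _POS_SCALE * np.random.default_rng([seed, 202]).standard_normal((_MAX_POS, dimension))
    try:
        rows = base[[_AA_INDEX[aa] for aa in sequence]]
    except KeyError as err:
        raise ValueError(f"non-canonical residue {err.args[0]!r}") from None
    return EmbeddingMatrix("", rows + pos[: len(sequence)])


def embed(records: Sequence[PeptideRecord], spec: EmbedderSpec) -> list[EmbeddingMatrix]:
    """Embed each record's sequence into an L x dimension matrix.

    Rows correspond to residues before any length standardization.
    """
    if spec.name == "synthetic":
        out = []
        for record in records:
            emb = synthetic_embed(record.sequence, spec.dimension, spec.seed)
            out.append(EmbeddingMatrix(record.epitope_id, emb.values))
        return out
    if spec.name == "esm2":
        return _esm2_embed(records, spec)
    raise ValueError(f"unknown embedder backend {spec.name!r}")


def _esm2_embed(records: Sequence[PeptideRecord], spec: EmbedderSpec) -> list[EmbeddingMatrix]:
    """Adapter for the pretrained ESM2 backend (esm2_t33_650M_UR50D).

    Extracts per-residue representations from the configured layer (final
    layer when unset) and drops the begin/end special-token rows, yielding
    an L x 1280 matrix per peptide.
    """
    try:
        import esm  # type: ignore
        import torch  # type: ignore
    except ImportError as err:
        raise CapabilityError(
            "the 'esm2' backend needs the fair-esm and torch packages; "
            "use EmbedderSpec(name='synthetic') instead"
        ) from err

    model, alphabet = esm.pretrained.esm2_t33_650M_UR50D()
    model.eval()
    layer = spec.layer if spec.layer is not None else model.num_layers
    converter = alphabet.get_batch_converter()
    _, _, tokens = converter([(r.epitope_id, r.sequence) for r in records])
    with torch.no_grad():
        reps = model(tokens, repr_layers=[layer])["representations"][layer]
    out = []
    for record, rep in zip(records, reps):
        rows = rep[1 : len(record.sequence) + 1].numpy().astype(np.float64)
        out.append(EmbeddingMatrix(record.epitope_id, rows))
    return out
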