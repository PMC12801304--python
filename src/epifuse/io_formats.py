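"""Peptide, metadata and embedding I/O with the epitope length rules.

Curated IFN-gamma epitope sets keep peptides of 8-20 residues (the range
spanned by MHC class I 8-11-mers and class II 13-20-mers) and exclude
peptides with non-natural amino acids.  Per-residue embedding matrices are
standardized to a fixed 20-row length so every downstream stage sees a
constant input shape: shorter peptides are zero-padded at the C-terminal
end, longer ones keep their N-terminal 20 rows.

Embedding sets travel in an NPZ or HDF5 container holding a stacked
``embeddings`` array of shape (N, L, D) and a parallel ``epitope_ids``
dataset; round-trips are bit-exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid letters.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Metadata columns recognised in tabular input beyond the required two.
METADATA_COLUMNS = ("host", "label", "source_molecule", "molecule_parent", "source_organism")


class FormatError(ValueError):
    """A file violates the expected format (missing column, bad label ...)."""


class ValidationError(ValueError):
    """Input data violates a contract (duplicate ids, shape mismatch ...)."""


@dataclass(frozen=True)
class PeptideRecord:
    """One epitope: sequence plus the knowledge-graph metadata fields.

    ``label`` is 1 for IFN-gamma-inducing, 0 for noninducing, None when
    unknown.  Metadata fields are None (never empty strings) when absent.
    """

    epitope_id: str
    sequence: str
    host: str | None = None
    label: int | None = None
    source_molecule: str | None = None
    molecule_parent: str | None = None
    source_organism: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.epitope_id!r}: empty sequence")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValidationError(
                f"record {self.epitope_id!r}: non-canonical residues {sorted(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(f"record {self.epitope_id!r}: label must be 0 or 1")


@dataclass
class EmbeddingMatrix:
    """L x D per-residue embedding of one peptide (rows = residues)."""

    epitope_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError(f"{self.epitope_id!r}: embedding must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.epitope_id!r}: embedding has non-finite entries")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def D(self) -> int:
        return self.values.shape[1]


def _parse_label(value) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        text = value.strip().lower()
        if text in ("", "nan"):
            return None
        if text == "inducing":
            return 1
        if text == "noninducing":
            return 0
        try:
            number = float(text)
        except ValueError:
            raise FormatError(f"unparseable label {value!r}") from None
        if number in (0.0, 1.0):
            return int(number)
        raise FormatError(f"unparseable label {value!r}")
    if value in (0, 1):
        return int(value)
    raise FormatError(f"unparseable label {value!r}")


def _clean(value) -> str | None:
    """Normalise a metadata cell: NaN/empty -> None, else stripped string."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    return text or None


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fasta", ".fa", ".faa", ".fna"):
        return "fasta"
    if suffix in (".csv", ".tsv", ".txt"):
        return "table"
    raise FormatError(f"cannot infer peptide format from extension {suffix!r}")


def read_peptides(path, format: str | None = None) -> list[PeptideRecord]:
    """Read peptides from FASTA or a CSV/TSV table into validated records.

    Records containing non-canonical residues are dropped with a logged
    count rather than aborting the whole read.  Duplicate ``epitope_id``
    values raise :class:`ValidationError`.

    Parameters
    ----------
    path : path-like
        Input file.  For tables the delimiter follows the extension
        (``.tsv`` -> tab, otherwise comma); a header row is required with
        at least ``epitope_id`` and ``sequence`` columns.
    format : {"fasta", "table"}, optional
        Override the extension-based format detection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    raw: list[dict] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            raw.append({"epitope_id": rec.id, "sequence": str(rec.seq).upper()})
    elif fmt == "table":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        frame = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
        for col in ("epitope_id", "sequence"):
            if col not in frame.columns:
                raise FormatError(f"{path.name}: required column {col!r} missing")
        for _, row in frame.iterrows():
            entry = {
                "epitope_id": _clean(row["epitope_id"]),
                "sequence": (_clean(row["sequence"]) or "").upper(),
            }
            for col in METADATA_COLUMNS:
                if col in frame.columns:
                    if col == "label":
                        entry["label"] = _parse_label(row[col])
                    else:
                        entry[col] = _clean(row[col])
            raw.append(entry)
    else:
        raise FormatError(f"unknown peptide format {fmt!r}")

    records: list[PeptideRecord] = []
    seen: set[str] = set()
    n_rejected = 0
    for entry in raw:
        try:
            record = PeptideRecord(**entry)
        except ValidationError:
            n_rejected += 1
            continue
        if record.epitope_id in seen:
            raise ValidationError(f"duplicate epitope_id {record.epitope_id!r}")
        seen.add(record.epitope_id)
        records.append(record)
    if n_rejected:
        logger.warning(
            "%s: rejected %d record(s) with non-canonical residues", path.name, n_rejected
        )
    return records


def write_peptides(records: Sequence[PeptideRecord], path) -> None:
    """Write records as a CSV/TSV table (delimiter from the extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    frame = pd.DataFrame(
        [
            {
                "epitope_id": r.epitope_id,
                "sequence": r.sequence,
                "host": r.host,
                "label": r.label,
                "source_molecule": r.source_molecule,
                "molecule_parent": r.molecule_parent,
                "source_organism": r.source_organism,
            }
            for r in records
        ]
    )
    frame.to_csv(path, sep=sep, index=False)


def filter_by_length(
    records: Iterable[PeptideRecord], min_len: int = 8, max_len: int = 20
) -> list[PeptideRecord]:
    """Keep records with min_len <= |sequence| <= max_len, order preserved."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    return [r for r in records if min_len <= len(r.sequence) <= max_len]


def standardize_length(emb: EmbeddingMatrix, target_len: int = 20) -> EmbeddingMatrix:
    """Pad or truncate an embedding matrix to exactly ``target_len`` rows.

    Zero rows are appended after the last residue row (C-terminal padding);
    matrices longer than ``target_len`` keep their first ``target_len``
    rows (N-terminal truncation).  Idempotent.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    if emb.L == 0:
        raise ValidationError(f"{emb.epitope_id!r}: embedding has no rows")
    if emb.L == target_len:
        return EmbeddingMatrix(emb.epitope_id, emb.values.copy())
    if emb.L > target_len:
        return EmbeddingMatrix(emb.epitope_id, emb.values[:target_len].copy())
    pad = np.zeros((target_len - emb.L, emb.D), dtype=emb.values.dtype)
    return EmbeddingMatrix(emb.epitope_id, np.vstack([emb.values, pad]))


def _check_consistent(embeddings: Sequence[EmbeddingMatrix]) -> tuple[int, int]:
    shapes = {e.values.shape for e in embeddings}
    if len(shapes) != 1:
        raise ValidationError(f"inconsistent embedding shapes in set: {sorted(shapes)}")
    return shapes.pop()


def save_embeddings(embeddings: Sequence[EmbeddingMatrix], path) -> None:
    """Save a consistent embedding set to ``.npz`` or ``.h5``/``.hdf5``."""
    if not embeddings:
        raise ValidationError("refusing to save an empty embedding set")
    _check_consistent(embeddings)
    path = Path(path)
    stacked = np.stack([e.values for e in embeddings])
    ids = np.array([e.epitope_id for e in embeddings])
    if path.suffix.lower() == ".npz":
        np.savez(path, embeddings=stacked, epitope_ids=ids)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as handle:
            handle.create_dataset("embeddings", data=stacked)
            handle.create_dataset("epitope_ids", data=ids.astype("S"))
    else:
        raise FormatError(f"unknown embedding container extension {path.suffix!r}")


def load_embeddings(path) -> list[EmbeddingMatrix]:
    """Load an embedding set written by :func:`save_embeddings`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".npz":
        with np.load(path, allow_pickle=False) as data:
            if "embeddings" not in data or "epitope_ids" not in data:
                raise FormatError(f"{path.name}: missing embeddings/epitope_ids arrays")
            stacked = data["embeddings"]
            ids = data["epitope_ids"]
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as handle:
            if "embeddings" not in handle or "epitope_ids" not in handle:
                raise FormatError(f"{path.name}: missing embeddings/epitope_ids datasets")
            stacked = handle["embeddings"][()]
            ids = [x.decode() for x in handle["epitope_ids"][()]]
    else:
        raise FormatError(f"unknown embedding container extension {path.suffix!r}")
    if stacked.ndim != 3:
        raise FormatError(f"{path.name}: embeddings array must be (N, L, D)")
    return [EmbeddingMatrix(str(i), v) for i, v in zip(ids, stacked)]
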