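"""In-memory biological knowledge graph over epitope metadata.

Node types: Epitope, Molecule, MoleculeParent, Organism.  Relations:
Epitope -DERIVED_FROM-> Molecule, Epitope -ORIGINATES_FROM-> Organism,
Molecule -BELONGS_TO-> MoleculeParent, plus Molecule -IS_VARIANT_OF->
Molecule accepted on import but unused by the contextual weighting.

The graph answers a single query pattern needed by retrieval reweighting:
the four properties of an epitope (host, source molecule, molecule parent,
source organism).  The epitope's inducing/noninducing label is stored as a
node attribute but deliberately kept out of the four weighting properties,
so retrieval reweighting can never peek at the class label.

Backed by a :class:`networkx.MultiDiGraph`; triples export/import keeps the
store interoperable with external graph databases.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from epifuse.io_formats import PeptideRecord, ValidationError

NODE_TYPES = ("Epitope", "Molecule", "MoleculeParent", "Organism")
RELATIONS = ("DERIVED_FROM", "ORIGINATES_FROM", "IS_VARIANT_OF", "BELONGS_TO")

#: node-id namespace prefixes, keeping e.g. a molecule and an organism with
#: the same name distinct.
_PREFIX = {
    "Epitope": "epitope::",
    "Molecule": "molecule::",
    "MoleculeParent": "parent::",
    "Organism": "organism::",
}

PROPERTY_CATEGORIES = ("host", "source_molecule", "molecule_parent", "source_organism")


@dataclass(frozen=True)
class EpitopeProperties:
    """The four weighting properties of one epitope; None marks absence."""

    host: str | None = None
    source_molecule: str | None = None
    molecule_parent: str | None = None
    source_organism: str | None = None

    def is_empty(self) -> bool:
        return all(
            getattr(self, c) is None for c in PROPERTY_CATEGORIES
        )


def _strip(value: str | None) -> str | None:
    if value is None:
        return None
    value = value.strip()
    return value or None


class KnowledgeGraph:
    """Typed property graph over epitopes and their biological context."""

    def __init__(self) -> None:
        self.graph = nx.MultiDiGraph()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[PeptideRecord]) -> "KnowledgeGraph":
        """Build the graph from validated peptide records.

        One Epitope node per record; Molecule / Organism / MoleculeParent
        nodes deduplicated by (whitespace-trimmed, case-sensitive) name.
        Absent metadata simply produces no edge.
        """
        kg = cls()
        for record in records:
            kg.add_record(record)
        return kg

    def add_record(self, record: PeptideRecord) -> None:
        eid = _PREFIX["Epitope"] + record.epitope_id
        if eid in self.graph:
            raise ValidationError(f"epitope {record.epitope_id!r} already in graph")
        host = _strip(record.host)
        molecule = _strip(record.source_molecule)
        parent = _strip(record.molecule_parent)
        organism = _strip(record.source_organism)
        self.graph.add_node(
            eid,
            node_type="Epitope",
            name=record.epitope_id,
            sequence=record.sequence,
            host=host,
            label=record.label,
            source_molecule=molecule,
            molecule_parent=parent,
            source_organism=organism,
        )
        if molecule is not None:
            mid = _PREFIX["Molecule"] + molecule
            self.graph.add_node(mid, node_type="Molecule", name=molecule)
            self.graph.add_edge(eid, mid, relation="DERIVED_FROM")
            if parent is not None:
                pid = _PREFIX["MoleculeParent"] + parent
                self.graph.add_node(pid, node_type="MoleculeParent", name=parent)
                if not any(
                    d.get("relation") == "BELONGS_TO"
                    for _, _, d in self.graph.out_edges(mid, data=True)
                ):
                    self.graph.add_edge(mid, pid, relation="BELONGS_TO")
        if organism is not None:
            oid = _PREFIX["Organism"] + organism
            self.graph.add_node(oid, node_type="Organism", name=organism)
            self.graph.add_edge(eid, oid, relation="ORIGINATES_FROM")

    # -- queries -----------------------------------------------------------

    def has_epitope(self, epitope_id: str) -> bool:
        return (_PREFIX["Epitope"] + epitope_id) in self.graph

    def epitope_ids(self) -> list[str]:
        return [
            data["name"]
            for _, data in self.graph.nodes(data=True)
            if data.get("node_type") == "Epitope"
        ]

    def get_label(self, epitope_id: str) -> int | None:
        node = _PREFIX["Epitope"] + epitope_id
        if node not in self.graph:
            raise KeyError(f"unknown epitope_id {epitope_id!r}")
        return self.graph.nodes[node].get("label")

    def get_properties(self, epitope_id: str) -> EpitopeProperties:
        """Resolve the four weighting properties of an epitope.

        Direct node attributes are preferred; when an attribute is absent
        (e.g. the graph was imported from bare triples) the answer falls
        back to edge traversal, including the transitive
        Epitope -> Molecule -> MoleculeParent hop.
        """
        node = _PREFIX["Epitope"] + epitope_id
        if node not in self.graph:
            raise KeyError(f"unknown epitope_id {epitope_id!r}")
        # explicit record metadata is authoritative, including explicit
        # absence (key present, value None); traversal is only a fallback
        # for graphs imported from bare triples where the key is missing.
        missing = object()
        attrs = self.graph.nodes[node]
        host = attrs.get("host")
        molecule = attrs.get("source_molecule", missing)
        parent = attrs.get("molecule_parent", missing)
        organism = attrs.get("source_organism", missing)

        if molecule is missing:
            molecule = self._neighbour_name(node, "DERIVED_FROM")
        if organism is missing:
            organism = self._neighbour_name(node, "ORIGINATES_FROM")
        if parent is missing:
            parent = (
                self._neighbour_name(_PREFIX["Molecule"] + molecule, "BELONGS_TO")
                if molecule is not None
                else None
            )
        return EpitopeProperties(
            host=host,
            source_molecule=molecule,
            molecule_parent=parent,
            source_organism=organism,
        )

    def _neighbour_name(self, node: str, relation: str) -> str | None:
        if node not in self.graph:
            return None
        for _, target, data in self.graph.out_edges(node, data=True):
            if data.get("relation") == relation:
                return self.graph.nodes[target].get("name")
        return None

    # -- accounting --------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_triples(self) -> int:
        return self.graph.number_of_edges()

    def triples(self) -> list[tuple[str, str, str]]:
        return [
            (u, d["relation"], v) for u, v, d in self.graph.edges(data=True)
        ]

    # -- interoperability --------------------------------------------------

    def export_triples(self, path) -> None:
        """Write edges as a TSV plus a companion ``<stem>.nodes.tsv``.

        The edge file has columns subject_id, relation, object_id; the node
        file carries node_type, name and the epitope attributes, so a
        re-import reproduces an isomorphic graph.
        """
        path = Path(path)
        edges = pd.DataFrame(
            self.triples(), columns=["subject_id", "relation", "object_id"]
        )
        edges.to_csv(path, sep="\t", index=False)
        rows = []
        for node, data in self.graph.nodes(data=True):
            rows.append(
                {
                    "node_id": node,
                    "node_type": data.get("node_type"),
                    "name": data.get("name"),
                    "sequence": data.get("sequence"),
                    "host": data.get("host"),
                    "label": data.get("label"),
                    "source_molecule": data.get("source_molecule"),
                    "molecule_parent": data.get("molecule_parent"),
                    "source_organism": data.get("source_organism"),
                    "has_metadata": int("source_molecule" in data),
                }
            )
        nodes = pd.DataFrame(
            rows,
            columns=[
                "node_id", "node_type", "name", "sequence", "host", "label",
                "source_molecule", "molecule_parent", "source_organism", "has_metadata",
            ],
        )
        nodes.to_csv(Path(str(path) + ".nodes.tsv"), sep="\t", index=False)

    @classmethod
    def from_triples(cls, path) -> "KnowledgeGraph":
        """Re-import a graph written by :meth:`export_triples`."""
        path = Path(path)
        kg = cls()
        nodes_path = Path(str(path) + ".nodes.tsv")
        if nodes_path.exists():
            nodes = pd.read_csv(nodes_path, sep="\t", dtype=str)
            for _, row in nodes.iterrows():
                label = row.get("label")
                attrs = {
                    "node_type": row["node_type"],
                    "name": row["name"],
                    "sequence": row.get("sequence") if pd.notna(row.get("sequence")) else None,
                    "host": row.get("host") if pd.notna(row.get("host")) else None,
                    "label": int(float(label)) if pd.notna(label) else None,
                }
                has_meta = row.get("has_metadata")
                if pd.notna(has_meta) and int(float(has_meta)):
                    for col in ("source_molecule", "molecule_parent", "source_organism"):
                        value = row.get(col)
                        attrs[col] = value if pd.notna(value) else None
                kg.graph.add_node(row["node_id"], **attrs)
        edges = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("subject_id", "relation", "object_id"):
            if col not in edges.columns:
                raise ValidationError(f"{path.name}: missing column {col!r}")
        for _, row in edges.iterrows():
            if row["relation"] not in RELATIONS:
                raise ValidationError(f"unknown relation {row['relation']!r}")
            for node in (row["subject_id"], row["object_id"]):
                if node not in kg.graph:
                    prefix, _, name = node.partition("::")
                    node_type = {v.rstrip(":"): k for k, v in _PREFIX.items()}.get(prefix)
                    kg.graph.add_node(node, node_type=node_type, name=name)
            kg.graph.add_edge(row["subject_id"], row["object_id"], relation=row["relation"])
        return kg

    def to_cypher(self) -> str:
        """Render CREATE statements loadable by a Cypher graph database."""
        lines = []
        for node, data in self.graph.nodes(data=True):
            props = {k: v for k, v in data.items() if v is not None}
            prop_text = ", ".join(f"{k}: {v!r}" for k, v in props.items() if k != "node_type")
            lines.append(f"CREATE (:{data.get('node_type', 'Node')} {{id: {node!r}, {prop_text}}});")
        for u, rel, v in self.triples():
            lines.append(
                f"MATCH (a {{id: {u!r}}}), (b {{id: {v!r}}}) CREATE (a)-[:{rel}]->(b);"
            )
        return "\n".join(lines) + "\n"


def build_kg(records: Iterable[PeptideRecord]) -> KnowledgeGraph:
    """Convenience alias for :meth:`KnowledgeGraph.from_records`."""
    return KnowledgeGraph.from_records(list(records))
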