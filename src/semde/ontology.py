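"""Directed acyclic ontology graph (OBO subset) and gene annotations.

The ontology model is deliberately small: terms with an id, name and
namespace, and child->parent edges restricted to ``is_a`` and ``part_of``.
That is all the semantic-similarity machinery needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

#: Relation types supported on edges and their default contribution weights.
RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

BIOLOGICAL_PROCESS = "biological_process"


@dataclass
class GoDag:
    """Typed acyclic term graph with child->parent edges.

    Parameters
    ----------
    graph :
        Directed graph whose edges point from child term to parent term and
        carry a ``relation`` attribute (``is_a`` or ``part_of``).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_term(self, term_id: str, name: str = "", namespace: str = BIOLOGICAL_PROCESS) -> None:
        self.graph.add_node(term_id, name=name, namespace=namespace)

    def add_edge(self, child: str, parent: str, relation: str = "is_a") -> None:
        if relation not in RELATION_WEIGHTS:
            raise ValueError(f"unsupported relation {relation!r}")
        self.graph.add_edge(child, parent, relation=relation)

    def validate(self) -> None:
        """Raise if the graph is cyclic or a non-root term cannot reach a root."""
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")
        roots = self.roots()
        if not roots:
            raise ValueError("ontology has no root term")
        for node in self.graph.nodes:
            if node in roots:
                continue
            if not any(r in nx.descendants(self.graph, node) for r in roots):
                raise ValueError(f"term {node} cannot reach a root")

    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def namespace(self, term_id: str) -> str:
        return self.graph.nodes[term_id].get("namespace", BIOLOGICAL_PROCESS)

    def parents(self, term_id: str):
        """Yield ``(parent, relation)`` pairs for a term."""
        for parent in self.graph.successors(term_id):
            yield parent, self.graph.edges[term_id, parent]["relation"]

    def ancestor_subgraph(self, term_id: str) -> nx.DiGraph:
        """Induced subgraph of the term and all of its ancestors."""
        nodes = {term_id} | nx.descendants(self.graph, term_id)
        return self.graph.subgraph(nodes)


@dataclass
class AnnotationSet:
    """Gene -> set-of-term-ids assignments restricted to one namespace."""

    assignments: dict[str, set[str]] = field(default_factory=dict)

    def annotate(self, gene: str, term: str) -> None:
        self.assignments.setdefault(gene, set()).add(term)

    def terms_for(self, gene: str) -> set[str]:
        return self.assignments.get(gene, set())

    def genes(self) -> list[str]:
        return sorted(self.assignments)

    def annotated_genes(self) -> set[str]:
        return {g for g, ts in self.assignments.items() if ts}

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, ts in self.assignments.items() if term in ts}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "term_id": t}
            for g in sorted(self.assignments)
            for t in sorted(self.assignments[g])
        ]
        return pd.DataFrame(rows, columns=["gene_id", "term_id"])


def parse_obo(path: str | Path) -> GoDag:
    """Parse an OBO-subset file into a :class:`GoDag`.

    Recognised stanza lines: ``id``, ``name``, ``namespace``, ``is_a``,
    ``relationship: part_of`` and ``is_obsolete``. Obsolete terms are
    skipped; terms outside ``biological_process`` are ignored at load time.
    """
    dag = GoDag()
    pending_edges: list[tuple[str, str, str]] = []
    current: dict | None = None

    def flush(cur: dict | None) -> None:
        if cur is None or cur.get("obsolete"):
            return
        if cur.get("namespace", BIOLOGICAL_PROCESS) != BIOLOGICAL_PROCESS:
            return
        dag.add_term(cur["id"], cur.get("name", ""), cur.get("namespace", BIOLOGICAL_PROCESS))
        pending_edges.extend(cur.get("edges", []))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                flush(current)
                current = {"edges": []}
            elif current is None or not line or line.startswith("["):
                if line.startswith("[") and line != "[Term]":
                    flush(current)
                    current = None  # non-Term stanza (e.g. [Typedef]); skip
                continue
            elif line.startswith("id:"):
                current["id"] = line[3:].strip()
            elif line.startswith("name:"):
                current["name"] = line[5:].strip()
            elif line.startswith("namespace:"):
                current["namespace"] = line[10:].strip()
            elif line.startswith("is_a:"):
                parent = line[5:].strip().split("!")[0].strip()
                current["edges"].append((current["id"], parent, "is_a"))
            elif line.startswith("relationship:"):
                parts = line[13:].strip().split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    current["edges"].append((current["id"], parts[1], "part_of"))
            elif line.startswith("is_obsolete:") and "true" in line:
                current["obsolete"] = True
    flush(current)

    for child, parent, rel in pending_edges:
        if child in dag and parent in dag:
            dag.add_edge(child, parent, rel)
    dag.validate()
    return dag


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Serialise a :class:`GoDag` as an OBO-subset file."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.graph.nodes):
            attrs = dag.graph.nodes[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {attrs.get('name', term)}\n")
            fh.write(f"namespace: {attrs.get('namespace', BIOLOGICAL_PROCESS)}\n")
            for parent, rel in sorted(dag.parents(term)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")


def parse_annotations(path: str | Path, dag: GoDag | None = None) -> AnnotationSet:
    """Read a GAF-like two-column TSV (gene_id, term_id).

    Terms absent from *dag* (when given) are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError(f"annotation file {path} must have gene_id and term_id columns")
    annots = AnnotationSet()
    dropped = 0
    for gene, term in zip(df["gene_id"], df["term_id"]):
        if dag is not None and term not in dag:
            dropped += 1
            continue
        annots.annotate(gene, term)
    if dropped:
        warnings.warn(f"{dropped} annotations referenced unknown terms and were dropped")
    return annots


def write_annotations(annots: AnnotationSet, path: str | Path) -> None:
    annots.to_frame().to_csv(path, sep="\t", index=False)
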