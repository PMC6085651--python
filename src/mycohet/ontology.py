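"""A minimal Gene Ontology style DAG: terms linked by ``is_a`` edges.

Annotation in this package is always *closed under ancestry*: a gene
annotated with a term is implicitly annotated with every ancestor of that
term ("paternal" terms).  :func:`propagate_annotations` performs that
closure.  The OBO surface is deliberately small — ``id``, ``name``,
``namespace``, ``is_a`` and ``is_obsolete`` — which is the subset the
enrichment stage needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .config import InputError


@dataclass
class GoDag:
    """Directed acyclic graph of ontology terms.

    ``graph`` holds child -> parent ``is_a`` edges, so the ancestors of a
    term are the nodes reachable from it.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)
    photosynthesis_like: set[str] = field(default_factory=set)

    # -- construction -------------------------------------------------------

    def add_term(self, term_id: str, name: str = "", namespace: str = "synthetic",
                 parents: Iterable[str] = (), obsolete: bool = False) -> None:
        self.graph.add_node(term_id)
        self.names[term_id] = name or term_id
        self.namespaces[term_id] = namespace
        if obsolete:
            self.obsolete.add(term_id)
        for p in parents:
            self.graph.add_edge(term_id, p)

    # -- queries -------------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def parents(self, term_id: str) -> set[str]:
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        return set(self.graph.predecessors(term_id))

    def roots(self) -> set[str]:
        return {t for t in self.graph if self.graph.out_degree(t) == 0}

    def leaves(self) -> set[str]:
        return {t for t in self.graph if self.graph.in_degree(t) == 0}

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable through is_a edges, excluding the term itself."""
        if term_id not in self.graph:
            raise InputError(f"unknown ontology term: {term_id}")
        return nx.descendants(self.graph, term_id)

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)

    def validate(self) -> "GoDag":
        if not self.is_acyclic():
            raise InputError("ontology graph contains a cycle")
        roots = self.roots()
        if not roots:
            raise InputError("ontology graph has no root")
        return self

    def ancestor_closure(self) -> dict[str, frozenset[str]]:
        """Term -> frozenset of the term plus all its ancestors.

        Computed once in reverse topological order; used to make
        propagation over thousands of genes cheap.
        """
        closure: dict[str, frozenset[str]] = {}
        for term in nx.topological_sort(self.graph.reverse(copy=False)):
            acc: set[str] = {term}
            for parent in self.graph.successors(term):
                acc |= closure[parent]
            closure[term] = frozenset(acc)
        return closure

    # -- OBO I/O -------------------------------------------------------------

    def to_obo(self, path: str | Path) -> None:
        lines = ["format-version: 1.2", "ontology: synthetic", ""]
        for term in sorted(self.graph.nodes):
            lines.append("[Term]")
            lines.append(f"id: {term}")
            lines.append(f"name: {self.names.get(term, term)}")
            lines.append(f"namespace: {self.namespaces.get(term, 'synthetic')}")
            if term in self.obsolete:
                lines.append("is_obsolete: true")
            for parent in sorted(self.graph.successors(term)):
                lines.append(f"is_a: {parent} ! {self.names.get(parent, parent)}")
            lines.append("")
        Path(path).write_text("\n".join(lines))

    @classmethod
    def from_obo(cls, path: str | Path) -> "GoDag":
        dag = cls()
        stanza: dict[str, list[str]] = {}
        in_term = False

        def flush() -> None:
            if not stanza or "id" not in stanza:
                return
            term_id = stanza["id"][0]
            parents = [v.split("!")[0].strip() for v in stanza.get("is_a", [])]
            dag.add_term(
                term_id,
                name=stanza.get("name", [term_id])[0],
                namespace=stanza.get("namespace", ["synthetic"])[0],
                parents=parents,
                obsolete=stanza.get("is_obsolete", ["false"])[0] == "true",
            )

        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if line == "[Term]":
                flush()
                stanza, in_term = {}, True
                continue
            if line.startswith("[") and line.endswith("]"):
                flush()
                stanza, in_term = {}, False
                continue
            if in_term and ": " in line:
                key, value = line.split(": ", 1)
                stanza.setdefault(key, []).append(value.strip())
        flush()
        return dag.validate()


def propagate_annotations(direct: Mapping[str, Iterable[str]], dag: GoDag,
                          ) -> dict[str, frozenset[str]]:
    """Close each gene's direct term set under is_a ancestry.

    The result is a superset of the input for every gene; genes with an
    empty direct set map to an empty set.  Unknown terms raise
    :class:`InputError` naming the term.
    """
    closure = dag.ancestor_closure()
    out: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        acc: set[str] = set()
        for t in terms:
            if t not in closure:
                raise InputError(f"unknown ontology term: {t} (gene {gene})")
            acc |= closure[t]
        out[gene] = frozenset(acc)
    return out
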