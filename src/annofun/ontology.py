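"""Term-hierarchy handling: OBO parsing and ancestor expansion.

Gene annotations made to a specific ontology term implicitly hold for every
ancestor of that term, so a complete annotation set attaches each gene to the
full ancestor closure of its directly assigned terms. Only the safe
annotation-propagating relationships (``is_a``, ``part_of`` by default) are
traversed; relationships like ``regulates`` do not license propagation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet

from .store import AnnotationStore, Association, Term, merge_stores

logger = logging.getLogger(__name__)

DEFAULT_RELATIONSHIPS = frozenset({"is_a", "part_of"})


class CycleError(ValueError):
    """The parsed hierarchy contains a directed cycle (listed in the message)."""


class OntologyDag:
    """A directed acyclic graph of terms with child->parent edges.

    Edges are typed by relationship name. The graph must be acyclic; this is
    checked at construction.
    """

    def __init__(self, graph: nx.MultiDiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise CycleError(
                "term hierarchy contains a cycle: "
                + " -> ".join(str(u) for u, _, _ in cycle)
                + f" -> {cycle[-1][1]}"
            )
        self._g = graph

    @classmethod
    def from_terms(
        cls, terms: Iterable[Term], relationship: str = "is_a"
    ) -> "OntologyDag":
        """Build a DAG from :class:`Term` objects using their ``parents`` sets."""
        g = nx.MultiDiGraph()
        terms = list(terms)
        ids = {t.id for t in terms}
        for t in terms:
            g.add_node(t.id, name=t.name)
        for t in terms:
            for p in t.parents:
                if p not in ids:
                    raise ValueError(f"term {t.id} references unknown parent {p}")
                g.add_edge(t.id, p, key=relationship)
        return cls(g)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def term_ids(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    def name(self, term_id: str) -> str:
        return self._g.nodes[term_id].get("name", "")

    def parents(self, term_id: str) -> frozenset[str]:
        if term_id not in self._g:
            raise KeyError(f"unknown term {term_id}")
        return frozenset(self._g.successors(term_id))

    def ancestor_closure(self, term_id: str) -> frozenset[str]:
        """The term itself plus every term reachable via parent edges
        (reflexive transitive closure upward)."""
        if term_id not in self._g:
            raise KeyError(f"unknown term {term_id}")
        return frozenset(nx.descendants(self._g, term_id)) | {term_id}


def parse_obo(
    path: str | Path,
    relationships: Iterable[str] = DEFAULT_RELATIONSHIPS,
) -> OntologyDag:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyDag`.

    Obsolete stanzas are excluded; edges are restricted to the requested
    relationship types. A parent reference to an id with no stanza of its own
    is an error, as is any cycle.
    """
    wanted = frozenset(relationships)
    raw = obonet.read_obo(str(path), ignore_obsolete=True)
    g = nx.MultiDiGraph()
    defined = {n for n, d in raw.nodes(data=True) if d}
    for n in defined:
        g.add_node(n, name=raw.nodes[n].get("name", ""))
    for u, v, key in raw.edges(keys=True):
        if key not in wanted:
            continue
        for endpoint in (u, v):
            if endpoint not in defined:
                raise ValueError(
                    f"{path}: edge {u} -[{key}]-> {v} references undefined term "
                    f"{endpoint}"
                )
        g.add_edge(u, v, key=key)
    return OntologyDag(g)


def expand_annotations(
    store: AnnotationStore,
    dag: OntologyDag,
    source: str,
    return_missing: bool = False,
):
    """Expand every association of ``source`` to the ancestor closure of its
    term, preserving the evidence tag (and E-value) of the seed record.

    The result is a superset of the input store and the operation is
    idempotent. Term ids absent from the DAG are left unexpanded and reported
    (release skew between annotation table and ontology file is tolerated).
    When ``return_missing`` is true, returns ``(store, sorted missing ids)``.
    """
    extra = AnnotationStore()
    missing: set[str] = set()
    for assoc in store.associations:
        if assoc.source != source:
            continue
        if assoc.term_id not in dag:
            missing.add(assoc.term_id)
            continue
        for anc in dag.ancestor_closure(assoc.term_id):
            if anc == assoc.term_id:
                continue
            extra.add(
                Association(assoc.gene, source, anc, assoc.evidence, assoc.evalue),
                term_name=dag.name(anc),
            )
    if missing:
        logger.warning(
            "%d term id(s) from source %r not in ontology; left unexpanded",
            len(missing),
            source,
        )
    out = merge_stores(store, extra)
    if return_missing:
        return out, sorted(missing)
    return out
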