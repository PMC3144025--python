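"""Gene-term annotation store.

The central container of the package: associations between genes (identified
by a value plus an identifier *namespace*, since several ID systems typically
coexist for one genome) and functional terms drawn from multiple annotation
sources (pathway databases, ontologies, protein-family resources, or
pseudo-sources such as differential-expression conditions).

Direct annotations and annotations transferred by homology are kept as
distinct evidence records and are never merged, so downstream analyses can
compare or combine them explicitly.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

DIRECT = "direct"
TRANSFERRED = "transferred"
_EVIDENCE = (DIRECT, TRANSFERRED)


class MalformedInputError(ValueError):
    """A data file violates its format contract; the message names the line."""


@dataclass(frozen=True, slots=True)
class GeneId:
    """A gene identifier together with the ID system it belongs to.

    Comparisons are case-sensitive; surrounding whitespace is stripped at
    construction (silent case-folding would hide data errors, but stray
    whitespace from hand-edited files is unambiguous noise).
    """

    value: str
    namespace: str

    def __post_init__(self) -> None:
        v = self.value.strip()
        ns = self.namespace.strip()
        if not v:
            raise ValueError("GeneId value must be non-empty")
        if not ns:
            raise ValueError("GeneId namespace must be non-empty")
        object.__setattr__(self, "value", v)
        object.__setattr__(self, "namespace", ns)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.namespace}:{self.value}"


@dataclass(frozen=True, slots=True)
class Term:
    """A functional term. Identity is the (source, id) pair, so terms from
    different databases never collide even if their ids do."""

    id: str
    name: str = ""
    source: str = ""
    parents: frozenset = frozenset()

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.id)


@dataclass(frozen=True, slots=True)
class Association:
    """One gene-term assignment with its evidence class.

    ``evalue`` is the BLAST E-value of the underlying homology hit and is
    present exactly when the evidence is ``transferred``.
    """

    gene: GeneId
    source: str
    term_id: str
    evidence: str = DIRECT
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.evidence not in _EVIDENCE:
            raise ValueError(f"unknown evidence class {self.evidence!r}")
        if self.evalue is not None:
            if self.evidence != TRANSFERRED:
                raise ValueError("evalue is only valid for transferred evidence")
            if self.evalue < 0:
                raise ValueError("evalue must be non-negative")

    @property
    def term_key(self) -> tuple[str, str]:
        return (self.source, self.term_id)


class AnnotationStore:
    """Set of :class:`Association` records plus the per-namespace gene universe.

    The universe may exceed the annotated genes (it is the enrichment
    background, i.e. the total number of genes in the genome). A forward map
    (gene -> term keys) and an inverted index (term key -> genes) are
    maintained consistently on every mutation.
    """

    def __init__(self) -> None:
        self._associations: set[Association] = set()
        self._terms: dict[tuple[str, str], Term] = {}
        self._universe: dict[str, set[GeneId]] = defaultdict(set)
        self._forward: dict[GeneId, set[tuple[str, str]]] = defaultdict(set)
        self._inverted: dict[tuple[str, str], set[GeneId]] = defaultdict(set)

    # -- construction -------------------------------------------------

    def add_gene(self, gene: GeneId) -> None:
        """Add a gene to the universe (possibly unannotated)."""
        self._universe[gene.namespace].add(gene)

    def register_term(self, term: Term) -> None:
        existing = self._terms.get(term.key)
        # A named registration wins over a bare id-only placeholder.
        if existing is None or (not existing.name and term.name):
            self._terms[term.key] = term

    def add(self, assoc: Association, term_name: str = "") -> None:
        self.add_gene(assoc.gene)
        if assoc.term_key not in self._terms or (
            term_name and not self._terms[assoc.term_key].name
        ):
            self.register_term(
                Term(id=assoc.term_id, name=term_name, source=assoc.source)
            )
        self._associations.add(assoc)
        self._forward[assoc.gene].add(assoc.term_key)
        self._inverted[assoc.term_key].add(assoc.gene)

    # -- accessors ----------------------------------------------------

    @property
    def associations(self) -> frozenset[Association]:
        return frozenset(self._associations)

    @property
    def gene_universe(self) -> Mapping[str, frozenset[GeneId]]:
        return {ns: frozenset(gs) for ns, gs in self._universe.items()}

    def universe(self, namespace: str) -> frozenset[GeneId]:
        return frozenset(self._universe.get(namespace, set()))

    def namespaces(self) -> list[str]:
        return sorted(self._universe)

    def sources(self) -> list[str]:
        return sorted({s for s, _ in self._terms})

    def term(self, source: str, term_id: str) -> Term:
        try:
            return self._terms[(source, term_id)]
        except KeyError:
            raise KeyError(f"unknown term {source}:{term_id}") from None

    def has_term(self, source: str, term_id: str) -> bool:
        return (source, term_id) in self._terms

    def terms(self, source: str | None = None) -> Iterator[Term]:
        for key in sorted(self._terms):
            if source is None or key[0] == source:
                yield self._terms[key]

    def genes_with_term(self, source: str, term_id: str) -> frozenset[GeneId]:
        if (source, term_id) not in self._terms:
            raise KeyError(f"unknown term {source}:{term_id}")
        return frozenset(self._inverted.get((source, term_id), set()))

    def term_keys_of_gene(self, gene: GeneId) -> frozenset[tuple[str, str]]:
        return frozenset(self._forward.get(gene, set()))

    def associations_of_gene(self, gene: GeneId) -> list[Association]:
        keys = self._forward.get(gene, set())
        return sorted(
            (a for a in self._associations if a.gene == gene and a.term_key in keys),
            key=lambda a: (a.source, a.term_id, a.evidence),
        )

    def __len__(self) -> int:
        return len(self._associations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationStore):
            return NotImplemented
        return (
            self._associations == other._associations
            and {k: v for k, v in self._universe.items() if v}
            == {k: v for k, v in other._universe.items() if v}
        )

    # -- operations ---------------------------------------------------

    def lookup_gene(self, gene: GeneId) -> tuple[list[tuple[Term, str]], bool]:
        """All annotations of one gene, grouped by source with direct records
        before transferred ones.

        Returns ``(records, known)``; ``known`` is False when the gene is not
        in the universe at all (an unknown-gene flag, distinct from a known
        but unannotated gene which yields an empty list with ``known=True``).
        """
        known = gene in self._universe.get(gene.namespace, set())
        if not known:
            return [], False
        order = {DIRECT: 0, TRANSFERRED: 1}
        recs = self.associations_of_gene(gene)
        recs.sort(key=lambda a: (a.source, order[a.evidence], a.term_id))
        return [(self._terms[a.term_key], a.evidence) for a in recs], True

    def keyword_search(self, query: str) -> list[tuple[Term, list[GeneId]]]:
        """Terms whose name contains ``query`` case-insensitively, each with
        its annotated genes (sorted by namespace then id)."""
        if not query:
            raise ValueError("query must be non-empty")
        q = query.lower()
        out: list[tuple[Term, list[GeneId]]] = []
        for key in sorted(self._terms):
            term = self._terms[key]
            if q in term.name.lower():
                genes = sorted(
                    self._inverted.get(key, set()),
                    key=lambda g: (g.namespace, g.value),
                )
                out.append((term, genes))
        return out


def merge_stores(a: AnnotationStore, b: AnnotationStore) -> AnnotationStore:
    """Union of two stores: associations de-duplicate as set union, but a
    direct and a transferred record for the same (gene, term) both survive —
    they are distinct evidence records."""
    out = AnnotationStore()
    for src in (a, b):
        for ns, genes in src.gene_universe.items():
            for g in genes:
                out.add_gene(g)
        for term in src.terms():
            out.register_term(term)
        for assoc in src.associations:
            out.add(assoc)
    return out


# -- I/O ---------------------------------------------------------------

_NULL = "-"


def load_gene_term_table(
    path: str | Path,
    format: str = "tsv",
    namespace: str = "default",
    source: str = "default",
    evidence: str = DIRECT,
    universe_path: str | Path | None = None,
) -> AnnotationStore:
    """Load a gene-term association table.

    ``tsv`` rows are ``gene_id<TAB>term_id[<TAB>term_name]``; ``gmt`` rows are
    ``term_id<TAB>description<TAB>gene1<TAB>gene2...`` (gene-matrix-transposed).
    ``#`` comment lines and blank lines are ignored. Duplicated rows collapse.
    The gene universe defaults to the genes seen; pass ``universe_path`` (one
    gene id per line) to include unannotated genes in the background.
    """
    if format not in ("tsv", "gmt"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    store = AnnotationStore()
    n_rows = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if format == "tsv":
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise MalformedInputError(
                        f"{path}:{lineno}: expected gene_id<TAB>term_id[<TAB>term_name]"
                    )
                gene = GeneId(fields[0], namespace)
                name = fields[2].strip() if len(fields) > 2 else ""
                store.add(
                    Association(gene, source, fields[1].strip(), evidence),
                    term_name=name,
                )
            else:  # gmt
                if len(fields) < 3:
                    raise MalformedInputError(
                        f"{path}:{lineno}: GMT rows need term, description, >=1 gene"
                    )
                term_id, desc = fields[0].strip(), fields[1].strip()
                if not term_id:
                    raise MalformedInputError(f"{path}:{lineno}: empty term id")
                for g in fields[2:]:
                    if g.strip():
                        store.add(
                            Association(GeneId(g, namespace), source, term_id, evidence),
                            term_name=desc,
                        )
            n_rows += 1
    if n_rows == 0:
        logger.warning("%s: empty annotation table; returning empty store", path)
    if universe_path is not None:
        for g in _read_gene_list(universe_path, namespace):
            store.add_gene(g)
    return store


def _read_gene_list(path: str | Path, namespace: str) -> list[GeneId]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(GeneId(line, namespace))
    return out


def read_gene_list(path: str | Path, namespace: str) -> list[GeneId]:
    """Read a gene list file: one id per line, ``#`` comments allowed."""
    return _read_gene_list(path, namespace)


def write_store(store: AnnotationStore, path: str | Path) -> None:
    """Dump a store as TSV with columns namespace, gene_id, source, term_id,
    term_name, evidence, evalue. Universe-only (unannotated) genes are written
    as rows whose term fields are the ``-`` sentinel so that write->read
    round-trips the universe exactly."""
    path = Path(path)
    annotated: set[GeneId] = set()
    rows: list[tuple] = []
    for a in store.associations:
        annotated.add(a.gene)
        name = store.term(a.source, a.term_id).name
        rows.append(
            (
                a.gene.namespace,
                a.gene.value,
                a.source,
                a.term_id,
                name or _NULL,
                a.evidence,
                repr(a.evalue) if a.evalue is not None else _NULL,
            )
        )
    for ns, genes in store.gene_universe.items():
        for g in sorted(genes - annotated, key=lambda g: g.value):
            rows.append((ns, g.value, _NULL, _NULL, _NULL, _NULL, _NULL))
    rows.sort()
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# namespace\tgene_id\tsource\tterm_id\tterm_name\tevidence\tevalue\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_store(path: str | Path) -> AnnotationStore:
    """Read a store dump produced by :func:`write_store`."""
    path = Path(path)
    store = AnnotationStore()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise MalformedInputError(
                    f"{path}:{lineno}: store dumps have exactly 7 columns"
                )
            ns, gid, source, term_id, name, evidence, evalue = fields
            gene = GeneId(gid, ns)
            if source == _NULL and term_id == _NULL:
                store.add_gene(gene)
                continue
            ev = None if evalue == _NULL else float(evalue)
            store.add(
                Association(gene, source, term_id, evidence, ev),
                term_name="" if name == _NULL else name,
            )
    return store


def check_index_consistency(store: AnnotationStore) -> bool:
    """True iff the inverted index agrees exactly with the forward map."""
    for term in store.terms():
        genes = store.genes_with_term(term.source, term.id)
        derived = {
            g
            for ns in store.namespaces()
            for g in store.universe(ns)
            if term.key in store.term_keys_of_gene(g)
        }
        if set(genes) != derived:
            return False
    return True
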