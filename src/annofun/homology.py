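"""Sequence-similarity plumbing: BLAST tabular parsing, best hits,
reciprocal best hits, coverage filtering, homology-based annotation transfer
and cross-namespace gene-identifier conversion.

Orthologous identifier pairs are deduced as reciprocal best BLAST hits
(each sequence is the other's top-scoring match in both search directions),
then filtered on alignment coverage: pairs covering 100% of both sequences
are kept unconditionally, the remainder only when coverage is at least the
threshold (default 75%). The mutual-best-hit criterion is itself the
disambiguator for one-to-many similarity: no id can occur in two surviving
pairs, so the result is a partial bijection between namespaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .store import (
    AnnotationStore,
    Association,
    GeneId,
    MalformedInputError,
    TRANSFERRED,
    merge_stores,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_COVERAGE = 0.75


@dataclass(frozen=True, slots=True)
class BlastHit:
    """One row of tabular BLAST output; coverages are fractions of the
    query/subject lengths spanned by the alignment, None when the optional
    length columns were absent."""

    query: GeneId
    subject: GeneId
    evalue: float
    bitscore: float
    query_coverage: float | None = None
    subject_coverage: float | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        for c in (self.query_coverage, self.subject_coverage):
            if c is not None and not (0.0 <= c <= 1.0):
                raise ValueError(f"coverage {c} outside [0, 1]")


@dataclass(frozen=True, slots=True)
class IdPair:
    """A validated cross-namespace identifier pair with its coverage
    metadata and the E-value of the supporting forward hit."""

    a: GeneId
    b: GeneId
    min_coverage: float | None
    full_coverage: bool
    evalue: float | None = None


class IdMap:
    """A partial bijection between gene ids of two namespaces.

    No id occurs in more than one pair, so ``a_to_b`` inverted is exactly
    ``b_to_a`` and list conversion is reversible on the mapped subset.
    """

    def __init__(self, namespace_a: str, namespace_b: str, pairs: Iterable[IdPair]):
        self.namespace_a = namespace_a
        self.namespace_b = namespace_b
        self._pairs: list[IdPair] = sorted(
            pairs, key=lambda p: (p.a.value, p.b.value)
        )
        self._a2b: dict[GeneId, IdPair] = {}
        self._b2a: dict[GeneId, IdPair] = {}
        for p in self._pairs:
            if p.a.namespace != namespace_a or p.b.namespace != namespace_b:
                raise ValueError(f"pair {p.a}~{p.b} violates map namespaces")
            if p.a in self._a2b or p.b in self._b2a:
                raise ValueError(f"id {p.a} or {p.b} occurs in more than one pair")
            self._a2b[p.a] = p
            self._b2a[p.b] = p

    @property
    def pairs(self) -> tuple[IdPair, ...]:
        return tuple(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, gene: GeneId) -> bool:
        return gene in self._a2b or gene in self._b2a

    def get(self, gene: GeneId) -> GeneId | None:
        """The partner of ``gene`` in the other namespace, if mapped."""
        if gene.namespace == self.namespace_a:
            p = self._a2b.get(gene)
            return p.b if p else None
        if gene.namespace == self.namespace_b:
            p = self._b2a.get(gene)
            return p.a if p else None
        raise ValueError(
            f"gene namespace {gene.namespace!r} not in map "
            f"({self.namespace_a!r}, {self.namespace_b!r})"
        )

    def pair_of(self, gene: GeneId) -> IdPair | None:
        return self._a2b.get(gene) or self._b2a.get(gene)

    def invert(self) -> "IdMap":
        return IdMap(
            self.namespace_b,
            self.namespace_a,
            [
                IdPair(p.b, p.a, p.min_coverage, p.full_coverage, p.evalue)
                for p in self._pairs
            ],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IdMap):
            return NotImplemented
        return (
            self.namespace_a == other.namespace_a
            and self.namespace_b == other.namespace_b
            and set(self._pairs) == set(other._pairs)
        )


# -- parsing -----------------------------------------------------------


def parse_blast_tabular(
    path: str | Path,
    query_namespace: str = "query",
    subject_namespace: str = "subject",
) -> list[BlastHit]:
    """Parse 12-column tabular BLAST output (outfmt 6), optionally carrying
    qlen and slen as columns 13-14 from which alignment coverages are
    computed (aligned span / sequence length). Without them coverage is
    marked unavailable."""
    path = Path(path)
    hits: list[BlastHit] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) not in (12, 14):
                raise MalformedInputError(
                    f"{path}:{lineno}: expected 12 or 14 tab-separated columns, "
                    f"got {len(f)}"
                )
            try:
                qstart, qend = int(f[6]), int(f[7])
                sstart, send = int(f[8]), int(f[9])
                evalue, bitscore = float(f[10]), float(f[11])
                qlen = int(f[12]) if len(f) == 14 else None
                slen = int(f[13]) if len(f) == 14 else None
            except ValueError as exc:
                raise MalformedInputError(f"{path}:{lineno}: {exc}") from None
            qcov = (abs(qend - qstart) + 1) / qlen if qlen else None
            scov = (abs(send - sstart) + 1) / slen if slen else None
            hits.append(
                BlastHit(
                    query=GeneId(f[0], query_namespace),
                    subject=GeneId(f[1], subject_namespace),
                    evalue=evalue,
                    bitscore=bitscore,
                    query_coverage=qcov,
                    subject_coverage=scov,
                )
            )
    return hits


# -- best hits and RBH -------------------------------------------------


def best_hits(
    hits: Iterable[BlastHit], max_evalue: float = DEFAULT_MAX_EVALUE
) -> dict[GeneId, BlastHit]:
    """Per query, the single qualifying hit with the smallest E-value.

    The E-value threshold is strict (< max_evalue). Ties on E-value break by
    higher bitscore, then lexicographically smaller subject id, which makes
    the result invariant under permutation of the input.
    """
    best: dict[GeneId, BlastHit] = {}
    for h in hits:
        if not (h.evalue < max_evalue):
            continue
        cur = best.get(h.query)
        if cur is None or (h.evalue, -h.bitscore, h.subject.value) < (
            cur.evalue,
            -cur.bitscore,
            cur.subject.value,
        ):
            best[h.query] = h
    return best


def reciprocal_best_hits(
    ab: Mapping[GeneId, BlastHit], ba: Mapping[GeneId, BlastHit]
) -> IdMap:
    """Mutual best hits: pair (a, b) kept iff a's best hit is b and b's best
    hit is a. Pair coverage is the minimum of the two hits' query coverages
    (conservative: an asymmetric fragment match cannot pass on one good
    direction alone); full coverage means both equal 1.0."""
    ns_a = next(iter(ab)).namespace if ab else "A"
    ns_b = next(iter(ba)).namespace if ba else "B"
    pairs: list[IdPair] = []
    for a, fwd in ab.items():
        back = ba.get(fwd.subject)
        if back is None or back.subject != a:
            continue
        covs = [c for c in (fwd.query_coverage, back.query_coverage) if c is not None]
        have_both = fwd.query_coverage is not None and back.query_coverage is not None
        min_cov = min(covs) if have_both else None
        full = have_both and fwd.query_coverage == 1.0 and back.query_coverage == 1.0
        pairs.append(IdPair(a, fwd.subject, min_cov, full, evalue=fwd.evalue))
    return IdMap(ns_a, ns_b, pairs)


def apply_coverage_filter(
    idmap: IdMap, min_coverage: float = DEFAULT_MIN_COVERAGE
) -> IdMap:
    """Keep full-coverage pairs unconditionally; keep the rest iff their
    minimum coverage is at least ``min_coverage``. Pairs lacking coverage
    metadata are dropped with a warning."""
    kept, dropped = [], []
    for p in idmap.pairs:
        if p.full_coverage:
            kept.append(p)
        elif p.min_coverage is None:
            logger.warning("pair %s~%s lacks coverage metadata; dropped", p.a, p.b)
            dropped.append(p)
        elif p.min_coverage >= min_coverage:
            kept.append(p)
        else:
            dropped.append(p)
    if dropped:
        logger.info(
            "coverage filter dropped %d of %d pairs", len(dropped), len(idmap.pairs)
        )
    return IdMap(idmap.namespace_a, idmap.namespace_b, kept)


# -- annotation transfer ----------------------------------------------


def transfer_annotations(store: AnnotationStore, idmap: IdMap) -> AnnotationStore:
    """Transfer direct annotations across an :class:`IdMap`, from its A
    namespace onto its B namespace (invert the map for the other direction).

    Only *direct* source records propagate — transferred annotations are
    never re-transferred, so no evidence chain of length two can form — and
    every emitted record is tagged ``transferred`` with the E-value of the
    supporting hit. The returned store is the input plus the new records.
    """
    extra = AnnotationStore()
    for p in idmap.pairs:
        for assoc in store.associations_of_gene(p.a):
            if assoc.evidence != "direct":
                continue
            name = store.term(assoc.source, assoc.term_id).name
            extra.add(
                Association(p.b, assoc.source, assoc.term_id, TRANSFERRED, p.evalue),
                term_name=name,
            )
    return merge_stores(store, extra)


def transfer_by_best_hit(
    store: AnnotationStore, best: Mapping[GeneId, BlastHit]
) -> AnnotationStore:
    """One-directional transfer without the reciprocity requirement: each
    query gene inherits the direct annotations of its single best hit (the
    mode used against large reference protein databases, where mutual best
    hits are not meaningful)."""
    extra = AnnotationStore()
    for query, hit in best.items():
        for assoc in store.associations_of_gene(hit.subject):
            if assoc.evidence != "direct":
                continue
            name = store.term(assoc.source, assoc.term_id).name
            extra.add(
                Association(query, assoc.source, assoc.term_id, TRANSFERRED, hit.evalue),
                term_name=name,
            )
    return merge_stores(store, extra)


# -- identifier conversion ---------------------------------------------


def convert_gene_list(
    genes: Iterable[GeneId], idmap: IdMap
) -> tuple[list[GeneId], list[GeneId]]:
    """Convert a gene list from the map's A namespace to its B namespace.

    Order-preserving; duplicate inputs collapse to the first occurrence;
    unmapped genes are returned separately. A gene from any other namespace
    is an error.
    """
    converted: list[GeneId] = []
    unmapped: list[GeneId] = []
    seen: set[GeneId] = set()
    for g in genes:
        if g.namespace != idmap.namespace_a:
            raise ValueError(
                f"gene {g} is not in source namespace {idmap.namespace_a!r}"
            )
        if g in seen:
            continue
        seen.add(g)
        partner = idmap.get(g)
        if partner is None:
            unmapped.append(g)
        else:
            converted.append(partner)
    return converted, unmapped


# -- I/O ---------------------------------------------------------------


def write_idmap(idmap: IdMap, path: str | Path) -> None:
    """Dump an IdMap as TSV: id_a, id_b, min_coverage, full_coverage, evalue.
    Namespaces travel in a header comment so the dump round-trips."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# namespaces\t{idmap.namespace_a}\t{idmap.namespace_b}\n")
        fh.write("# id_a\tid_b\tmin_coverage\tfull_coverage\tevalue\n")
        for p in idmap.pairs:
            fh.write(
                "\t".join(
                    [
                        p.a.value,
                        p.b.value,
                        repr(p.min_coverage) if p.min_coverage is not None else "-",
                        "1" if p.full_coverage else "0",
                        repr(p.evalue) if p.evalue is not None else "-",
                    ]
                )
                + "\n"
            )


def read_idmap(path: str | Path) -> IdMap:
    path = Path(path)
    ns_a, ns_b = "A", "B"
    pairs: list[IdPair] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("# namespaces\t"):
                _, ns_a, ns_b = line.split("\t")
                continue
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 5:
                raise MalformedInputError(f"{path}:{lineno}: expected 5 columns")
            pairs.append(
                IdPair(
                    GeneId(f[0], ns_a),
                    GeneId(f[1], ns_b),
                    None if f[2] == "-" else float(f[2]),
                    f[3] == "1",
                    None if f[4] == "-" else float(f[4]),
                )
            )
    return IdMap(ns_a, ns_b, pairs)
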