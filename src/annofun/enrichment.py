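"""Cumulative hypergeometric term-enrichment testing for gene lists.

For a list of n genes drawn from a background of N genes of which K carry a
given functional term, the enrichment p-value of observing k or more
term-carrying genes in the list is the hypergeometric upper tail
P(X >= k), X ~ Hypergeometric(N, K, n). One test is performed per term that
hits the list at least once, and results are ranked by ascending p-value.
Benjamini-Hochberg q-values are attached as an extra column but never used
for ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .store import AnnotationStore, GeneId, Term

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: background size, K: background genes carrying the term, n: list size,
    k: list genes carrying the term. Computed via the survival function for
    numerical stability; exact at the boundaries (k = 0 gives 1, k > min(n, K)
    is invalid).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """One tested term with its four test parameters, the raw p-value, the
    BH q-value, and the list genes that carry the term."""

    term: Term
    N: int
    K: int
    n: int
    k: int
    p_value: float
    q_value: float | None = None
    gene_hits: tuple[GeneId, ...] = ()


def enrich(
    gene_list: Sequence[GeneId],
    store: AnnotationStore,
    background: Iterable[GeneId] | None = None,
    sources: Iterable[str] | None = None,
    evidence: str | None = None,
    exclude_terms: Iterable[tuple[str, str]] = (),
) -> list[EnrichmentResult]:
    """Test every term of the requested sources for overrepresentation in
    ``gene_list`` and return results ranked by ascending p-value (ties break
    by descending k, then term key).

    The background defaults to the full gene universe of the list's
    namespace — the total number of genes in the genome, not merely the
    annotated ones. List genes absent from the background are dropped with a
    warning; only terms with k >= 1 are reported. ``evidence`` restricts the
    associations considered to one evidence class ("direct" or
    "transferred"); by default both are used together. ``exclude_terms`` is a
    stop-list of (source, term_id) keys (e.g. ontology namespace roots, which
    annotate everything and return uninformative p = 1 rows).
    """
    # de-duplicate preserving order: sampling is without replacement
    uniq: list[GeneId] = []
    seen: set[GeneId] = set()
    for g in gene_list:
        if g not in seen:
            seen.add(g)
            uniq.append(g)
    if not uniq:
        raise ValueError("gene list is empty after de-duplication")
    namespaces = {g.namespace for g in uniq}
    if len(namespaces) > 1:
        raise ValueError(f"gene list mixes namespaces {sorted(namespaces)}")
    ns = namespaces.pop()

    if background is None:
        bg = set(store.universe(ns))
    else:
        bg = set(background)
    if len(bg) < len(uniq):
        raise ValueError(
            f"background ({len(bg)} genes) smaller than gene list ({len(uniq)})"
        )
    kept = [g for g in uniq if g in bg]
    dropped = [g for g in uniq if g not in bg]
    if dropped:
        logger.warning(
            "%d list gene(s) absent from the background were dropped", len(dropped)
        )
    if not kept:
        raise ValueError("no list gene is present in the background")

    wanted_sources = set(sources) if sources is not None else set(store.sources())
    stop = set(exclude_terms)
    N, n = len(bg), len(kept)
    kept_set = set(kept)

    # count K and k per term in one pass over the relevant associations
    carriers: dict[tuple[str, str], set[GeneId]] = {}
    for assoc in store.associations:
        if assoc.source not in wanted_sources or assoc.term_key in stop:
            continue
        if evidence is not None and assoc.evidence != evidence:
            continue
        if assoc.gene in bg:
            carriers.setdefault(assoc.term_key, set()).add(assoc.gene)

    results: list[EnrichmentResult] = []
    for key, genes in carriers.items():
        hits = [g for g in kept if g in genes]
        k = len(hits)
        if k < 1:
            continue
        K = len(genes)
        p = hypergeom_upper_tail(N, K, n, k)
        results.append(
            EnrichmentResult(
                term=store.term(*key),
                N=N,
                K=K,
                n=n,
                k=k,
                p_value=p,
                gene_hits=tuple(hits),
            )
        )
    results.sort(key=lambda r: (r.p_value, -r.k, r.term.source, r.term.id))
    if results:
        q = stats.false_discovery_control([r.p_value for r in results])
        results = [
            EnrichmentResult(
                r.term, r.N, r.K, r.n, r.k, r.p_value, float(qi), r.gene_hits
            )
            for r, qi in zip(results, q)
        ]
    return results


def subset_by_term(
    gene_list: Sequence[GeneId], term: tuple[str, str], store: AnnotationStore
) -> list[GeneId]:
    """Order-preserving sublist of the list genes annotated with ``term``
    (so a refined list can be re-run through :func:`enrich`)."""
    source, term_id = term
    members = store.genes_with_term(source, term_id)  # raises on unknown term
    seen: set[GeneId] = set()
    out = []
    for g in gene_list:
        if g in members and g not in seen:
            seen.add(g)
            out.append(g)
    return out


def pathway_partition(
    term: tuple[str, str],
    gene_list: Sequence[GeneId],
    store: AnnotationStore,
) -> tuple[frozenset[GeneId], frozenset[GeneId]]:
    """Split a pathway's members into those present in the gene list and
    those found in the genome but not in the list (the two disjoint sets a
    pathway-map highlight is built from)."""
    source, term_id = term
    members = store.genes_with_term(source, term_id)
    listed = set(gene_list)
    return frozenset(members & listed), frozenset(members - listed)


def write_results(
    results: Sequence[EnrichmentResult], path, sep: str = "\t"
) -> None:
    """Write ranked results as the portal-style tab-delimited table."""
    import pathlib

    with pathlib.Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            sep.join(
                [
                    "source",
                    "term_id",
                    "term_name",
                    "k",
                    "K",
                    "n",
                    "N",
                    "p_value",
                    "q_value",
                    "gene_hits",
                ]
            )
            + "\n"
        )
        for r in results:
            fh.write(
                sep.join(
                    [
                        r.term.source,
                        r.term.id,
                        r.term.name,
                        str(r.k),
                        str(r.K),
                        str(r.n),
                        str(r.N),
                        f"{r.p_value:.6g}",
                        f"{r.q_value:.6g}" if r.q_value is not None else "-",
                        ",".join(g.value for g in r.gene_hits),
                    ]
                )
                + "\n"
            )
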