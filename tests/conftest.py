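import numpy as np
import pytest

from annofun import AnnotationStore, Association, GeneId


def gid(value: str, ns: str = "ns1") -> GeneId:
    return GeneId(value, ns)


def make_store(rows, universe=None, ns: str = "ns1") -> AnnotationStore:
    """rows: iterable of (gene, source, term_id[, evidence[, evalue]]) tuples
    with plain-string genes; universe: extra plain-string gene ids."""
    store = AnnotationStore()
    for row in rows:
        gene, source, term_id, *rest = row
        evidence = rest[0] if rest else "direct"
        evalue = rest[1] if len(rest) > 1 else None
        store.add(Association(GeneId(gene, ns), source, term_id, evidence, evalue))
    for g in universe or ():
        store.add_gene(GeneId(g, ns))
    return store


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
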