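"""Expanding gene annotations to their ontology ancestors.

A gene annotated to a specific term implicitly carries every ancestor of
that term, so enrichment can detect broader categories. This example builds
a small is_a hierarchy, annotates one gene at a leaf, and shows the
annotation set before and after ancestor expansion.
"""

from annofun import (
    AnnotationStore, Association, GeneId, OntologyDag, Term, expand_annotations,
)

dag = OntologyDag.from_terms([
    Term("M:0001", name="metabolism"),
    Term("M:0002", name="sulfur metabolism", parents=frozenset({"M:0001"})),
    Term("M:0003", name="sulfate assimilation", parents=frozenset({"M:0002"})),
])

store = AnnotationStore()
store.add(Association(GeneId("g1", "jgi3"), "go", "M:0003"),
          term_name="sulfate assimilation")

expanded = expand_annotations(store, dag, "go")
for label, s in [("before", store), ("after", expanded)]:
    terms = sorted(tid for _, tid in s.term_keys_of_gene(GeneId("g1", "jgi3")))
    print(f"{label} expansion: g1 -> {terms}")

# After expansion the gene carries the leaf plus both ancestors, so a list
# of sulfate-assimilation genes can show enrichment for the broader
# "sulfur metabolism" category as well.
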