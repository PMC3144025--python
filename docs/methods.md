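# Methods

This note records the statistical models behind `annofun`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical and design decisions a maintainer would want to know.

## Annotation model

An annotation is a triple (gene, term, evidence). Genes are identified by a
(value, namespace) pair because several identifier systems typically coexist
for one genome (e.g. two assembly versions and two gene-prediction sets);
matching is case-sensitive with surrounding whitespace stripped, since these
identifier systems are case-stable and silent case-folding would mask data
errors. Term identity is (source, id), so terms from different databases
never collide. Evidence is either `direct` (asserted for this gene in the
source database) or `transferred` (inferred from a homolog); the two classes
are stored as distinct records for the same (gene, term) and are never
merged, so analyses can use them jointly or separately.

The *gene universe* per namespace may exceed the annotated genes: the
enrichment background is the total number of genes in the genome, and a
universe file of unannotated gene models can be supplied. By default the
universe is the set of genes seen in loaded tables — the conservative choice
when no gene-model catalogue is available; both behaviours are exposed.

## Ontology expansion

A gene annotated to a term implicitly carries every ancestor of that term.
`expand_annotations` adds, for each association, one association per term in
the reflexive transitive closure over parent edges, preserving the evidence
tag. Only `is_a` and `part_of` edges are traversed by default: these are the
relationships that safely propagate annotation; `regulates`-style relations
do not license it and are never followed. The operation is idempotent and
monotone, and the expanded term set of every gene is upward-closed in the
DAG. Term ids present in annotation tables but missing from the ontology
file are tolerated (release skew) — they are left unexpanded and reported.
Ontology namespace roots can be excluded from enrichment via a stop-list,
because a root annotates everything and always returns p = 1.

## Homology mapping and identifier conversion

Best hits are selected per query among BLAST hits with E-value strictly
below 1e-5 (strict `<`); ties on E-value break by descending bitscore, then
ascending subject id, making the result invariant under permutation of the
hit file. A pair (a, b) is retained when a's best hit is b *and* b's best
hit is a (reciprocal best hit); mutuality itself disambiguates one-to-many
similarity, so the result is always a partial bijection and the map inverted
equals the map computed in the opposite direction.

Pair coverage is the minimum of the two directions' query coverages
(aligned query span / query length); "full coverage" means both equal 1.
Full-coverage pairs pass the coverage filter unconditionally; the rest pass
at ≥ 0.75 by default. The conservative minimum prevents an asymmetric
fragment match from passing on one good direction alone.

Two transfer modes exist because they serve different situations:
`transfer_annotations` requires an RBH id map (appropriate between two
finite, comparable protein sets), while `transfer_by_best_hit` transfers
from a query's single best hit without reciprocity (appropriate against a
large reference database where mutuality is not meaningful). In both modes
only *direct* source annotations propagate and every emitted record is
tagged `transferred` with the supporting hit's E-value — transferred
annotations never re-transfer, so no evidence chain of length two can form.

## Term enrichment

For a de-duplicated list of n genes from a background of N genes, K of which
carry a term and k of which in the list do, the p-value is the upper tail of
the hypergeometric distribution, P(X ≥ k) with X ~ Hypergeom(N, K, n),
evaluated through the survival function (log-space internally) rather than
naive pmf summation. Only terms with k ≥ 1 are reported, one test per term,
ranked by ascending p-value with ties broken by descending k then term key.
Benjamini–Hochberg q-values are attached as an additional column but never
used for ranking, preserving the raw-p ordering while acknowledging modern
multiple-testing practice. Duplicate list genes collapse before testing
(sampling is without replacement); list genes outside the background are
dropped and reported. The `evidence` flag restricts testing to direct or
transferred records; the default tests them jointly, which is the more
common need when the caller has already decided to trust the transfers —
passing the flag reproduces a strict separate-evidence comparison.

`subset_by_term` extracts the list genes carrying one term so a refined list
can be re-run, and `pathway_partition` splits a term's members into
in-list vs in-genome-but-not-in-list — the two sets a pathway-map highlight
is drawn from.

## Differential expression

Counts are normalized per condition to a common depth (counts per million
uniquely mapped reads by default). For each gene, λ is the mean of its
normalized values across *all* conditions, including the tested one. A
condition with value x is called over-expressed when x/λ > 2 and
P(X ≥ ⌈x⌉ | λ) < 0.05, under-expressed when x/λ < 1/2 and
P(X ≤ ⌊x⌋ | λ) < 0.05. Normalized values are not integers; rounding outward
(⌈x⌉ for the upper tail, ⌊x⌋ for the lower) is conservative in both
directions. No multiple-testing correction is applied to calls — the rule is
a fixed per-test threshold — and both the fold threshold and α are
parameters. The Poisson model understates biological overdispersion; on real
compendia this inflates calls for highly expressed genes, which is a known
property of this class of rule rather than an implementation artifact.

Calls are materialized as pseudo-terms `over:<condition>` /
`under:<condition>` under source `condition`, so condition enrichment of a
gene list is ordinary term enrichment against that store.

## Coexpression search

Similarity uses correlation distance d(u, v) = 1 − Pearson(u, v) (0 =
identical shape, 2 = anti-correlated; invariant under positive affine
transformations of either profile) on one of three representations of the
normalized matrix: absolute values, log2(x + 1), or log2 ratios to the
gene's cross-condition mean. Genes with constant profiles have undefined
correlation: a constant query is an error, constant candidates are excluded.
The default of k = 100 neighbors reflects the typical working size of a
"functionally related genes" report; a distance ceiling is available.

The low-variance filter drops genes below a variance quantile (default
0.25). Variance is always ranked on the log2(x + 1) scale even when the
similarity representation is absolute or log-ratio, because raw-scale
variance is dominated by expression level and would rank abundance, not
variability. Constant rows are dropped for any positive quantile.

## Synthetic generators and what they show

The generators are the package's study conditions, not mere test plumbing.

*Annotation fixture* — a 2,000-gene genome, 50 background terms each
carried independently by 5% of genes, one planted term carried by exactly 1%
of genes, and a 20-gene list consisting (by default) entirely of carriers.
These sizes make the planted signal strong but leave background terms enough
mass to produce competing small p-values, so top-rank recovery is a
meaningful check. Infeasible specs (list fraction requiring more carriers
than exist) raise rather than silently degrade.

*Null calibration* — a dedicated configuration
(`null_calibration_spec`) for checking that the p-value of an unenriched
term is approximately Uniform(0, 1) across seeds. The hypergeometric
p-value is discrete; its null distribution approaches uniformity only when
the p-value step (the maximal pmf value) is small against the resolution of
the calibration test and the attainable p-grid varies between replicates.
The configuration therefore uses a 12,000-gene genome, a term carried
independently per gene at probability 0.5 (so the carrier count varies seed
to seed), and a uniformly drawn 2,000-gene list, giving a step near 0.02
against a Kolmogorov–Smirnov resolution of about 0.07 at 500 replicates.
Smaller designs are measurably super-uniform — a property of discrete
p-values, not an implementation error.

*Expression fixture* — 24 conditions at a baseline of 50 normalized counts,
library depths uniform in [0.8, 1.25] million. Fifty DE genes get a 4-fold
multiplier in one condition each (round-robin); one 20-gene module shares a
per-condition latent log2 profile with loading a = σ·√(ρ/(1−ρ)) against
independent log-noise of sd σ = 0.5, so the latent pairwise correlation is
ρ = 0.9; counts are Poisson at the per-gene mean times depth. Twenty-four
conditions is a realistic compendium size and is what makes module recovery
identifiable: with far fewer conditions the maximal spurious correlation
among ~2,000 background genes approaches the weakest within-module
correlation. What passing these tests shows is that the pipeline recovers
the signals its model assumes — Poisson counts, log-linear modules; real
RNA-seq adds overdispersion, correlated library artifacts, and non-modular
covariation that these fixtures deliberately do not emulate, so measured
power here is an upper bound on real-data behaviour.

*BLAST fixture* — true pairs are mutual best hits (default full coverage,
sequence length 300 so coverages like 0.74/0.75 are exactly representable),
each shadowed by a weaker secondary hit so best-hit selection is exercised;
low-coverage decoys survive reciprocity but not the coverage filter;
one-way decoys and above-threshold hits exercise mutuality and the E-value
cutoff. The generator writes real outfmt-6(+qlen,slen) files and a truth
table; every truth pair appears in the files.

All generators are pure functions of their spec including the seed.

## Numerical choices and degenerate inputs

- Hypergeometric and Poisson tails go through scipy survival/cdf functions;
  the test suite checks them against exhaustive enumeration (all C(N, n)
  lists, N ≤ 12, agreement to 1e-12) and direct pmf summation (λ ≤ 50,
  x ≤ 200, to 1e-10) respectively.
- k = 0 returns p = 1 exactly; results are clipped to [0, 1].
- Tie-breaks everywhere are lexicographic on stable keys (term key, gene
  id, subject id) so every ranking is deterministic under input permutation.
- Genes with λ = 0 are skipped by DE calling; empty stores, empty hit
  files and empty maps flow through as empty results, not errors; malformed
  rows raise errors naming the file and line.
- Store dumps preserve universe-only genes via sentinel rows, so
  write → read is exact set equality including the background.

## Problem sizes in the verification suite

The acceptance checks run at the generators' default sizes: 500 seeds for
null calibration, 200 for planted-term recovery, 100 each for DE power /
false-call rate and module recovery, 100 random DAGs (≤ 200 nodes) for
closure agreement, and the full N ≤ 12 enumeration for the hypergeometric
oracle. The whole suite completes in about two minutes on one CPU.

## Known limitations

- The Poisson DE rule ignores biological overdispersion and replicate
  structure; it is a per-condition screening rule, not an inferential model
  comparable to negative-binomial methods.
- Annotation transfer assumes functional equivalence of best/reciprocal
  hits; paralogy and domain-level similarity can transfer wrong labels at
  permissive thresholds.
- The enrichment test treats genes as exchangeable; gene length, GC or
  expression-level ascertainment biases are not modeled.
- Keyword search is a plain case-insensitive substring match over term
  names — no stemming or synonym handling.
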