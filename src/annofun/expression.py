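"""Expression-matrix handling: normalization, Poisson differential-expression
calling, condition pseudo-term stores, and coexpression nearest-neighbor
search.

Counts are first normalized per condition for sequencing depth (counts per
million uniquely mapped reads by default). A gene is called differentially
expressed in a condition when its normalized value shows more than a
``fold_threshold``-fold change relative to its average expression across all
conditions *and* the Poisson cumulative probability of a value at least (over)
or at most (under) as extreme, at rate equal to that average, is below
``alpha``. Over/under calls become pseudo-terms ("over-expressed in c",
"under-expressed in c") so that condition enrichment reuses the ordinary
term-enrichment machinery unchanged.

Coexpression search ranks genes by correlation distance 1 - Pearson(u, v)
on one of three representations of the matrix: absolute (normalized) counts,
log counts, or log ratios to the gene's mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .store import AnnotationStore, Association, GeneId

logger = logging.getLogger(__name__)

RAW = "raw"
NORMALIZED = "normalized"
LOG = "log"
LOGRATIO = "logratio"

CONDITION_SOURCE = "condition"


class ExpressionMatrix:
    """A gene x condition matrix of expression values with a scale tag.

    ``scale`` tracks what the values mean: raw counts, depth-normalized
    counts, log2 counts, or log2 ratios to the gene mean. Raw and normalized
    values must be non-negative; condition labels must be unique.
    """

    def __init__(
        self,
        genes: Sequence[GeneId],
        conditions: Sequence[str],
        values: np.ndarray,
        scale: str = RAW,
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(genes), len(conditions)):
            raise ValueError(
                f"values shape {values.shape} != ({len(genes)}, {len(conditions)})"
            )
        if len(set(conditions)) != len(conditions):
            raise ValueError("condition labels must be unique")
        if len(set(genes)) != len(genes):
            raise ValueError("gene ids must be unique")
        if scale in (RAW, NORMALIZED) and (values < 0).any():
            raise ValueError(f"negative entries invalid on scale {scale!r}")
        self.genes: list[GeneId] = list(genes)
        self.conditions: list[str] = list(conditions)
        self.values = values
        self.scale = scale
        self._row = {g: i for i, g in enumerate(self.genes)}

    def __contains__(self, gene: GeneId) -> bool:
        return gene in self._row

    def row(self, gene: GeneId) -> np.ndarray:
        try:
            return self.values[self._row[gene]]
        except KeyError:
            raise KeyError(f"gene {gene} not in matrix") from None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=[g.value for g in self.genes],
            columns=self.conditions,
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, namespace: str, scale: str = RAW
    ) -> "ExpressionMatrix":
        genes = [GeneId(str(i), namespace) for i in df.index]
        return cls(genes, [str(c) for c in df.columns], df.to_numpy(float), scale)


def read_matrix(path: str | Path, namespace: str = "default") -> ExpressionMatrix:
    """Read a count matrix: TSV with gene ids in the first column and a
    header row of condition labels."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return ExpressionMatrix.from_frame(df, namespace, scale=RAW)


def read_library_sizes(path: str | Path) -> dict[str, float]:
    """Two-column TSV: condition label, uniquely mapped read count."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["condition", "reads"], comment="#"
    )
    return dict(zip(df["condition"].astype(str), df["reads"].astype(float)))


def normalize_counts(
    raw: ExpressionMatrix,
    library_sizes: Mapping[str, float],
    target: float = 1e6,
) -> ExpressionMatrix:
    """Scale each condition's counts to a common depth of ``target`` uniquely
    mapped reads (counts per million by default)."""
    if raw.scale != RAW:
        raise ValueError(f"expected raw counts, got scale {raw.scale!r}")
    factors = np.empty(len(raw.conditions))
    for j, c in enumerate(raw.conditions):
        try:
            lib = float(library_sizes[c])
        except KeyError:
            raise ValueError(f"no library size for condition {c!r}") from None
        if lib <= 0:
            raise ValueError(f"library size for {c!r} must be positive, got {lib}")
        factors[j] = target / lib
    return ExpressionMatrix(
        raw.genes, raw.conditions, raw.values * factors, scale=NORMALIZED
    )


@dataclass(frozen=True, slots=True)
class DifferentialCall:
    """One significant expression change of a gene in one condition.

    ``fold_change`` is the ratio of the condition value to the gene's mean
    across all conditions (> threshold for over-calls, < 1/threshold for
    under-calls); ``p_value`` is the Poisson tail probability at that mean.
    """

    gene: GeneId
    condition: str
    direction: str  # "over" | "under"
    fold_change: float
    p_value: float


def poisson_upper_tail(x: float, lam: float) -> float:
    """P(X >= ceil(x)) for X ~ Poisson(lam); the over-expression tail.
    Non-integer values are rounded up, which is the conservative direction."""
    if lam < 0:
        raise ValueError("rate must be non-negative")
    k = math.ceil(x)
    if k <= 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def poisson_lower_tail(x: float, lam: float) -> float:
    """P(X <= floor(x)) for X ~ Poisson(lam); the under-expression tail."""
    if lam < 0:
        raise ValueError("rate must be non-negative")
    return float(stats.poisson.cdf(math.floor(x), lam))


def call_differential(
    m: ExpressionMatrix,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
) -> list[DifferentialCall]:
    """Call per-condition over-/under-expression on a normalized matrix.

    For each gene with positive cross-condition mean lam and each condition
    with value x: over iff x/lam > fold_threshold and P(X >= ceil(x)) < alpha;
    under iff x/lam < 1/fold_threshold and P(X <= floor(x)) < alpha, both
    tails at rate lam. Genes with lam = 0 are skipped. No multiple-testing
    correction is applied (the fixed-alpha rule); calls are sorted by gene
    then condition.
    """
    if m.scale != NORMALIZED:
        raise ValueError(f"expected normalized counts, got scale {m.scale!r}")
    if len(m.conditions) < 2:
        raise ValueError("need at least 2 conditions")
    lam = m.values.mean(axis=1)
    active = lam > 0
    x = m.values
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.divide(
            x, lam[:, None], out=np.zeros_like(x), where=lam[:, None] > 0
        )
    over_gate = active[:, None] & (fold > fold_threshold)
    under_gate = active[:, None] & (fold < 1.0 / fold_threshold)
    # Poisson tails only where the fold gate passes (vectorized)
    p_over = np.ones_like(x)
    p_under = np.ones_like(x)
    if over_gate.any():
        rows, cols = np.nonzero(over_gate)
        k = np.ceil(x[rows, cols])
        p_over[rows, cols] = stats.poisson.sf(k - 1, lam[rows])
    if under_gate.any():
        rows, cols = np.nonzero(under_gate)
        p_under[rows, cols] = stats.poisson.cdf(np.floor(x[rows, cols]), lam[rows])
    calls: list[DifferentialCall] = []
    for i, j in zip(*np.nonzero(over_gate & (p_over < alpha))):
        calls.append(
            DifferentialCall(
                m.genes[i], m.conditions[j], "over", float(fold[i, j]), float(p_over[i, j])
            )
        )
    for i, j in zip(*np.nonzero(under_gate & (p_under < alpha))):
        calls.append(
            DifferentialCall(
                m.genes[i],
                m.conditions[j],
                "under",
                float(fold[i, j]),
                float(p_under[i, j]),
            )
        )
    calls.sort(key=lambda c: (c.gene.value, c.condition, c.direction))
    return calls


def build_condition_store(
    calls: Iterable[DifferentialCall], universe: Iterable[GeneId]
) -> AnnotationStore:
    """Turn differential calls into an annotation store with pseudo-terms
    ``over:<condition>`` / ``under:<condition>`` under source "condition",
    directly consumable by the enrichment module."""
    store = AnnotationStore()
    for g in universe:
        store.add_gene(g)
    for c in calls:
        term_id = f"{c.direction}:{c.condition}"
        store.add(
            Association(c.gene, CONDITION_SOURCE, term_id, "direct"),
            term_name=f"{c.direction}-expressed in {c.condition}",
        )
    return store


def variance_filter(m: ExpressionMatrix, quantile: float = 0.25) -> ExpressionMatrix:
    """Drop low-variance genes: those whose cross-condition variance falls
    below the given quantile of the per-gene variance distribution.

    Variance is always ranked on the log2(x + 1) representation for raw or
    normalized input (variance there is much less dominated by expression
    level); log-scale input is ranked as-is. Constant rows are always dropped
    for any quantile > 0. Row order is preserved.
    """
    if not (0 <= quantile < 1):
        raise ValueError("quantile must be in [0, 1)")
    if quantile == 0:
        return m
    vals = m.values
    if m.scale in (RAW, NORMALIZED):
        vals = np.log2(vals + 1.0)
    var = vals.var(axis=1)
    threshold = float(np.quantile(var, quantile))
    keep = (var >= threshold) & (var > 0)
    idx = np.nonzero(keep)[0]
    return ExpressionMatrix(
        [m.genes[i] for i in idx], m.conditions, m.values[idx], scale=m.scale
    )


def transform(
    m: ExpressionMatrix, mode: str = "log", pseudocount: float = 1.0
) -> ExpressionMatrix:
    """One of the three representations used for similarity search:
    ``absolute`` (identity), ``log`` (log2(x + pseudocount)) or ``logratio``
    (log2 of x over the gene's cross-condition mean, both pseudocounted)."""
    if m.scale != NORMALIZED:
        raise ValueError(f"expected normalized counts, got scale {m.scale!r}")
    if mode == "absolute":
        return ExpressionMatrix(m.genes, m.conditions, m.values.copy(), NORMALIZED)
    if pseudocount <= 0 and (m.values == 0).any():
        raise ValueError("non-positive pseudocount with zero counts")
    if mode == "log":
        return ExpressionMatrix(
            m.genes, m.conditions, np.log2(m.values + pseudocount), LOG
        )
    if mode == "logratio":
        lam = m.values.mean(axis=1, keepdims=True)
        return ExpressionMatrix(
            m.genes,
            m.conditions,
            np.log2((m.values + pseudocount) / (lam + pseudocount)),
            LOGRATIO,
        )
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True, slots=True)
class SimilarityResult:
    """Nearest neighbors of a query gene under correlation distance, sorted
    by non-decreasing distance (query excluded)."""

    query: GeneId
    neighbors: tuple[tuple[GeneId, float], ...]
    representation: str


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson(u, v): 0 for identical shape, 2 for exact anti-correlation.
    Undefined (raises) when either vector is constant."""
    su, sv = np.std(u), np.std(v)
    if su == 0 or sv == 0:
        raise ValueError("correlation undefined for a constant profile")
    r = float(np.corrcoef(u, v)[0, 1])
    return 1.0 - r


def nearest_neighbors(
    gene: GeneId,
    m: ExpressionMatrix,
    k: int = 100,
    max_distance: float | None = None,
) -> SimilarityResult:
    """The k genes with expression profiles most similar to the query under
    correlation distance, ascending, ties broken by gene id. Genes whose
    profile is constant (correlation undefined) are excluded from the
    candidate set; a constant query is an error. ``max_distance`` optionally
    caps the neighbor distance."""
    q = m.row(gene)
    if np.std(q) == 0:
        raise ValueError(f"correlation undefined: query {gene} has zero variance")
    vals = m.values
    sd = vals.std(axis=1)
    ok = sd > 0
    centered = vals - vals.mean(axis=1, keepdims=True)
    qc = q - q.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = centered @ qc / (np.sqrt((centered**2).sum(axis=1)) * np.sqrt((qc**2).sum()))
    dist = 1.0 - r
    order = []
    for i in np.nonzero(ok)[0]:
        g = m.genes[i]
        if g == gene:
            continue
        d = float(dist[i])
        if max_distance is not None and d > max_distance:
            continue
        order.append((d, g.value, g))
    order.sort(key=lambda t: (t[0], t[1]))
    rep = {NORMALIZED: "absolute", LOG: "log", LOGRATIO: "logratio"}.get(
        m.scale, m.scale
    )
    return SimilarityResult(
        query=gene,
        neighbors=tuple((g, d) for d, _, g in order[:k]),
        representation=rep,
    )
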