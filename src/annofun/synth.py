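"""Synthetic fixture generators.

Everything in the package is testable without downloads: these generators
fabricate annotation stores with planted enriched terms, count matrices with
planted differentially expressed genes and coexpression modules, and paired
tabular BLAST files with a known true ortholog pairing. Each generator is a
pure function of its :class:`FixtureSpec` (same seed, same fixture).

Default study conditions: a genome of 2,000 genes annotated by 50 background
terms at 5% frequency; an expression compendium of 24 conditions with a
baseline of 50 normalized counts per gene, differential genes at a 4-fold
multiplier in one condition each, and coexpression modules of 20 genes with
within-module correlation 0.9 on the log2 scale (log-noise sd 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .store import AnnotationStore, Association, GeneId

NAMESPACE = "synth"
BLAST_NS_A = "nsA"
BLAST_NS_B = "nsB"


def null_calibration_spec(seed: int) -> "FixtureSpec":
    """Study conditions for checking that the enrichment p-value of an
    unenriched term is approximately Uniform(0, 1).

    A hypergeometric p-value is discrete; its null distribution only
    approaches uniformity when many values of k are attainable (the p-value
    step, the maximal pmf value, must be small against the resolution of the
    calibration test) and the carrier count varies between replicates.
    Hence: a 12,000-gene genome, a term carried independently by each gene
    with probability 0.5, and a uniformly drawn list of 2,000 genes.
    Background terms are kept to ten — they play no role in the
    calibration."""
    return FixtureSpec(
        n_genes=12000,
        n_terms=10,
        planted_terms=(
            PlantedTerm(frequency=0.5, list_size=2000, fraction=None, exact=False),
        ),
        seed=seed,
    )


@dataclass(frozen=True, slots=True)
class PlantedTerm:
    """A term planted into the annotation fixture.

    ``frequency`` is its carrier fraction in the background; ``fraction`` is
    the fraction of the planted gene list that carries it (None draws the
    list uniformly from all genes — the null configuration). With
    ``exact=True`` the carrier count is exactly ``round(frequency*n_genes)``
    (so a planted list fraction is always feasible); with ``exact=False``
    each gene carries the term independently with probability ``frequency``,
    which is the natural null model for calibration studies."""

    term_id: str = "planted00"
    frequency: float = 0.01
    list_size: int = 20
    fraction: float | None = 1.0
    exact: bool = True


@dataclass(frozen=True, slots=True)
class PlantedModule:
    """A coexpression module: ``size`` genes sharing a latent log2 profile
    with pairwise correlation ``correlation`` against log-noise of sd
    ``noise_sd``."""

    size: int = 20
    correlation: float = 0.9
    noise_sd: float = 0.5


@dataclass(frozen=True, slots=True)
class FixtureSpec:
    """All the knobs of the generators in one immutable record."""

    n_genes: int = 2000
    n_terms: int = 50
    n_conditions: int = 24
    background_rate: float = 0.05
    planted_terms: tuple[PlantedTerm, ...] = (PlantedTerm(),)
    planted_modules: tuple[PlantedModule, ...] = (PlantedModule(),)
    # expression
    baseline: float = 50.0
    n_de_genes: int = 50
    de_multiplier: float = 4.0
    # blast
    n_pairs: int = 20
    pair_coverages: tuple[float, ...] | None = None
    n_one_way_decoys: int = 3
    lowcov_decoy_coverages: tuple[float, ...] = (0.6,)
    seq_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for pt in self.planted_terms:
            if pt.fraction is not None and not (0 < pt.fraction <= 1):
                raise ValueError("planted fraction must be in (0, 1]")
            if not (0 < pt.frequency < 1) or pt.list_size < 1:
                raise ValueError("invalid planted term spec")
        for pm in self.planted_modules:
            if pm.size < 1 or not (0 < pm.correlation < 1) or pm.noise_sd <= 0:
                raise ValueError("invalid planted module spec")
        if self.n_genes < 1 or self.n_terms < 0 or self.n_conditions < 2:
            raise ValueError("invalid fixture dimensions")


def _genes(n: int) -> list[GeneId]:
    return [GeneId(f"g{i:05d}", NAMESPACE) for i in range(n)]


# -- annotation fixture ------------------------------------------------


def synth_annotation_fixture(
    spec: FixtureSpec,
) -> tuple[AnnotationStore, list[GeneId]]:
    """Build an annotation store with uniform background term assignment and
    a gene list enriched for the (first) planted term.

    Background terms annotate each gene independently at
    ``spec.background_rate``. Each planted term gets carriers per its
    ``frequency`` (an exact count, or a per-gene Bernoulli draw when
    ``exact=False``). The returned list has
    ``list_size`` genes of which ``round(fraction * list_size)`` are carriers
    of the first planted term; with ``fraction=None`` the list is drawn
    uniformly from the genome (no planting — the null case).
    """
    rng = np.random.default_rng(spec.seed)
    genes = _genes(spec.n_genes)
    store = AnnotationStore()
    for g in genes:
        store.add_gene(g)
    for j in range(spec.n_terms):
        mask = rng.random(spec.n_genes) < spec.background_rate
        tid = f"t{j:03d}"
        for i in np.nonzero(mask)[0]:
            store.add(
                Association(genes[i], "synthdb", tid),
                term_name=f"background pathway {j:03d}",
            )
    carrier_idx: dict[str, np.ndarray] = {}
    for pt in spec.planted_terms:
        if pt.exact:
            n_car = max(1, round(pt.frequency * spec.n_genes))
            idx = rng.choice(spec.n_genes, size=n_car, replace=False)
        else:
            idx = np.nonzero(rng.random(spec.n_genes) < pt.frequency)[0]
        carrier_idx[pt.term_id] = idx
        for i in idx:
            store.add(
                Association(genes[i], "synthdb", pt.term_id),
                term_name=f"planted pathway {pt.term_id}",
            )
    pt = spec.planted_terms[0]
    if pt.fraction is None:
        chosen = rng.choice(spec.n_genes, size=pt.list_size, replace=False)
    else:
        idx = carrier_idx[pt.term_id]
        n_hit = round(pt.fraction * pt.list_size)
        if n_hit > len(idx):
            raise ValueError(
                f"planted term {pt.term_id!r} has {len(idx)} carriers but the "
                f"list needs {n_hit}; raise frequency or shrink the list"
            )
        hits = rng.choice(idx, size=n_hit, replace=False)
        non_carriers = np.setdiff1d(np.arange(spec.n_genes), idx)
        rest = rng.choice(non_carriers, size=pt.list_size - n_hit, replace=False)
        chosen = np.concatenate([hits, rest])
    gene_list = [genes[i] for i in chosen]
    return store, gene_list


# -- expression fixture ------------------------------------------------


def synth_expression_fixture(
    spec: FixtureSpec,
) -> tuple[ExpressionMatrix, dict[str, float], dict[str, pd.DataFrame]]:
    """Build a raw count matrix with planted coexpression modules and planted
    differentially expressed genes, plus library sizes and truth tables.

    Gene means: module genes follow ``2**(log2(baseline) + a*z_c + sd*eps)``
    with a shared per-condition latent profile ``z`` and loading
    ``a = sd*sqrt(rho/(1-rho))`` (so the latent pairwise log-correlation is
    rho); DE genes sit at baseline except a ``de_multiplier``-fold bump in
    one designated condition; the rest are flat at baseline. Counts are
    Poisson at mean scaled by each condition's library depth.

    Returns ``(raw matrix, library sizes, truth)`` where ``truth`` has a
    "de" table (gene, condition, multiplier) and a "modules" table
    (gene, module).
    """
    rng = np.random.default_rng(spec.seed)
    genes = _genes(spec.n_genes)
    conditions = [f"c{j:02d}" for j in range(spec.n_conditions)]
    mean = np.full((spec.n_genes, spec.n_conditions), spec.baseline, dtype=float)

    modules_rows = []
    row = 0
    for mod_idx, pm in enumerate(spec.planted_modules):
        z = rng.standard_normal(spec.n_conditions)
        a = pm.noise_sd * np.sqrt(pm.correlation / (1.0 - pm.correlation))
        for _ in range(pm.size):
            eps = rng.standard_normal(spec.n_conditions)
            level = np.log2(spec.baseline) + a * z + pm.noise_sd * eps
            mean[row] = np.power(2.0, level)
            modules_rows.append((genes[row].value, mod_idx))
            row += 1
    de_rows = []
    for d in range(spec.n_de_genes):
        cond = d % spec.n_conditions
        mean[row, cond] *= spec.de_multiplier
        de_rows.append((genes[row].value, conditions[cond], spec.de_multiplier))
        row += 1
    if row > spec.n_genes:
        raise ValueError("planted genes exceed n_genes")

    libs = rng.uniform(0.8e6, 1.25e6, size=spec.n_conditions)
    counts = rng.poisson(mean * (libs / 1e6)[None, :]).astype(float)
    matrix = ExpressionMatrix(genes, conditions, counts, scale="raw")
    truth = {
        "de": pd.DataFrame(de_rows, columns=["gene", "condition", "multiplier"]),
        "modules": pd.DataFrame(modules_rows, columns=["gene", "module"]),
    }
    return matrix, dict(zip(conditions, libs)), truth


# -- blast fixture -----------------------------------------------------


def _blast_row(
    q: str, s: str, evalue: float, bitscore: float, cov: float, length: int
) -> str:
    span = round(cov * length)
    fields = [
        q,
        s,
        "98.50",
        str(span),
        "3",
        "0",
        "1",
        str(span),
        "1",
        str(span),
        f"{evalue:.2e}",
        f"{bitscore:.1f}",
        str(length),
        str(length),
    ]
    return "\t".join(fields)


def synth_blast_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, Path, pd.DataFrame]:
    """Write a pair of tabular BLAST files (A->B and B->A) with a known true
    pairing and decoys, returning their paths and the truth table.

    True pairs ``a_i ~ b_i`` are mutual best hits at the requested coverage
    (default full), each shadowed by a weaker secondary hit so best-hit
    selection is exercised. Low-coverage decoy pairs are mutual best hits at
    the listed coverages (they survive reciprocity but not the coverage
    filter); one-way decoys hit an already-taken partner in one direction
    only. Truth columns: a, b, coverage, is_true, expect_kept (whether the
    pair should survive reciprocity plus a 75% coverage filter).
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    L = spec.seq_length
    ab_rows: list[str] = []
    ba_rows: list[str] = []
    records = []

    covs = spec.pair_coverages
    if covs is not None and len(covs) != spec.n_pairs:
        raise ValueError("pair_coverages length must equal n_pairs")
    n_total = spec.n_pairs + len(spec.lowcov_decoy_coverages)
    for i in range(n_total):
        if i < spec.n_pairs:
            cov = 1.0 if covs is None else covs[i]
            is_true = True
        else:
            cov = spec.lowcov_decoy_coverages[i - spec.n_pairs]
            is_true = False
        a, b = f"a{i:04d}", f"b{i:04d}"
        e_best = 10.0 ** rng.uniform(-80, -40)
        ab_rows.append(_blast_row(a, b, e_best, 500.0, cov, L))
        ba_rows.append(_blast_row(b, a, e_best, 500.0, cov, L))
        # weaker secondary hit to the next subject over
        other = f"b{(i + 1) % n_total:04d}"
        ab_rows.append(_blast_row(a, other, 1e-8, 80.0, 0.5, L))
        records.append(
            {
                "a": a,
                "b": b,
                "coverage": cov,
                "is_true": is_true,
                "expect_kept": cov == 1.0 or cov >= 0.75,
            }
        )
    for d in range(spec.n_one_way_decoys):
        # hits b0000 (whose best is a0000) in one direction only
        ab_rows.append(_blast_row(f"ax{d:03d}", "b0000", 1e-30, 200.0, 1.0, L))
    # above-threshold hit: must be ignored entirely by best_hits
    ab_rows.append(_blast_row("aweak", "b0001", 1e-4, 40.0, 1.0, L))

    rng.shuffle(ab_rows)
    rng.shuffle(ba_rows)
    path_ab = out_dir / "a_vs_b.blast.tsv"
    path_ba = out_dir / "b_vs_a.blast.tsv"
    path_ab.write_text("\n".join(ab_rows) + "\n", encoding="utf-8")
    path_ba.write_text("\n".join(ba_rows) + "\n", encoding="utf-8")
    truth = pd.DataFrame.from_records(records)
    return path_ab, path_ba, truth
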