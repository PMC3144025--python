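"""Normalization, Poisson DE calling, condition store, similarity search."""

import numpy as np
import pytest

from annofun import (
    ExpressionMatrix,
    GeneId,
    build_condition_store,
    call_differential,
    correlation_distance,
    enrich,
    nearest_neighbors,
    normalize_counts,
    transform,
    variance_filter,
)
from annofun.expression import poisson_lower_tail, poisson_upper_tail

from conftest import gid
from oracles import (
    poisson_lower_tail_by_summation,
    poisson_upper_tail_by_summation,
)


def matrix(values, scale="normalized", ns="ns1", conditions=None):
    values = np.asarray(values, dtype=float)
    genes = [GeneId(f"g{i}", ns) for i in range(values.shape[0])]
    conds = conditions or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, conds, values, scale=scale)


class TestNormalize:
    def test_counts_per_million(self):
        raw = matrix([[10.0, 10.0]], scale="raw")
        m = normalize_counts(raw, {"c0": 1e6, "c1": 2e6})
        assert m.values.tolist() == [[10.0, 5.0]]
        assert m.scale == "normalized"

    def test_equal_libraries_one_common_factor(self):
        raw = matrix([[4.0, 8.0], [2.0, 6.0]], scale="raw")
        m = normalize_counts(raw, {"c0": 2e6, "c1": 2e6})
        assert np.allclose(m.values, np.asarray([[4, 8], [2, 6]]) * 0.5)

    def test_bad_library_sizes_rejected(self):
        raw = matrix([[1.0, 1.0]], scale="raw")
        with pytest.raises(ValueError):
            normalize_counts(raw, {"c0": 0.0, "c1": 1e6})
        with pytest.raises(ValueError):
            normalize_counts(raw, {"c0": 1e6})  # missing c1


class TestPoissonTails:
    def test_matches_pmf_summation_oracle(self, rng):
        for _ in range(150):
            lam = float(rng.uniform(0.1, 50))
            k = int(rng.integers(0, 200))
            assert poisson_upper_tail(k, lam) == pytest.approx(
                poisson_upper_tail_by_summation(k, lam), abs=1e-10
            )
            assert poisson_lower_tail(k, lam) == pytest.approx(
                poisson_lower_tail_by_summation(k, lam), abs=1e-10
            )

    def test_over_call_example(self):
        # lambda=10, x=25: fold 2.5 and upper tail well below alpha
        p = poisson_upper_tail(25, 10.0)
        assert p == pytest.approx(poisson_upper_tail_by_summation(25, 10.0), abs=1e-10)
        assert p < 1e-4

    def test_boundary_case_just_misses_alpha(self):
        # lambda=2, x=5: fold 2.5 passes the gate but p ~ 0.0527 > 0.05
        p = poisson_upper_tail(5, 2.0)
        assert p == pytest.approx(1 - np.exp(-2) * 7, abs=1e-12)
        assert p > 0.05


class TestCallDifferential:
    def test_clear_over_call(self):
        # one condition at 25 vs mean 10 in a flat background
        vals = [[10.0] * 9 + [25.0]] # mean 11.5, fold 2.17
        calls = call_differential(matrix(vals))
        assert [(c.condition, c.direction) for c in calls] == [("c9", "over")]

    def test_no_call_without_fold_change(self):
        vals = [[10.0, 10.0, 10.0]]
        assert call_differential(matrix(vals)) == []

    def test_boundary_poisson_case_not_called(self):
        # per-condition value 5 vs mean 2: fold 2.5 but p = 0.0527 > alpha
        vals = [[1.0, 1.0, 1.0, 5.0]]  # mean exactly 2
        assert call_differential(matrix(vals)) == []

    def test_under_call(self):
        vals = [[50.0] * 7 + [10.0]]  # mean 45, fold 0.22, P(X<=10|45) tiny
        calls = call_differential(matrix(vals))
        assert [(c.condition, c.direction) for c in calls] == [("c7", "under")]

    def test_zero_mean_genes_skipped_and_raw_rejected(self):
        assert call_differential(matrix([[0.0, 0.0]])) == []
        with pytest.raises(ValueError):
            call_differential(matrix([[1.0, 2.0]], scale="raw"))

    def test_calls_respect_gates_on_random_matrices(self, rng):
        vals = rng.poisson(20, size=(60, 8)).astype(float)
        m = matrix(vals)
        for c in call_differential(m):
            assert c.p_value < 0.05
            if c.direction == "over":
                assert c.fold_change > 2.0
            else:
                assert c.fold_change < 0.5


class TestConditionStore:
    def test_pseudo_terms_feed_enrichment(self):
        vals = [[10.0] * 7 + [40.0], [10.0] * 8, [10.0] * 8]
        m = matrix(vals)
        calls = call_differential(m)
        store = build_condition_store(calls, m.genes)
        assert store.genes_with_term("condition", "over:c7") == {gid("g0")}
        results = enrich([gid("g0")], store, sources=["condition"])
        assert results[0].term.id == "over:c7"

    def test_no_calls_empty_store_with_universe(self):
        store = build_condition_store([], [gid("g0"), gid("g1")])
        assert len(store) == 0
        assert len(store.universe("ns1")) == 2


class TestVarianceFilter:
    def test_quantile_zero_is_identity(self):
        m = matrix(np.ones((3, 4)))
        assert variance_filter(m, 0.0) is m

    def test_constant_row_always_dropped(self):
        vals = np.vstack([[5.0, 5.0, 5.0], [1.0, 9.0, 30.0]])
        out = variance_filter(matrix(vals), 0.25)
        assert [g.value for g in out.genes] == ["g1"]

    def test_lowest_variance_gene_dropped_at_quartile(self):
        vals = np.array(
            [
                [10, 10, 11, 10],
                [10, 30, 5, 60],
                [10, 14, 8, 12],
                [1, 90, 4, 30],
            ],
            dtype=float,
        )
        out = variance_filter(matrix(vals), 0.25)
        assert [g.value for g in out.genes] == ["g1", "g2", "g3"]


class TestTransform:
    def test_absolute_is_identity(self):
        m = matrix([[3.0, 5.0]])
        out = transform(m, "absolute")
        assert np.array_equal(out.values, m.values)

    def test_log_with_unit_pseudocount(self):
        out = transform(matrix([[1.0, 3.0]]), "log")
        assert out.values.tolist() == [[1.0, 2.0]]

    def test_constant_row_logratio_is_zero(self):
        out = transform(matrix([[7.0, 7.0, 7.0]]), "logratio")
        assert np.allclose(out.values, 0.0)

    def test_bad_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            transform(matrix([[0.0, 1.0]]), "log", pseudocount=0.0)


class TestNearestNeighbors:
    def test_duplicate_profile_at_distance_zero(self):
        vals = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]]
        res = nearest_neighbors(gid("g0"), matrix(vals), k=2)
        assert res.neighbors[0][0] == gid("g1")
        assert res.neighbors[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profile_ranks_last_at_distance_two(self):
        vals = [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [1.0, 2.0, 2.9]]
        res = nearest_neighbors(gid("g0"), matrix(vals), k=5)
        assert res.neighbors[-1][0] == gid("g1")
        assert res.neighbors[-1][1] == pytest.approx(2.0, abs=1e-12)

    def test_affine_transform_invariance(self, rng):
        u = rng.normal(size=12)
        v = rng.normal(size=12)
        d = correlation_distance(u, v)
        assert correlation_distance(3.5 * u + 2.0, v) == pytest.approx(d, abs=1e-10)
        assert 0.0 <= d <= 2.0
        assert correlation_distance(u, u) == pytest.approx(0.0, abs=1e-12)

    def test_constant_query_rejected(self):
        vals = [[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]
        with pytest.raises(ValueError, match="correlation undefined"):
            nearest_neighbors(gid("g0"), matrix(vals))

    def test_deterministic_under_row_permutation(self, rng):
        vals = rng.uniform(1.0, 100.0, size=(30, 10))
        m = matrix(vals)
        ref = nearest_neighbors(gid("g3"), m, k=10)
        perm = rng.permutation(30)
        m2 = ExpressionMatrix(
            [m.genes[i] for i in perm], m.conditions, vals[perm], scale=m.scale
        )
        res = nearest_neighbors(gid("g3"), m2, k=10)
        assert [(g.value, round(d, 12)) for g, d in ref.neighbors] == [
            (g.value, round(d, 12)) for g, d in res.neighbors
        ]
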