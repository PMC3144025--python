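"""Best hits, reciprocal best hits, coverage filtering, transfer, conversion."""

import pytest

from annofun import (
    BlastHit,
    GeneId,
    IdMap,
    IdPair,
    apply_coverage_filter,
    best_hits,
    convert_gene_list,
    parse_blast_tabular,
    read_idmap,
    reciprocal_best_hits,
    transfer_annotations,
    transfer_by_best_hit,
    write_idmap,
)
from annofun.store import MalformedInputError

from conftest import make_store


def a(v):
    return GeneId(v, "A")


def b(v):
    return GeneId(v, "B")


def hit(q, s, evalue=1e-50, bitscore=500.0, qcov=1.0, scov=1.0):
    return BlastHit(a(q), b(s), evalue, bitscore, qcov, scov)


def rhit(q, s, evalue=1e-50, bitscore=500.0, qcov=1.0, scov=1.0):
    return BlastHit(b(q), a(s), evalue, bitscore, qcov, scov)


def row(q, s, qstart, qend, evalue, bitscore=100.0, qlen=None, slen=None):
    f = [q, s, "99.0", str(qend - qstart + 1), "0", "0", str(qstart), str(qend),
         "1", str(qend - qstart + 1), str(evalue), str(bitscore)]
    if qlen is not None:
        f += [str(qlen), str(slen)]
    return "\t".join(f)


class TestParseBlastTabular:
    def test_coverage_from_optional_length_columns(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            row("q1", "s1", 1, 100, 1e-30, qlen=100, slen=100) + "\n"
            + row("q2", "s2", 1, 75, 1e-30, qlen=100, slen=100) + "\n"
        )
        hits = parse_blast_tabular(p, "A", "B")
        assert hits[0].query_coverage == 1.0
        assert hits[1].query_coverage == 0.75

    def test_twelve_columns_coverage_unavailable(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(row("q1", "s1", 1, 100, 1e-30) + "\n")
        (h,) = parse_blast_tabular(p)
        assert h.query_coverage is None and h.subject_coverage is None

    def test_wrong_column_count_rejected_with_line(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\ts1\t99.0\t100\t0\t0\t1\t100\t1\t100\t1e-30\n")  # 11 cols
        with pytest.raises(MalformedInputError, match=":1"):
            parse_blast_tabular(p)

    def test_non_numeric_field_rejected_with_line(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(row("q1", "s1", 1, 100, 1e-30) + "\n")
        p.write_text(p.read_text() + row("q2", "s2", 1, 100, 1e-30).replace("1e-30", "oops") + "\n")
        with pytest.raises(MalformedInputError, match=":2"):
            parse_blast_tabular(p)


class TestBestHits:
    def test_smallest_evalue_wins(self):
        m = best_hits([hit("q", "s1", 1e-10), hit("q", "s2", 1e-3)])
        assert m[a("q")].subject == b("s1")

    def test_threshold_is_strict(self):
        assert best_hits([hit("q", "s", 1e-4)]) == {}
        assert best_hits([hit("q", "s", 1e-5)]) == {}  # < not <=
        assert a("q") in best_hits([hit("q", "s", 0.99e-5)])

    def test_tie_breaks_by_bitscore_then_subject_id(self):
        hits = [
            hit("q", "s2", 1e-20, bitscore=300),
            hit("q", "s1", 1e-20, bitscore=400),
            hit("q", "s0", 1e-20, bitscore=300),
        ]
        assert best_hits(hits)[a("q")].subject == b("s1")
        # equal bitscore: lexicographically smaller subject
        hits2 = [hit("q", "s2", 1e-20, 300), hit("q", "s0", 1e-20, 300)]
        assert best_hits(hits2)[a("q")].subject == b("s0")

    def test_invariant_under_input_permutation(self, rng):
        hits = [
            hit(f"q{i % 4}", f"s{j}", evalue=10.0 ** -(6 + (i * j) % 5),
                bitscore=100 + (i + j) % 3)
            for i in range(8)
            for j in range(5)
        ]
        ref = best_hits(hits)
        for _ in range(10):
            perm = [hits[i] for i in rng.permutation(len(hits))]
            assert best_hits(perm) == ref


class TestReciprocalBestHits:
    def test_mutual_pair_kept_one_way_rejected(self):
        ab = best_hits([hit("a1", "b1"), hit("a2", "b2")])
        ba = best_hits([rhit("b1", "a1"), rhit("b2", "a9")])
        idmap = reciprocal_best_hits(ab, ba)
        assert [(p.a.value, p.b.value) for p in idmap.pairs] == [("a1", "b1")]

    def test_empty_inputs_give_empty_map(self):
        assert len(reciprocal_best_hits({}, {})) == 0

    def test_symmetric_under_swap(self):
        ab = best_hits([hit("a1", "b1", qcov=0.8), hit("a2", "b2")])
        ba = best_hits([rhit("b1", "a1", qcov=0.9), rhit("b2", "a2")])
        fwd = reciprocal_best_hits(ab, ba)
        rev = reciprocal_best_hits(ba, ab)
        assert {(p.a.value, p.b.value, p.min_coverage) for p in fwd.pairs} == {
            (p.b.value, p.a.value, p.min_coverage) for p in rev.pairs
        }

    def test_partial_bijection_enforced(self):
        with pytest.raises(ValueError):
            IdMap("A", "B", [IdPair(a("a1"), b("b1"), 1.0, True),
                             IdPair(a("a1"), b("b2"), 1.0, True)])

    def test_pair_coverage_is_min_of_directions(self):
        ab = best_hits([hit("a1", "b1", qcov=0.8)])
        ba = best_hits([rhit("b1", "a1", qcov=1.0)])
        (p,) = reciprocal_best_hits(ab, ba).pairs
        assert p.min_coverage == 0.8 and not p.full_coverage


class TestCoverageFilter:
    @pytest.mark.parametrize(
        "cov,kept", [(1.0, True), (0.75, True), (0.74, False), (0.6, False)]
    )
    def test_threshold_boundaries(self, cov, kept):
        idmap = IdMap(
            "A", "B", [IdPair(a("a1"), b("b1"), cov, cov == 1.0, 1e-50)]
        )
        out = apply_coverage_filter(idmap)
        assert (len(out) == 1) is kept

    def test_full_coverage_kept_even_below_threshold_setting(self):
        idmap = IdMap("A", "B", [IdPair(a("a1"), b("b1"), 1.0, True)])
        assert len(apply_coverage_filter(idmap, min_coverage=2.0)) == 1

    def test_missing_metadata_dropped_with_warning(self, caplog):
        idmap = IdMap("A", "B", [IdPair(a("a1"), b("b1"), None, False)])
        with caplog.at_level("WARNING"):
            out = apply_coverage_filter(idmap)
        assert len(out) == 0
        assert any("coverage" in r.message for r in caplog.records)


class TestTransfer:
    def make_map(self):
        return IdMap("A", "B", [IdPair(a("a1"), b("b1"), 1.0, True, 1e-42)])

    def test_direct_annotations_transfer_with_evalue(self):
        store = make_store([("a1", "kegg", "T1")], ns="A")
        out = transfer_annotations(store, self.make_map())
        recs = out.associations_of_gene(b("b1"))
        assert [(r.term_id, r.evidence, r.evalue) for r in recs] == [
            ("T1", "transferred", 1e-42)
        ]

    def test_unmapped_gene_contributes_nothing(self):
        store = make_store([("a2", "kegg", "T1")], ns="A")
        out = transfer_annotations(store, self.make_map())
        assert out == store

    def test_transferred_annotations_do_not_chain(self):
        store = make_store(
            [("a1", "kegg", "T1", "direct"), ("a1", "go", "T2", "transferred", 1e-9)],
            ns="A",
        )
        out = transfer_annotations(store, self.make_map())
        target = out.associations_of_gene(b("b1"))
        assert {r.term_id for r in target} == {"T1"}  # T2 not re-transferred

    def test_never_adds_direct_evidence_to_target(self):
        store = make_store([("a1", "kegg", "T1")], ns="A")
        out = transfer_annotations(store, self.make_map())
        assert all(
            r.evidence == "transferred"
            for r in out.associations
            if r.gene.namespace == "B"
        )
        assert store.associations <= out.associations  # source never decreases

    def test_best_hit_mode_transfers_without_reciprocity(self):
        # annotations live on the subject side; queries inherit them
        store = make_store([("b1", "kegg", "T1")], ns="B")
        best = best_hits([hit("a1", "b1", 1e-30)])
        out = transfer_by_best_hit(store, best)
        recs = out.associations_of_gene(a("a1"))
        assert [(r.term_id, r.evidence, r.evalue) for r in recs] == [
            ("T1", "transferred", 1e-30)
        ]


class TestConvertGeneList:
    def make_map(self):
        return IdMap(
            "A",
            "B",
            [
                IdPair(a("a1"), b("b1"), 1.0, True),
                IdPair(a("a2"), b("b2"), 1.0, True),
            ],
        )

    def test_order_preserving_with_unmapped_report(self):
        converted, unmapped = convert_gene_list(
            [a("a2"), a("a1"), a("a3")], self.make_map()
        )
        assert [g.value for g in converted] == ["b2", "b1"]
        assert [g.value for g in unmapped] == ["a3"]

    def test_duplicates_collapse(self):
        converted, unmapped = convert_gene_list(
            [a("a1"), a("a1"), a("a2")], self.make_map()
        )
        assert [g.value for g in converted] == ["b1", "b2"]

    def test_round_trip_is_identity_on_mapped_subset(self):
        m = self.make_map()
        fwd, _ = convert_gene_list([a("a1"), a("a2"), a("a3")], m)
        back, _ = convert_gene_list(fwd, m.invert())
        assert back == [a("a1"), a("a2")]

    def test_namespace_mismatch_rejected(self):
        with pytest.raises(ValueError):
            convert_gene_list([b("b1")], self.make_map())


def test_idmap_round_trips_through_tsv(tmp_path):
    idmap = IdMap(
        "jgi3",
        "au5",
        [
            IdPair(GeneId("a1", "jgi3"), GeneId("b1", "au5"), 1.0, True, 1e-42),
            IdPair(GeneId("a2", "jgi3"), GeneId("b2", "au5"), 0.8, False, None),
        ],
    )
    path = tmp_path / "map.tsv"
    write_idmap(idmap, path)
    assert read_idmap(path) == idmap
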