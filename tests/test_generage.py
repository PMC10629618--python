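import numpy as np
import pytest

from cggtools.fixtures import FixtureSpec, make_fixture
from cggtools.generage import (
    BinaryHitMatrix,
    build_matrix,
    cluster,
    detect_multidomain,
    symmetrify,
)
from cggtools.io import SequenceRecord, SimilarityEdge

from .conftest import random_protein


def edge(q, s, evalue=1e-20):
    return SimilarityEdge(q, s, 90.0, 50, 5, 0, 1, 50, 1, 50, evalue, 100.0)


def matrix_from_bool(ids, rows):
    hits = np.array(rows, dtype=bool)
    np.fill_diagonal(hits, True)
    return BinaryHitMatrix(list(ids), hits, np.zeros_like(hits, dtype=np.int8))


class TestBuildMatrix:
    def test_directed_cell_set_pre_validation(self):
        m = build_matrix([edge("A", "B")], ["A", "B"])
        assert m["A", "B"] and not m["B", "A"]

    def test_no_edges_gives_identity(self):
        m = build_matrix([], ["A", "B", "C"])
        assert np.array_equal(m.hits, np.eye(3, dtype=bool))

    def test_threshold_and_cell_count(self):
        edges = [edge("A", "B"), edge("B", "A"), edge("A", "C", evalue=1.0)]
        m = build_matrix(edges, ["A", "B", "C"], max_evalue=1e-5)
        assert m.hits.sum() == 3 + 2  # diagonal plus the two passing cells

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            build_matrix([edge("A", "Z")], ["A", "B"])


class TestSymmetrify:
    def test_symmetric_matrix_unchanged(self, blosum62, rng):
        records = [SequenceRecord(i, "", random_protein(rng, 40)) for i in "AB"]
        m = matrix_from_bool("AB", [[1, 1], [1, 1]])
        out = symmetrify(m, records, blosum62, n_shuffles=5, seed=0)
        assert np.array_equal(out.hits, m.hits)

    def test_identical_sequences_corrected_to_true(self, blosum62, rng):
        seq = random_protein(rng, 100)
        records = [SequenceRecord("A", "", seq), SequenceRecord("B", "", seq)]
        m = matrix_from_bool("AB", [[1, 1], [0, 1]])
        out = symmetrify(m, records, blosum62, n_shuffles=30, seed=1)
        assert out["A", "B"] and out["B", "A"]

    def test_unrelated_sequences_cleared(self, blosum62, rng):
        records = [SequenceRecord("A", "", random_protein(rng, 100)),
                   SequenceRecord("B", "", random_protein(rng, 100))]
        m = matrix_from_bool("AB", [[1, 1], [0, 1]])
        out = symmetrify(m, records, blosum62, n_shuffles=30, seed=1)
        assert not out["A", "B"] and not out["B", "A"]

    def test_idempotent_and_symmetric_on_random_matrices(self, blosum62, rng):
        for trial in range(10):
            n = int(rng.integers(3, 10))
            ids = [f"p{i}" for i in range(n)]
            records = [SequenceRecord(i, "", random_protein(rng, 30)) for i in ids]
            hits = rng.random((n, n)) < 0.3
            m = BinaryHitMatrix(ids, hits | np.eye(n, dtype=bool),
                                np.zeros((n, n), dtype=np.int8))
            once = symmetrify(m, records, blosum62, n_shuffles=10, seed=trial)
            assert once.is_symmetric()
            twice = symmetrify(once, records, blosum62, n_shuffles=10, seed=trial)
            assert np.array_equal(once.hits, twice.hits)

    def test_missing_sequence_for_asymmetric_pair(self, blosum62, rng):
        records = [SequenceRecord("A", "", random_protein(rng, 30))]
        m = matrix_from_bool("AB", [[1, 1], [0, 1]])
        with pytest.raises(KeyError):
            symmetrify(m, records, blosum62, n_shuffles=5)


class TestMultiDomain:
    def test_path_centre_called_with_witness(self):
        m = matrix_from_bool("ABC", [[1, 1, 0], [1, 1, 1], [0, 1, 1]])
        calls = detect_multidomain(m)
        assert len(calls) == 1
        assert calls[0].protein_id == "B"
        assert calls[0].witnesses == [("A", "C")]

    def test_triangle_has_no_calls(self):
        m = matrix_from_bool("ABC", np.ones((3, 3)))
        assert detect_multidomain(m) == []

    def test_asymmetric_matrix_rejected(self):
        hits = np.array([[1, 1], [0, 1]], dtype=bool)
        m = BinaryHitMatrix(["A", "B"], hits, np.zeros_like(hits, dtype=np.int8))
        with pytest.raises(ValueError):
            detect_multidomain(m)

    def test_fixture_composite_called(self, blosum62):
        from cggtools.align import all_vs_all

        records, _ = make_fixture(FixtureSpec(n_sequences=0, seed=21, fusion_trios=1))
        edges = all_vs_all(records, blosum62, min_score=100)
        m = build_matrix(edges, [r.id for r in records])
        m = symmetrify(m, records, blosum62, n_shuffles=20, seed=3)
        calls = detect_multidomain(m)
        assert [c.protein_id for c in calls] == ["FUS00C"]
        assert calls[0].witnesses == [("FUS00A", "FUS00B")]


class TestCluster:
    def test_triangle_single_family(self):
        m = matrix_from_bool("ABC", np.ones((3, 3)))
        fams = cluster(m, [])
        assert [(f[0], f[1]) for f in fams.families] == [(1, ["A", "B", "C"])]

    def test_path_centre_attached_to_both_families(self):
        m = matrix_from_bool("ABC", [[1, 1, 0], [1, 1, 1], [0, 1, 1]])
        calls = detect_multidomain(m)
        fams = cluster(m, calls)
        cores = sorted(core for _, core, _ in fams.families)
        assert cores == [["A"], ["C"]]
        for _, _, attached in fams.families:
            assert attached == ["B"]
        assert fams.multidomain == ["B"]

    def test_empty_off_diagonal_all_singletons(self):
        m = matrix_from_bool("ABCD", np.eye(4))
        fams = cluster(m, [])
        assert all(len(core) == 1 and not att for _, core, att in fams.families)

    def test_core_families_partition_non_multidomain(self, rng):
        n = 8
        ids = [f"p{i}" for i in range(n)]
        hits = rng.random((n, n)) < 0.3
        hits = hits | hits.T | np.eye(n, dtype=bool)
        m = BinaryHitMatrix(ids, hits, np.zeros((n, n), dtype=np.int8))
        calls = detect_multidomain(m)
        fams = cluster(m, calls)
        core_members = sorted(x for _, core, _ in fams.families for x in core)
        md = {c.protein_id for c in calls}
        assert core_members == sorted(set(ids) - md)
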