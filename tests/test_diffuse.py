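import pytest

from cggtools.diffuse import (
    RectHit,
    build_rect_matrix,
    detect_fusions,
    span_overlap_fraction,
    write_fusions,
)
from cggtools.fixtures import FixtureSpec, make_fixture
from cggtools.io import SequenceRecord, SimilarityEdge

from .conftest import random_protein


def edge(q, s, s_start, s_end, bitscore=300.0, evalue=1e-30):
    return SimilarityEdge(q, s, 95.0, s_end - s_start + 1, 2, 0,
                          1, s_end - s_start + 1, s_start, s_end, evalue, bitscore)


@pytest.fixture()
def trio():
    records, truth = make_fixture(FixtureSpec(n_sequences=0, seed=31, fusion_trios=1))
    by_id = {r.id: r for r in records}
    return by_id, truth


class TestOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, 100), (120, 220), 0.0),
            ((1, 100), (21, 120), 0.8),  # 80 shared / shorter span 100
            ((1, 100), (1, 100), 1.0),
            ((1, 10), (10, 30), 0.1),
            ((5, 8), (1, 100), 1.0),
        ],
    )
    def test_fraction_of_shorter_span(self, a, b, expected):
        assert span_overlap_fraction(a, b) == pytest.approx(expected)
        assert span_overlap_fraction(b, a) == pytest.approx(expected)


class TestRectMatrix:
    def test_planted_trio_cells_disjoint_spans(self, trio):
        by_id, truth = trio
        query = [by_id["FUS00A"], by_id["FUS00B"]]
        reference = [by_id["FUS00C"]]
        cells = build_rect_matrix(query, reference, min_score=100)
        assert set(cells) == {("FUS00A", "FUS00C"), ("FUS00B", "FUS00C")}
        a_hit = cells[("FUS00A", "FUS00C")]
        b_hit = cells[("FUS00B", "FUS00C")]
        assert span_overlap_fraction(
            (a_hit.start, a_hit.end), (b_hit.start, b_hit.end)
        ) <= 0.1

    def test_edges_below_threshold_excluded(self):
        q = [SequenceRecord("q0", "", "MKVL" * 10)]
        r = [SequenceRecord("r0", "", "MKVL" * 10)]
        cells = build_rect_matrix(q, r, edges=[edge("q0", "r0", 1, 40, bitscore=20.0)],
                                  min_score=50)
        assert cells == {}

    def test_best_hit_per_cell_kept(self):
        q = [SequenceRecord("q0", "", "MKVL" * 10)]
        r = [SequenceRecord("r0", "", "MKVL" * 20)]
        edges = [edge("q0", "r0", 1, 40, bitscore=100.0),
                 edge("q0", "r0", 41, 80, bitscore=250.0)]
        cells = build_rect_matrix(q, r, edges=edges)
        assert cells[("q0", "r0")].start == 41

    def test_overlapping_id_spaces_rejected(self):
        q = [SequenceRecord("same", "", "MKVL")]
        r = [SequenceRecord("same", "", "MLVL")]
        with pytest.raises(ValueError, match="overlap"):
            build_rect_matrix(q, r, edges=[])


class TestDetectFusions:
    def test_planted_trio_called(self, trio, tmp_path):
        by_id, _ = trio
        query = [by_id["FUS00A"], by_id["FUS00B"]]
        reference = [by_id["FUS00C"]]
        cells = build_rect_matrix(query, reference, min_score=100)
        cands = detect_fusions(cells, query, seed=5)
        assert len(cands) == 1
        cand = cands[0]
        assert cand.composite_id == "FUS00C"
        assert [c.component_id for c in cand.components] == ["FUS00A", "FUS00B"]
        out = tmp_path / "fusions.tsv"
        write_fusions(cands, out)
        line = out.read_text().strip()
        assert line.startswith("FUS00C\t2\tFUS00A:")

    def test_overlapping_spans_rejected(self, rng):
        query = [SequenceRecord("c1", "", random_protein(rng, 100)),
                 SequenceRecord("c2", "", random_protein(rng, 100))]
        cells = {
            ("c1", "R"): RectHit("c1", "R", 300.0, 1, 100),
            ("c2", "R"): RectHit("c2", "R", 300.0, 21, 120),
        }
        cands = detect_fusions(cells, query, max_component_overlap=0.1,
                               validate_components=False, seed=5)
        assert cands == []

    def test_homologous_components_rejected_only_with_validation(self, rng):
        # composite = R + linker + R' where R' is a mutated copy of R:
        # spans are distinct but the components share the same domain
        base = random_protein(rng, 70)
        mutated = list(base)
        for pos in rng.choice(70, size=7, replace=False):
            mutated[pos] = "A" if mutated[pos] != "A" else "G"
        mutated = "".join(mutated)
        c1 = SequenceRecord("c1", "", base + random_protein(rng, 70))
        c2 = SequenceRecord("c2", "", mutated + random_protein(rng, 70))
        composite = SequenceRecord("R", "", base + random_protein(rng, 15) + mutated)
        cells = build_rect_matrix([c1, c2], [composite], min_score=100)
        assert set(cells) == {("c1", "R"), ("c2", "R")}
        with_validation = detect_fusions(cells, [c1, c2], seed=5)
        without = detect_fusions(cells, [c1, c2], validate_components=False, seed=5)
        assert with_validation == []
        assert len(without) == 1

    def test_component_order_invariance(self, trio):
        by_id, _ = trio
        query = [by_id["FUS00A"], by_id["FUS00B"]]
        reference = [by_id["FUS00C"]]
        cells = build_rect_matrix(query, reference, min_score=100)
        fwd = detect_fusions(cells, query, seed=5)
        rev = detect_fusions(dict(reversed(list(cells.items()))),
                             list(reversed(query)), seed=5)
        assert fwd == rev

    def test_composite_only_reported_from_reference_side(self, trio):
        by_id, _ = trio
        components = [by_id["FUS00A"], by_id["FUS00B"]]
        composite = [by_id["FUS00C"]]
        # swap the roles: composites are requested from the reference set,
        # so putting the composite on the query side must yield nothing
        cells = build_rect_matrix(composite, components, min_score=100)
        cands = detect_fusions(cells, composite, seed=5)
        assert cands == []

    def test_spans_within_composite_and_fractions_bounded(self, trio):
        by_id, _ = trio
        query = [by_id["FUS00A"], by_id["FUS00B"]]
        reference = [by_id["FUS00C"]]
        cells = build_rect_matrix(query, reference, min_score=100)
        (cand,) = detect_fusions(cells, query, seed=5)
        for comp in cand.components:
            assert 1 <= comp.start <= comp.end <= len(by_id["FUS00C"].residues)
        assert all(0.0 <= f <= 1.0 for f in cand.overlap_fractions.values())

    def test_bad_overlap_bound_rejected(self):
        with pytest.raises(ValueError):
            detect_fusions({}, [], max_component_overlap=1.5)
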