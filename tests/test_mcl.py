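import numpy as np
import pytest

from cggtools.io import SimilarityEdge
from cggtools.mcl import (
    DEFAULT_EVALUE_CAP,
    build_graph,
    emit_outputs,
    inflate,
    mcl,
)


def edge(q, s, evalue=1e-20, bitscore=100.0):
    return SimilarityEdge(q, s, 90.0, 50, 5, 0, 1, 50, 1, 50, evalue, bitscore)


def clique_edges(members, evalue=1e-30):
    out = []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            out.append(edge(a, b, evalue))
            out.append(edge(b, a, evalue))
    return out


class TestBuildGraph:
    def test_neglog_weighting(self):
        g = build_graph([edge("A", "B", evalue=1e-50)])
        assert g["A"]["B"]["weight"] == pytest.approx(50.0)

    def test_zero_evalue_capped(self):
        g = build_graph([edge("A", "B", evalue=0.0)])
        assert g["A"]["B"]["weight"] == DEFAULT_EVALUE_CAP

    def test_directed_duplicates_take_max_weight(self):
        g = build_graph([edge("A", "B", evalue=1e-50), edge("B", "A", evalue=1e-30)])
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["weight"] == pytest.approx(50.0)

    def test_thresholds_drop_edges(self):
        edges = [edge("A", "B", evalue=1e-3), edge("C", "D", evalue=1e-30)]
        g = build_graph(edges, max_evalue=1e-10)
        assert set(g.edges) == {("C", "D")}

    def test_self_hits_discarded(self):
        g = build_graph([edge("A", "A"), edge("A", "B")])
        assert not any(u == v for u, v in g.edges)

    def test_bitscore_weighting(self):
        g = build_graph([edge("A", "B", bitscore=185.0)], weighting="bitscore")
        assert g["A"]["B"]["weight"] == pytest.approx(185.0)


class TestInflation:
    def test_closed_form_column(self):
        col = np.array([[0.75], [0.25]])
        out = inflate(col, 2.0)
        assert np.allclose(out, [[0.9], [0.1]])

    def test_inflation_one_is_identity(self, rng):
        m = rng.random((6, 4))
        m /= m.sum(axis=0)
        assert np.allclose(inflate(m, 1.0), m)

    def test_columns_stochastic_after_inflation(self, rng):
        m = rng.random((8, 8))
        m /= m.sum(axis=0)
        for r in (1.2, 2.0, 5.0):
            assert np.allclose(inflate(m, r).sum(axis=0), 1.0, atol=1e-9)


class TestMcl:
    def test_disjoint_triangles_give_two_families(self):
        edges = clique_edges(["A", "B", "C"]) + clique_edges(["D", "E", "F"])
        fams = mcl(build_graph(edges), inflation=2.0)
        assert fams.as_partition() == {
            frozenset({"A", "B", "C"}),
            frozenset({"D", "E", "F"}),
        }

    def test_single_vertex_singleton(self):
        import networkx as nx

        g = nx.Graph()
        g.add_node("solo")
        fams = mcl(g)
        assert fams.families == [(1, ["solo"])]

    def test_family_ids_incremental_sorted_by_size(self):
        edges = clique_edges(["A", "B", "C", "D"]) + clique_edges(["X", "Y"])
        fams = mcl(build_graph(edges))
        assert [fid for fid, _ in fams.families] == [1, 2]
        assert len(fams.families[0][1]) >= len(fams.families[1][1])

    def test_partition_covers_every_vertex_once(self, rng):
        members = [f"v{i}" for i in range(12)]
        edges = []
        for _ in range(30):
            a, b = rng.choice(members, size=2, replace=False)
            edges.append(edge(str(a), str(b), evalue=10.0 ** -int(rng.integers(5, 60))))
        g = build_graph(edges)
        fams = mcl(g)
        assert sorted(fams.members()) == sorted(g.nodes)

    def test_planted_partition_recovered(self, rng):
        groups = [[f"g{k}_{i}" for i in range(5)] for k in range(4)]
        edges = []
        for group in groups:
            edges.extend(clique_edges(group))
        fams = mcl(build_graph(edges), inflation=2.0)
        assert fams.as_partition() == {frozenset(g) for g in groups}

    def test_edge_order_invariance(self, rng):
        groups = [[f"g{k}_{i}" for i in range(4)] for k in range(3)]
        edges = []
        for group in groups:
            edges.extend(clique_edges(group))
        # weak inter-group noise
        edges.append(edge("g0_0", "g1_0", evalue=1e-6))
        baseline = mcl(build_graph(edges)).as_partition()
        for seed in range(3):
            shuffled = list(edges)
            np.random.default_rng(seed).shuffle(shuffled)
            assert mcl(build_graph(shuffled)).as_partition() == baseline

    def test_higher_inflation_at_least_as_fine(self):
        groups = [[f"g{k}_{i}" for i in range(4)] for k in range(3)]
        edges = []
        for group in groups:
            edges.extend(clique_edges(group))
        edges.append(edge("g0_0", "g1_0", evalue=1e-25))
        edges.append(edge("g1_1", "g2_0", evalue=1e-25))
        g = build_graph(edges)
        coarse = mcl(g, inflation=1.4).n_families
        fine = mcl(g, inflation=5.0).n_families
        assert fine >= coarse

    def test_inflation_below_one_rejected(self):
        with pytest.raises(ValueError):
            mcl(build_graph([edge("A", "B")]), inflation=0.5)


class TestEmitOutputs:
    def test_three_files_with_documented_schemas(self, tmp_path):
        edges = clique_edges(["A", "B", "C"]) + clique_edges(["D", "E"])
        g = build_graph(edges)
        fams = mcl(g)
        paths = emit_outputs(g, fams, tmp_path / "run")
        assert len(paths) == 3
        vis, raw, famfile = paths
        assert all(p.exists() for p in paths)

        vis_lines = vis.read_text().splitlines()
        assert len(vis_lines) == g.number_of_edges()
        for line in vis_lines:
            a, b, w = line.split("\t")
            assert float(w) > 0

        raw_lines = raw.read_text().splitlines()
        assert len(raw_lines) == fams.n_families

        fam_lines = famfile.read_text().splitlines()
        total = 0
        for expected_id, line in enumerate(fam_lines, 1):
            fid, count, members = line.split("\t")
            assert int(fid) == expected_id
            assert int(count) == len(members.split(","))
            total += int(count)
        assert total == g.number_of_nodes()
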