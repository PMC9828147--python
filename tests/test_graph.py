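"""Bipartite DFI graph: I/O, statistics, decomposition, splitting, sampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dfinder.exceptions import CapacityError, EmptyGraphError, ParseError
from dfinder.graph import (
    BipartiteDFIGraph,
    FoodComposition,
    decompose_foods,
    density,
    load_edge_list,
    pa_score,
    sample_negatives,
    save_edge_list,
    split_edges,
)

from .conftest import random_bipartite
import pandas as pd


class TestLoadEdgeList:
    def test_deduplicates_edges(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("D1\tF1\nD1\tF2\nD1\tF2\n")
        g = load_edge_list(p)
        assert (g.n_drugs, g.n_foods, g.n_edges) == (1, 2, 2)

    def test_neighbor_maps(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("D1\tF1\nD2\tF1\n")
        g = load_edge_list(p)
        assert g.neighbors_of_food["F1"] == {"D1", "D2"}
        assert g.neighbors_of_drug["D1"] == {"F1"}

    def test_edge_count_matches_distinct_lines(self, tmp_path):
        # 50 random lines with repeats; oracle = distinct-line count
        rng = np.random.default_rng(42)
        lines = [f"D{rng.integers(8)}\tF{rng.integers(8)}" for _ in range(50)]
        p = tmp_path / "e.tsv"
        p.write_text("\n".join(lines) + "\n")
        g = load_edge_list(p)
        assert g.n_edges == len(set(lines))

    def test_comments_and_header_skipped(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("# comment\ndrug_id\tfood_id\nD1\tF1\n")
        assert load_edge_list(p).n_edges == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("D1\tF1\nonlyonecolumn\n")
        with pytest.raises(ParseError, match=":2"):
            load_edge_list(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("# nothing\n")
        with pytest.raises(EmptyGraphError):
            load_edge_list(p)

    def test_roundtrip(self, tiny_graph, tmp_path):
        p = tmp_path / "e.tsv"
        save_edge_list(tiny_graph, p)
        g2 = load_edge_list(p)
        assert g2.edges == tiny_graph.edges


class TestGraphInvariants:
    def test_namespace_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BipartiteDFIGraph(["X"], ["X"], [("X", "X")])

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(KeyError):
            BipartiteDFIGraph(["D1"], ["F1"], [("D1", "F2")])

    def test_degree_sums_equal_edge_count(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = random_bipartite(rng)
            assert sum(g.drug_degree(d) for d in g.drug_ids) == g.n_edges
            assert sum(g.food_degree(f) for f in g.food_ids) == g.n_edges


class TestDensity:
    @pytest.mark.parametrize(
        "M, N, E, expected",
        [(143, 213, 1784, 0.059), (779, 818, 15890, 0.025)],
    )
    def test_reference_network_densities(self, M, N, E, expected):
        """The two curated DFI networks' printed densities at 3 decimals."""
        rng = np.random.default_rng(0)
        pairs = rng.choice(M * N, size=E, replace=False)
        drugs = [f"D{i}" for i in range(M)]
        foods = [f"F{j}" for j in range(N)]
        edges = [(drugs[p // N], foods[p % N]) for p in pairs]
        g = BipartiteDFIGraph(drugs, foods, edges)
        assert round(density(g), 3) == expected

    def test_complete_graph_density_one(self):
        g = BipartiteDFIGraph.from_edges(
            [(d, f) for d in ("D1", "D2") for f in ("F1", "F2", "F3")]
        )
        assert density(g) == 1.0

    def test_density_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            assert 0.0 <= density(random_bipartite(rng)) <= 1.0

    def test_empty_graph_errors(self):
        with pytest.raises(EmptyGraphError):
            density(BipartiteDFIGraph([], [], []))


class TestDecomposeFoods:
    def _comp(self, rows):
        return FoodComposition(
            pd.DataFrame(rows, columns=["food", "constituent", "content"])
        )

    def test_top_k_of_oversized_food(self):
        rng = np.random.default_rng(3)
        contents = rng.permutation(25).astype(float)
        comp = self._comp([("apple", f"c{i}", c) for i, c in enumerate(contents)])
        got = decompose_foods(comp, k=20)["apple"]
        assert len(got) == 20
        top20 = set(np.argsort(-contents)[:20])
        assert {int(c[1:]) for c in got} == top20

    def test_undersized_food_keeps_all(self):
        comp = self._comp([("kiwi", f"c{i}", float(i)) for i in range(5)])
        assert len(decompose_foods(comp, k=20)["kiwi"]) == 5

    def test_sorted_by_descending_content(self):
        comp = self._comp([("x", "a", 3.0), ("x", "b", 1.0), ("x", "c", 2.0)])
        assert decompose_foods(comp, k=2)["x"] == ["a", "c"]

    def test_content_ties_broken_lexicographically(self):
        comp = self._comp([("x", "b", 1.0), ("x", "a", 1.0), ("x", "c", 2.0)])
        assert decompose_foods(comp, k=2)["x"] == ["c", "a"]

    def test_negative_content_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            self._comp([("x", "a", -1.0)])

    def test_output_size_is_min_k_n(self):
        rng = np.random.default_rng(9)
        rows = [
            (f"food{f}", f"c{i}", float(rng.random()))
            for f in range(5)
            for i in range(int(rng.integers(1, 30)))
        ]
        comp = self._comp(rows)
        sizes = comp.table.groupby("food").size()
        for k in (1, 3, 20):
            for food, consts in decompose_foods(comp, k=k).items():
                assert len(consts) == min(k, sizes[food])


class TestSplitEdges:
    def test_twenty_percent_holdout(self):
        g = BipartiteDFIGraph.from_edges(
            [(f"D{i}", f"F{j}") for i in range(10) for j in range(10)]
        )
        split = split_edges(g, test_fraction=0.2, seed=0)
        assert len(split.test_pos) == 20
        assert len(split.train_pos) == 80

    def test_determinism(self, tiny_graph):
        a = split_edges(tiny_graph, 0.5, seed=3)
        b = split_edges(tiny_graph, 0.5, seed=3)
        assert a.test_pos == b.test_pos

    def test_round_half_up(self, tiny_graph):
        # 4 edges * 0.375 = 1.5 -> 2 held out
        assert len(split_edges(tiny_graph, 0.375, seed=0).test_pos) == 2

    @given(st.integers(0, 10_000))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed % 200)
        g = random_bipartite(rng)
        s = split_edges(g, 0.2, seed=seed)
        assert s.train_pos | s.test_pos == set(g.edges)
        assert not s.train_pos & s.test_pos

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, tiny_graph, frac):
        with pytest.raises(ValueError):
            split_edges(tiny_graph, frac, seed=0)

    def test_split_tsv_roundtrip(self, tiny_graph, tmp_path):
        s = split_edges(tiny_graph, 0.5, seed=1)
        s.test_neg = sample_negatives(tiny_graph, 2, seed=1)
        p = tmp_path / "split.tsv"
        s.to_tsv(p)
        from dfinder.graph import EdgeSplit

        s2 = EdgeSplit.from_tsv(p)
        assert (s2.train_pos, s2.test_pos, s2.test_neg) == (
            s.train_pos,
            s.test_pos,
            s.test_neg,
        )


class TestSampleNegatives:
    def test_exhaustion_returns_all_non_edges(self, tiny_graph):
        # 3x3 grid, 4 edges -> exactly 5 non-edges
        got = sample_negatives(tiny_graph, 5, seed=0)
        assert len(got) == 5
        assert not got & tiny_graph.edges

    def test_determinism(self, tiny_graph):
        a = sample_negatives(tiny_graph, 3, seed=9)
        b = sample_negatives(tiny_graph, 3, seed=9)
        assert a == b

    def test_never_returns_edges_or_excluded(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = random_bipartite(rng)
            cap = g.n_drugs * g.n_foods - g.n_edges
            if cap < 2:
                continue
            exclude = set(list(sorted(g.edges))[:1])
            got = sample_negatives(g, min(cap - 1, 5), seed=1, exclude=exclude)
            assert not got & set(g.edges)
            assert not got & exclude

    def test_capacity_error(self, tiny_graph):
        with pytest.raises(CapacityError):
            sample_negatives(tiny_graph, 6, seed=0)

    def test_degree_matched_frequencies_track_degree(self):
        """Drug sampling frequency proportional to degree within 3 sigma."""
        g = BipartiteDFIGraph.from_edges(
            [("D1", "F1"), ("D1", "F2"), ("D1", "F3"), ("D2", "F1"), ("D3", "F2")]
        )
        # weights over allowed (non-edge) pairs with degree products:
        # remaining pairs: (D2,F2):1*2 (D2,F3):1*1 (D3,F1):1*2 (D3,F3):1*1
        weights = {("D2", "F2"): 2, ("D2", "F3"): 1, ("D3", "F1"): 2, ("D3", "F3"): 1}
        total = sum(weights.values())
        n_draws = 10_000
        counts = {k: 0 for k in weights}
        for s in range(n_draws):
            (pair,) = sample_negatives(g, 1, mode="degree_matched", seed=s)
            counts[pair] += 1
        for pair, w in weights.items():
            p = w / total
            sigma = np.sqrt(n_draws * p * (1 - p))
            assert abs(counts[pair] - n_draws * p) < 3 * sigma


class TestPAScore:
    def test_degree_product(self, tiny_graph):
        g = BipartiteDFIGraph.from_edges(
            [("D1", f"F{i}") for i in range(3)] + [(f"D{j}", "F0") for j in range(2, 6)]
        )
        assert pa_score(g, ("D1", "F0")) == 3 * 5

    def test_isolated_node_scores_zero(self):
        g = BipartiteDFIGraph(["D1"], ["F1", "F2"], [("D1", "F1")])
        assert pa_score(g, ("D1", "F2")) == 0.0

    def test_unknown_node_errors(self, tiny_graph):
        with pytest.raises(KeyError):
            pa_score(tiny_graph, ("D99", "F1"))

    def test_ranking_matches_brute_force_degree_products(self):
        rng = np.random.default_rng(13)
        g = random_bipartite(rng)
        pairs = [
            (g.drug_ids[rng.integers(g.n_drugs)], g.food_ids[rng.integers(g.n_foods)])
            for _ in range(20)
        ]
        scores = [pa_score(g, p) for p in pairs]
        brute = [
            sum(1 for e in g.edges if e[0] == d) * sum(1 for e in g.edges if e[1] == f)
            for d, f in pairs
        ]
        assert scores == [float(b) for b in brute]
        assert np.argsort(scores, kind="stable").tolist() == np.argsort(
            [float(b) for b in brute], kind="stable"
        ).tolist()
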