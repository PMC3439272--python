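"""Score tables across conditions: assembly, filtering, variance ranking,
clustering, subnetwork extraction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from edgeflux.dataset import DataSet
from edgeflux.network import AnnotationMap, Edge, InteractionNetwork
from edgeflux.tables import (EdgeFluxTable, TermScoreTable,
                             extract_subnetwork, extract_term_subnetwork,
                             filter_rows, hierarchical_cluster,
                             parse_filter_expression, rank_by_variance,
                             run_conditions)
from edgeflux.terms import annotate_interactions


@pytest.fixture
def small_run():
    net = InteractionNetwork(
        [Edge("A", "B"), Edge("B", "C"), Edge("C", "D"), Edge("A", "C")])
    data = DataSet(pd.DataFrame({
        "gene": ["A", "B", "C", "D"],
        "hot": [3.0, 2.0, 0.0, -1.0],
        "flat": [0.5, 0.5, 0.5, 0.5],
        "hot2": [3.0, 2.0, 0.0, -1.0],
    }), "gene")
    annotation = AnnotationMap(
        term_to_genes={"T_AB": frozenset({"A", "B"}),
                       "T_CD": frozenset({"C", "D"})},
        term_names={"T_AB": "", "T_CD": ""})
    annot = annotate_interactions(net, annotation)
    return net, data, annot


def ef_fixture(rows):
    """rows: dict row-label -> condition values (c1, c2)."""
    frame = pd.DataFrame([
        {"source": a, "target": b, "directedness": "undirected", "type": "",
         "c1": v1, "c2": v2}
        for (a, b), (v1, v2) in rows.items()])
    return EdgeFluxTable(frame)


class TestRunConditions:
    def test_one_score_column_per_condition(self, small_run):
        net, data, annot = small_run
        ef, terms = run_conditions(net, data, ["hot", "flat"],
                                   annotation=annot)
        assert ef.condition_columns == ["hot", "flat"]
        assert len(ef) == 4
        assert terms.condition_columns == ["hot", "flat"]

    def test_constant_column_scores_zero(self, small_run):
        net, data, _ = small_run
        ef, _ = run_conditions(net, data, ["flat"])
        assert ef.frame["flat"].abs().max() == 0.0

    def test_duplicate_columns_give_identical_scores(self, small_run):
        net, data, _ = small_run
        ef, _ = run_conditions(net, data, ["hot", "hot2"])
        assert (ef.frame["hot"] == ef.frame["hot2"]).all()

    def test_unknown_column_names_the_column(self, small_run):
        net, data, _ = small_run
        with pytest.raises(KeyError, match="nope"):
            run_conditions(net, data, ["nope"])


class TestFilterRows:
    def test_or_combination_with_figure_thresholds(self):
        table = ef_fixture({("A", "B"): (2.3, 0.1),
                            ("B", "C"): (1.0, 1.75),
                            ("C", "D"): (0.2, 0.3)})
        kept = filter_rows(table, [("c1", ">", 2.25), ("c2", ">", 1.70)],
                           combine="or")
        assert sorted(kept.row_ids) == ["A--B", "B--C"]

    def test_and_combination(self):
        table = ef_fixture({("A", "B"): (2.3, 1.8), ("B", "C"): (2.3, 0.1)})
        kept = filter_rows(table, [("c1", ">", 2.25), ("c2", ">", 1.70)],
                           combine="and")
        assert list(kept.row_ids) == ["A--B"]

    def test_empty_result_permitted(self):
        table = ef_fixture({("A", "B"): (0.1, 0.1)})
        kept = filter_rows(table, [("c1", ">", 99.0)])
        assert len(kept) == 0

    def test_undefined_cell_never_satisfies(self):
        table = ef_fixture({("A", "B"): (math.nan, math.nan)})
        for op in (">", "<", ">=", "<=", "==", "!="):
            assert len(filter_rows(table, [("c1", op, 0.0)])) == 0

    def test_idempotent(self):
        table = ef_fixture({("A", "B"): (2.3, 0.1), ("B", "C"): (0.0, 2.0)})
        clauses = [("c1", ">", 1.0), ("c2", ">", 1.0)]
        once = filter_rows(table, clauses, "or")
        twice = filter_rows(once, clauses, "or")
        assert once.frame.reset_index(drop=True).equals(
            twice.frame.reset_index(drop=True))

    def test_unknown_column_rejected(self):
        table = ef_fixture({("A", "B"): (1.0, 1.0)})
        with pytest.raises(KeyError, match="zz"):
            filter_rows(table, [("zz", ">", 0.0)])

    def test_expression_parser(self):
        clauses, combine = parse_filter_expression("c1 > 2.25 or c2 > 1.70")
        assert combine == "or"
        assert clauses == [("c1", ">", 2.25), ("c2", ">", 1.70)]
        with pytest.raises(ValueError):
            parse_filter_expression("c1 > 1 or c2 > 2 and c3 > 3")
        with pytest.raises(ValueError):
            parse_filter_expression("c1 >>> nonsense")


class TestRankByVariance:
    def test_descending_variance_with_top_k(self):
        table = ef_fixture({("A", "B"): (0.0, 4.0),   # var 8
                            ("B", "C"): (0.0, 1.0),   # var 0.5
                            ("C", "D"): (1.0, 1.0)})  # var 0
        top = rank_by_variance(table, top_k=2)
        assert list(top.row_ids) == ["A--B", "B--C"]

    def test_constant_row_ranks_last(self):
        table = ef_fixture({("A", "B"): (1.0, 1.0), ("B", "C"): (0.0, 0.5)})
        ranked = rank_by_variance(table, top_k=2)
        assert list(ranked.row_ids) == ["B--C", "A--B"]

    def test_ties_break_lexicographically(self):
        table = ef_fixture({("D", "E"): (0.0, 1.0), ("A", "B"): (2.0, 3.0)})
        ranked = rank_by_variance(table, top_k=2)
        assert list(ranked.row_ids) == ["A--B", "D--E"]

    def test_top_k_validation(self):
        table = ef_fixture({("A", "B"): (0.0, 1.0)})
        with pytest.raises(ValueError, match="top_k"):
            rank_by_variance(table, top_k=0)


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_height_zero(self):
        table = ef_fixture({("A", "B"): (1.0, 2.0), ("C", "D"): (1.0, 2.0),
                            ("E", "F"): (9.0, 9.0)})
        res = hierarchical_cluster(table)
        assert res.linkage_matrix[0, 2] == 0.0

    def test_distant_row_joins_last_vs_brute_force(self):
        # brute-force agglomeration on the 3x3 euclidean distance matrix
        vals = {("A", "B"): (0.0, 0.0), ("C", "D"): (1.0, 0.0),
                ("E", "F"): (50.0, 50.0)}
        table = ef_fixture(vals)
        res = hierarchical_cluster(table, metric="euclidean",
                                   linkage="average")
        pts = {k: np.array(v) for k, v in vals.items()}
        dists = {frozenset((a, b)): float(np.linalg.norm(pts[a] - pts[b]))
                 for a, b in itertools.combinations(pts, 2)}
        first_pair = min(dists, key=dists.get)
        assert set(first_pair) == {("A", "B"), ("C", "D")}
        # the outlier is the last leaf to join: final merge height far above
        assert res.linkage_matrix[-1, 2] > res.linkage_matrix[0, 2] * 10

    def test_correlation_metric_affine_invariant(self):
        base = {("A", "B"): (1.0, 2.0, 3.0), ("C", "D"): (3.0, 2.0, 1.0),
                ("E", "F"): (1.0, 3.0, 2.0)}
        scaled = {k: tuple(5.0 * x + 7.0 for x in v) for k, v in base.items()}

        def tab(rows):
            frame = pd.DataFrame([
                {"source": a, "target": b, "directedness": "undirected",
                 "type": "", "c1": v[0], "c2": v[1], "c3": v[2]}
                for (a, b), v in rows.items()])
            return EdgeFluxTable(frame)

        r1 = hierarchical_cluster(tab(base), metric="correlation")
        r2 = hierarchical_cluster(tab(scaled), metric="correlation")
        assert r1.row_ids == r2.row_ids
        assert np.allclose(r1.linkage_matrix[:, 2], r2.linkage_matrix[:, 2],
                           atol=1e-12)

    def test_rows_with_undefined_cells_dropped(self, caplog):
        table = ef_fixture({("A", "B"): (1.0, math.nan),
                            ("C", "D"): (1.0, 2.0), ("E", "F"): (3.0, 4.0)})
        res = hierarchical_cluster(table)
        assert res.dropped == ["A--B"]
        assert len(res.row_ids) == 2

    def test_fewer_than_two_complete_rows_rejected(self):
        table = ef_fixture({("A", "B"): (1.0, math.nan)})
        with pytest.raises(ValueError, match="2 complete rows"):
            hierarchical_cluster(table)

    def test_newick_parses_with_all_leaves(self):
        import io
        from Bio import Phylo
        table = ef_fixture({("A", "B"): (1.0, 2.0), ("C", "D"): (4.0, 5.0),
                            ("E", "F"): (0.0, 9.0), ("G", "H"): (2.0, 2.0)})
        res = hierarchical_cluster(table)
        tree = Phylo.read(io.StringIO(res.newick), "newick")
        leaves = sorted(t.name for t in tree.get_terminals())
        assert leaves == ["A--B", "C--D", "E--F", "G--H"]
        assert all(t.branch_length is not None and t.branch_length >= 0
                   for t in tree.get_terminals())


class TestExtractSubnetwork:
    def test_edge_set_equals_selection_no_expansion(self):
        net = InteractionNetwork([Edge("A", "B"), Edge("B", "C"),
                                  Edge("C", "D"), Edge("D", "E")])
        keys = [("A", "B", False), ("B", "C", False), ("C", "D", False)]
        sub, _ = extract_subnetwork(keys, net)
        assert {e.key for e in sub.edges} == set(keys)
        assert sub.nodes == {"A", "B", "C", "D"}

    def test_node_attributes_restricted_to_present_nodes(self):
        net = InteractionNetwork([Edge("A", "B"), Edge("C", "D")])
        sub, attrs = extract_subnetwork(
            [("A", "B", False)], net,
            {"A": {"x": 1.0}, "C": {"x": 2.0}})
        assert attrs == {"A": {"x": 1.0}}

    def test_unknown_edge_named_in_error(self):
        net = InteractionNetwork([Edge("A", "B")])
        with pytest.raises(KeyError, match="X"):
            extract_subnetwork([("X", "Y", False)], net)

    def test_empty_selection_rejected(self):
        net = InteractionNetwork([Edge("A", "B")])
        with pytest.raises(ValueError, match="empty"):
            extract_subnetwork([], net)

    def test_term_extraction_takes_all_carrying_edges(self):
        net = InteractionNetwork(
            [Edge("A", "B"), Edge("B", "C"), Edge("C", "D")])
        annotation = AnnotationMap(
            term_to_genes={"T": frozenset({"A", "B", "C"})},
            term_names={"T": ""})
        annot = annotate_interactions(net, annotation)
        sub, _ = extract_term_subnetwork(["T"], annot, net)
        assert {e.key for e in sub.edges} == {("A", "B", False),
                                              ("B", "C", False)}
        with pytest.raises(ValueError, match="no network edge"):
            extract_term_subnetwork(["UNKNOWN"], annot, net)


def test_table_tsv_round_trip(tmp_path, small_run):
    net, data, annot = small_run
    ef, terms = run_conditions(net, data, ["hot", "flat"], annotation=annot)
    p = tmp_path / "ef.tsv"
    ef.to_tsv(p, header_lines=["params: q=0.01"])
    back = EdgeFluxTable.from_tsv(p)
    assert list(back.frame.columns) == list(ef.frame.columns)
    assert np.allclose(back.frame["hot"], ef.frame["hot"], atol=1e-9)
    tp = tmp_path / "terms.tsv"
    terms.to_tsv(tp)
    tback = TermScoreTable.from_tsv(tp)
    assert list(tback.frame["term"]) == list(terms.frame["term"])
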