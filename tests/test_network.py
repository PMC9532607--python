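import itertools

import networkx as nx
import pandas as pd
import pytest

from panmethnet.network import (
    aggregate_edges,
    classify_concordance,
    export_network,
    multi_degree_nodes,
)


def corr_rows(pair_cohort_r, significant=True):
    """Build a per-cohort correlation table from (a, b, cohort, r) tuples."""
    rows = [
        {"feature_a": a, "feature_b": b, "cohort": c, "r": r,
         "p_value": 0.001 if significant else 0.5, "n": 50,
         "significant": significant}
        for a, b, c, r in pair_cohort_r
    ]
    return pd.DataFrame(rows)


class TestClassifyConcordance:
    @pytest.mark.parametrize("np_, nn, expected", [
        (5, 0, "total_positive"), (0, 5, "total_negative"), (1, 1, "partial"),
    ])
    def test_stated_cases(self, np_, nn, expected):
        assert classify_concordance(np_, nn) == expected

    def test_exhaustive_truth_table(self):
        for n_pos, n_neg in itertools.product(range(7), repeat=2):
            if n_pos + n_neg == 0 or n_pos + n_neg > 6:
                continue
            got = classify_concordance(n_pos, n_neg)
            if n_neg == 0:
                assert got == "total_positive"
            elif n_pos == 0:
                assert got == "total_negative"
            else:
                assert got == "partial"

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            classify_concordance(0, 0)


class TestAggregateEdges:
    def test_full_concordance_pair(self):
        table = corr_rows([("LCN2", "MMP9", f"C{i}", 0.5) for i in range(8)])
        edges = aggregate_edges(table, min_cohorts=5)
        assert len(edges) == 1
        edge = edges.iloc[0]
        assert edge["n_significant"] == 8
        assert edge["concordance"] == "total_positive"

    def test_partial_concordance_pair(self):
        rows = [("LCN2", "SLC22A17", f"C{i}", -0.5) for i in range(7)]
        rows += [("LCN2", "SLC22A17", f"D{i}", 0.4) for i in range(3)]
        edges = aggregate_edges(corr_rows(rows), min_cohorts=5)
        edge = edges.iloc[0]
        assert edge["n_significant"] == 10
        assert edge["n_negative"] == 7 and edge["n_positive"] == 3
        assert edge["concordance"] == "partial"

    def test_below_threshold_no_edge(self):
        table = corr_rows([("A", "B", f"C{i}", 0.5) for i in range(4)])
        assert aggregate_edges(table, min_cohorts=5).empty

    def test_non_significant_cohorts_ignored(self):
        sig = corr_rows([("A", "B", f"C{i}", 0.5) for i in range(5)])
        nonsig = corr_rows([("A", "B", "X1", -0.9)], significant=False)
        edges = aggregate_edges(pd.concat([sig, nonsig]), min_cohorts=5)
        assert edges.iloc[0]["concordance"] == "total_positive"
        assert edges.iloc[0]["n_significant"] == 5

    def test_pooled_rows_rejected(self):
        table = corr_rows([("A", "B", "pooled", 0.5)])
        with pytest.raises(ValueError, match="pooled"):
            aggregate_edges(table, min_cohorts=1)

    def test_invariant_to_row_order_and_antimonotone_filter(self):
        rows = ([("A", "B", f"C{i}", 0.5) for i in range(6)]
                + [("A", "C", f"C{i}", -0.4) for i in range(5)])
        table = corr_rows(rows)
        shuffled = table.sample(frac=1.0, random_state=0)
        e1 = aggregate_edges(table, 5).reset_index(drop=True)
        e2 = aggregate_edges(shuffled, 5).reset_index(drop=True)
        pd.testing.assert_frame_equal(e1, e2)
        for lo, hi in [(1, 5), (5, 6), (6, 7)]:
            assert len(aggregate_edges(table, hi)) <= len(
                aggregate_edges(table, lo))

    def test_both_orientations_count_each_cohort_once(self):
        rows = corr_rows(
            [("A", "B", "C1", 0.5), ("B", "A", "C1", 0.5),
             ("A", "B", "C2", 0.5)]
        )
        edge = aggregate_edges(rows, 1).iloc[0]
        assert edge["n_significant"] == 2


class TestExportNetwork:
    def _edges(self):
        rows = ([("G1", "P1", f"C{i}", 0.6) for i in range(5)]
                + [("G2", "P1", f"C{i}", -0.5) for i in range(5)]
                + [("G1", "P2", f"C{i}", 0.4) for i in range(5)])
        return aggregate_edges(corr_rows(rows), 5)

    def test_empty_table_valid_files(self, tmp_path):
        empty = self._edges().iloc[0:0]
        export_network(empty, "sif", tmp_path / "e.sif")
        assert (tmp_path / "e.sif").read_text() == ""
        export_network(empty, "tsv", tmp_path / "e.tsv")
        assert "feature_a" in (tmp_path / "e.tsv").read_text()

    def test_sif_line_count_and_interaction_type(self, tmp_path):
        edges = self._edges()
        export_network(edges, "sif", tmp_path / "n.sif")
        lines = (tmp_path / "n.sif").read_text().splitlines()
        assert len(lines) == 3
        assert all(len(l.split("\t")) == 3 for l in lines)
        types = {l.split("\t")[1] for l in lines}
        assert types <= {"total_positive", "total_negative", "partial"}

    def test_graphml_round_trip_preserves_attributes(self, tmp_path):
        edges = self._edges()
        path = tmp_path / "n.graphml"
        export_network(edges, "graphml", path)
        graph = nx.read_graphml(path)
        assert graph.number_of_edges() == len(edges)
        for _, row in edges.iterrows():
            attrs = graph.edges[row["feature_a"], row["feature_b"]]
            assert attrs["concordance"] == row["concordance"]
            assert attrs["n_significant"] == row["n_significant"]
            assert attrs["mean_r"] == pytest.approx(row["mean_r"])

    def test_unknown_format_errors(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_network(self._edges(), "xml", tmp_path / "x")

    def test_export_reimport_preserves_edge_multiset(self, tmp_path):
        edges = self._edges()
        path = tmp_path / "n.tsv"
        export_network(edges, "tsv", path)
        back = pd.read_csv(path, sep="\t")
        orig = edges.sort_values(["feature_a", "feature_b"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(back, orig)


class TestMultiDegreeNodes:
    def test_degree_two(self):
        edges = pd.DataFrame({
            "feature_a": ["G1", "G2"], "feature_b": ["P1", "P1"],
        })
        table = multi_degree_nodes(edges, ["G1", "G2", "G3"])
        assert list(table["feature_id"]) == ["P1"]
        assert table.iloc[0]["anchor_degree"] == 2

    def test_no_edges_empty(self):
        empty = pd.DataFrame(columns=["feature_a", "feature_b"])
        assert multi_degree_nodes(empty, ["G1"]).empty

    def test_star_reaches_degree_three(self):
        edges = pd.DataFrame({
            "feature_a": ["G1", "G2", "P"], "feature_b": ["P", "P", "G3"],
        })
        table = multi_degree_nodes(edges, ["G1", "G2", "G3"])
        assert table.iloc[0]["anchor_degree"] == 3
        assert table.iloc[0]["anchors"] == "G1,G2,G3"
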