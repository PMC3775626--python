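import json

import numpy as np
import pandas as pd
import pytest

from phylodiv.data_model import (
    AlignmentError,
    CountTable,
    SampleCounts,
    TableFormatError,
    TreeParseError,
    align_tree_table,
    compute_edge_masses,
    read_count_table,
    read_newick,
    reroot,
    write_biom_json,
    write_newick,
)
from phylodiv.phylo_alpha import bwpd, pd_unrooted
from phylodiv.synthetic import random_tree

from _oracles import brute_edge_masses


class TestReadNewick:
    def test_t0_shape(self):
        tree = read_newick("((A:1.0,B:1.0):1.0,C:1.0);")
        assert sorted(tree.tip_labels) == ["A", "B", "C"]
        assert tree.n_edges == 4
        assert tree.total_length == 4.0

    def test_single_leaf_degenerate(self):
        with pytest.warns(UserWarning, match="single-leaf"):
            tree = read_newick("A:1.0;")
        assert tree.n_nodes == 1
        assert tree.n_edges == 0
        assert tree.tip_labels == ["A"]

    @pytest.mark.parametrize("bad", ["((A:1,B:1:);", "((A:1,B:1);", "(A:1,B:2"])
    def test_malformed(self, bad):
        with pytest.raises(TreeParseError):
            read_newick(bad)

    def test_duplicate_leaf_labels(self):
        with pytest.raises(TreeParseError):
            read_newick("(A:1,A:1);")

    def test_negative_branch_length(self):
        with pytest.raises(TreeParseError, match="negative"):
            read_newick("(A:1,B:-0.5);")

    def test_missing_lengths_default_zero_with_warning(self):
        with pytest.warns(UserWarning, match="missing branch length"):
            tree = read_newick("((A:1,B),C:2);")
        assert tree.total_length == 3.0

    def test_quoted_labels(self):
        tree = read_newick("('leaf one':1,'leaf two':2);")
        assert sorted(tree.tip_labels) == ["leaf one", "leaf two"]

    def test_internal_labels_preserved(self):
        tree = read_newick("((A:1,B:1)AB:1,C:1)root;")
        assert "AB" in tree.labels

    def test_round_trip(self):
        text = "((A:1,B:2.5):0.25,('C 1':1,D:3):1.5);"
        first = write_newick(read_newick(text))
        second = write_newick(read_newick(first))
        assert first == second
        t1, t2 = read_newick(text), read_newick(first)
        assert sorted(t1.tip_labels) == sorted(t2.tip_labels)
        assert t1.total_length == pytest.approx(t2.total_length, abs=0)


class TestCountTable:
    def _tsv(self, tmp_path, body):
        p = tmp_path / "table.tsv"
        p.write_text(body)
        return p

    def test_read_tsv(self, tmp_path):
        p = self._tsv(tmp_path, "leaf\tS1\nA\t2\nB\t1\nC\t1\n")
        table = read_count_table(p, format="tsv")
        assert table.leaf_labels == ["A", "B", "C"]
        assert int(table.totals()["S1"]) == 4

    def test_biom_sparse_round_trip(self, tmp_path):
        df = pd.DataFrame({"S1": [2, 1, 1], "S2": [0, 3, 0]}, index=["A", "B", "C"])
        table = CountTable(df)
        p = tmp_path / "t.biom"
        write_biom_json(table, p)
        again = read_count_table(p, format="biom-json")
        assert again == table

    def test_biom_dense(self, tmp_path):
        doc = {
            "id": "x", "format": "Biological Observation Matrix 1.0.0",
            "format_url": "", "type": "OTU table", "generated_by": "t", "date": "",
            "matrix_type": "dense", "matrix_element_type": "int", "shape": [2, 1],
            "rows": [{"id": "A", "metadata": None}, {"id": "B", "metadata": None}],
            "columns": [{"id": "S1", "metadata": None}],
            "data": [[2], [3]],
        }
        p = tmp_path / "d.biom"
        p.write_text(json.dumps(doc))
        table = read_count_table(p)
        assert table.data.loc["B", "S1"] == 3

    def test_non_integer_cell(self, tmp_path):
        p = self._tsv(tmp_path, "leaf\tS1\nA\t1.5\nB\t1\n")
        with pytest.raises(TableFormatError, match="non-integer"):
            read_count_table(p, format="tsv")

    def test_negative_cell(self, tmp_path):
        p = self._tsv(tmp_path, "leaf\tS1\nA\t-1\nB\t1\n")
        with pytest.raises(TableFormatError, match="negative"):
            read_count_table(p, format="tsv")

    def test_non_numeric_cell(self, tmp_path):
        p = self._tsv(tmp_path, "leaf\tS1\nA\tx\nB\t1\n")
        with pytest.raises(TableFormatError):
            read_count_table(p, format="tsv")

    def test_duplicate_rows(self):
        df = pd.DataFrame([[1], [2]], index=["A", "A"], columns=["S1"])
        with pytest.raises(TableFormatError, match="duplicate"):
            CountTable(df)


class TestAlign:
    @pytest.fixture
    def tree(self):
        return read_newick("((A:1,B:1):1,C:1);")

    def test_strict_identity(self, tree):
        table = CountTable(pd.DataFrame({"S1": [2, 1, 1]}, index=["A", "B", "C"]))
        assert align_tree_table(tree, table, "strict") == table

    def test_strict_mismatch_names_offender(self, tree):
        table = CountTable(pd.DataFrame({"S1": [2, 1, 1, 1]}, index=["A", "B", "C", "D"]))
        with pytest.raises(AlignmentError, match="D"):
            align_tree_table(tree, table, "strict")

    def test_intersect_drops_with_warning(self, tree):
        table = CountTable(pd.DataFrame({"S1": [2, 1, 1, 1]}, index=["A", "B", "C", "D"]))
        with pytest.warns(UserWarning, match="dropping 1"):
            out = align_tree_table(tree, table, "intersect")
        assert out.leaf_labels == ["A", "B", "C"]


class TestEdgeMasses:
    def test_t0_masses(self, t0):
        tree, sample = t0
        em = compute_edge_masses(tree, sample)
        by_label = {tree.labels[v]: int(em.d[v]) for v in tree.tip_ids()}
        assert by_label == {"A": 2, "B": 1, "C": 1}
        assert sorted(em.edge_counts().tolist()) == [1, 1, 2, 3]
        assert sorted(em.edge_fractions().tolist()) == [0.25, 0.25, 0.5, 0.75]

    def test_single_leaf_mass(self, t0):
        tree, _ = t0
        em = compute_edge_masses(tree, SampleCounts({"C": 5}))
        assert sorted(em.edge_counts().tolist()) == [0, 0, 0, 5]
        assert em.n == 5

    def test_empty_sample_errors(self, t0):
        tree, _ = t0
        with pytest.raises(ValueError, match="empty sample"):
            compute_edge_masses(tree, SampleCounts({"A": 0}))

    def test_unknown_leaf_errors(self, t0):
        tree, _ = t0
        with pytest.raises(AlignmentError):
            compute_edge_masses(tree, SampleCounts({"Z": 1}))

    def test_internal_edges_match_brute_recount_50_leaves(self):
        rng = np.random.default_rng(7)
        tree = random_tree(50, seed=3)
        counts = dict(zip(tree.tip_labels, rng.integers(0, 20, size=50).tolist()))
        sample = SampleCounts(counts)
        em = compute_edge_masses(tree, sample)
        oracle = brute_edge_masses(tree, counts)
        for v in tree.edge_ids():
            assert em.d[v] == oracle[int(v)]

    def test_leaf_edge_conservation(self, random_fixture_factory):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tree, sample = random_fixture_factory(rng)
            em = compute_edge_masses(tree, sample)
            leaf_sum = sum(int(em.d[v]) for v in tree.tip_ids() if v != tree.root)
            assert leaf_sum == sample.n


class TestReroot:
    def test_identity(self, t0):
        tree, _ = t0
        again = reroot(tree, tree.root)
        assert np.array_equal(again.parent, tree.parent)
        assert np.array_equal(again.length, tree.length)

    def test_unknown_node(self, t0):
        tree, _ = t0
        with pytest.raises(ValueError, match="unknown node"):
            reroot(tree, 99)

    def test_pd_invariant_under_internal_reroot(self, t0):
        tree, sample = t0
        internal = [v for v in range(tree.n_nodes) if tree.children[v] and v != tree.root]
        t2 = reroot(tree, internal[0])
        assert pd_unrooted(t2, sample) == pytest.approx(pd_unrooted(tree, sample), abs=1e-12)

    def test_bwpd_invariant_under_leaf_reroot(self, t0):
        tree, sample = t0
        leaf = tree.tip_index()["C"]
        t2 = reroot(tree, leaf)
        for theta in (0, 0.25, 0.5, 1):
            assert bwpd(t2, sample, theta) == pytest.approx(bwpd(tree, sample, theta), abs=1e-12)

    def test_mass_vector_flip_invariant(self, random_fixture_factory):
        # multiset of (length, min(d, n-d)) is a rooting-free edge signature
        rng = np.random.default_rng(5)
        for _ in range(10):
            tree, sample = random_fixture_factory(rng)
            em = compute_edge_masses(tree, sample)
            sig = sorted(
                (round(float(tree.length[v]), 12), min(int(em.d[v]), em.n - int(em.d[v])))
                for v in tree.edge_ids()
            )
            node = int(rng.integers(tree.n_nodes))
            t2 = reroot(tree, node)
            em2 = compute_edge_masses(t2, sample)
            sig2 = sorted(
                (round(float(t2.length[v]), 12), min(int(em2.d[v]), em2.n - int(em2.d[v])))
                for v in t2.edge_ids()
            )
            assert sig == sig2
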