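"""Container invariants and file round-trips."""

import numpy as np
import pytest

from mmgg import (
    ConstraintSet,
    FormatError,
    Network,
    Partition,
    ValidationError,
    read_constraints,
    read_network,
    read_partition,
    write_constraints,
    write_network,
    write_partition,
)


class TestNetwork:
    def test_edge_list_construction(self, tmp_path):
        p = tmp_path / "net.txt"
        p.write_text("0 1\n1 2\n")
        net = read_network(p)
        assert net.n_nodes == 3
        assert net.n_edges == 2
        assert np.array_equal(net.adjacency, net.adjacency.T)

    def test_duplicate_and_reciprocal_edges_collapse(self, tmp_path):
        p = tmp_path / "net.txt"
        p.write_text("a b\nb a\na b\n")
        net = read_network(p)
        assert net.n_nodes == 2
        assert net.n_edges == 1

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "net.txt"
        p.write_text("0 1\n3 3\n")
        with caplog.at_level("WARNING"):
            net = read_network(p)
        assert "self-loop" in caplog.text
        assert np.all(np.diag(net.adjacency) == 0)

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        p = tmp_path / "net.txt"
        p.write_text("# header\n0 1  # trailing\n\n1 2\n")
        assert read_network(p).n_edges == 2

    def test_bad_line_reports_line_number(self, tmp_path):
        p = tmp_path / "net.txt"
        p.write_text("0 1\n0 1 2\n")
        with pytest.raises(FormatError, match="line 2"):
            read_network(p)

    def test_gml_arcs_symmetrized(self, tmp_path):
        p = tmp_path / "net.gml"
        p.write_text(
            "graph [\n directed 1\n node [ id 0 ]\n node [ id 1 ]\n"
            " node [ id 2 ]\n edge [ source 0 target 1 ]\n"
            " edge [ source 1 target 0 ]\n]\n"
        )
        net = read_network(p)
        assert net.n_edges == 1
        assert net.n_nodes == 3  # isolated declared node kept, degree 0
        assert net.degrees[2] == 0

    def test_edgelist_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        a = (rng.random((12, 12)) < 0.3).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        # ensure no isolated nodes so the edge list covers all of them
        for i in range(12):
            if a[i].sum() == 0:
                j = (i + 1) % 12
                a[i, j] = a[j, i] = 1.0
        net = Network(a)
        p = tmp_path / "net.txt"
        write_network(net, p)
        back = read_network(p)
        order = [back.node_ids.index(v) for v in net.node_ids]
        assert np.array_equal(back.adjacency[np.ix_(order, order)], net.adjacency)

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ValidationError):
            Network(np.array([[0, 1], [0, 0]]))  # asymmetric
        with pytest.raises(ValidationError):
            Network(np.array([[1, 0], [0, 0]]))  # self-loop


class TestConstraints:
    def test_read_and_dedup(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("0\t1\tml\n1\t0\tml\n2\t3\tcl\n")
        cs = read_constraints(p)
        assert cs.must_link == frozenset({(0, 1)})
        assert cs.cannot_link == frozenset({(2, 3)})
        assert cs.size == 2

    def test_pair_in_both_sets_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("0\t1\tml\n0\t1\tcl\n")
        with pytest.raises(ValidationError):
            read_constraints(p)

    def test_unknown_tag_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("0\t1\tmaybe\n")
        with pytest.raises(FormatError, match="unknown tag"):
            read_constraints(p)

    def test_self_pair_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("2\t2\tml\n")
        with pytest.raises(FormatError):
            read_constraints(p)

    def test_roundtrip(self, tmp_path):
        cs = ConstraintSet(frozenset({(0, 3), (1, 2)}), frozenset({(0, 4)}))
        p = tmp_path / "c.tsv"
        write_constraints(cs, p)
        assert read_constraints(p) == cs


class TestPartitionIO:
    def test_roundtrip(self, tmp_path):
        part = Partition(np.array([1, 1, 2]), 2)
        p = tmp_path / "p.tsv"
        write_partition(part, p)
        back, ids = read_partition(p)
        assert np.array_equal(back.labels, part.labels)
        assert ids == ["0", "1", "2"]

    def test_empty_partition(self, tmp_path):
        p = tmp_path / "p.tsv"
        write_partition(Partition(np.array([], dtype=int), 0), p)
        assert p.read_text() == ""

    def test_node_order_preserved(self, tmp_path):
        p = tmp_path / "p.tsv"
        write_partition(Partition(np.array([2, 1]), 2), p, node_ids=["b", "a"])
        assert p.read_text().splitlines() == ["b\t2", "a\t1"]

    def test_labels_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            Partition(np.array([1, 3]), 2)
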