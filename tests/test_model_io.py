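"""Domain types, weight scaling and the three map file formats."""

import numpy as np
import pytest

from fcmkit import (
    Edge,
    Factor,
    FuzzyCognitiveMap,
    read_adjacency_csv,
    read_edge_list,
    read_graphml,
    scale_weights,
    write_adjacency_csv,
    write_edge_list,
    write_graphml,
)
from fcmkit.errors import (
    DuplicateEdgeError,
    FormatError,
    MapParseError,
    MapStateError,
    WeightRangeError,
)
from conftest import random_map


def build_map(edges, name="m", scaled=False):
    fcm = FuzzyCognitiveMap(name=name, scaled=scaled)
    for node in sorted({n for e in edges for n in e[:2]}):
        fcm.add_factor(node, node)
    for s, t, w, *sign in edges:
        fcm.add_edge(s, t, w, sign[0] if sign else 1)
    return fcm


class TestModel:
    def test_factor_label_must_be_nonempty(self):
        with pytest.raises(ValueError):
            Factor("f1", "   ")

    def test_edge_sign_and_weight_validation(self):
        with pytest.raises(ValueError):
            Edge("a", "b", 3, sign=2)
        with pytest.raises(ValueError):
            Edge("a", "b", -3)  # inhibition goes through sign, not weight

    def test_unscaled_map_rejects_out_of_scale_weights(self):
        fcm = FuzzyCognitiveMap("m")
        fcm.add_factor("A", "A")
        fcm.add_factor("B", "B")
        with pytest.raises(WeightRangeError):
            fcm.add_edge("A", "B", 7)
        with pytest.raises(WeightRangeError):
            fcm.add_edge("A", "B", 0.5)

    def test_duplicate_edges_and_unknown_endpoints_rejected(self):
        fcm = build_map([("A", "B", 4)])
        with pytest.raises(DuplicateEdgeError):
            fcm.add_edge("A", "B", 2)
        with pytest.raises(ValueError):
            fcm.add_edge("A", "Z", 2)

    def test_self_loops_accepted(self):
        fcm = build_map([("A", "A", 2)])
        assert fcm.edge("A", "A").weight == 2


class TestScaleWeights:
    def test_raw_weights_map_onto_fifths(self):
        fcm = build_map([("A", "B", 5), ("B", "C", 1), ("C", "A", 3, -1)])
        scaled = scale_weights(fcm)
        assert scaled.edge("A", "B").signed_weight == 1.0
        assert scaled.edge("B", "C").signed_weight == pytest.approx(0.2)
        assert scaled.edge("C", "A").signed_weight == pytest.approx(-0.6)

    def test_scaling_preserves_structure_and_is_bijective_on_weights(self):
        fcm, _ = random_map(seed=5, n_nodes=8, n_edges=20, scaled=False)
        scaled = scale_weights(fcm)
        assert scaled.n_edges == fcm.n_edges
        for e in fcm.edges:
            s = scaled.edge(e.source, e.target)
            assert s.sign == e.sign
            assert s.weight == pytest.approx(e.weight / 5)
        assert {round(e.weight, 1) for e in scaled.edges} <= {0.2, 0.4, 0.6, 0.8, 1.0}

    def test_rescaling_and_bad_constant_are_errors(self):
        fcm = build_map([("A", "B", 4)])
        scaled = scale_weights(fcm)
        with pytest.raises(MapStateError):
            scale_weights(scaled)
        with pytest.raises(ValueError):
            scale_weights(fcm, constant=0)


class TestAdjacencyCsv:
    def test_direct_parse(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(",A,B,C\nA,0,4,0\nB,,0,2\nC,0,0,0\n")
        fcm = read_adjacency_csv(path)
        assert fcm.n_factors == 3 and fcm.n_edges == 2
        weights = {(fcm.factor(e.source).label, fcm.factor(e.target).label): e.weight
                   for e in fcm.edges}
        assert weights == {("A", "B"): 4.0, ("B", "C"): 2.0}

    def test_all_zero_table_gives_edgeless_map(self, tmp_path):
        path = tmp_path / "z.csv"
        path.write_text(",A,B\nA,0,0\nB,0,0\n")
        fcm = read_adjacency_csv(path)
        assert (fcm.n_factors, fcm.n_edges) == (2, 0)

    @pytest.mark.parametrize(
        "content,error",
        [
            (",A,C\nA,0,1\nB,0,0\n", FormatError),  # label mismatch
            (",A,B,C\nA,0,1,0\nB,0,0,0\n", FormatError),  # not square
            (",A,B\nA,0,strong\nB,0,0\n", MapParseError),  # non-numeric cell
        ],
    )
    def test_malformed_tables_raise(self, tmp_path, content, error):
        path = tmp_path / "bad.csv"
        path.write_text(content)
        with pytest.raises(error):
            read_adjacency_csv(path)

    def test_negative_cell_is_inhibitory(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text(",A,B\nA,0,-4\nB,0,0\n")
        fcm = read_adjacency_csv(path)
        (edge,) = fcm.edges
        assert (edge.weight, edge.sign) == (4.0, -1)


class TestEdgeList:
    def test_direct_parse_with_signs(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("source,target,weight,sign\nA,B,5,+\nB,C,1,-\n")
        fcm = read_edge_list(path)
        assert (fcm.n_factors, fcm.n_edges) == (3, 2)
        assert sorted(e.sign for e in fcm.edges) == [-1, 1]

    def test_header_only_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("source,target,weight,sign\n")
        fcm = read_edge_list(path)
        assert (fcm.n_factors, fcm.n_edges) == (0, 0)

    def test_out_of_range_weight_cites_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("source,target,weight\nA,B,7\n")
        with pytest.raises(WeightRangeError, match="row 2"):
            read_edge_list(path)

    def test_duplicate_pair_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("source,target,weight\nA,B,3\nA,B,2\n")
        with pytest.raises(DuplicateEdgeError):
            read_edge_list(path)


class TestGraphml:
    def test_weight_from_attribute_and_label(self, tmp_path):
        fcm = build_map([("A", "B", 3)])
        path = tmp_path / "g.graphml"
        write_graphml(fcm, path)
        back = read_graphml(path)
        (edge,) = back.edges
        assert (edge.weight, edge.sign) == (3.0, 1)

    def test_negative_label_token_is_inhibitory(self, tmp_path):
        import networkx as nx

        g = nx.DiGraph()
        g.add_node("n0", label="A")
        g.add_node("n1", label="B")
        g.add_edge("n0", "n1", label="-4")
        path = tmp_path / "g.graphml"
        nx.write_graphml(g, path)
        (edge,) = read_graphml(path).edges
        assert (edge.weight, edge.sign) == (4.0, -1)

    def test_undirected_and_weightless_edges_raise(self, tmp_path):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("a", "b", weight=2)
        undirected = tmp_path / "u.graphml"
        nx.write_graphml(g, undirected)
        with pytest.raises(FormatError):
            read_graphml(undirected)

        d = nx.DiGraph()
        d.add_edge("a", "b", label="strong")
        bad = tmp_path / "d.graphml"
        nx.write_graphml(d, bad)
        with pytest.raises(MapParseError):
            read_graphml(bad)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize(
        "writer,reader",
        [
            (write_adjacency_csv, read_adjacency_csv),
            (write_edge_list, read_edge_list),
            (write_graphml, read_graphml),
        ],
    )
    def test_write_read_identity(self, tmp_path, seed, writer, reader):
        fcm, _ = random_map(seed=seed, n_nodes=7, n_edges=14, scaled=False)
        path = tmp_path / "map.file"
        writer(fcm, path)
        back = reader(path, name=fcm.name)
        assert back.structurally_equal(fcm)

    def test_self_loop_survives_round_trip(self, tmp_path):
        fcm = build_map([("A", "A", 2), ("A", "B", 3, -1)])
        path = tmp_path / "loop.csv"
        write_adjacency_csv(fcm, path)
        back = read_adjacency_csv(path, name="m")
        assert back.structurally_equal(fcm)

    def test_empty_map_round_trip(self, tmp_path):
        fcm = FuzzyCognitiveMap("empty")
        path = tmp_path / "empty.csv"
        write_adjacency_csv(fcm, path)
        back = read_adjacency_csv(path, name="empty")
        assert (back.n_factors, back.n_edges) == (0, 0)
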