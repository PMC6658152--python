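"""Skeleton -> graph extraction, widths, central node, link weights."""

import networkx as nx
import numpy as np
import pytest
from scipy import ndimage

from fundusgraph.errors import CentralAssignmentError, GraphExtractionError
from fundusgraph.segmentation import OpticDisc
from fundusgraph.vessel_graph import (
    WeightConfig,
    apply_weights,
    assign_central_node,
    build_graph,
    estimate_widths,
    extract_graph,
    skeletonize,
)


def _kinds(vg):
    from collections import Counter

    return Counter(d["kind"] for _, d in vg.graph.nodes(data=True))


def pixel_graph_contracted(skel):
    """Brute-force oracle: 8-connectivity pixel graph, touching junction
    pixels (degree >= 3) merged into one supernode, then every degree-2
    chain contracted away."""
    h = nx.Graph()
    px = list(map(tuple, np.argwhere(skel)))
    h.add_nodes_from(px)
    for r, c in px:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr, dc) != (0, 0) and (r + dr, c + dc) in h:
                    h.add_edge((r, c), (r + dr, c + dc))
    junctions = {n for n in h if h.degree(n) >= 3}
    cluster_of = {}
    for cid, comp in enumerate(nx.connected_components(h.subgraph(junctions))):
        for n in comp:
            cluster_of[n] = ("cluster", cid)
    m = nx.MultiGraph()
    for n in h:
        m.add_node(cluster_of.get(n, n))
    for u, v in h.edges():
        cu, cv = cluster_of.get(u, u), cluster_of.get(v, v)
        if cu != cv:
            m.add_edge(cu, cv)
    changed = True
    while changed:
        changed = False
        for n in list(m.nodes):
            if m.degree(n) == 2 and not any(v == n for _, v in m.edges(n)):
                neigh = [v for _, v in m.edges(n)]
                m.remove_node(n)
                m.add_edge(neigh[0], neigh[1])
                changed = True
    return m


class TestSkeletonize:
    def test_rectangle_reduces_to_path(self):
        m = np.zeros((30, 120), bool)
        m[12:17, 10:110] = True
        sk = skeletonize(m).data
        assert abs(sk.sum() - 100) <= 4

    def test_single_pixel(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert skeletonize(m).data.sum() == 1

    def test_component_count_preserved(self, rng):
        m = np.zeros((120, 120), bool)
        for _ in range(6):
            r, c = rng.integers(10, 100, 2)
            m[r : r + rng.integers(4, 14), c : c + rng.integers(4, 14)] = True
        s8 = np.ones((3, 3), int)
        assert ndimage.label(skeletonize(m).data, s8)[1] == ndimage.label(m, s8)[1]

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            sk = skeletonize(np.zeros((16, 16), bool))
        assert not sk.data.any()


class TestExtractGraph:
    def test_straight_line(self):
        m = np.zeros((9, 109), bool)
        m[4, 4:104] = True
        vg = extract_graph(m)
        assert (vg.n_nodes, vg.n_links) == (2, 1)
        assert _kinds(vg) == {"endpoint": 2}
        (edge,) = vg.graph.edges(data=True)
        assert edge[2]["L"] == 100

    def test_plus_sign(self):
        m = np.zeros((41, 41), bool)
        m[20, 5:36] = True
        m[5:36, 20] = True
        vg = extract_graph(m)
        assert (vg.n_nodes, vg.n_links) == (5, 4)
        assert _kinds(vg) == {"endpoint": 4, "bifurcation": 1}

    def test_pure_cycle_raises(self):
        # diamond ring: every pixel has exactly two 8-neighbours
        rr, cc = np.mgrid[0:31, 0:31]
        ring = (np.abs(rr - 15) + np.abs(cc - 15)) == 10
        with pytest.raises(GraphExtractionError):
            extract_graph(ring)

    @pytest.mark.parametrize("shape", ["T", "H", "Y"])
    def test_matches_contracted_pixel_graph(self, shape):
        """Extraction is isomorphic to the degree-2-contracted pixel graph."""
        m = np.zeros((40, 40), bool)
        if shape == "T":
            m[10, 5:35] = True
            m[10:30, 20] = True
        elif shape == "H":
            m[5:35, 10] = True
            m[5:35, 30] = True
            m[20, 10:31] = True
        else:
            m[20:35, 20] = True
            for i in range(12):
                m[19 - i, 20 - i] = True
                m[19 - i, 20 + i] = True
        vg = extract_graph(m, spur_length=0)
        oracle = pixel_graph_contracted(m)
        assert nx.is_isomorphic(vg.graph, oracle)

    def test_transposition_invariance(self, synthetic_image):
        skel = skeletonize(synthetic_image.mask).data
        a = extract_graph(skel)
        b = extract_graph(skel.T.copy())
        assert (a.n_nodes, a.n_links) == (b.n_nodes, b.n_links)
        assert sorted(dict(a.graph.degree()).values()) == sorted(
            dict(b.graph.degree()).values()
        )

    def test_clean_tree_is_a_tree(self):
        from fundusgraph.synthetic import clean_tree_spec, generate_vessel_tree

        img = generate_vessel_tree(clean_tree_spec(seed=2))
        vg = extract_graph(skeletonize(img.mask))
        assert vg.n_links == vg.n_nodes - 1

    def test_counts_close_to_ground_truth(self):
        from fundusgraph.features import basic_counts
        from fundusgraph.synthetic import clean_tree_spec, generate_vessel_tree

        img = generate_vessel_tree(clean_tree_spec(seed=6))
        gt = img.tree.counts()
        bc = basic_counts(build_graph(img.mask)).as_dict()
        for k in ("nodes", "links", "endpoints", "bifurcations"):
            assert abs(bc[k] - gt[k]) / gt[k] <= 0.05


class TestWidths:
    def test_rectangle_width(self):
        m = np.zeros((30, 120), bool)
        m[12:17, 10:110] = True
        vg = build_graph(m)
        (edge,) = vg.graph.edges(data=True)
        assert edge[2]["N"] == m.sum()
        assert abs(edge[2]["W"] - 5.0) <= 0.5

    def test_one_pixel_line_width_one(self):
        m = np.zeros((9, 60), bool)
        m[4, 4:54] = True
        vg = build_graph(m)
        (edge,) = vg.graph.edges(data=True)
        assert edge[2]["W"] == 1.0

    def test_pixel_assignment_conserved(self, synthetic_image):
        vg = build_graph(synthetic_image.mask)
        total = sum(d["N"] for *_, d in vg.graph.edges(data=True))
        assert total == synthetic_image.mask.sum()


class TestCentralNode:
    def _line_graph(self):
        m = np.zeros((9, 109), bool)
        m[4, 4:104] = True
        return extract_graph(m)

    def test_exact_position(self):
        vg = self._line_graph()
        vg = assign_central_node(vg, OpticDisc(center=(4.0, 4.0), radius=10.0))
        assert vg.graph.nodes[vg.central]["pos"] == (4.0, 4.0)

    def test_tie_breaks_to_lower_id(self):
        vg = self._line_graph()
        # midpoint is equidistant from both endpoints
        vg = assign_central_node(vg, OpticDisc(center=(4.0, 53.5), radius=100.0))
        assert vg.central == min(vg.graph.nodes)

    def test_too_far_fails(self):
        vg = self._line_graph()
        with pytest.raises(CentralAssignmentError):
            assign_central_node(vg, OpticDisc(center=(4.0, 1000.0), radius=2.0))

    def test_empty_graph_fails(self):
        from fundusgraph.vessel_graph import VesselGraph

        with pytest.raises(CentralAssignmentError):
            assign_central_node(VesselGraph(nx.MultiGraph()), OpticDisc((0, 0), 5))


class TestWeights:
    def test_direct_evaluation(self):
        m = np.zeros((9, 109), bool)
        m[4, 4:104] = True
        vg = extract_graph(m)
        for _, _, d in vg.graph.edges(data=True):
            d["L"], d["W"] = 10, 2
        apply_weights(vg, WeightConfig(l=1, a=-2))
        assert [d["weight"] for *_, d in vg.graph.edges(data=True)] == [2.5]

    def test_width_only_and_unit_configs(self, synthetic_image):
        vg = build_graph(synthetic_image.mask)
        apply_weights(vg, WeightConfig(l=0, a=1))
        assert all(
            d["weight"] == d["W"] for *_, d in vg.graph.edges(data=True)
        )
        apply_weights(vg, WeightConfig(l=0, a=0))
        assert all(d["weight"] == 1.0 for *_, d in vg.graph.edges(data=True))
        apply_weights(vg, WeightConfig(l=1, a=2))
        assert all(d["weight"] > 0 for *_, d in vg.graph.edges(data=True))


class TestSerialization:
    def test_csv_and_graphml(self, tmp_path, synthetic_image):
        vg = build_graph(
            synthetic_image.mask,
            disc=OpticDisc(synthetic_image.disc_center, synthetic_image.disc_radius),
            config=WeightConfig(0, 1),
        )
        vg.to_csv(tmp_path / "nodes.csv", tmp_path / "edges.csv")
        vg.to_graphml(tmp_path / "g.graphml")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_nodes() == vg.n_nodes
        assert back.number_of_edges() == vg.n_links
        import pandas as pd

        nodes = pd.read_csv(tmp_path / "nodes.csv")
        assert (nodes.kind == "central").sum() == 1
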