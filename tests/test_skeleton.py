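"""Skeletonization, MST topology and inter-node measurement."""

import itertools

import numpy as np
import pytest

from phenocloud import (
    ContractionParams,
    PointCloud,
    build_skeleton_graph,
    contract_point_cloud,
    extract_node_positions,
    generate_stem,
    geodesic_node_distance,
    inter_node_length,
    measure_internode_spacings,
)
from conftest import random_rotation


def brute_force_mst_weight(points: np.ndarray) -> float:
    """Minimum spanning-tree weight by exhausting all labeled trees.

    Every labeled tree on n vertices corresponds to a Prufer sequence of
    length n - 2; decoding each sequence enumerates the n^(n-2) spanning
    trees of the complete graph."""
    n = len(points)
    dist = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    if n == 2:
        return dist[0, 1]
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        seq_list = list(seq)
        total = 0.0
        deg = degree[:]
        for v in seq_list:
            leaf = min(i for i in range(n) if deg[i] == 1)
            total += dist[leaf, v]
            deg[leaf] -= 1
            deg[v] -= 1
        last = [i for i in range(n) if deg[i] == 1]
        total += dist[last[0], last[1]]
        best = min(best, total)
    return best


def cylinder_cloud(rng, radius=0.01, length=1.0, n=2000):
    theta = rng.uniform(0, 2 * np.pi, n)
    z = rng.uniform(0, length, n)
    return PointCloud(np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), z]))


class TestContraction:
    def test_cylinder_collapses_to_axis(self, rng):
        """2000 points on a 1 cm tube end within 5 mm of the axis."""
        contracted = contract_point_cloud(cylinder_cloud(rng))
        axis_dist = np.linalg.norm(contracted.points[:, :2], axis=1)
        assert axis_dist.max() < 0.005

    def test_line_is_a_fixed_structure(self):
        t = np.linspace(0.0, 1.0, 300)
        line = PointCloud(np.column_stack([t, np.zeros_like(t), np.zeros_like(t)]))
        contracted = contract_point_cloud(line)
        normal_drift = np.abs(contracted.points[:, 1:]).max()
        assert normal_drift < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            contract_point_cloud(PointCloud([[0, 0, 0], [1, 0, 0], [0, 1, 0]]))

    def test_contraction_shrinks_spread(self, rng):
        cloud = cylinder_cloud(rng)
        rms = lambda pts: np.sqrt(((pts - pts.mean(0)) ** 2).sum(1).mean())
        assert rms(contract_point_cloud(cloud).points) <= rms(cloud.points)

    def test_rotation_equivariance(self, rng):
        """contract(R x) equals R contract(x) to float precision."""
        cloud = cylinder_cloud(rng, n=800)
        R = random_rotation(11)
        a = contract_point_cloud(cloud).points @ R.T
        b = contract_point_cloud(PointCloud(cloud.points @ R.T)).points
        assert np.abs(a - b).max() < 1e-6


class TestSkeletonGraph:
    def test_collinear_points_form_path(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        graph = build_skeleton_graph(PointCloud(pts), sample_spacing=0.1)
        assert graph.total_length == pytest.approx(3.0)
        assert sorted(map(tuple, graph.edges.tolist())) == [(0, 1), (1, 2), (2, 3)]

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_mst_matches_exhaustive_enumeration(self, n, seed):
        pts = np.random.default_rng(seed).uniform(0, 1, (n, 3))
        graph = build_skeleton_graph(PointCloud(pts), sample_spacing=1e-6)
        assert graph.total_length == pytest.approx(brute_force_mst_weight(pts))

    def test_spanning_tree_shape(self, rng):
        pts = rng.normal(size=(100, 3))
        graph = build_skeleton_graph(PointCloud(pts), sample_spacing=1e-6)
        assert graph.edges.shape[0] == graph.nodes.shape[0] - 1
        import networkx as nx

        assert nx.is_tree(graph.graph)

    def test_edge_weights_are_euclidean(self, rng):
        pts = rng.normal(size=(30, 3))
        graph = build_skeleton_graph(PointCloud(pts), sample_spacing=1e-6)
        for (i, j), w in zip(graph.edges, graph.weights):
            assert w == pytest.approx(np.linalg.norm(graph.nodes[i] - graph.nodes[j]))
            assert w > 0

    def test_too_few_vertices(self):
        with pytest.raises(ValueError, match=">= 2"):
            build_skeleton_graph(PointCloud([[0, 0, 0]]), sample_spacing=0.1)


def y_graph(arm_length=0.3, spacing=0.004):
    arms = []
    for d in ([0, 0, 1.0], [1.0, 0, -0.5], [-1.0, 0, -0.5]):
        d = np.asarray(d) / np.linalg.norm(d)
        arms.append(np.outer(np.linspace(0.01, arm_length, 40), d))
    pts = np.vstack(arms + [np.zeros((1, 3))])
    return build_skeleton_graph(PointCloud(pts), sample_spacing=spacing)


class TestNodes:
    def test_y_shape_has_one_branch_three_ends(self):
        graph = y_graph()
        assert graph.branch_nodes.size == 1
        assert graph.end_nodes.size == 3
        nodes = extract_node_positions(graph)
        branch = [n for n in nodes if n.kind == "branch"]
        assert len(branch) == 1 and branch[0].degree == 3

    def test_path_graph_has_no_branch_nodes(self):
        pts = np.column_stack([np.linspace(0, 1, 20), np.zeros(20), np.zeros(20)])
        graph = build_skeleton_graph(PointCloud(pts), sample_spacing=1e-6)
        nodes = extract_node_positions(graph)
        assert sum(n.kind == "branch" for n in nodes) == 0
        assert sum(n.kind == "end" for n in nodes) == 2

    def test_nodes_sorted_by_height(self):
        zs = [n.position[2] for n in extract_node_positions(y_graph())]
        assert zs == sorted(zs)

    def test_inter_node_length_is_euclidean_chord(self):
        graph = y_graph()
        a, b = 0, graph.nodes.shape[0] - 1
        assert inter_node_length(graph, a, b) == pytest.approx(
            np.linalg.norm(graph.nodes[a] - graph.nodes[b]))
        assert inter_node_length(graph, a, a) == 0.0
        # the chord can never exceed the along-tree path
        assert inter_node_length(graph, a, b) <= geodesic_node_distance(graph, a, b) + 1e-12

    def test_invalid_node_id(self):
        with pytest.raises(IndexError):
            inter_node_length(y_graph(), 0, 10_000)

    def test_simple_vertical_distance(self):
        pts = np.array([[0, 0, 0], [0, 0, 0.25]])
        graph = build_skeleton_graph(PointCloud(pts), sample_spacing=1e-6)
        assert inter_node_length(graph, 0, 1) == pytest.approx(0.25)


class TestStemRecovery:
    def test_single_spacing_recovered(self):
        """A stem with two nodes 0.25 m apart measures 0.25 m within 5%."""
        fix = generate_stem([0.25], seed=42)
        graph = build_skeleton_graph(contract_point_cloud(fix.cloud))
        spacings = measure_internode_spacings(graph)
        assert spacings.shape == (1,)
        assert spacings[0] == pytest.approx(0.25, rel=0.05)

    def test_inter_node_invariant_to_rigid_motion(self):
        """Chord lengths depend only on node geometry, not the world frame."""
        fix = generate_stem([0.10, 0.25], seed=7)
        graph = build_skeleton_graph(contract_point_cloud(fix.cloud))
        R = random_rotation(5)
        moved = graph.nodes @ R.T + np.array([3.0, -1.0, 2.0])
        d0 = np.linalg.norm(graph.nodes[0] - graph.nodes[-1])
        d1 = np.linalg.norm(moved[0] - moved[-1])
        assert d1 == pytest.approx(d0, rel=1e-9)
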