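import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phospho3d.clustering import (
    SpatialGraph,
    assign_type_and_centroid,
    build_graphs,
    centrality,
    cluster_closeness,
    find_clusters,
    floyd_warshall,
    geodesics,
    threshold_top_percent,
)
from phospho3d.types import ClusterType, ProximityPair, PairClass, SiteVertex, VertexKind


def _vertex(pos, kind=VertexKind.PHOSPHOSITE, gene="G", tx="ENST1", weight=1):
    alt = "A" if kind is VertexKind.MUTATION else None
    return SiteVertex(gene=gene, transcript=tx, position=pos, ref_residue="S",
                      kind=kind, alt_residue=alt, weight=weight)


def _pair(a, b, d):
    return ProximityPair(a=a, b=b, distance_angstrom=d, best_structure="1AAA:AA",
                         pair_class=PairClass.SITE_SITE,
                         linear_separation=abs(a.position - b.position),
                         cross_chain=False)


def _random_weight_matrix(rng, n, p_edge=0.6):
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p_edge:
            w[i, j] = w[j, i] = rng.uniform(0.5, 10.0)
    return w


def _dijkstra_oracle(w):
    import networkx as nx

    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if np.isfinite(w[i, j]):
            g.add_edge(i, j, weight=w[i, j])
    out = np.full_like(w, np.inf)
    np.fill_diagonal(out, 0.0)
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="weight"):
        for dst, dist in lengths.items():
            out[src, dst] = dist
    return out


class TestBuildGraphs:
    def test_components_split(self):
        a, b, c, d, e = (_vertex(p) for p in (1, 2, 3, 4, 5))
        graphs = build_graphs([_pair(a, b, 1.0), _pair(b, c, 2.0), _pair(d, e, 3.0)])
        assert sorted(len(g.vertices) for g in graphs) == [2, 3]

    def test_no_pairs_no_graphs(self):
        assert build_graphs([]) == []

    def test_partition_matches_union_find_oracle(self):
        rng = np.random.default_rng(5)
        vertices = [_vertex(p) for p in range(1, 13)]
        pairs = []
        for i, j in itertools.combinations(range(12), 2):
            if rng.random() < 0.15:
                pairs.append(_pair(vertices[i], vertices[j], rng.uniform(1, 9)))

        parent = list(range(12))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for p in pairs:
            parent[find(p.a.position - 1)] = find(p.b.position - 1)
        oracle = {}
        for p in pairs:
            for v in (p.a, p.b):
                oracle.setdefault(find(v.position - 1), set()).add(v.position)
        got = {frozenset(v.position for v in g.vertices) for g in build_graphs(pairs)}
        assert got == {frozenset(s) for s in oracle.values()}


class TestGeodesics:
    def test_path_sum(self):
        a, b, c = _vertex(1), _vertex(2), _vertex(3)
        g = geodesics(build_graphs([_pair(a, b, 1.0), _pair(b, c, 2.0)])[0])
        idx = {v.position: i for i, v in
               enumerate(build_graphs([_pair(a, b, 1.0), _pair(b, c, 2.0)])[0].vertices)}
        assert g[idx[1], idx[3]] == pytest.approx(3.0)

    def test_triangle_shortcut(self):
        a, b, c = _vertex(1), _vertex(2), _vertex(3)
        graph = build_graphs([_pair(a, b, 1.0), _pair(b, c, 1.0), _pair(a, c, 5.0)])[0]
        g = geodesics(graph)
        idx = {v.position: i for i, v in enumerate(graph.vertices)}
        assert g[idx[1], idx[3]] == pytest.approx(2.0)

    def test_matches_dijkstra_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            w = _random_weight_matrix(rng, 8)
            assert np.allclose(floyd_warshall(w), _dijkstra_oracle(w))

    def test_disconnected_graph_rejected(self):
        graph = SpatialGraph(vertices=[_vertex(1), _vertex(2)], edges=[])
        with pytest.raises(ValueError, match="disconnected"):
            geodesics(graph)


class TestCentralityAndCc:
    def test_two_vertices_unit_geodesic(self):
        g = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert centrality(g) == pytest.approx([0.5, 0.5])

    def test_three_clique_unit_geodesics(self):
        g = np.ones((3, 3)) - np.eye(3)
        c = centrality(g)
        assert c == pytest.approx([1.0, 1.0, 1.0])
        assert cluster_closeness(c) == pytest.approx(3.0)

    def test_weighted_mode_direct_evaluation(self):
        g = np.array([[0.0, 2.0], [2.0, 0.0]])
        c = centrality(g, weights=np.array([1.0, 3.0]), use_weights=True)
        assert c == pytest.approx([3 * 0.25, 1 * 0.25])

    def test_two_vertices_g2_unweighted_cc(self):
        g = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert cluster_closeness(centrality(g)) == pytest.approx(0.5)

    def test_geodesic_scale_rescales_exponent(self):
        g = np.array([[0.0, 10.0], [10.0, 0.0]])
        assert centrality(g, scale=10.0) == pytest.approx([0.5, 0.5])

    def test_cc_equals_member_resummation(self, planted_run):
        _, clusters, _ = planted_run
        for cl in clusters:
            assert cl.cc_score == pytest.approx(sum(cl.centralities), rel=1e-9)

    def test_non_finite_geodesic_rejected(self):
        g = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError):
            centrality(g)


class TestTypeAndCentroid:
    def test_hybrid_requires_both_kinds(self):
        graph = SpatialGraph(
            vertices=[_vertex(1, VertexKind.MUTATION), _vertex(2, VertexKind.MUTATION),
                      _vertex(3, VertexKind.PHOSPHOSITE)],
            edges=[(0, 1, 1.0), (1, 2, 1.0)])
        cl = assign_type_and_centroid(graph, centrality(geodesics(graph)), "0.0")
        assert cl.cluster_type is ClusterType.HYBRID

    def test_site_only(self):
        graph = SpatialGraph(vertices=[_vertex(1), _vertex(2), _vertex(3)],
                             edges=[(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        cl = assign_type_and_centroid(graph, centrality(geodesics(graph)), "0.0")
        assert cl.cluster_type is ClusterType.SITE_ONLY

    def test_centrality_tie_breaks_to_lower_position(self):
        graph = SpatialGraph(vertices=[_vertex(9), _vertex(4)], edges=[(0, 1, 1.0)])
        c = centrality(geodesics(graph))
        assert c[0] == c[1]
        cl = assign_type_and_centroid(graph, c, "0.0")
        assert cl.centroid.position == 4

    def test_centroid_is_argmax(self, planted_run):
        _, clusters, _ = planted_run
        for cl in clusters:
            assert max(cl.centralities) == pytest.approx(
                cl.centralities[[m.key for m in cl.members].index(cl.centroid.key)])


class TestThreshold:
    def _clusters(self, scores, ctype=ClusterType.HYBRID):
        out = []
        for i, s in enumerate(scores):
            kinds = ([_vertex(1, VertexKind.MUTATION), _vertex(2)]
                     if ctype is ClusterType.HYBRID else [_vertex(1), _vertex(2)])
            out.append(type("C", (), {})())
            from phospho3d.types import Cluster
            out[-1] = Cluster(cluster_id=f"{i}.0", members=kinds,
                              centralities=[s / 2, s / 2], centroid=kinds[0],
                              cc_score=float(s), cluster_type=ctype)
        return out

    def test_top5_of_100_distinct_scores(self):
        retained = threshold_top_percent(self._clusters(range(1, 101)), percent=5)
        assert sorted(c.cc_score for c in retained) == [96, 97, 98, 99, 100]

    def test_single_cluster_degenerate_percentile(self):
        retained = threshold_top_percent(self._clusters([2.5]), percent=5)
        assert len(retained) == 1

    def test_types_thresholded_independently(self):
        hybrid = self._clusters(range(1, 21), ClusterType.HYBRID)
        site = self._clusters(range(101, 121), ClusterType.SITE_ONLY)
        retained = threshold_top_percent(hybrid + site, percent=10)
        by_type = {}
        for c in retained:
            by_type.setdefault(c.cluster_type, []).append(c.cc_score)
        assert sorted(by_type[ClusterType.HYBRID]) == [19, 20]
        assert sorted(by_type[ClusterType.SITE_ONLY]) == [119, 120]

    def test_ties_at_threshold_retained(self):
        retained = threshold_top_percent(self._clusters([1] * 10), percent=5)
        assert len(retained) == 10

    def test_rank_percentile_recorded_for_all(self):
        clusters = self._clusters(range(1, 11))
        threshold_top_percent(clusters, percent=20)
        assert all(c.rank_percentile_within_type is not None for c in clusters)
        assert max(c.rank_percentile_within_type for c in clusters) == 100.0


# --------------------------------------------------------------- properties

@st.composite
def connected_weighted_graphs(draw):
    n = draw(st.integers(min_value=2, max_value=8))
    weights = {}
    # spanning path guarantees connectivity; extra random edges on top
    for i in range(n - 1):
        weights[(i, i + 1)] = draw(st.floats(0.5, 10.0))
    for i, j in itertools.combinations(range(n), 2):
        if (i, j) not in weights and draw(st.booleans()):
            weights[(i, j)] = draw(st.floats(0.5, 10.0))
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    for (i, j), d in weights.items():
        w[i, j] = w[j, i] = d
    return w


@settings(max_examples=60, deadline=None, derandomize=True)
@given(connected_weighted_graphs())
def test_geodesic_matrix_invariants(w):
    g = floyd_warshall(w)
    n = g.shape[0]
    assert np.allclose(g, g.T)
    assert np.allclose(np.diag(g), 0.0)
    assert np.all(g <= w + 1e-9)  # never longer than the direct edge
    for i, j, k in itertools.product(range(n), repeat=3):
        assert g[i, j] <= g[i, k] + g[k, j] + 1e-9


@settings(max_examples=40, deadline=None, derandomize=True)
@given(connected_weighted_graphs(), st.floats(0.5, 10.0))
def test_adding_edge_never_increases_geodesics_or_decreases_cc(w, new_weight):
    n = w.shape[0]
    g_before = floyd_warshall(w)
    w2 = w.copy()
    candidates = [(i, j) for i, j in itertools.combinations(range(n), 2)
                  if not np.isfinite(w[i, j])]
    if not candidates:
        return
    i, j = candidates[0]
    w2[i, j] = w2[j, i] = new_weight
    g_after = floyd_warshall(w2)
    assert np.all(g_after <= g_before + 1e-9)
    cc_before = cluster_closeness(centrality(g_before))
    cc_after = cluster_closeness(centrality(g_after))
    assert cc_after >= cc_before - 1e-9


@settings(max_examples=30, deadline=None, derandomize=True)
@given(connected_weighted_graphs(), st.randoms(use_true_random=False))
def test_cc_invariant_under_vertex_relabeling(w, rnd):
    n = w.shape[0]
    perm = list(range(n))
    rnd.shuffle(perm)
    w_perm = w[np.ix_(perm, perm)]
    cc = cluster_closeness(centrality(floyd_warshall(w)))
    cc_perm = cluster_closeness(centrality(floyd_warshall(w_perm)))
    assert cc == pytest.approx(cc_perm, rel=1e-9)


def test_planted_cluster_outscores_scattered_controls(planted_run, scatter):
    """The planted dense cluster's Cc strictly exceeds every cluster Cc from
    a uniformly scattered control."""
    from phospho3d.pipeline import cluster_dataset

    _, planted_clusters, _ = planted_run
    planted_cc = max(c.cc_score for c in planted_clusters)
    _, control_clusters, _ = cluster_dataset(
        scatter.mutations, scatter.sites, scatter.structures, scatter.transcript_map)
    assert control_clusters, "control fixture should produce clusters"
    assert planted_cc > max(c.cc_score for c in control_clusters)
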