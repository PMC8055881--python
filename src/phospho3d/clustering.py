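"""Spatial cluster discovery on the proximity graph.

Each connected component of the proximity-pair graph is an undirected graph
G = (V, E) whose edge weights are closest-atom distances in Å.  Geodesics
g_ij are all-pairs shortest-path lengths obtained by Floyd–Warshall seeded
with the edge-distance matrix.  Per-vertex centrality is

    c(v_i) = sum_{j != i} w_j * 2^(-g_ij / s)

with w_j = 1 in unweighted ("site") mode or the vertex recurrence weight in
"recurrence" mode, and s a configurable geodesic scale (default 1, i.e. the
exponent is the geodesic in Å).  The cluster closeness score is
Cc = sum_i c(v_i); a high Cc indicates a dense 3D cluster.  The centroid is
the member of maximal centrality.  Within each cluster type (hybrid /
mutation-only / site-only), clusters at or above the top-percent Cc
empirical quantile are retained.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import Cluster, ClusterType, ProximityPair, SiteVertex, VertexKind

REL_TOL = 1e-9


@dataclass
class SpatialGraph:
    """Connected undirected graph of vertices with Å-distance edge weights.

    Edge weights are >= 0: a direct-overlap pair (mutation and phosphosite at
    the same residue) legitimately has distance 0 between distinct vertices.
    """

    vertices: list[SiteVertex]
    edges: list[tuple[int, int, float]] = field(default_factory=list)  # (i, j, weight)

    def weight_matrix(self) -> np.ndarray:
        n = len(self.vertices)
        w = np.full((n, n), np.inf)
        np.fill_diagonal(w, 0.0)
        for i, j, d in self.edges:
            if i == j:
                raise ValueError("self-edge in spatial graph")
            if d < 0:
                raise ValueError("negative edge weight")
            w[i, j] = w[j, i] = min(w[i, j], d)
        return w


def build_graphs(pairs: list[ProximityPair]) -> list[SpatialGraph]:
    """Split the proximity-pair graph into connected components.

    One :class:`SpatialGraph` per component; vertices with no pair never
    appear.  Component order and vertex order within a component are
    deterministic (sorted by vertex key).
    """
    adjacency: dict[tuple, dict[tuple, float]] = {}
    vertex_of: dict[tuple, SiteVertex] = {}
    for p in pairs:
        ka, kb = p.a.key, p.b.key
        vertex_of[ka], vertex_of[kb] = p.a, p.b
        adjacency.setdefault(ka, {})[kb] = min(
            adjacency.get(ka, {}).get(kb, np.inf), p.distance_angstrom)
        adjacency.setdefault(kb, {})[ka] = adjacency[ka][kb]

    seen: set[tuple] = set()
    graphs: list[SpatialGraph] = []
    for start in sorted(adjacency):
        if start in seen:
            continue
        stack, component = [start], []
        seen.add(start)
        while stack:
            k = stack.pop()
            component.append(k)
            for nb in adjacency[k]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        component.sort()
        index = {k: i for i, k in enumerate(component)}
        edges = [
            (index[k], index[nb], d)
            for k in component
            for nb, d in adjacency[k].items()
            if index[k] < index[nb]
        ]
        graphs.append(SpatialGraph(vertices=[vertex_of[k] for k in component], edges=edges))
    return graphs


def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths from a symmetric weight matrix (inf = no edge)."""
    g = np.array(weights, dtype=float)
    n = g.shape[0]
    for k in range(n):
        np.minimum(g, g[:, k:k + 1] + g[k:k + 1, :], out=g)
    return g


def geodesics(graph: SpatialGraph) -> np.ndarray:
    """Geodesic matrix g_ij of a connected graph; errors if disconnected."""
    g = floyd_warshall(graph.weight_matrix())
    if not np.all(np.isfinite(g)):
        raise ValueError("graph is disconnected; pass connected components")
    return g


def centrality(
    g: np.ndarray,
    weights: np.ndarray | None = None,
    use_weights: bool = False,
    scale: float = 1.0,
) -> np.ndarray:
    """Per-vertex centrality c(v_i) = sum_{j != i} w_j * 2^(-g_ij / scale)."""
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite geodesic")
    n = g.shape[0]
    contrib = np.power(2.0, -np.asarray(g, float) / scale)
    np.fill_diagonal(contrib, 0.0)
    if use_weights:
        if weights is None:
            raise ValueError("weighted mode requires per-vertex weights")
        w = np.asarray(weights, float)
        if np.any(w < 1):
            raise ValueError("weights must be >= 1")
        return contrib @ w
    return contrib.sum(axis=1)


def cluster_closeness(c: np.ndarray) -> float:
    """Cluster closeness score Cc = sum_i c(v_i)."""
    return float(np.sum(c))


def assign_type_and_centroid(
    graph: SpatialGraph,
    c: np.ndarray,
    cluster_id: str,
) -> Cluster:
    """Finalize a cluster: type from member kinds; centroid = argmax centrality.

    Centrality ties break deterministically toward the member with the lower
    transcript position, then the lexicographically smaller gene symbol.
    """
    kinds = {v.kind for v in graph.vertices}
    if kinds == {VertexKind.MUTATION}:
        ctype = ClusterType.MUTATION_ONLY
    elif kinds == {VertexKind.PHOSPHOSITE}:
        ctype = ClusterType.SITE_ONLY
    else:
        ctype = ClusterType.HYBRID
    order = sorted(
        range(len(graph.vertices)),
        key=lambda i: (-c[i], graph.vertices[i].position, graph.vertices[i].gene),
    )
    centroid = graph.vertices[order[0]]
    return Cluster(
        cluster_id=cluster_id,
        members=list(graph.vertices),
        centralities=[float(x) for x in c],
        centroid=centroid,
        cc_score=cluster_closeness(c),
        cluster_type=ctype,
    )


def find_clusters(
    pairs: list[ProximityPair],
    vertex_type: str = "recurrence",
    geodesic_scale: float = 1.0,
) -> list[Cluster]:
    """Full clustering: components -> geodesics -> centralities -> Cc.

    ``vertex_type`` is "recurrence" (mutation recurrence as vertex weight;
    phosphosites weigh 1) or "site" (all weights 1).  Cluster IDs are
    "<gene-or-complex index>.<subindex>", assigned deterministically.
    """
    if vertex_type not in ("site", "recurrence"):
        raise ValueError("vertex_type must be 'site' or 'recurrence'")
    graphs = build_graphs(pairs)

    keyed = []  # (gene-set key, min vertex key, graph)
    for graph in graphs:
        gene_key = tuple(sorted({v.gene for v in graph.vertices}))
        keyed.append((gene_key, min(v.key for v in graph.vertices), graph))
    keyed.sort(key=lambda t: (t[0], t[1]))
    group_index: dict[tuple, int] = {}
    sub_counter: dict[tuple, int] = {}
    clusters: list[Cluster] = []
    for gene_key, _, graph in keyed:
        if gene_key not in group_index:
            group_index[gene_key] = len(group_index)
        sub = sub_counter.get(gene_key, 0)
        sub_counter[gene_key] = sub + 1
        cid = f"{group_index[gene_key]}.{sub}"
        g = geodesics(graph)
        w = np.array([v.weight for v in graph.vertices], float)
        c = centrality(g, weights=w, use_weights=(vertex_type == "recurrence"),
                       scale=geodesic_scale)
        clusters.append(assign_type_and_centroid(graph, c, cid))
    return clusters


def threshold_top_percent(
    clusters: list[Cluster],
    percent: float = 5.0,
) -> list[Cluster]:
    """Retain, per cluster type, clusters with Cc at or above the
    (100 - percent)th empirical percentile of that type's Cc distribution.

    Ties at the threshold are retained; every input cluster gets its
    rank percentile (in [0, 100]) recorded in place.
    """
    retained: list[Cluster] = []
    by_type: dict[ClusterType, list[Cluster]] = {}
    for cl in clusters:
        by_type.setdefault(cl.cluster_type, []).append(cl)
    for ctype, group in by_type.items():
        scores = np.array([cl.cc_score for cl in group])
        threshold = float(np.percentile(scores, 100.0 - percent))
        for cl in group:
            cl.rank_percentile_within_type = float(
                100.0 * np.mean(scores <= cl.cc_score))
            if cl.cc_score >= threshold:
                retained.append(cl)
    return retained


def write_cluster_table(clusters: list[Cluster], path) -> None:
    """Write the per-member cluster table (one row per cluster member)."""
    import pandas as pd

    rows = []
    for cl in clusters:
        for v, c in zip(cl.members, cl.centralities):
            rows.append({
                "Cluster_ID": cl.cluster_id,
                "Gene": v.gene,
                "Transcript": v.transcript,
                "Position": v.position,
                "Residue_Label": v.label,
                "Kind": v.kind.value,
                "Weight": v.weight,
                "Centrality": c,
                "Is_Centroid": int(v.key == cl.centroid.key),
                "Cc": cl.cc_score,
                "Cluster_Type": cl.cluster_type.value,
                "Rank_Percentile": cl.rank_percentile_within_type,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
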