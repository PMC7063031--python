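"""Mapper topological-data-analysis pipeline over feature point clouds.

Points are *features* (handcrafted and/or learned): one point per feature,
whose coordinates are that feature's values over every (window, channel)
pair of a dataset.  The pipeline is:

1. build the point cloud and z-score each point's vector;
2. PCA keeping the smallest number of components reaching 99% variance;
3. a 2-D t-SNE lens (perplexity 30);
4. an overlapping axis-aligned cover of the lens (5 divisions per
   dimension, 65% overlap -> 25 regions);
5. Ward partial clustering of each region's points in the reduced space;
6. graph assembly: one node per cluster, an edge whenever two clusters
   share a point.

Three scenarios are supported: ``A`` (handcrafted features only), ``B``
(learned features only) and ``C`` (both).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .handcrafted import FeatureTable

__all__ = ["PointCloud", "Lens", "Cover", "TopoGraph", "MapperConfig",
           "build_point_cloud", "reduce_pca", "tsne_lens", "build_cover",
           "partial_cluster", "assemble_graph", "run_scenario"]


@dataclass
class PointCloud:
    """One point per feature; coordinates are values over windows x channels."""

    points: np.ndarray        # (n_features, n_windows * n_channels)
    ids: list[str]            # unique feature names
    labels: list[str]         # functional group or block label per feature

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be 2-D")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("feature ids must be unique")
        if not (len(self.ids) == len(self.labels) == self.points.shape[0]):
            raise ValueError("ids/labels/points length mismatch")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class Lens:
    coords: np.ndarray  # (n_points, 2)
    quality: float      # final embedding divergence (KL), lower is better

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)


@dataclass
class Cover:
    """k x k axis-aligned overlapping rectangles tiling the lens bounding box."""

    lows: np.ndarray   # (n_regions, dims)
    highs: np.ndarray  # (n_regions, dims)
    k: int
    overlap: float

    def __len__(self) -> int:
        return len(self.lows)

    def membership(self, coords: np.ndarray) -> list[np.ndarray]:
        """Point indices inside each region (closed intervals)."""
        coords = np.asarray(coords)
        out = []
        for lo, hi in zip(self.lows, self.highs):
            inside = np.all((coords >= lo) & (coords <= hi), axis=1)
            out.append(np.where(inside)[0])
        return out


@dataclass
class TopoGraph:
    graph: nx.Graph
    ids: list[str]
    labels: list[str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def member_union(self) -> set[int]:
        out: set[int] = set()
        for _, data in self.graph.nodes(data=True):
            out |= set(data["members"])
        return out

    def membership_partition(self) -> frozenset[frozenset[int]]:
        """Node member sets as a canonical (order-free) structure."""
        return frozenset(frozenset(d["members"])
                         for _, d in self.graph.nodes(data=True))

    def composition(self, node) -> dict[str, float]:
        members = self.graph.nodes[node]["members"]
        labels = [self.labels[i] for i in members]
        return {lab: labels.count(lab) / len(labels) for lab in set(labels)}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": [
                {"id": str(n),
                 "members": [self.ids[i] for i in d["members"]],
                 "composition": self.composition(n)}
                for n, d in self.graph.nodes(data=True)
            ],
            "edges": [[str(u), str(v)] for u, v in self.graph.edges],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(str(n), members=",".join(self.ids[i] for i in d["members"]))
        for u, v in self.graph.edges:
            g.add_edge(str(u), str(v))
        nx.write_graphml(g, path)


@dataclass(frozen=True)
class MapperConfig:
    pca_variance: float = 0.99
    perplexity: float = 30.0
    lens_dims: int = 2
    k: int = 5
    overlap: float = 0.65
    #: cluster in the PCA-reduced space (True) or the raw point space
    cluster_in_reduced: bool = True
    #: use the (k+1)^dims vertex-centred cover instead of k^dims cells
    vertex_cover: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# pipeline steps


def build_point_cloud(tables: FeatureTable | Sequence[FeatureTable],
                      scenario: str = "A") -> PointCloud:
    """Assemble the feature-major point cloud for a scenario.

    ``A`` expects the handcrafted table, ``B`` the learned table, ``C`` both
    (handcrafted first).  Each point is z-scored along its own vector.
    """
    if isinstance(tables, FeatureTable):
        tables = [tables]
    scenario = scenario.upper()
    if scenario in ("A", "B"):
        if len(tables) != 1:
            raise ValueError(f"scenario {scenario} takes exactly one table")
        table = tables[0]
    elif scenario == "C":
        if len(tables) != 2:
            raise ValueError("scenario C takes (handcrafted, learned) tables")
        table = tables[0].concat_features(tables[1])
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    pts = table.feature_matrix().copy()
    mu = pts.mean(axis=1, keepdims=True)
    sd = pts.std(axis=1, keepdims=True)
    pts = (pts - mu) / np.maximum(sd, 1e-12)
    return PointCloud(pts, list(table.feature_names), list(table.feature_labels))


def reduce_pca(cloud: PointCloud, variance: float = 0.99,
               seed: int = 0) -> tuple[np.ndarray, int]:
    """Project to the smallest number of components reaching the variance
    target; returns ``(reduced points, n_components)``."""
    if len(cloud) < 2:
        raise ValueError("need at least 2 points")
    max_comp = min(cloud.points.shape) - 1
    pca = PCA(n_components=max_comp, random_state=seed)
    reduced = pca.fit_transform(cloud.points)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance) + 1)
    n_comp = min(n_comp, max_comp)
    return reduced[:, :n_comp], n_comp


def tsne_lens(reduced: np.ndarray, perplexity: float = 30.0, dims: int = 2,
              seed: int = 0) -> Lens:
    """Deterministic (given seed) t-SNE lens; reports the final divergence."""
    n = len(reduced)
    if perplexity >= n:
        warnings.warn(f"perplexity {perplexity} >= number of points {n}; "
                      "clamping", stacklevel=2)
        perplexity = max(1.0, (n - 1) / 3.0)
    elif n <= 3 * perplexity:
        warnings.warn(f"only {n} points for perplexity {perplexity}; "
                      "lens may be unstable", stacklevel=2)
    X = np.asarray(reduced, dtype=np.float64)
    # centre and scale globally so the lens is exactly invariant to uniform
    # translation/scaling of the point cloud
    X = X - X.mean(axis=0)
    spread = np.sqrt(np.mean(X ** 2))
    if spread > 0:
        X = X / spread
    tsne = TSNE(n_components=dims, perplexity=perplexity, random_state=seed,
                init="pca", method="exact" if n < 1500 else "barnes_hut")
    coords = tsne.fit_transform(X)
    return Lens(coords, float(tsne.kl_divergence_))


def build_cover(lens: Lens | np.ndarray, k: int = 5, overlap: float = 0.65,
                vertex_cover: bool = False) -> Cover:
    """Overlapping axis-aligned cover of the lens bounding box.

    The box is split into ``k`` cells per dimension of side ``H``; each
    region is its cell expanded symmetrically to side ``D = H / (1 -
    overlap)`` so adjacent regions share a fraction ``overlap`` of their
    extent.  With ``vertex_cover`` the regions are centred on the ``(k+1)``
    cell vertices per dimension instead.
    """
    coords = lens.coords if isinstance(lens, Lens) else np.asarray(lens)
    if coords.size == 0:
        raise ValueError("empty lens")
    if not 0 <= overlap < 1:
        raise ValueError("overlap fraction must be in [0, 1)")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    H = span / k
    D = H / (1.0 - overlap)
    dims = coords.shape[1]
    if vertex_cover:
        centers_1d = [lo[d] + H[d] * np.arange(k + 1) for d in range(dims)]
    else:
        centers_1d = [lo[d] + H[d] * (np.arange(k) + 0.5) for d in range(dims)]
    grids = np.meshgrid(*centers_1d, indexing="ij")
    centers = np.stack([g.ravel() for g in grids], axis=1)
    lows = centers - D / 2.0
    highs = centers + D / 2.0
    # tiny expansion so boundary points are always covered
    pad = 1e-9 * span
    lows -= pad
    highs += pad
    return Cover(lows, highs, k, overlap)


def _first_gap_threshold(merge_distances: np.ndarray) -> float | None:
    """First-gap heuristic: histogram the sorted merge distances with
    ceil(sqrt(n)) bins and cut at the first empty bin."""
    d = np.sort(merge_distances)
    d = d[d > 0]
    if len(d) == 0:
        return None
    # ceil(sqrt(n)) + 1 bins: the extra bin lets a dominant final merge
    # open a gap even in very small regions (e.g. two distant pairs)
    nbins = int(np.ceil(np.sqrt(len(d)))) + 1
    counts, edges = np.histogram(d, bins=nbins)
    empty = np.where(counts == 0)[0]
    if len(empty) == 0:
        return None
    return float(edges[empty[0]])


def partial_cluster(points: np.ndarray) -> list[np.ndarray]:
    """Ward clustering of one region's points; returns index groups.

    The dendrogram is cut with the first-gap heuristic on the merge
    distances, falling back to a single cluster.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        return []
    if n == 1:
        return [np.array([0])]
    Z = linkage(points, method="ward")
    thr = _first_gap_threshold(Z[:, 2])
    if thr is None:
        return [np.arange(n)]
    assignment = fcluster(Z, t=thr, criterion="distance")
    return [np.where(assignment == c)[0] for c in np.unique(assignment)]


def assemble_graph(region_clusters: Sequence[Sequence[np.ndarray]],
                   ids: Sequence[str], labels: Sequence[str]) -> TopoGraph:
    """Combine per-region clusterings into the topological graph.

    ``region_clusters[r]`` holds clusters of *global* point indices for
    region ``r``; nodes are clusters, edges join clusters sharing a point.
    """
    g = nx.Graph()
    node_members: list[frozenset[int]] = []
    for r, clusters in enumerate(region_clusters):
        for c, members in enumerate(clusters):
            node = (r, c)
            member_set = frozenset(int(i) for i in members)
            g.add_node(node, members=sorted(member_set))
            node_members.append(member_set)
    nodes = list(g.nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            mi = frozenset(g.nodes[nodes[i]]["members"])
            mj = frozenset(g.nodes[nodes[j]]["members"])
            if mi & mj:
                g.add_edge(nodes[i], nodes[j])
    return TopoGraph(g, list(ids), list(labels))


def run_scenario(tables: FeatureTable | Sequence[FeatureTable],
                 scenario: str = "A",
                 config: MapperConfig = MapperConfig()) -> tuple[TopoGraph, dict]:
    """End-to-end Mapper run; returns the graph and a report dict."""
    cloud = build_point_cloud(tables, scenario)
    reduced, n_comp = reduce_pca(cloud, config.pca_variance, config.seed)
    lens = tsne_lens(reduced, config.perplexity, config.lens_dims, config.seed)
    cover = build_cover(lens, config.k, config.overlap, config.vertex_cover)
    member_lists = cover.membership(lens.coords)
    cluster_space = reduced if config.cluster_in_reduced else cloud.points
    region_clusters = []
    for members in member_lists:
        clusters = partial_cluster(cluster_space[members])
        region_clusters.append([members[c] for c in clusters])
    graph = assemble_graph(region_clusters, cloud.ids, cloud.labels)
    report = {
        "scenario": scenario.upper(),
        "n_points": len(cloud),
        "n_pca_components": n_comp,
        "lens_divergence": lens.quality,
        "n_regions": len(cover),
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "node_composition": {str(n): graph.composition(n)
                             for n in graph.graph.nodes},
    }
    return graph, report
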