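import numpy as np
import pytest

from emglens.convnet import extract_learned_features
from emglens.mapper_tda import (Cover, MapperConfig, PointCloud,
                                assemble_graph, build_cover,
                                build_point_cloud, partial_cluster,
                                reduce_pca, run_scenario, tsne_lens)
from emglens.signal_io import WindowedDataset


class TestPointCloud:
    def test_scenario_a_has_79_points(self, small_table):
        cloud = build_point_cloud(small_table, "A")
        assert len(cloud) == 79
        assert cloud.points.shape[1] == small_table.n_windows * 10

    def test_scenario_b_has_384_points_at_default_width(self, small_dataset):
        from emglens.convnet import build_model
        model = build_model(seed=0)  # default 6 blocks x 64 maps
        subset = WindowedDataset(small_dataset.windows[:4],
                                 dict(small_dataset.split))
        table = extract_learned_features(model, subset)
        cloud = build_point_cloud(table, "B")
        assert len(cloud) == 384

    def test_scenario_c_concatenates(self, small_table, trained_tiny_model,
                                     small_dataset):
        subset = WindowedDataset(small_dataset.windows[::3],
                                 dict(small_dataset.split))
        learned = extract_learned_features(trained_tiny_model, subset)
        cloud = build_point_cloud([small_table, learned], "C")
        assert len(cloud) == 79 + trained_tiny_model.config.n_blocks * \
            trained_tiny_model.config.feature_maps

    def test_points_are_z_scored(self, small_table):
        cloud = build_point_cloud(small_table, "A")
        np.testing.assert_allclose(cloud.points.mean(axis=1), 0, atol=1e-9)
        sds = cloud.points.std(axis=1)
        assert np.all((np.isclose(sds, 1.0)) | (sds < 1e-9))

    def test_mismatched_window_sets_rejected(self, small_table,
                                             trained_tiny_model,
                                             small_dataset):
        other = WindowedDataset(small_dataset.windows[:5],
                                dict(small_dataset.split))
        learned = extract_learned_features(trained_tiny_model, other)
        with pytest.raises(ValueError):
            build_point_cloud([small_table, learned], "C")


class TestReducePCA:
    def test_planar_cloud_needs_two_components(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 40))
        coeffs = rng.standard_normal((30, 2))
        cloud = PointCloud(coeffs @ basis, [f"f{i}" for i in range(30)],
                           ["g"] * 30)
        _, n = reduce_pca(cloud, 0.99)
        assert n == 2

    def test_reconstruction_error_within_variance_budget(self, small_table):
        cloud = build_point_cloud(small_table, "A")
        reduced, n = reduce_pca(cloud, 0.99)
        total_var = np.var(cloud.points - cloud.points.mean(0), axis=0).sum()
        kept_var = np.var(reduced, axis=0).sum()
        assert kept_var >= 0.99 * total_var

    def test_isotropic_gaussian_keeps_most_dimensions(self):
        rng = np.random.default_rng(1)
        d = 40
        cloud = PointCloud(rng.standard_normal((400, d)),
                           [f"f{i}" for i in range(400)], ["g"] * 400)
        _, n = reduce_pca(cloud, 0.99)
        assert 0.9 * d <= n <= d


class TestTsneLens:
    def test_separated_blobs_stay_separated(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((40, 5))
        b = rng.standard_normal((40, 5)) + 60.0
        pts = np.vstack([a, b])
        lens = tsne_lens(pts, perplexity=10, seed=0)
        ca = lens.coords[:40].mean(axis=0)
        cb = lens.coords[40:].mean(axis=0)
        within = np.mean([np.linalg.norm(lens.coords[:40] - ca, axis=1).mean(),
                          np.linalg.norm(lens.coords[40:] - cb, axis=1).mean()])
        assert np.linalg.norm(ca - cb) / within > 2.0

    def test_same_seed_identical(self):
        pts = np.random.default_rng(3).standard_normal((50, 4))
        l1 = tsne_lens(pts, perplexity=10, seed=7)
        l2 = tsne_lens(pts, perplexity=10, seed=7)
        np.testing.assert_array_equal(l1.coords, l2.coords)
        assert l1.quality == l2.quality

    def test_excess_perplexity_warns(self):
        pts = np.random.default_rng(4).standard_normal((20, 3))
        with pytest.warns(UserWarning):
            tsne_lens(pts, perplexity=30, seed=0)


class TestCover:
    def test_25_regions(self):
        coords = np.random.default_rng(5).uniform(size=(100, 2))
        cover = build_cover(coords, k=5, overlap=0.65)
        assert len(cover) == 25

    def test_every_point_covered(self):
        coords = np.random.default_rng(6).standard_normal((200, 2)) * 10
        cover = build_cover(coords, k=5, overlap=0.65)
        members = cover.membership(coords)
        counts = np.zeros(len(coords), dtype=int)
        for m in members:
            counts[m] += 1
        assert counts.min() >= 1

    def test_zero_overlap_partitions(self):
        coords = np.random.default_rng(7).uniform(size=(300, 2))
        cover = build_cover(coords, k=5, overlap=0.0)
        members = cover.membership(coords)
        counts = np.zeros(len(coords), dtype=int)
        for m in members:
            counts[m] += 1
        # interior points fall in exactly one cell (boundaries may share)
        assert np.mean(counts == 1) > 0.95
        assert counts.min() >= 1

    def test_cell_centers_multiply_covered_at_065(self):
        # brute-force membership check for points at the cell centres
        coords = np.random.default_rng(8).uniform(size=(50, 2))
        cover = build_cover(coords, k=5, overlap=0.65)
        lo = coords.min(axis=0)
        H = (coords.max(axis=0) - lo) / 5
        centers = np.array([[lo[0] + H[0] * (i + 0.5), lo[1] + H[1] * (j + 0.5)]
                            for i in range(5) for j in range(5)])
        counts = np.zeros(len(centers), dtype=int)
        for m in cover.membership(centers):
            counts[m] += 1
        assert np.all(counts[1:-1] > 1)

    def test_overlap_one_rejected(self):
        with pytest.raises(ValueError):
            build_cover(np.zeros((3, 2)), overlap=1.0)

    def test_vertex_variant_region_count(self):
        coords = np.random.default_rng(9).uniform(size=(50, 2))
        cover = build_cover(coords, k=5, overlap=0.65, vertex_cover=True)
        assert len(cover) == 36


class TestPartialCluster:
    def test_identical_points_one_cluster(self):
        clusters = partial_cluster(np.zeros((8, 3)))
        assert len(clusters) == 1
        assert len(clusters[0]) == 8

    def test_two_far_pairs_two_clusters(self):
        pts = np.array([[0.0, 0], [0.1, 0], [100.0, 0], [100.1, 0]])
        clusters = partial_cluster(pts)
        assert len(clusters) == 2
        sets = {frozenset(c.tolist()) for c in clusters}
        assert sets == {frozenset({0, 1}), frozenset({2, 3})}

    def test_singleton(self):
        clusters = partial_cluster(np.array([[1.0, 2.0]]))
        assert len(clusters) == 1 and list(clusters[0]) == [0]

    def test_clusters_partition_region(self):
        pts = np.random.default_rng(10).standard_normal((30, 4))
        clusters = partial_cluster(pts)
        all_idx = sorted(int(i) for c in clusters for i in c)
        assert all_idx == list(range(30))


class TestAssembleGraph:
    def test_identical_points_complete_graph(self):
        # same 3 points clustered in 4 regions -> complete graph on 4 nodes
        region_clusters = [[np.array([0, 1, 2])] for _ in range(4)]
        g = assemble_graph(region_clusters, ["a", "b", "c"], ["x"] * 3)
        assert g.n_nodes == 4
        assert g.n_edges == 6

    def test_disjoint_clusters_no_edges(self):
        region_clusters = [[np.array([0, 1])], [np.array([2, 3])]]
        g = assemble_graph(region_clusters, list("abcd"), ["x"] * 4)
        assert g.n_edges == 0

    def test_20_point_brute_force_oracle(self):
        """Steps 3-5 against an independent brute-force implementation."""
        from scipy.cluster.hierarchy import fcluster, linkage

        rng = np.random.default_rng(11)
        lens = np.vstack([rng.standard_normal((10, 2)),
                          rng.standard_normal((10, 2)) + 8.0])
        space = lens  # cluster in the lens space itself for the toy
        k, p = 3, 0.4
        cover = build_cover(lens, k=k, overlap=p)
        member_lists = cover.membership(lens)
        region_clusters = [[m[c] for c in partial_cluster(space[m])]
                           for m in member_lists]
        g = assemble_graph(region_clusters,
                           [str(i) for i in range(20)], ["x"] * 20)

        # --- oracle: explicit region geometry and membership ---
        lo, hi = lens.min(axis=0), lens.max(axis=0)
        H = (hi - lo) / k
        D = H / (1 - p)
        oracle_nodes = []
        for i in range(k):
            for j in range(k):
                c = lo + H * (np.array([i, j]) + 0.5)
                inside = [n for n in range(20)
                          if abs(lens[n, 0] - c[0]) <= D[0] / 2 + 1e-8
                          and abs(lens[n, 1] - c[1]) <= D[1] / 2 + 1e-8]
                if not inside:
                    continue
                if len(inside) == 1:
                    oracle_nodes.append(frozenset(inside))
                    continue
                Z = linkage(space[inside], method="ward")
                d = np.sort(Z[:, 2])
                d = d[d > 0]
                nb = int(np.ceil(np.sqrt(len(d)))) + 1
                counts, edges = np.histogram(d, bins=nb)
                zero = np.where(counts == 0)[0]
                if len(zero) == 0:
                    oracle_nodes.append(frozenset(inside))
                    continue
                labels = fcluster(Z, t=edges[zero[0]], criterion="distance")
                for lab in np.unique(labels):
                    oracle_nodes.append(frozenset(
                        np.array(inside)[labels == lab].tolist()))
        oracle_edges = sum(
            1 for a in range(len(oracle_nodes))
            for b in range(a + 1, len(oracle_nodes))
            if oracle_nodes[a] & oracle_nodes[b])

        assert g.membership_partition() == frozenset(oracle_nodes)
        assert g.n_edges == oracle_edges


class TestRunScenario:
    @pytest.fixture(scope="class")
    def scenario_a(self, small_table):
        return run_scenario(small_table, "A", MapperConfig(seed=0))

    def test_report_contents(self, scenario_a):
        graph, report = scenario_a
        assert report["n_points"] == 79
        assert report["n_regions"] == 25
        assert report["n_nodes"] == graph.n_nodes

    def test_member_union_covers_clustered_points(self, scenario_a,
                                                  small_table):
        graph, _ = scenario_a
        assert graph.member_union() == set(range(79))

    def test_fixed_seed_reproducible(self, small_table, scenario_a):
        graph2, report2 = run_scenario(small_table, "A", MapperConfig(seed=0))
        graph, report = scenario_a
        assert graph.membership_partition() == graph2.membership_partition()
        assert report["n_edges"] == report2["n_edges"]

    def test_groups_cluster_better_than_permuted_null(self, scenario_a):
        """Node purity vs. a label-permuted null (permutation baseline)."""
        graph, _ = scenario_a
        rng = np.random.default_rng(0)

        def mean_purity(labels):
            vals = []
            for _, d in graph.graph.nodes(data=True):
                members = d["members"]
                if len(members) < 2:
                    continue
                labs = [labels[i] for i in members]
                vals.append(max(labs.count(l) for l in set(labs)) / len(labs))
            return np.mean(vals)

        observed = mean_purity(graph.labels)
        null = [mean_purity(list(rng.permutation(graph.labels)))
                for _ in range(30)]
        assert observed > np.mean(null)

    def test_uniform_affine_deformation_invariance(self, small_table):
        """Translating/scaling every point leaves node membership unchanged."""
        cloud = build_point_cloud(small_table, "A")
        g1, _ = run_scenario(small_table, "A", MapperConfig(seed=1))
        shifted = PointCloud(cloud.points * 3.0 + 11.0, cloud.ids, cloud.labels)
        # re-run the tail of the pipeline on the deformed cloud
        from emglens.mapper_tda import (assemble_graph, build_cover,
                                        partial_cluster, reduce_pca, tsne_lens)
        red1, _ = reduce_pca(cloud, 0.99, seed=1)
        red2, _ = reduce_pca(shifted, 0.99, seed=1)
        l1 = tsne_lens(red1, 30, seed=1)
        l2 = tsne_lens(red2, 30, seed=1)
        for red, lens, tag in ((red1, l1, "base"), (red2, l2, "deformed")):
            cover = build_cover(lens, 5, 0.65)
            members = cover.membership(lens.coords)
            rc = [[m[c] for c in partial_cluster(red[m])] for m in members]
            graph = assemble_graph(rc, cloud.ids, cloud.labels)
            if tag == "base":
                base_partition = graph.membership_partition()
            else:
                assert graph.membership_partition() == base_partition

    def test_missing_model_for_b(self, small_table):
        with pytest.raises(ValueError):
            build_point_cloud([small_table, small_table], "A")


class TestExports:
    def test_json_and_graphml(self, small_table, tmp_path):
        graph, _ = run_scenario(small_table, "A", MapperConfig(seed=0))
        graph.to_json(tmp_path / "g.json")
        graph.to_graphml(tmp_path / "g.graphml")
        import json
        with open(tmp_path / "g.json") as fh:
            payload = json.load(fh)
        assert len(payload["nodes"]) == graph.n_nodes
        assert len(payload["edges"]) == graph.n_edges
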