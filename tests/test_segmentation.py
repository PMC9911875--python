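"""Plane fitting, leveling, colour split, clustering and merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canopyrecon.cloud import ColoredPointCloud
from canopyrecon.geometry import rotation_about_axis
from canopyrecon.segmentation import (
    ClusterBounds,
    color_segment,
    density_cluster,
    exg_index,
    extract_plants,
    fit_ground_plane,
    level_cloud,
    merge_clusters,
    otsu_threshold,
    segment_plants,
    SegmentationParams,
)
from canopyrecon.synthetic import labeled_row_cloud


def cloud_of(points, colors=None):
    points = np.asarray(points, dtype=float)
    if colors is None:
        colors = np.full((len(points), 3), 0.5)
    return ColoredPointCloud(points, colors)


class TestGroundPlane:
    def test_noisy_z0_plane_with_outliers(self):
        rng = np.random.default_rng(0)
        plane = np.column_stack([rng.random(1000), rng.random(1000),
                                 np.zeros(1000)])
        outliers = np.column_stack([rng.random(50), rng.random(50),
                                    np.full(50, 0.5)])
        model = fit_ground_plane(cloud_of(np.vstack([plane, outliers])),
                                 dist_thresh=0.005, iters=200, seed=1)
        np.testing.assert_allclose(model.n, [0, 0, 1], atol=1e-6)
        assert model.d == pytest.approx(0.0, abs=1e-6)
        assert len(model.inlier_indices) >= 1000

    def test_exact_offset_plane(self):
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.random(100), rng.random(100),
                               np.full(100, 0.3)])
        model = fit_ground_plane(cloud_of(pts), seed=0)
        np.testing.assert_allclose(model.n, [0, 0, 1], atol=1e-9)
        assert model.d == pytest.approx(-0.3, abs=1e-9)

    def test_three_points_exact_plane(self):
        pts = [[0, 0, 0.1], [1, 0, 0.1], [0, 1, 0.1]]
        model = fit_ground_plane(cloud_of(pts), seed=0)
        np.testing.assert_allclose(model.n, [0, 0, 1], atol=1e-9)
        assert model.d == pytest.approx(-0.1)

    def test_collinear_cloud_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            fit_ground_plane(cloud_of(pts), iters=20, seed=0)

    def test_seeded_fit_is_deterministic(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.random(200), rng.random(200),
                               rng.normal(0, 0.002, 200)])
        m1 = fit_ground_plane(cloud_of(pts), seed=7)
        m2 = fit_ground_plane(cloud_of(pts), seed=7)
        np.testing.assert_array_equal(m1.n, m2.n)


class TestLeveling:
    def test_already_level_plane_identity(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.random(50), rng.random(50), np.zeros(50)])
        model = fit_ground_plane(cloud_of(pts), seed=0)
        _, T = level_cloud(cloud_of(pts), model)
        np.testing.assert_allclose(T.M, np.eye(4), atol=1e-9)

    def test_tilted_plane_levels_to_z0(self):
        rng = np.random.default_rng(1)
        flat = np.column_stack([rng.random(500), rng.random(500),
                                np.zeros(500)])
        R = rotation_about_axis([1, 0, 0], np.radians(10.0))
        tilted = flat @ R.T + [0, 0, 0.2]
        cloud = cloud_of(tilted)
        model = fit_ground_plane(cloud, seed=0)
        leveled, _ = level_cloud(cloud, model)
        refit = fit_ground_plane(leveled, seed=0)
        np.testing.assert_allclose(np.abs(refit.n), [0, 0, 1], atol=1e-6)
        assert refit.d == pytest.approx(0.0, abs=1e-6)
        assert np.abs(leveled.points[:, 2]).max() < 1e-6


class TestColorSplit:
    @pytest.mark.parametrize(
        "rgb,expect",
        [((50, 200, 50), 300.0), ((120, 120, 120), 0.0), ((200, 50, 50), -150.0)],
    )
    def test_excess_green_arithmetic(self, rgb, expect):
        assert exg_index(np.array([rgb]))[0] == expect

    def test_otsu_separates_two_level_set(self):
        vals = np.array([10, 10, 10, 200, 200, 200], dtype=float)
        t = otsu_threshold(vals)
        assert 10 < t < 200
        assert np.array_equal(vals > t, [False] * 3 + [True] * 3)

    def test_otsu_bimodal_mixture_separates_the_modes(self):
        # the histogram gap between the modes gives exactly tied variances;
        # the tie rule picks the lowest gap edge, which still yields a
        # perfect separation of the two populations
        rng = np.random.default_rng(3)
        low = rng.normal(-100, 20, 1000)
        high = rng.normal(300, 20, 1000)
        t = otsu_threshold(np.concatenate([low, high]))
        assert low.max() <= t < high.min()

    def test_otsu_constant_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full(10, 5.0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_otsu_equals_exhaustive_search(self, seed):
        """The chosen edge maximises between-class variance over all edges,
        and exact ties resolve to the lowest edge."""
        rng = np.random.default_rng(seed)
        vals = np.concatenate([
            rng.normal(0, 1, 150), rng.normal(rng.uniform(2, 8), 1, 100)
        ])
        bins = 64
        t = otsu_threshold(vals, bins=bins)
        hist, edges = np.histogram(vals, bins=bins,
                                   range=(vals.min(), vals.max()))
        centers = (edges[:-1] + edges[1:]) / 2
        variances = []
        for k in range(bins - 1):  # split after bin k
            w0 = hist[: k + 1].sum()
            w1 = hist[k + 1:].sum()
            if w0 == 0 or w1 == 0:
                variances.append(0.0)
            else:
                mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / w0
                mu1 = (hist[k + 1:] * centers[k + 1:]).sum() / w1
                variances.append(w0 * w1 * (mu0 - mu1) ** 2)
        variances = np.asarray(variances)
        # maximisers up to float round-off (empty gap bins tie exactly)
        tied = np.nonzero(variances >= variances.max() * (1 - 1e-9))[0]
        assert t == pytest.approx(edges[tied[0] + 1])

    def test_green_grey_partition(self):
        rng = np.random.default_rng(4)
        n = 200
        pts = rng.random((2 * n, 3))
        colors = np.vstack([
            np.tile([0.1, 0.8, 0.1], (n, 1)),  # green
            np.tile([0.5, 0.5, 0.5], (n, 1)),  # grey
        ])
        plant, soil = color_segment(ColoredPointCloud(pts, colors))
        assert len(plant) == n and len(soil) == n
        assert np.all(plant.colors[:, 1] > 0.7)

    def test_constant_colour_all_soil_with_warning(self):
        cloud = cloud_of(np.random.default_rng(0).random((20, 3)))
        with pytest.warns(UserWarning, match="constant"):
            plant, soil = color_segment(cloud)
        assert len(plant) == 0 and len(soil) == 20

    def test_partition_conserves_points(self, sampled_cloud):
        plant, soil = color_segment(sampled_cloud)
        assert len(plant) + len(soil) == len(sampled_cloud)


def eps_graph_components(points, eps):
    """Brute-force connected components of the eps-neighbourhood graph."""
    n = len(points)
    labels = -np.ones(n, dtype=int)
    current = 0
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    adj = d <= eps
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = current
        while stack:
            j = stack.pop()
            for k in np.nonzero(adj[j])[0]:
                if labels[k] < 0:
                    labels[k] = current
                    stack.append(k)
        current += 1
    return labels


class TestDensityCluster:
    def test_two_blobs_two_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.01, (100, 3))
        b = rng.normal(0, 0.01, (100, 3)) + [0.5, 0, 0]
        clusters = density_cluster(cloud_of(np.vstack([a, b])),
                                   eps=0.04, min_points=40)
        assert len(clusters) == 2
        sizes = sorted(len(c.member_indices) for c in clusters)
        assert sizes == [100, 100]

    def test_small_blob_below_min_points_is_noise(self):
        rng = np.random.default_rng(1)
        blob = rng.normal(0, 0.005, (30, 3))
        assert density_cluster(cloud_of(blob), eps=0.04, min_points=40) == []

    def test_chain_within_eps_is_one_cluster(self):
        pts = np.column_stack([np.arange(50) * 0.03, np.zeros(50), np.zeros(50)])
        clusters = density_cluster(cloud_of(pts), eps=0.04, min_points=2)
        assert len(clusters) == 1
        assert len(clusters[0].member_indices) == 50

    def test_matches_eps_graph_components_oracle(self):
        """Where every point is core, density clustering is exactly the
        connected components of the eps graph."""
        rng = np.random.default_rng(2)
        blobs = [rng.normal(0, 0.02, (rng.integers(60, 200), 3))
                 + rng.uniform(-0.5, 0.5, 3) for _ in range(6)]
        pts = np.vstack(blobs)[:2000]
        eps, min_points = 0.05, 5
        # precondition for the oracle: all points are core points
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        assert ((d <= eps).sum(axis=1) >= min_points).all()
        expect = eps_graph_components(pts, eps)
        clusters = density_cluster(cloud_of(pts), eps=eps, min_points=min_points)
        assert len(clusters) == len(np.unique(expect))
        got = -np.ones(len(pts), dtype=int)
        for lab, c in enumerate(clusters):
            got[c.member_indices] = lab
        # label-set equality up to renaming
        mapping = {}
        for e, g in zip(expect, got):
            assert g >= 0
            assert mapping.setdefault(e, g) == g

    def test_cluster_bounds_and_center(self):
        pts = np.array([[0, 0.1, 0], [0.01, 0.3, 0.02], [0.02, 0.2, 0.01]])
        c = ClusterBounds.from_points(pts, np.arange(3))
        assert c.center(axis=1) == pytest.approx(0.2)
        assert c.mins[1] <= c.center(1) <= c.maxs[1]


def bounds(ymin, ymax, idx):
    return ClusterBounds([0.0, ymin, 0.0], [0.1, ymax, 0.1], idx)


class TestMergeClusters:
    def test_contained_center_absorbed(self):
        a = bounds(0.00, 0.30, np.array([0, 1]))
        b = bounds(0.10, 0.14, np.array([2]))  # centre 0.12 inside A
        merged = merge_clusters([a, b], axis=1)
        assert len(merged) == 1
        assert merged[0].mins[1] == 0.0 and merged[0].maxs[1] == 0.30
        assert sorted(merged[0].member_indices) == [0, 1, 2]

    def test_disjoint_untouched(self):
        a = bounds(0.0, 0.1, np.array([0]))
        b = bounds(0.2, 0.3, np.array([1]))
        merged = merge_clusters([a, b], axis=1)
        assert len(merged) == 2

    def test_containment_chain_collapses_to_one(self):
        a = bounds(0.00, 0.40, np.array([0]))
        b = bounds(0.05, 0.2501, np.array([1]))  # centre 0.15 in A
        c = bounds(0.14, 0.16, np.array([2]))  # centre 0.15 in B (and A)
        merged = merge_clusters([a, b, c], axis=1)
        assert len(merged) == 1
        assert sorted(merged[0].member_indices) == [0, 1, 2]

    def test_fixpoint_no_center_inside_other(self):
        rng = np.random.default_rng(5)
        clusters = [
            bounds(lo, lo + rng.uniform(0.02, 0.3), np.array([i]))
            for i, lo in enumerate(rng.uniform(0, 1, 12))
        ]
        merged = merge_clusters(clusters, axis=1)
        for i, ci in enumerate(merged):
            for j, cj in enumerate(merged):
                if i != j:
                    assert not (
                        cj.mins[1] <= ci.center(1) <= cj.maxs[1]
                    ), "fixpoint not reached"

    def test_termination_in_at_most_n_minus_1_absorptions(self):
        rng = np.random.default_rng(6)
        clusters = [
            bounds(lo, lo + rng.uniform(0.05, 0.5), np.array([i]))
            for i, lo in enumerate(rng.uniform(0, 0.5, 15))
        ]
        merged = merge_clusters(clusters, axis=1)
        # each absorption removes exactly one cluster
        assert len(clusters) - len(merged) <= len(clusters) - 1
        total = sorted(np.concatenate([c.member_indices for c in merged]))
        assert total == list(range(15))


class TestExtractPlants:
    def test_margin_and_half_open_bounds(self):
        pts = np.array([
            [0.0, 0.0, 0.0], [0.1, 0.1, 0.1],  # cluster members
            [0.1 + 0.002, 0.0, 0.0],  # exactly at max + margin: excluded
            [0.1 + 0.0019, 0.05, 0.05],  # just inside
        ])
        cluster = ClusterBounds([0.0, 0.0, 0.0], [0.1, 0.1, 0.1],
                                np.array([0, 1]))
        crops = extract_plants(cloud_of(pts), [cluster], margin=0.002)
        assert len(crops) == 1
        assert len(crops[0]) == 3  # members + the just-inside point

    def test_empty_crop_dropped_with_warning(self):
        cluster = ClusterBounds([10.0, 10, 10], [11.0, 11, 11], np.array([0]))
        with pytest.warns(UserWarning, match="empty crop"):
            crops = extract_plants(cloud_of([[0.0, 0, 0]]), [cluster])
        assert crops == []

    def test_three_plant_row_recovers_each_plant(self, three_plant_scene):
        """Crops contain >=95% of each plant's labelled points and nothing
        from the neighbours."""
        scene, gt = three_plant_scene
        cloud, labels = labeled_row_cloud(scene, density=3.0e5, seed=1)
        plant_mask = labels >= 0
        plant_cloud = ColoredPointCloud(cloud.points[plant_mask],
                                        cloud.colors[plant_mask])
        plant_labels = labels[plant_mask]
        plants, merged = segment_plants(
            plant_cloud, SegmentationParams(row_axis=0)
        )
        assert len(plants) == 3
        order = np.argsort([p.points[:, 0].mean() for p in plants])
        for k, idx in enumerate(order):
            crop = plants[idx]
            crop_set = set(map(tuple, np.round(crop.points, 9)))
            own = np.round(plant_cloud.points[plant_labels == k], 9)
            others = np.round(plant_cloud.points[plant_labels != k], 9)
            frac = np.mean([tuple(p) in crop_set for p in own])
            assert frac >= 0.95
            assert not any(tuple(p) in crop_set for p in others)
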