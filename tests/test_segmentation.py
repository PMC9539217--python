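"""Individual-tree segmentation, crown outlines/metrics and reference
matching."""

import numpy as np
import pytest
from shapely.geometry import MultiPoint

from canopyfuse import (
    crown_metrics,
    crown_outline,
    match_to_reference,
    segment_trees,
)
from canopyfuse.containers import VEGETATION, GroundTruth, TreeRecord
from canopyfuse.segmentation import _alpha_shape

from conftest import make_cloud


def veg_cloud(x, y, hag, **kw):
    cloud = make_cloud(x, y, np.asarray(hag, float), **kw)
    cloud.classification[:] = VEGETATION
    cloud.hag = np.asarray(hag, float)
    return cloud


def synthetic_crown(cx, cy, radius=1.5, height=15.0, n=300, seed=0):
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * np.pi, n)
    x = cx + r * np.cos(th)
    y = cy + r * np.sin(th)
    hag = height * (1 - (r / radius) ** 2) * rng.uniform(0.5, 1.0, n)
    hag = np.maximum(hag, 2.1)
    # ensure a unique apex at the stem
    x[0], y[0], hag[0] = cx, cy, height
    return x, y, hag


def exhaustive_sweep(cloud, spacing_threshold, min_height=2.0):
    """Oracle: the same descending-height sweep with no spatial indexing."""
    mask = (cloud.classification == VEGETATION) & (cloud.hag >= min_height)
    idx = np.nonzero(mask)[0]
    order = idx[np.argsort(-cloud.hag[idx])]
    labels = {}
    clusters = []  # list of lists of point indices
    for i in order:
        best, best_d2 = -1, spacing_threshold**2
        for lab, members in enumerate(clusters):
            d2 = min(
                (cloud.x[j] - cloud.x[i]) ** 2 + (cloud.y[j] - cloud.y[i]) ** 2
                for j in members
            )
            if d2 <= best_d2:
                best_d2, best = d2, lab
        if best < 0:
            best = len(clusters)
            clusters.append([])
        clusters[best].append(i)
        labels[i] = best
    return labels


class TestSegmentTrees:
    def test_single_crown_one_tree(self):
        x, y, h = synthetic_crown(10, 10)
        trees = segment_trees(veg_cloud(x, y, h), min_points=50)
        assert len(trees) == 1
        assert len(trees[0].points) >= 0.99 * len(x)

    def test_two_distant_crowns_no_cross_assignment(self):
        x1, y1, h1 = synthetic_crown(5, 5, seed=1)
        x2, y2, h2 = synthetic_crown(15, 5, seed=2)
        cloud = veg_cloud(
            np.concatenate([x1, x2]), np.concatenate([y1, y2]),
            np.concatenate([h1, h2]),
        )
        trees = segment_trees(cloud, spacing_threshold=2.0, min_points=50)
        assert len(trees) == 2
        for t in trees:
            assert (t.points.x < 10).all() or (t.points.x > 10).all()

    def test_empty_vegetation_gives_empty_output(self):
        cloud = make_cloud([1.0], [1.0], [1.0])
        assert segment_trees(cloud) == []

    def test_partition_property(self, processed_scene):
        trees = processed_scene["trees"]
        cloud = processed_scene["cloud_norm"]
        total = sum(len(t.points) for t in trees)
        veg = (cloud.classification == VEGETATION) & (cloud.hag >= 2.0)
        assert total <= veg.sum()
        # no coordinate appears in two trees
        seen = set()
        for t in trees:
            for xyz in zip(t.points.x, t.points.y, t.points.z):
                assert xyz not in seen
                seen.add(xyz)

    def test_monotone_in_spacing_threshold(self):
        rng = np.random.default_rng(3)
        xs, ys, hs = [], [], []
        for i, (cx, cy) in enumerate([(4, 4), (9, 4), (5, 10), (12, 11)]):
            x, y, h = synthetic_crown(cx, cy, radius=1.8, seed=i)
            xs.append(x), ys.append(y), hs.append(h)
        cloud = veg_cloud(np.concatenate(xs), np.concatenate(ys),
                          np.concatenate(hs))
        counts = [
            len(segment_trees(cloud, spacing_threshold=s, min_points=20))
            for s in (0.8, 1.5, 2.5, 4.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_agrees_with_exhaustive_sweep_oracle(self):
        rng = np.random.default_rng(7)
        n = 150
        cloud = veg_cloud(rng.uniform(0, 20, n), rng.uniform(0, 20, n),
                          rng.uniform(2.0, 20, n))
        trees = segment_trees(cloud, spacing_threshold=2.0, min_points=1)
        oracle = exhaustive_sweep(cloud, 2.0)
        # same partition: build label vectors and compare as partitions
        mine = {}
        for t in trees:
            for xyz in zip(t.points.x, t.points.y, t.points.z):
                mine[xyz] = t.tree_id
        pairs = set()
        for i, lab in oracle.items():
            key = (cloud.x[i], cloud.y[i], cloud.z[i])
            pairs.add((mine[key], lab))
        # bijection between label sets
        assert len({a for a, _ in pairs}) == len(pairs)
        assert len({b for _, b in pairs}) == len(pairs)

    def test_sparse_scene_detection_rate(self, processed_scene):
        match = processed_scene["match"]
        assert match.detection_rate >= 0.95


class TestCrownOutline:
    def test_filled_square_area(self):
        g = np.arange(0, 10.001, 0.5)
        gx, gy = np.meshgrid(g, g)
        tree = TreeRecord(
            tree_id=0,
            points=veg_cloud(gx.ravel(), gy.ravel(),
                             np.full(gx.size, 5.0)),
            apex_xy=(5, 5),
        )
        poly = crown_outline(tree)
        assert poly.area == pytest.approx(100.0, rel=0.05)

    def test_three_points_triangle(self):
        tree = TreeRecord(
            tree_id=0,
            points=veg_cloud([0, 4, 0], [0, 0, 3], [5, 5, 5]),
            apex_xy=(0, 0),
        )
        poly = crown_outline(tree, alpha=10.0)
        assert poly.area == pytest.approx(6.0, abs=1e-9)

    def test_c_shape_concave_hull_smaller_than_convex(self):
        th = np.linspace(0.25 * np.pi, 1.75 * np.pi, 300)
        rng = np.random.default_rng(1)
        r = 5.0 + rng.uniform(-0.4, 0.4, th.size)
        x, y = r * np.cos(th), r * np.sin(th)
        tree = TreeRecord(
            tree_id=0, points=veg_cloud(x, y, np.full(th.size, 5.0)),
            apex_xy=(0, 0),
        )
        poly = crown_outline(tree, alpha=1.5)
        convex = MultiPoint(np.column_stack([x, y])).convex_hull
        assert poly.area < convex.area

    def test_collinear_points_fail(self):
        tree = TreeRecord(
            tree_id=0, points=veg_cloud([0, 1, 2], [0, 1, 2], [5, 5, 5]),
            apex_xy=(0, 0),
        )
        with pytest.raises(ValueError):
            crown_outline(tree)

    def test_degenerate_alpha_falls_back_to_convex_hull(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(0, 5, 50), rng.uniform(0, 5, 50)
        tree = TreeRecord(
            tree_id=0, points=veg_cloud(x, y, np.full(50, 5.0)),
            apex_xy=(0, 0),
        )
        poly = crown_outline(tree, alpha=1e-6)  # every triangle rejected
        convex = MultiPoint(np.column_stack([x, y])).convex_hull
        assert poly.equals(convex)


class TestCrownMetrics:
    def test_cylinder_volume(self):
        rng = np.random.default_rng(4)
        n = 4000
        r = 3.0 * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        h = rng.uniform(0, 10, n)
        tree = TreeRecord(
            tree_id=0,
            points=veg_cloud(5 + r * np.cos(th), 5 + r * np.sin(th), h),
            apex_xy=(5, 5),
        )
        crown_outline(tree)
        crown_metrics(tree)
        assert tree.crown_volume == pytest.approx(np.pi * 9 * 10, rel=0.15)
        assert tree.height == pytest.approx(10.0, abs=0.1)
        assert tree.crown_width == pytest.approx(6.0, rel=0.1)

    def test_isolated_cone_height_and_area(self):
        # dense cone: height 18, footprint radius 3
        rng = np.random.default_rng(9)
        n = 5000
        r = 3.0 * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        h = 18.0 * (1 - r / 3.0) * rng.uniform(0.35, 1.0, n)
        x, y = 10 + r * np.cos(th), 10 + r * np.sin(th)
        x[0], y[0], h[0] = 10.0, 10.0, 18.0
        tree = TreeRecord(tree_id=0, points=veg_cloud(x, y, h),
                          apex_xy=(10, 10))
        crown_outline(tree)
        crown_metrics(tree)
        assert tree.height == pytest.approx(18.0, abs=0.3)
        assert tree.crown_area == pytest.approx(np.pi * 9, rel=0.15)

    def test_single_slice_flat_crown(self):
        g = np.arange(0, 4.001, 0.2)
        gx, gy = np.meshgrid(g, g)
        tree = TreeRecord(
            tree_id=0,
            points=veg_cloud(gx.ravel(), gy.ravel(), np.full(gx.size, 3.0)),
            apex_xy=(2, 2),
        )
        crown_outline(tree)
        crown_metrics(tree)
        # all points in one 0.5 m slice: V = hull area x 0.5
        hull_area = MultiPoint(tree.points.xy).convex_hull.area
        assert tree.crown_volume == pytest.approx(hull_area * 0.5, rel=1e-9)

    def test_cone_height_and_area_from_generator_truth(self, processed_scene):
        truth = processed_scene["truth"]
        trees = processed_scene["trees"]
        match = processed_scene["match"]
        stems = truth.stems.reset_index(drop=True)
        checked = 0
        for t in trees:
            si = match.assignments.get(t.tree_id)
            if si is None:
                continue
            s = stems.loc[si]
            # matched pairs already agree within the 20% matching rule;
            # boundary points can migrate between adjacent clusters
            assert t.height == pytest.approx(s.height, rel=0.20)
            area_truth = np.pi * s.crown_radius**2
            assert t.crown_area == pytest.approx(area_truth, rel=0.45)
            checked += 1
        assert checked >= 30


class TestMatchToReference:
    def test_perfect_segmentation(self, processed_scene):
        match = processed_scene["match"]
        assert match.n_correct <= match.n_detected
        assert match.total_accuracy == match.n_correct / match.n_reference

    def test_printed_count_arithmetic(self):
        # rates from externally supplied counts follow the definitions
        from canopyfuse import segmentation_rates

        rates = segmentation_rates(1040, 936, 880)
        assert rates["detection_rate"] == 90.00
        assert rates["total_accuracy"] == 84.62

    def test_no_detections_raises(self, processed_scene):
        with pytest.raises(ValueError):
            match_to_reference([], processed_scene["truth"])

    def test_distant_detection_is_false_positive(self):
        import pandas as pd

        x, y, h = synthetic_crown(5, 5, height=15.0)
        cloud = veg_cloud(x, y, h)
        trees = segment_trees(cloud, min_points=50)
        truth = GroundTruth(
            stems=pd.DataFrame(
                {"tree_id": [0], "x": [50.0], "y": [50.0],
                 "species": ["JM"], "height": [15.0], "crown_radius": [1.5]}
            ),
            crown_polygons={},
        )
        match = match_to_reference(trees, truth, max_dist=2.0)
        assert match.n_correct == 0
        assert match.truth_status[0] == "missed"
        assert match.detection_status[trees[0].tree_id] == "false_positive"

    def test_height_disagreement_blocks_match(self):
        import pandas as pd

        x, y, h = synthetic_crown(5, 5, height=15.0)
        trees = segment_trees(veg_cloud(x, y, h), min_points=50)
        for t in trees:
            crown_outline(t)
            crown_metrics(t)
        truth = GroundTruth(
            stems=pd.DataFrame(
                {"tree_id": [0], "x": [5.0], "y": [5.0], "species": ["JM"],
                 "height": [30.0], "crown_radius": [1.5]}
            ),
            crown_polygons={},
        )
        match = match_to_reference(trees, truth, max_dist=2.0)
        assert match.n_correct == 0
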