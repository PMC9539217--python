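"""Individual-tree delineation from the normalized point cloud.

The clusterer is a top-down exclusion sweep over vegetation points in
descending height-above-ground: the highest unassigned point seeds a new
tree; every subsequent point joins the existing tree whose 2-D point set
is horizontally nearest, provided that distance is within the spacing
threshold, and otherwise seeds a tree of its own.  Crown outlines are
alpha shapes (concave hulls) of the projected points with a convex-hull
fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .containers import VEGETATION, GroundTruth, PointCloud, TreeRecord


def segment_trees(cloud: PointCloud, spacing_threshold: float = 2.0,
                  min_points: int = 50, min_height: float = 2.0) -> list:
    """Distance-based point-cloud clustering into individual trees.

    Points below ``min_height`` above ground are excluded; clusters with
    fewer than ``min_points`` points are discarded.  The output is a
    partition: every vegetation point belongs to at most one tree.
    """
    mask = (cloud.classification == VEGETATION) & (cloud.hag >= min_height)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    order = idx[np.argsort(-cloud.hag[idx])]

    # spatial hash with cell = spacing threshold: any point within the
    # threshold of (x, y) lies in the 3x3 cell neighbourhood
    cell = spacing_threshold
    grid: dict = {}
    labels = np.full(len(cloud), -1, dtype=int)
    seeds = []  # index of the apex point per label
    xs, ys = cloud.x, cloud.y

    for i in order:
        ci, cj = int(xs[i] // cell), int(ys[i] // cell)
        best_lab, best_d2 = -1, spacing_threshold**2
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                bucket = grid.get((ci + di, cj + dj))
                if not bucket:
                    continue
                bx, by, bl = bucket
                d2 = (np.array(bx) - xs[i]) ** 2 + (np.array(by) - ys[i]) ** 2
                k = int(np.argmin(d2))
                if d2[k] <= best_d2:
                    best_d2 = d2[k]
                    best_lab = bl[k]
        if best_lab < 0:
            best_lab = len(seeds)
            seeds.append(i)
        labels[i] = best_lab
        bucket = grid.setdefault((ci, cj), ([], [], []))
        bucket[0].append(xs[i])
        bucket[1].append(ys[i])
        bucket[2].append(best_lab)

    trees = []
    tree_id = 0
    for lab, seed_idx in enumerate(seeds):
        members = np.nonzero(labels == lab)[0]
        if members.size < min_points:
            continue
        trees.append(
            TreeRecord(
                tree_id=tree_id,
                points=cloud.subset(members),
                apex_xy=(float(xs[seed_idx]), float(ys[seed_idx])),
            )
        )
        tree_id += 1
    return trees


def _alpha_shape(xy: np.ndarray, alpha: float):
    """Union of Delaunay triangles whose circumradius is <= alpha."""
    tri = Delaunay(xy)
    pts = xy[tri.simplices]  # (m, 3, 2)
    a = np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1)
    b = np.linalg.norm(pts[:, 1] - pts[:, 2], axis=1)
    c = np.linalg.norm(pts[:, 2] - pts[:, 0], axis=1)
    s = 0.5 * (a + b + c)
    area = np.sqrt(np.maximum(s * (s - a) * (s - b) * (s - c), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = np.where(area > 0, a * b * c / (4.0 * area), np.inf)
    keep = circum_r <= alpha
    if not keep.any():
        return None
    return unary_union([Polygon(t) for t in pts[keep]])


def crown_outline(tree: TreeRecord, alpha: float = None) -> Polygon:
    """Concave-hull crown outline of the tree's projected points.

    ``alpha`` defaults to 3x the median nearest-neighbour spacing of the
    projection (scale-free across point densities).  Falls back to the
    convex hull when the alpha shape is disconnected or degenerate.
    Sets ``crown_polygon`` and ``crown_area`` on the record.
    """
    xy = tree.points.xy
    if len(xy) < 3:
        raise ValueError("need at least 3 points for a crown outline")
    hull = MultiPoint(xy).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise ValueError("crown points are collinear")
    if alpha is None:
        kd = cKDTree(xy)
        d, _ = kd.query(xy, k=2)
        alpha = 3.0 * float(np.median(d[:, 1]))
    shape = _alpha_shape(xy, alpha)
    if (
        shape is None
        or shape.geom_type != "Polygon"
        or shape.area == 0
        or not shape.is_valid
    ):
        shape = hull
    tree.crown_polygon = shape
    tree.crown_area = float(shape.area)
    return shape


def crown_metrics(tree: TreeRecord, slice_height: float = 0.5) -> TreeRecord:
    """Fill H_T, W_C, A_C and V_C on the record.

    * H_T: maximum height above ground.
    * W_C: mean of the crown polygon's bounding-box width and height.
    * A_C: crown polygon area.
    * V_C: sum over 0.5 m height slices (from the crown base up) of each
      slice's convex-hull area times the slice thickness.
    """
    if tree.crown_polygon is None:
        crown_outline(tree)
    hag = tree.points.hag
    tree.height = float(np.max(hag))
    minx, miny, maxx, maxy = tree.crown_polygon.bounds
    tree.crown_width = float(0.5 * ((maxx - minx) + (maxy - miny)))
    tree.crown_area = float(tree.crown_polygon.area)

    base = float(np.min(hag))
    n_slices = max(1, int(np.ceil((tree.height - base) / slice_height)))
    vol = 0.0
    for k in range(n_slices):
        z0 = base + k * slice_height
        if k == n_slices - 1:  # top slice closed
            in_slice = (hag >= z0) & (hag <= tree.height)
        else:
            in_slice = (hag >= z0) & (hag < z0 + slice_height)
        if in_slice.sum() >= 3:
            hull = MultiPoint(tree.points.xy[in_slice]).convex_hull
            vol += hull.area * slice_height
    tree.crown_volume = float(vol)
    return tree


@dataclass
class SegmentationMatch:
    """Detection bookkeeping against a reference stem map."""

    n_reference: int
    n_detected: int
    n_correct: int
    detection_rate: float
    total_accuracy: float
    truth_status: dict = field(default_factory=dict)      # stem id -> status
    detection_status: dict = field(default_factory=dict)  # tree id -> status
    assignments: dict = field(default_factory=dict)       # tree id -> stem row

    def to_dict(self) -> dict:
        return {
            "n_reference": self.n_reference,
            "n_detected": self.n_detected,
            "n_correct": self.n_correct,
            "detection_rate": self.detection_rate,
            "total_accuracy": self.total_accuracy,
        }


def match_to_reference(trees, truth: GroundTruth,
                       max_dist: float = 2.0,
                       height_tolerance: float = 0.20) -> SegmentationMatch:
    """Greedy one-to-one matching of detected apexes to reference stems.

    Candidate pairs are sorted by apex-to-stem distance; a pair is
    accepted when the distance is within ``max_dist`` and the detected
    height agrees with the reference height within ``height_tolerance``
    (fractional).  Accepted pairs count as correct.  Reference stems
    claimed by two or more detections are over-segmented; detections
    whose crown polygon covers two or more stems are under-segmented;
    unmatched reference stems are missed.
    """
    if not trees or len(truth) == 0:
        raise ValueError("both detections and reference must be non-empty")
    stems = truth.stems.reset_index(drop=True)
    apexes = np.array([t.apex_xy for t in trees])
    sxy = stems[["x", "y"]].to_numpy(float)

    d = np.linalg.norm(apexes[:, None, :] - sxy[None, :, :], axis=2)
    pairs = np.argwhere(d <= max_dist)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]])
    matched_det: dict = {}
    matched_stem: dict = {}
    for k in order:
        ti, si = pairs[k]
        if ti in matched_det or si in matched_stem:
            continue
        h_det = trees[ti].height
        h_ref = float(stems.loc[si, "height"])
        if np.isfinite(h_det) and h_ref > 0:
            if abs(h_det - h_ref) > height_tolerance * h_ref:
                continue
        matched_det[ti] = si
        matched_stem[si] = ti

    # claims for over-segmentation: any detection within max_dist of a stem
    claims = (d <= max_dist).sum(axis=0)

    truth_status = {}
    for si in range(len(stems)):
        if si in matched_stem:
            truth_status[si] = "correct"
        elif claims[si] >= 2:
            truth_status[si] = "over_segmented"
        else:
            truth_status[si] = "missed"

    detection_status = {}
    for ti, tree in enumerate(trees):
        if ti in matched_det:
            detection_status[tree.tree_id] = "correct"
            continue
        covered = 0
        if tree.crown_polygon is not None:
            covered = sum(
                tree.crown_polygon.contains(Point(px, py))
                for px, py in sxy
            )
        detection_status[tree.tree_id] = (
            "under_segmented" if covered >= 2 else "false_positive"
        )

    n_ref = len(stems)
    n_det = len(trees)
    n_cor = len(matched_det)
    return SegmentationMatch(
        n_reference=n_ref,
        n_detected=n_det,
        n_correct=n_cor,
        detection_rate=n_det / n_ref,
        total_accuracy=n_cor / n_ref,
        truth_status=truth_status,
        detection_status=detection_status,
        assignments={trees[ti].tree_id: int(si) for ti, si in matched_det.items()},
    )
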