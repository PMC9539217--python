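"""Point-cloud and spectral preprocessing.

Denoising is statistical outlier removal on k-nearest-neighbour mean
distances.  Ground filtering is progressive TIN densification: seed a
triangulated terrain surface from the lowest point of each coarse cell,
then iteratively admit points that lie within an iteration angle and an
iteration distance of their containing triangle (defaults 10 degrees and
1.5 m).  Heights are normalised against the TIN-interpolated ground
surface.  Spectra are smoothed with a Savitzky-Golay filter, and the
hyperspectral frame is co-registered onto the LiDAR frame with a full 2-D
quadratic polynomial fitted to control-point pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.signal import savgol_filter
from scipy.spatial import Delaunay, cKDTree

from .containers import GROUND, NOISE, VEGETATION, HyperspectralCube, PointCloud


def denoise(cloud: PointCloud, k_neighbors: int = 10,
            sd_multiplier: float = 3.0) -> PointCloud:
    """Flag statistical outliers as noise.

    A point is noise when its mean distance to its ``k_neighbors`` nearest
    neighbours exceeds the global mean of that statistic by more than
    ``sd_multiplier`` standard deviations.  Surviving point coordinates
    are untouched; flagged points get classification NOISE.
    """
    if len(cloud) == 0:
        raise ValueError("empty point cloud")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    out = cloud.copy()
    if len(cloud) < k_neighbors + 1:
        warnings.warn("too few points to denoise; returning cloud unchanged")
        return out
    kd = cKDTree(np.column_stack([cloud.x, cloud.y, cloud.z]))
    dists, _ = kd.query(
        np.column_stack([cloud.x, cloud.y, cloud.z]), k=k_neighbors + 1
    )
    mean_d = dists[:, 1:].mean(axis=1)  # drop self-distance
    thr = mean_d.mean() + sd_multiplier * mean_d.std()
    out.classification[mean_d > thr] = NOISE
    return out


def _seed_points(x, y, z, cell: float):
    """Lowest point per coarse grid cell."""
    ci = np.floor(x / cell).astype(int)
    cj = np.floor(y / cell).astype(int)
    key = ci * 1_000_003 + cj
    order = np.lexsort((z, key))
    key_sorted = key[order]
    first = np.ones(len(key), dtype=bool)
    first[1:] = key_sorted[1:] != key_sorted[:-1]
    return order[first]


def filter_ground(cloud: PointCloud, iter_angle: float = 10.0,
                  iter_distance: float = 1.5, cell: float = 20.0,
                  max_iterations: int = 50) -> PointCloud:
    """Progressive TIN densification ground filter.

    Starting from per-cell lowest seeds, a candidate is admitted to the
    ground TIN when the angle between the candidate and each vertex of its
    containing triangle is at most ``iter_angle`` degrees AND its distance
    to the triangle plane is at most ``iter_distance`` metres.  Iterates
    (retriangulating after each sweep) until no point is admitted.
    Noise-classified points are never considered.
    """
    out = cloud.copy()
    valid = out.classification != NOISE
    idx_valid = np.nonzero(valid)[0]
    x, y, z = out.x[idx_valid], out.y[idx_valid], out.z[idx_valid]
    n = len(idx_valid)
    if n < 3:
        raise ValueError("not enough points for ground filtering")

    seeds = _seed_points(x, y, z, cell)
    ground = np.zeros(n, dtype=bool)
    ground[seeds] = True
    if ground.sum() < 3 or np.linalg.matrix_rank(
        np.column_stack([x[seeds], y[seeds], np.ones(len(seeds))])
    ) < 3:
        raise ValueError("fewer than 3 non-collinear ground seeds")

    # virtual boundary seeds (corners + edge midpoints of the bounding box,
    # at the elevation of the nearest real seed) so the initial TIN hull
    # covers the whole extent; they join the TIN but never the output
    x0, x1, y0, y1 = x.min(), x.max(), y.min(), y.max()
    xm, ym = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
    bx = np.array([x0, xm, x1, x0, x1, x0, xm, x1])
    by = np.array([y0, y0, y0, ym, ym, y1, y1, y1])
    seed_kd = cKDTree(np.column_stack([x[seeds], y[seeds]]))
    _, nearest = seed_kd.query(np.column_stack([bx, by]))
    bz = z[seeds][nearest]

    tan_thr = np.tan(np.radians(iter_angle))
    for _ in range(max_iterations):
        gx = np.concatenate([x[ground], bx])
        gy = np.concatenate([y[ground], by])
        gz = np.concatenate([z[ground], bz])
        try:
            tri = Delaunay(np.column_stack([gx, gy]))
        except Exception as exc:  # degenerate seed geometry
            raise ValueError(f"ground TIN construction failed: {exc}")
        cand = np.nonzero(~ground)[0]
        if cand.size == 0:
            break
        simplex = tri.find_simplex(np.column_stack([x[cand], y[cand]]))
        inside = simplex >= 0
        if not inside.any():
            break
        cand = cand[inside]
        simp = tri.simplices[simplex[inside]]  # (m, 3) vertex indices
        vx, vy, vz = gx[simp], gy[simp], gz[simp]

        # plane through the triangle
        e1 = np.stack([vx[:, 1] - vx[:, 0], vy[:, 1] - vy[:, 0],
                       vz[:, 1] - vz[:, 0]], axis=1)
        e2 = np.stack([vx[:, 2] - vx[:, 0], vy[:, 2] - vy[:, 0],
                       vz[:, 2] - vz[:, 0]], axis=1)
        nvec = np.cross(e1, e2)
        nn = np.linalg.norm(nvec, axis=1)
        nn[nn == 0] = np.inf
        rel = np.stack([x[cand] - vx[:, 0], y[cand] - vy[:, 0],
                        z[cand] - vz[:, 0]], axis=1)
        dist_plane = np.abs((rel * nvec).sum(axis=1)) / nn

        # angle to each vertex: atan(dz_above_plane / horizontal distance)
        dxv = x[cand][:, None] - vx
        dyv = y[cand][:, None] - vy
        horiz = np.hypot(dxv, dyv)
        horiz[horiz == 0] = 1e-9
        tan_angles = dist_plane[:, None] / horiz
        ok = (dist_plane <= iter_distance) & (tan_angles.max(axis=1) <= tan_thr)
        if not ok.any():
            break
        ground[cand[ok]] = True

    out.classification[idx_valid[ground]] = GROUND
    out.classification[idx_valid[~ground]] = VEGETATION
    return out


def normalize_heights(cloud: PointCloud) -> PointCloud:
    """Set ``hag`` = z minus the TIN-interpolated ground elevation.

    Points outside the ground convex hull fall back to nearest-neighbour
    extrapolation and are flagged in ``flags`` metadata; negative heights
    (interpolation artifacts) are clamped to zero.
    """
    out = cloud.copy()
    gmask = out.classification == GROUND
    if gmask.sum() < 3:
        raise ValueError("ground points must be classified before normalization")
    pts = np.column_stack([out.x[gmask], out.y[gmask]])
    lin = LinearNDInterpolator(pts, out.z[gmask])
    near = NearestNDInterpolator(pts, out.z[gmask])
    q = np.column_stack([out.x, out.y])
    gz = lin(q)
    outside = np.isnan(gz)
    if outside.any():
        gz[outside] = near(q[outside])
    hag = out.z - gz
    n_clamped = int((hag < 0).sum())
    out.hag = np.maximum(hag, 0.0)
    # keep bookkeeping on the array object (PointCloud has no flags field)
    out.n_clamped_negative = n_clamped
    out.n_extrapolated = int(outside.sum())
    return out


def smooth_spectra(data, window: int = 7, polyorder: int = 2):
    """Savitzky-Golay smoothing along the band axis.

    Accepts a single spectrum, a matrix of spectra (last axis = bands) or
    a :class:`HyperspectralCube`; output has the same shape.  Endpoints
    use polynomial interpolation on the truncated window.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if isinstance(data, HyperspectralCube):
        smoothed = savgol_filter(
            data.data.astype(np.float64), window, polyorder, axis=-1,
            mode="interp",
        ).astype(data.data.dtype)
        return HyperspectralCube(
            data=np.clip(smoothed, 0.0, 1.0),
            wavelengths=data.wavelengths,
            x0=data.x0, y0=data.y0, gsd=data.gsd, nodata=data.nodata,
        )
    arr = np.asarray(data, dtype=float)
    if window > arr.shape[-1]:
        raise ValueError("window exceeds number of bands")
    return savgol_filter(arr, window, polyorder, axis=-1, mode="interp")


@dataclass
class QuadraticTransform:
    """Full 2-D quadratic mapping fitted to control-point pairs.

    Maps (x, y) -> (x', y') via six coefficients per output axis on the
    design [1, x, y, x^2, x*y, y^2].  ``rms`` is the fit residual in map
    units.  ``inverse`` (fitted from the swapped pairs) is used when
    resampling a raster onto the target frame.
    """

    coef_x: np.ndarray
    coef_y: np.ndarray
    rms: float
    inverse: "QuadraticTransform" = None

    def __call__(self, x, y):
        d = _quad_design(np.asarray(x, float), np.asarray(y, float))
        return d @ self.coef_x, d @ self.coef_y


def _quad_design(x, y):
    return np.stack([np.ones_like(x), x, y, x**2, x * y, y**2], axis=-1)


def fit_quadratic_registration(source_xy, target_xy,
                               fit_inverse: bool = True) -> QuadraticTransform:
    """Least-squares fit of the quadratic registration from >= 6 control
    point pairs (cube frame -> LiDAR frame)."""
    src = np.asarray(source_xy, float)
    dst = np.asarray(target_xy, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("control points must be (n, 2) arrays of equal shape")
    if len(src) < 6:
        raise ValueError("need at least 6 control-point pairs")
    design = _quad_design(src[:, 0], src[:, 1])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("control points are degenerate (rank-deficient design)")
    cx, *_ = np.linalg.lstsq(design, dst[:, 0], rcond=None)
    cy, *_ = np.linalg.lstsq(design, dst[:, 1], rcond=None)
    pred = np.column_stack([design @ cx, design @ cy])
    rms = float(np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1))))
    inv = (
        fit_quadratic_registration(dst, src, fit_inverse=False)
        if fit_inverse
        else None
    )
    return QuadraticTransform(coef_x=cx, coef_y=cy, rms=rms, inverse=inv)


def register_cube(cube: HyperspectralCube,
                  transform: QuadraticTransform) -> HyperspectralCube:
    """Resample the cube onto the LiDAR frame by nearest neighbour.

    Nearest-neighbour lookup keeps reflectance values exact — spectra are
    never blended across crown boundaries.  Each target pixel centre is
    mapped back through the inverse quadratic into the source frame.
    """
    if transform.inverse is None:
        raise ValueError("transform has no fitted inverse")
    rows, cols, _ = cube.data.shape
    xs, ys = cube.pixel_centers()
    gx, gy = np.meshgrid(xs, ys)
    sx, sy = transform.inverse(gx.ravel(), gy.ravel())
    srow, scol = cube.world_to_pixel(sx, sy)
    srow = np.clip(np.round(srow).astype(int), 0, rows - 1)
    scol = np.clip(np.round(scol).astype(int), 0, cols - 1)
    data = cube.data[srow, scol].reshape(rows, cols, cube.n_bands)
    nodata = cube.nodata[srow, scol].reshape(rows, cols)
    return HyperspectralCube(
        data=data, wavelengths=cube.wavelengths,
        x0=cube.x0, y0=cube.y0, gsd=cube.gsd, nodata=nodata,
    )
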