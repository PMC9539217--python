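"""Synthetic forest-scene simulator.

Generates co-registered multi-return LiDAR point clouds, hyperspectral
reflectance cubes and ground-truth stem maps for a mixed conifer/broadleaf
stand, so that every downstream stage (ground filtering, individual-tree
segmentation, crown-spectrum extraction, feature fusion, classification)
can be exercised end-to-end without field data.

The stand model is deliberately geometric rather than radiative:

* terrain is a smooth low-relief surface (two low-frequency sinusoids,
  < 3 m relief over 100 m);
* each tree is a solid of revolution (cone, ellipsoid or dome) with a
  species-specific height and crown-radius range;
* LiDAR pulses fall on a jittered grid at the configured density; a pulse
  over a crown returns first from the crown top surface, and produces
  later returns deeper in the crown with geometrically decaying
  probability (0.4 per extra order) and echo intensity attenuated by 0.7
  per order;
* crown pixels in the cube take the species reflectance endmember scaled
  by a sunlit or shadow factor derived from the cosine between the crown
  surface normal and a fixed sun direction, plus i.i.d. Gaussian noise;
  background pixels get a soil ramp spectrum.

Every random draw comes from a single :class:`numpy.random.Generator`
seeded from ``SceneConfig.seed``, so identical configs give identical
scenes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point

from .containers import (
    GROUND,
    UNASSIGNED,
    VEGETATION,
    GroundTruth,
    HyperspectralCube,
    PointCloud,
)

# Stated jitter applied to crown returns; the "point inside dilated crown
# solid" invariant is asserted against these values.
XY_JITTER = 0.3
Z_JITTER = 0.15

EXTRA_RETURN_PROB = 0.4     # geometric decay per additional echo order
INTENSITY_ATTENUATION = 0.7  # per echo order

SUN_AZIMUTH_DEG = 180.0  # sun from the south
SUN_ELEVATION_DEG = 45.0

GROUND_INTENSITY_MEAN = 35.0
GROUND_INTENSITY_SD = 8.0


class PlacementError(RuntimeError):
    """Raised when the extent cannot hold ``n_trees`` at ``min_spacing``."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} stems at the "
            "requested minimum spacing"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass
class SpeciesModel:
    """Per-species generative parameters.

    ``reflectance_endmember`` is the sunlit crown spectrum sampled on the
    scene's wavelength grid; shaded pixels are this spectrum scaled by the
    shadow factor.  ``intensity_mean``/``intensity_sd`` parameterise the
    Gaussian first-echo intensity distribution.
    """

    name: str
    crown_form: str  # cone | ellipsoid | hemisphere
    height_range: tuple
    crown_radius_range: tuple
    reflectance_endmember: np.ndarray
    intensity_mean: float
    intensity_sd: float
    crown_base_frac: float = 0.35

    def __post_init__(self):
        if self.crown_form not in ("cone", "ellipsoid", "hemisphere"):
            raise ValueError(f"unknown crown form {self.crown_form!r}")
        e = np.asarray(self.reflectance_endmember, dtype=float)
        if e.min() < 0 or e.max() > 1:
            raise ValueError("endmember reflectance must lie in [0, 1]")
        if self.intensity_sd <= 0:
            raise ValueError("intensity_sd must be positive")
        self.reflectance_endmember = e

    def validate_nir(self, wavelengths: np.ndarray) -> None:
        nir = wavelengths >= 760.0
        if self.reflectance_endmember[nir].mean() <= 0.25:
            raise ValueError(
                f"species {self.name}: sunlit NIR mean must exceed 0.25 "
                "for the sunlit-pixel rule to be exercisable"
            )


@dataclass
class SceneConfig:
    """Scene geometry, sensor and noise settings.

    Defaults mirror a UAV acquisition over a temperate mixed stand:
    180 points/m^2, up to 5 echoes per pulse, 10 cm ground sampling and
    300 bands across 400-1000 nm.
    """

    extent: tuple = (50.0, 50.0)
    n_trees: int = 50
    species_mix: dict = None
    min_spacing: float = 3.5
    point_density: float = 180.0
    max_returns: int = 5
    gsd: float = 0.10
    n_bands: int = 300
    wavelength_range: tuple = (400.0, 1000.0)
    shadow_fraction: float = 0.35
    noise_sd_spectral: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")
        if self.n_bands < 2:
            raise ValueError("need at least 2 bands")
        if self.species_mix is not None:
            total = sum(self.species_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("species_mix proportions must sum to 1")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)


# ---------------------------------------------------------------------------
# default species set: a five-species mixed conifer/broadleaf stand


def _vegetation_spectrum(wl, green_peak, nir_plateau, red_edge, vis_base=0.05):
    """Smooth leaf-like reflectance: green bump, logistic red edge, water dip."""
    green = green_peak * np.exp(-0.5 * ((wl - 552.0) / 32.0) ** 2)
    edge = nir_plateau / (1.0 + np.exp(-(wl - red_edge) / 14.0))
    water = 0.04 * nir_plateau * np.exp(-0.5 * ((wl - 970.0) / 22.0) ** 2)
    red_abs = 0.02 * np.exp(-0.5 * ((wl - 670.0) / 25.0) ** 2)
    return np.clip(vis_base + green + edge - water - red_abs, 0.0, 1.0)


def default_species_models(wavelengths=None) -> list:
    """The default five-species stand: one conifer (larch) and four
    broadleaves, with distinct green-peak and NIR-plateau behaviour and
    overlapping but species-dependent echo intensity distributions."""
    if wavelengths is None:
        wavelengths = np.linspace(400.0, 1000.0, 300)
    wl = np.asarray(wavelengths, float)
    spec = [
        # name, form, heights, radii, green_peak, nir, red_edge, I_mean, I_sd
        ("JM", "ellipsoid", (14, 20), (1.0, 1.6), 0.065, 0.52, 718.0, 110.0, 18.0),
        ("LG", "cone", (16, 24), (0.9, 1.4), 0.040, 0.36, 712.0, 70.0, 15.0),
        ("TA", "ellipsoid", (12, 18), (1.1, 1.7), 0.080, 0.46, 722.0, 95.0, 18.0),
        ("QM", "hemisphere", (15, 22), (1.1, 1.7), 0.055, 0.49, 726.0, 120.0, 20.0),
        ("UP", "hemisphere", (10, 16), (1.0, 1.5), 0.072, 0.42, 715.0, 85.0, 18.0),
    ]
    models = []
    for name, form, hr, rr, gp, nir, re, im, isd in spec:
        models.append(
            SpeciesModel(
                name=name,
                crown_form=form,
                height_range=hr,
                crown_radius_range=rr,
                reflectance_endmember=_vegetation_spectrum(wl, gp, nir, re),
                intensity_mean=im,
                intensity_sd=isd,
            )
        )
    return models


def scene_preset(name: str, seed: int = 0, **overrides) -> SceneConfig:
    """Two shipped presets: ``sparse`` (well-separated crowns) and
    ``dense`` (overlapping crowns)."""
    if name == "sparse":
        cfg = dict(extent=(50.0, 50.0), n_trees=50, min_spacing=3.5)
    elif name == "dense":
        cfg = dict(extent=(50.0, 50.0), n_trees=90, min_spacing=2.0)
    else:
        raise ValueError(f"unknown preset {name!r}")
    cfg.update(overrides)
    return SceneConfig(seed=seed, **cfg)


# ---------------------------------------------------------------------------
# crown solids


def _crown_top_z(form, d, stem_z, height, base_frac, radius):
    """Absolute z of the crown top surface at horizontal stem distance d."""
    h_abs = stem_z + height
    cb = stem_z + base_frac * height
    frac = np.clip(d / radius, 0.0, 1.0)
    if form == "cone":
        return h_abs - frac * (h_abs - cb)
    circ = np.sqrt(np.maximum(0.0, 1.0 - frac**2))
    if form == "ellipsoid":
        zc = 0.5 * (cb + h_abs)
        return zc + 0.5 * (h_abs - cb) * circ
    # hemisphere: dome from crown base
    return cb + (h_abs - cb) * circ


def _surface_normal(form, dx, dy, height, base_frac, radius):
    """Outward unit normal of the crown top surface at offset (dx, dy)."""
    d = np.hypot(dx, dy)
    span = height * (1.0 - base_frac)
    with np.errstate(invalid="ignore", divide="ignore"):
        if form == "cone":
            slope = span / radius  # |dz/dd|
            nx = np.where(d > 0, dx / d, 0.0) * slope
            ny = np.where(d > 0, dy / d, 0.0) * slope
            nz = np.ones_like(d)
        else:
            if form == "ellipsoid":
                sz = 0.5 * span
            else:  # hemisphere
                sz = span
            # top surface z = z0 + sz*sqrt(1-(d/r)^2) => |dz/dd| = sz*d/(r^2*circ)
            circ = np.sqrt(np.maximum(1e-9, 1.0 - np.clip(d / radius, 0, 1) ** 2))
            dzdd = (sz * d) / (radius**2 * circ)
            nx = np.where(d > 0, dx / d, 0.0) * dzdd
            ny = np.where(d > 0, dy / d, 0.0) * dzdd
            nz = np.ones_like(d)
    norm = np.sqrt(nx**2 + ny**2 + nz**2)
    return nx / norm, ny / norm, nz / norm


def _sun_vector():
    az = math.radians(SUN_AZIMUTH_DEG)
    el = math.radians(SUN_ELEVATION_DEG)
    # pointing from the surface toward the sun
    return (
        math.sin(az) * math.cos(el),
        math.cos(az) * math.cos(el),
        math.sin(el),
    )


def terrain_elevation(x, y, seed: int = 0):
    """Smooth low-relief terrain: two low-frequency sinusoids, < 3 m
    relief over 100 m.  Phases are drawn from the seed so different scenes
    get different (but reproducible) terrain."""
    rng = np.random.default_rng(int(seed) + 7919)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return 1.2 * np.sin(2 * np.pi * x / 83.0 + p1) + 0.9 * np.cos(
        2 * np.pi * y / 67.0 + p2
    )


# ---------------------------------------------------------------------------
# stem placement


def _place_stems(cfg: SceneConfig, models, rng):
    """Poisson-disk-style rejection sampling of stem locations."""
    width, depth = cfg.extent
    margin = max(m.crown_radius_range[1] for m in models)
    names = [m.name for m in models]
    if cfg.species_mix is None:
        probs = np.full(len(models), 1.0 / len(models))
    else:
        probs = np.array([cfg.species_mix.get(n, 0.0) for n in names], float)

    xs, ys = [], []
    attempts = 0
    max_attempts = 200 * cfg.n_trees
    while len(xs) < cfg.n_trees and attempts < max_attempts:
        attempts += 1
        x = rng.uniform(margin, width - margin)
        y = rng.uniform(margin, depth - margin)
        if xs:
            d2 = (np.array(xs) - x) ** 2 + (np.array(ys) - y) ** 2
            if d2.min() < cfg.min_spacing**2:
                continue
        xs.append(x)
        ys.append(y)
    if len(xs) < cfg.n_trees:
        raise PlacementError(cfg.n_trees, len(xs))

    species_idx = rng.choice(len(models), size=cfg.n_trees, p=probs)
    trees = []
    for i, (x, y, si) in enumerate(zip(xs, ys, species_idx)):
        m = models[si]
        trees.append(
            {
                "tree_id": i,
                "x": x,
                "y": y,
                "species": m.name,
                "model": m,
                "height": rng.uniform(*m.height_range),
                "radius": rng.uniform(*m.crown_radius_range),
                "stem_z": float(terrain_elevation(x, y, cfg.seed)),
                # tree-level random effects: crowns of one species differ in
                # echo intensity (moisture, incidence angle) and in spectral
                # brightness / NIR shoulder (pigment and structure variation)
                "intensity_factor": float(
                    np.clip(rng.normal(1.0, 0.12), 0.5, 1.5)
                ),
                "brightness": float(np.clip(rng.normal(1.0, 0.06), 0.7, 1.3)),
                "nir_tilt": float(rng.normal(0.0, 0.05)),
            }
        )
    return trees


# ---------------------------------------------------------------------------
# LiDAR sampling


def _sample_point_cloud(cfg: SceneConfig, trees, rng) -> PointCloud:
    width, depth = cfg.extent
    spacing = 1.0 / math.sqrt(cfg.point_density)
    nx = int(round(width / spacing))
    ny = int(round(depth / spacing))
    gx, gy = np.meshgrid(
        (np.arange(nx) + 0.5) * width / nx, (np.arange(ny) + 0.5) * depth / ny
    )
    px = gx.ravel() + rng.uniform(-0.5, 0.5, gx.size) * width / nx
    py = gy.ravel() + rng.uniform(-0.5, 0.5, gy.size) * depth / ny
    n_pulses = px.size
    zg = terrain_elevation(px, py, cfg.seed)

    # which tree (if any) intercepts each pulse: highest crown surface wins
    best_top = np.full(n_pulses, -np.inf)
    best_tree = np.full(n_pulses, -1, dtype=int)
    kd = cKDTree(np.column_stack([px, py]))
    for t in trees:
        idx = np.array(kd.query_ball_point([t["x"], t["y"]], t["radius"]), dtype=int)
        if idx.size == 0:
            continue
        d = np.hypot(px[idx] - t["x"], py[idx] - t["y"])
        top = _crown_top_z(
            t["model"].crown_form, d, t["stem_z"], t["height"],
            t["model"].crown_base_frac, t["radius"],
        )
        better = top > best_top[idx]
        best_top[idx[better]] = top[better]
        best_tree[idx[better]] = t["tree_id"]

    covered = best_tree >= 0
    parts = []

    # pure ground pulses: single return on the terrain
    gmask = ~covered
    n_g = int(gmask.sum())
    parts.append(
        PointCloud(
            x=px[gmask],
            y=py[gmask],
            z=zg[gmask] + rng.normal(0, 0.01, n_g),
            intensity=np.clip(
                rng.normal(GROUND_INTENSITY_MEAN, GROUND_INTENSITY_SD, n_g), 1, 65535
            ),
            return_number=np.ones(n_g, dtype=int),
            num_returns=np.ones(n_g, dtype=int),
            classification=np.full(n_g, UNASSIGNED, dtype=np.uint8),
            source=np.full(n_g, "ground", dtype=object),
        )
    )

    # crown pulses: first return from the top surface, extra returns deeper
    cidx = np.nonzero(covered)[0]
    if cidx.size:
        tree_by_id = {t["tree_id"]: t for t in trees}
        tid = best_tree[cidx]
        first_z = best_top[cidx] + rng.normal(0, Z_JITTER, cidx.size)
        # number of returns per pulse: geometric decay, capped
        extra = (
            rng.random((cidx.size, cfg.max_returns - 1)) < EXTRA_RETURN_PROB
        )
        # a pulse has k extra returns only if all previous orders fired
        k_extra = np.cumprod(extra, axis=1).sum(axis=1)
        num_ret = 1 + k_extra

        means = np.array(
            [
                tree_by_id[i]["model"].intensity_mean
                * tree_by_id[i]["intensity_factor"]
                for i in tid
            ]
        )
        sds = np.array([tree_by_id[i]["model"].intensity_sd for i in tid])
        stem_zs = np.array([tree_by_id[i]["stem_z"] for i in tid])
        heights = np.array([tree_by_id[i]["height"] for i in tid])
        base_fracs = np.array(
            [tree_by_id[i]["model"].crown_base_frac for i in tid]
        )
        crown_base_z = stem_zs + base_fracs * heights

        prev_z = first_z
        for order in range(1, cfg.max_returns + 1):
            live = num_ret >= order
            n_live = int(live.sum())
            if n_live == 0:
                break
            if order == 1:
                ox, oy, oz = px[cidx][live], py[cidx][live], first_z[live]
            else:
                # deeper into the crown, never below the crown base
                frac = rng.uniform(0.25, 0.7, n_live)
                oz = prev_z[live] - frac * np.maximum(
                    prev_z[live] - crown_base_z[live], 0.0
                )
                ox = px[cidx][live] + rng.uniform(-XY_JITTER, XY_JITTER, n_live)
                oy = py[cidx][live] + rng.uniform(-XY_JITTER, XY_JITTER, n_live)
                nz = prev_z.copy()
                nz[live] = oz
                prev_z = nz
            inten = np.clip(
                rng.normal(means[live], sds[live])
                * INTENSITY_ATTENUATION ** (order - 1),
                1,
                65535,
            )
            parts.append(
                PointCloud(
                    x=ox,
                    y=oy,
                    z=oz,
                    intensity=inten,
                    return_number=np.full(n_live, order, dtype=int),
                    num_returns=num_ret[live].astype(int),
                    classification=np.full(n_live, UNASSIGNED, dtype=np.uint8),
                    source=np.array(
                        [f"crown:{i}" for i in tid[live]], dtype=object
                    ),
                )
            )

    return PointCloud.concatenate(parts)


# ---------------------------------------------------------------------------
# hyperspectral cube


def _soil_spectrum(wl):
    return 0.08 + 0.22 * (wl - wl[0]) / (wl[-1] - wl[0])


def _render_cube(cfg: SceneConfig, trees, rng) -> HyperspectralCube:
    width, depth = cfg.extent
    wl = cfg.wavelengths
    cols = int(round(width / cfg.gsd))
    rows = int(round(depth / cfg.gsd))
    x0, y0 = 0.0, depth  # top-left corner at (0, depth); north-up

    soil = _soil_spectrum(wl).astype(np.float32)
    data = np.broadcast_to(soil, (rows, cols, cfg.n_bands)).copy()

    xs = x0 + (np.arange(cols) + 0.5) * cfg.gsd
    ys = y0 - (np.arange(rows) + 0.5) * cfg.gsd
    sun = _sun_vector()

    ztop_map = np.full((rows, cols), -np.inf)
    for t in trees:
        m = t["model"]
        r = t["radius"]
        c0 = max(0, int((t["x"] - r - x0) / cfg.gsd))
        c1 = min(cols, int((t["x"] + r - x0) / cfg.gsd) + 2)
        r0 = max(0, int((y0 - (t["y"] + r)) / cfg.gsd))
        r1 = min(rows, int((y0 - (t["y"] - r)) / cfg.gsd) + 2)
        if c0 >= c1 or r0 >= r1:
            continue
        subx, suby = np.meshgrid(xs[c0:c1], ys[r0:r1])
        dx = subx - t["x"]
        dy = suby - t["y"]
        d = np.hypot(dx, dy)
        inside = d <= r
        if not inside.any():
            continue
        top = _crown_top_z(
            m.crown_form, d, t["stem_z"], t["height"], m.crown_base_frac, r
        )
        claim = inside & (top > ztop_map[r0:r1, c0:c1])
        if not claim.any():
            continue
        nxv, nyv, nzv = _surface_normal(
            m.crown_form, dx, dy, t["height"], m.crown_base_frac, r
        )
        cosf = nxv * sun[0] + nyv * sun[1] + nzv * sun[2]
        cosf = np.clip(cosf, 0.0, 1.0)
        # shaded = lowest shadow_fraction quantile of the claim's cosines
        if cfg.shadow_fraction > 0:
            thr = np.quantile(cosf[claim], cfg.shadow_fraction)
            shaded = claim & (cosf <= thr)
        else:
            shaded = np.zeros_like(claim)
        sunlit = claim & ~shaded

        scale = np.zeros_like(cosf, dtype=np.float32)
        scale[sunlit] = 1.0
        scale[shaded] = 0.45
        jitter = rng.normal(1.0, 0.03, scale.shape).astype(np.float32)
        endmember = np.clip(
            m.reflectance_endmember
            * t["brightness"]
            * (1.0 + t["nir_tilt"] * (wl - 700.0) / 300.0),
            0.0, 1.0,
        ).astype(np.float32)
        block = data[r0:r1, c0:c1]
        spectra = (scale * jitter)[..., None] * endmember
        block[claim] = spectra[claim]
        ztop_map[r0:r1, c0:c1][claim] = top[claim]

    if cfg.noise_sd_spectral > 0:
        data += rng.standard_normal(data.shape, dtype=np.float32) * np.float32(
            cfg.noise_sd_spectral
        )
    np.clip(data, 0.0, 1.0, out=data)
    return HyperspectralCube(data=data, wavelengths=wl, x0=x0, y0=y0, gsd=cfg.gsd)


# ---------------------------------------------------------------------------
# public entry points


def generate_scene(config: SceneConfig, species_models=None):
    """Generate a co-registered (PointCloud, HyperspectralCube, GroundTruth)
    triple.  Fully reproducible from ``config.seed``."""
    if species_models is None:
        species_models = default_species_models(config.wavelengths)
    if not species_models:
        raise ValueError("need at least one species model")
    for m in species_models:
        if len(m.reflectance_endmember) != config.n_bands:
            raise ValueError(
                f"species {m.name}: endmember has {len(m.reflectance_endmember)}"
                f" bands, scene expects {config.n_bands}"
            )
        m.validate_nir(config.wavelengths)

    rng = np.random.default_rng(config.seed)
    trees = _place_stems(config, species_models, rng)
    cloud = _sample_point_cloud(config, trees, rng)
    cube = _render_cube(config, trees, rng)

    stems = pd.DataFrame(
        {
            "tree_id": [t["tree_id"] for t in trees],
            "x": [t["x"] for t in trees],
            "y": [t["y"] for t in trees],
            "species": [t["species"] for t in trees],
            "height": [t["height"] for t in trees],
            "crown_radius": [t["radius"] for t in trees],
        }
    )
    polys = {
        t["tree_id"]: Point(t["x"], t["y"]).buffer(t["radius"], quad_segs=32)
        for t in trees
    }
    return cloud, cube, GroundTruth(stems=stems, crown_polygons=polys)


def inject_gross_errors(
    cloud: PointCloud, n_high: int, n_low: int, seed: int
) -> PointCloud:
    """Add high gross errors (birds / air returns far above the canopy) and
    low gross errors (multipath returns below the terrain), tagged in the
    ``source`` provenance channel as ``noise_high`` / ``noise_low``."""
    if len(cloud) == 0:
        raise ValueError("cannot inject outliers into an empty cloud")
    if n_high == 0 and n_low == 0:
        return cloud.copy()
    rng = np.random.default_rng(seed)
    zmax, zmin = cloud.z.max(), cloud.z.min()
    n = n_high + n_low
    x = rng.uniform(cloud.x.min(), cloud.x.max(), n)
    y = rng.uniform(cloud.y.min(), cloud.y.max(), n)
    z = np.concatenate(
        [
            zmax + rng.uniform(40.0, 120.0, n_high),
            zmin - rng.uniform(5.0, 20.0, n_low),
        ]
    )
    tags = np.array(["noise_high"] * n_high + ["noise_low"] * n_low, dtype=object)
    extra = PointCloud(
        x=x,
        y=y,
        z=z,
        intensity=rng.uniform(1, 200, n),
        return_number=np.ones(n, dtype=int),
        num_returns=np.ones(n, dtype=int),
        classification=np.full(n, UNASSIGNED, dtype=np.uint8),
        source=tags,
    )
    return PointCloud.concatenate([cloud, extra])
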