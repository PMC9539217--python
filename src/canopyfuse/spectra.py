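"""Crown-spectrum extraction from the registered hyperspectral cube.

A tree's representative spectrum is the per-band mean of the 100 sunlit
pixels nearest the crown centre, where a pixel counts as sunlit when its
reflectance at the 850 nm near-infrared band exceeds 0.25 (reflectance on
the [0, 1] scale).  Sunlit crown surfaces are dominated by first-order
scattering, so this average is much less contaminated by shade and
understory than a whole-crown mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely import contains_xy as _poly_contains
from shapely.geometry import Polygon

from .containers import HyperspectralCube, TreeRecord

SUNLIT_WAVELENGTH_NM = 850.0
SUNLIT_THRESHOLD = 0.25
DEFAULT_N_SUNLIT = 100


def band_at(wavelengths, target_nm: float):
    """Index of the band nearest ``target_nm`` plus the distance in nm.

    Raises when the target lies outside the grid by more than one band
    spacing.
    """
    wl = np.asarray(wavelengths, float)
    spacing = np.diff(wl).max()
    if target_nm < wl[0] - spacing or target_nm > wl[-1] + spacing:
        raise ValueError(
            f"target {target_nm} nm outside wavelength grid "
            f"[{wl[0]}, {wl[-1]}] by more than one band spacing"
        )
    idx = int(np.argmin(np.abs(wl - target_nm)))
    return idx, float(abs(wl[idx] - target_nm))


@dataclass
class CrownPixelSet:
    """Pixels of one crown: coordinates, spectra and sunlit flags."""

    rows: np.ndarray
    cols: np.ndarray
    spectra: np.ndarray           # (n_pixels, n_bands)
    sunlit: np.ndarray            # bool
    distance_to_center: np.ndarray  # metres
    nir_band: int = 0             # index of the 850 nm band
    shortfall: bool = False       # fewer sunlit pixels than requested
    fallback: bool = False        # no sunlit pixel; brightest-NIR decile used

    def __len__(self) -> int:
        return len(self.rows)


def mask_crown(cube: HyperspectralCube, polygon: Polygon,
               center=None) -> CrownPixelSet:
    """Pixels whose centres fall inside the crown polygon.

    Nodata pixels are excluded.  ``center`` defaults to the polygon
    centroid and feeds the per-pixel distance used by
    :func:`select_sunlit`.
    """
    xs, ys = cube.pixel_centers()
    minx, miny, maxx, maxy = polygon.bounds
    cmask = (xs >= minx - cube.gsd) & (xs <= maxx + cube.gsd)
    rmask = (ys >= miny - cube.gsd) & (ys <= maxy + cube.gsd)
    cs = np.nonzero(cmask)[0]
    rs = np.nonzero(rmask)[0]
    if cs.size == 0 or rs.size == 0:
        import warnings

        warnings.warn("crown polygon falls entirely outside the raster")
        nir_idx, _ = band_at(cube.wavelengths, SUNLIT_WAVELENGTH_NM)
        return _empty_pixel_set(cube.n_bands, nir_idx)
    gc, gr = np.meshgrid(cs, rs)
    gx = xs[gc]
    gy = ys[gr]
    inside = _poly_contains(polygon, gx, gy)
    inside &= ~cube.nodata[gr, gc]
    rows = gr[inside]
    cols = gc[inside]
    nir_idx, _ = band_at(cube.wavelengths, SUNLIT_WAVELENGTH_NM)
    if rows.size == 0:
        return _empty_pixel_set(cube.n_bands, nir_idx)
    if center is None:
        center = (polygon.centroid.x, polygon.centroid.y)
    dist = np.hypot(xs[cols] - center[0], ys[rows] - center[1])
    spectra = cube.data[rows, cols].astype(float)
    sunlit = spectra[:, nir_idx] > SUNLIT_THRESHOLD
    return CrownPixelSet(
        rows=rows, cols=cols, spectra=spectra, sunlit=sunlit,
        distance_to_center=dist, nir_band=nir_idx,
    )


def _empty_pixel_set(n_bands: int, nir_band: int = 0) -> CrownPixelSet:
    return CrownPixelSet(
        rows=np.empty(0, int), cols=np.empty(0, int),
        spectra=np.empty((0, n_bands)), sunlit=np.empty(0, bool),
        distance_to_center=np.empty(0), nir_band=nir_band,
    )


def select_sunlit(pixels: CrownPixelSet,
                  n_pixels: int = DEFAULT_N_SUNLIT) -> CrownPixelSet:
    """The ``n_pixels`` sunlit pixels nearest the crown centre.

    Ties in distance break by row-major pixel order.  If fewer sunlit
    pixels exist, all are used and the shortfall flag is set; if none
    exist, the brightest-NIR decile of all crown pixels is used and the
    fallback flag is set.
    """
    if len(pixels) == 0:
        raise ValueError("empty crown pixel set")
    sun_idx = np.nonzero(pixels.sunlit)[0]
    shortfall = fallback = False
    if sun_idx.size == 0:
        fallback = True
        nir = pixels.spectra[:, pixels.nir_band]
        decile = max(1, len(pixels) // 10)
        sun_idx = np.argsort(-nir, kind="stable")[:decile]
    elif sun_idx.size < n_pixels:
        shortfall = True

    if sun_idx.size > n_pixels:
        # row-major order is the secondary sort key
        rowmajor = pixels.rows[sun_idx] * (pixels.cols.max() + 1) + pixels.cols[
            sun_idx
        ]
        order = np.lexsort((rowmajor, pixels.distance_to_center[sun_idx]))
        sun_idx = sun_idx[order[:n_pixels]]

    return CrownPixelSet(
        rows=pixels.rows[sun_idx],
        cols=pixels.cols[sun_idx],
        spectra=pixels.spectra[sun_idx],
        sunlit=pixels.sunlit[sun_idx],
        distance_to_center=pixels.distance_to_center[sun_idx],
        nir_band=pixels.nir_band,
        shortfall=shortfall,
        fallback=fallback,
    )


def mean_spectrum(pixels: CrownPixelSet) -> np.ndarray:
    """Per-band arithmetic mean over the pixel set."""
    if len(pixels) == 0:
        raise ValueError("cannot average an empty pixel set")
    return pixels.spectra.mean(axis=0)


def extract_crown_spectra(trees, cube: HyperspectralCube,
                          n_sunlit: int = DEFAULT_N_SUNLIT) -> list:
    """Fill ``crown_spectrum`` on every tree record; trees whose crown
    yields no pixels are flagged and left without a spectrum."""
    for tree in trees:
        if tree.crown_polygon is None:
            tree.flags["no_polygon"] = True
            continue
        pixels = mask_crown(cube, tree.crown_polygon)
        if len(pixels) == 0:
            tree.flags["no_pixels"] = True
            continue
        chosen = select_sunlit(pixels, n_sunlit)
        tree.crown_spectrum = mean_spectrum(chosen)
        if chosen.shortfall:
            tree.flags["sunlit_shortfall"] = True
        if chosen.fallback:
            tree.flags["sunlit_fallback"] = True
    return trees
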