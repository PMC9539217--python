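"""Hyperspectral feature catalog: 363 named features per tree.

Per tree the catalog is the 300 original reflectance bands
(``band_1``..``band_300``), 18 vegetation indices computed from
nearest-band lookups, and the leading components of three linear
transforms fitted across the tree set: 10 principal components (PCA),
15 minimum-noise-fraction components (MNF, ordered by signal-to-noise
ratio) and 20 independent components (ICA, ordered by a negentropy
approximation with a deterministic sign convention).

The transforms are fitted on the matrix of crown mean spectra — one
300-vector per tree — not on image pixels, which keeps the pipeline
image-free once crown spectra are extracted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, FastICA
from sklearn.utils.validation import check_is_fitted

from .containers import new_feature_table
from .spectra import band_at

INDEX_NAMES = (
    "NDVI", "SRI", "EVI", "ARVI", "SGI", "RENDVI", "MRESRI", "MRENDVI",
    "VREI1", "REPI", "PRI", "SIPI", "RGRI", "CRI1", "CRI2", "ARI1",
    "ARI2", "WBI",
)


def _safe_div(num, den, flags, name):
    if den == 0:
        flags.add(name)
        return np.nan
    return num / den


def vegetation_indices(spectrum, wavelengths, mresri_literature: bool = False):
    """The 18 vegetation indices, from nearest-band reflectance lookups.

    Returns ``(values, missing)`` where ``values`` maps index name to
    value and ``missing`` is the set of indices whose denominator was
    zero (value NaN).

    ``mresri_literature`` switches the MRESRI denominator from the
    as-published form (rho705 + rho445) to the common literature form
    (rho705 - rho445).
    """
    s = np.asarray(spectrum, float)
    wl = np.asarray(wavelengths, float)

    def r(nm):
        return s[band_at(wl, nm)[0]]

    flags: set = set()
    v = {}
    v["NDVI"] = _safe_div(r(865) - r(672), r(865) + r(672), flags, "NDVI")
    v["SRI"] = _safe_div(r(865), r(672), flags, "SRI")
    v["EVI"] = 2.5 * _safe_div(
        r(865) - r(672), r(865) + 6 * r(672) - 7.5 * r(464) + 1, flags, "EVI"
    )
    v["ARVI"] = _safe_div(
        r(865) - (2 * r(672) - r(464)),
        r(865) + (2 * r(672) - r(464)),
        flags, "ARVI",
    )
    green = (wl >= 500) & (wl <= 599)
    red = (wl >= 600) & (wl <= 699)
    v["SGI"] = float(s[green].mean())
    v["RENDVI"] = _safe_div(r(750) - r(705), r(750) + r(705), flags, "RENDVI")
    mresri_den = r(705) - r(445) if mresri_literature else r(705) + r(445)
    v["MRESRI"] = _safe_div(r(750) - r(445), mresri_den, flags, "MRESRI")
    v["MRENDVI"] = _safe_div(
        r(750) - r(705), r(750) + r(705) - 2 * r(445), flags, "MRENDVI"
    )
    v["VREI1"] = _safe_div(r(740), r(720), flags, "VREI1")
    v["REPI"] = _red_edge_position(s, wl)
    v["PRI"] = _safe_div(r(570) - r(531), r(531) + r(570), flags, "PRI")
    v["SIPI"] = _safe_div(r(800) - r(445), r(800) - r(680), flags, "SIPI")
    v["RGRI"] = _safe_div(float(s[red].sum()), float(s[green].sum()), flags, "RGRI")
    for name, a, b in (
        ("CRI1", 510, 550), ("CRI2", 510, 700), ("ARI1", 550, 700)
    ):
        if r(a) == 0 or r(b) == 0:
            flags.add(name)
            v[name] = np.nan
        else:
            v[name] = 1.0 / r(a) - 1.0 / r(b)
    if r(550) == 0 or r(700) == 0:
        flags.add("ARI2")
        v["ARI2"] = np.nan
    else:
        v["ARI2"] = r(800) * (1.0 / r(550) - 1.0 / r(700))
    v["WBI"] = _safe_div(r(970), r(900), flags, "WBI")
    return v, flags


def _red_edge_position(s, wl):
    """Wavelength of the maximum first derivative over 690-740 nm.

    Finite differences on the band grid, each assigned to the upper band
    of its pair; ties go to the longest wavelength (the far side of the
    inflection, the conventional red-edge reading).
    """
    in_range = np.nonzero((wl >= 690.0) & (wl <= 740.0))[0]
    if len(in_range) < 2:
        raise ValueError("wavelength grid too coarse for the red-edge window")
    i0, i1 = in_range[0], in_range[-1]
    deriv = (s[i0 + 1 : i1 + 1] - s[i0 : i1]) / (wl[i0 + 1 : i1 + 1] - wl[i0 : i1])
    upper_wl = wl[i0 + 1 : i1 + 1]
    best = deriv.max()
    # tie rule: the longest wavelength attaining the maximum (within fp noise)
    winners = upper_wl[deriv >= best - 1e-12 * max(1.0, abs(best))]
    return float(winners.max())


class MNFRotation(BaseEstimator, TransformerMixin):
    """Minimum-noise-fraction rotation.

    Noise variance is estimated per band from band-to-band first
    differences of each spectrum (a diagonal noise covariance — robust
    when trees are far fewer than bands); the noise-whitened data is then
    rotated by PCA and components are ordered by descending
    signal-to-noise ratio.

    Attributes (after fit): ``mean_``, ``noise_sd_``, ``components_``
    (n_components x n_bands loadings in the original band space) and
    ``snr_`` (descending).
    """

    def __init__(self, n_components: int = 15):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        n, p = X.shape
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        d = np.diff(X, axis=1) / np.sqrt(2.0)
        nv = np.empty(p)
        nv[1:-1] = 0.5 * (np.mean(d[:, :-1] ** 2, 0) + np.mean(d[:, 1:] ** 2, 0))
        nv[0] = np.mean(d[:, 0] ** 2)
        nv[-1] = np.mean(d[:, -1] ** 2)
        nv = np.maximum(nv, 1e-12 * max(nv.max(), 1e-30))
        self.noise_sd_ = np.sqrt(nv)
        Xw = Xc / self.noise_sd_
        k = min(self.n_components, n - 1, p)
        if k < self.n_components:
            warnings.warn(
                f"rank supports only {k} MNF components "
                f"({self.n_components} requested)"
            )
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(Xw)
        # eigenvalue of the whitened covariance = SNR + 1
        self.snr_ = pca.explained_variance_ - 1.0
        self.components_ = pca.components_ / self.noise_sd_[None, :]
        self._whitened_pca = pca
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, float)
        return (X - self.mean_) @ self.components_.T


class OrderedICA(BaseEstimator, TransformerMixin):
    """FastICA with a canonical component order and sign.

    ICA has no intrinsic component ordering, so after the fixed-seed
    fixed-point fit the components are sorted by descending negentropy
    (log-cosh approximation) and each is signed so that its
    largest-magnitude loading is positive.
    """

    def __init__(self, n_components: int = 20, random_state: int = 0,
                 max_iter: int = 2000, tol: float = 1e-5):
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        n, p = X.shape
        k = min(self.n_components, n - 1, p)
        if k < self.n_components:
            warnings.warn(
                f"rank supports only {k} ICA components "
                f"({self.n_components} requested)"
            )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*did not converge.*")
            ica = FastICA(
                n_components=k, random_state=self.random_state,
                max_iter=self.max_iter, tol=self.tol, whiten="unit-variance",
            )
            scores = ica.fit_transform(X)
        # negentropy approximation J ~ (E[logcosh(y)] - E[logcosh(nu)])^2
        std = scores.std(axis=0, ddof=0)
        std[std == 0] = 1.0
        y_std = scores / std
        gauss_ref = 0.6931471805599453  # E[log cosh nu], nu ~ N(0,1)
        negent = (np.mean(np.log(np.cosh(y_std)), axis=0) - gauss_ref) ** 2
        order = np.argsort(-negent)
        comps = ica.components_[order]
        signs = np.sign(comps[np.arange(len(order)),
                               np.argmax(np.abs(comps), axis=1)])
        signs[signs == 0] = 1.0
        self.components_ = comps * signs[:, None]
        self.mean_ = ica.mean_
        self.negentropy_ = negent[order]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, float)
        return (X - self.mean_) @ self.components_.T


def fit_transform_suite(spectra: np.ndarray, n_pca: int = 10, n_mnf: int = 15,
                        n_ica: int = 20, seed: int = 0):
    """Fit the PCA / MNF / ICA triple on a trees x bands spectra matrix.

    Returns ``(models, scores)`` where ``models`` is a dict of fitted
    transformers and ``scores`` a dict of trees x components arrays.
    """
    spectra = np.asarray(spectra, float)
    n = len(spectra)
    if n < 2:
        raise ValueError("need at least 2 spectra to fit transforms")
    k_pca = min(n_pca, n - 1, spectra.shape[1])
    if k_pca < n_pca:
        warnings.warn(f"rank supports only {k_pca} PCA components")
    pca = PCA(n_components=k_pca, svd_solver="full").fit(spectra)
    mnf = MNFRotation(n_components=n_mnf).fit(spectra)
    ica = OrderedICA(n_components=n_ica, random_state=seed).fit(spectra)
    models = {"PCA": pca, "MNF": mnf, "ICA": ica}
    scores = {
        "PCA": pca.transform(spectra),
        "MNF": mnf.transform(spectra),
        "ICA": ica.transform(spectra),
    }
    return models, scores


def assemble_hsi_features(trees, wavelengths, seed: int = 0,
                          mresri_literature: bool = False,
                          n_pca: int = 10, n_mnf: int = 15,
                          n_ica: int = 20):
    """Build the trees x 363 hyperspectral feature table.

    Trees without a crown spectrum are dropped (logged via a warning).
    Returns ``(table, models)``; the table carries per-column provenance
    tags (band / index / PCA / MNF / ICA) in ``attrs``.
    """
    kept = [t for t in trees if t.crown_spectrum is not None]
    dropped = len(trees) - len(kept)
    if dropped:
        warnings.warn(f"{dropped} trees lack a crown spectrum and were dropped")
    if len(kept) < 2:
        raise ValueError("need at least 2 trees with spectra")
    wl = np.asarray(wavelengths, float)
    spectra = np.vstack([t.crown_spectrum for t in kept])
    index = [t.tree_id for t in kept]

    band_cols = [f"band_{i + 1}" for i in range(spectra.shape[1])]
    values = {c: spectra[:, i] for i, c in enumerate(band_cols)}
    prov = {c: "band" for c in band_cols}

    vi_rows = []
    for t in kept:
        vals, flags = vegetation_indices(t.crown_spectrum, wl,
                                         mresri_literature=mresri_literature)
        if flags:
            t.flags["index_missing"] = sorted(flags)
        vi_rows.append(vals)
    for name in INDEX_NAMES:
        values[name] = np.array([row[name] for row in vi_rows])
        prov[name] = "index"

    models, scores = fit_transform_suite(
        spectra, n_pca=n_pca, n_mnf=n_mnf, n_ica=n_ica, seed=seed
    )
    for kind in ("PCA", "MNF", "ICA"):
        sc = scores[kind]
        for j in range(sc.shape[1]):
            col = f"{kind}{j + 1}"
            values[col] = sc[:, j]
            prov[col] = kind

    columns = list(values)
    table = new_feature_table(
        index, columns, {c: values[c] for c in columns}, prov
    )
    return table, models
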