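"""Core in-memory containers shared by every pipeline stage.

All geometry lives in a single projected metric CRS.  The point cloud is a
struct-of-arrays (one NumPy array per attribute) rather than an
array-of-structs, so that per-stage masking and vectorised statistics stay
cheap on clouds of a few hundred thousand points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping

# LAS-style classification codes
UNASSIGNED = 1
GROUND = 2
VEGETATION = 5
NOISE = 7

_POINT_COLUMNS = ("x", "y", "z", "intensity", "return_number", "num_returns")


@dataclass
class PointCloud:
    """Multi-return LiDAR point cloud.

    Attributes
    ----------
    x, y, z : float64 arrays, metres in a projected CRS.
    intensity : float64 array, echo amplitude on a 16-bit scale.
    return_number, num_returns : int arrays, 1..max_returns,
        ``return_number <= num_returns`` per point.
    classification : uint8 array of LAS-style codes
        (UNASSIGNED / GROUND / VEGETATION / NOISE).
    hag : float64 array, height above ground in metres; NaN until
        :func:`canopyfuse.preprocess.normalize_heights` has run.
    source : object array of provenance tags set by the scene simulator
        (e.g. ``"ground"``, ``"crown:7"``, ``"noise_high"``); empty strings
        for real data.  Used only by tests and diagnostics.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    intensity: np.ndarray
    return_number: np.ndarray
    num_returns: np.ndarray
    classification: np.ndarray = None
    hag: np.ndarray = None
    source: np.ndarray = None

    def __post_init__(self):
        n = len(self.x)
        if self.classification is None:
            self.classification = np.full(n, UNASSIGNED, dtype=np.uint8)
        if self.hag is None:
            self.hag = np.full(n, np.nan)
        if self.source is None:
            self.source = np.full(n, "", dtype=object)
        if np.any(self.return_number > self.num_returns):
            raise ValueError("return_number exceeds num_returns for some points")

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, mask: np.ndarray) -> "PointCloud":
        """Return a copy restricted to ``mask`` (boolean or index array)."""
        return PointCloud(
            x=self.x[mask].copy(),
            y=self.y[mask].copy(),
            z=self.z[mask].copy(),
            intensity=self.intensity[mask].copy(),
            return_number=self.return_number[mask].copy(),
            num_returns=self.num_returns[mask].copy(),
            classification=self.classification[mask].copy(),
            hag=self.hag[mask].copy(),
            source=self.source[mask].copy(),
        )

    def copy(self) -> "PointCloud":
        return self.subset(np.ones(len(self), dtype=bool))

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "z": self.z,
                "intensity": self.intensity,
                "return_number": self.return_number,
                "num_returns": self.num_returns,
                "classification": self.classification,
                "hag": self.hag,
                "source": self.source,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PointCloud":
        missing = [c for c in _POINT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"point table missing columns: {missing}")
        n = len(df)
        return cls(
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            z=df["z"].to_numpy(float),
            intensity=df["intensity"].to_numpy(float),
            return_number=df["return_number"].to_numpy(int),
            num_returns=df["num_returns"].to_numpy(int),
            classification=(
                df["classification"].to_numpy(np.uint8)
                if "classification" in df
                else None
            ),
            hag=df["hag"].to_numpy(float) if "hag" in df else None,
            source=(
                df["source"].fillna("").to_numpy(object) if "source" in df else None
            ),
        )

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def load_csv(cls, path) -> "PointCloud":
        return cls.from_dataframe(pd.read_csv(path, keep_default_na=False,
                                              na_values=["nan", "NaN", ""]))

    @staticmethod
    def concatenate(clouds) -> "PointCloud":
        clouds = list(clouds)
        return PointCloud(
            x=np.concatenate([c.x for c in clouds]),
            y=np.concatenate([c.y for c in clouds]),
            z=np.concatenate([c.z for c in clouds]),
            intensity=np.concatenate([c.intensity for c in clouds]),
            return_number=np.concatenate([c.return_number for c in clouds]),
            num_returns=np.concatenate([c.num_returns for c in clouds]),
            classification=np.concatenate([c.classification for c in clouds]),
            hag=np.concatenate([c.hag for c in clouds]),
            source=np.concatenate([c.source for c in clouds]),
        )


@dataclass
class HyperspectralCube:
    """Georeferenced reflectance cube, north-up square pixels.

    ``data`` has shape (rows, cols, bands) with reflectance in [0, 1].
    Pixel (row, col) has its centre at
    ``x = x0 + (col + 0.5) * gsd`` and ``y = y0 - (row + 0.5) * gsd``
    where (x0, y0) is the outer corner of the top-left pixel.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    x0: float
    y0: float
    gsd: float
    nodata: np.ndarray = None  # bool (rows, cols); True where invalid

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (rows, cols, bands)")
        if self.data.shape[2] != len(self.wavelengths):
            raise ValueError("band count does not match wavelength list")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if self.nodata is None:
            self.nodata = np.zeros(self.data.shape[:2], dtype=bool)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def pixel_centers(self):
        """Return (xs, ys) 1-D arrays of column / row centre coordinates."""
        rows, cols = self.data.shape[:2]
        xs = self.x0 + (np.arange(cols) + 0.5) * self.gsd
        ys = self.y0 - (np.arange(rows) + 0.5) * self.gsd
        return xs, ys

    def world_to_pixel(self, x, y):
        """Map CRS coordinates to fractional (row, col)."""
        col = (np.asarray(x) - self.x0) / self.gsd - 0.5
        row = (self.y0 - np.asarray(y)) / self.gsd - 0.5
        return row, col


@dataclass
class GroundTruth:
    """Reference stem map from the scene simulator (or a field survey).

    ``stems`` has one row per tree: x, y, species, height, crown_radius,
    tree_id.  ``crown_polygons`` maps tree_id to the true crown footprint.
    """

    stems: pd.DataFrame
    crown_polygons: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.stems)

    def to_geojson(self, path) -> None:
        feats = []
        for _, row in self.stems.iterrows():
            poly = self.crown_polygons.get(row["tree_id"])
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(poly) if poly is not None else None,
                    "properties": {
                        "tree_id": int(row["tree_id"]),
                        "x": float(row["x"]),
                        "y": float(row["y"]),
                        "species": str(row["species"]),
                        "height": float(row["height"]),
                    },
                }
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclass
class TreeRecord:
    """One segmented tree and everything derived from it."""

    tree_id: int
    points: PointCloud
    apex_xy: tuple
    crown_polygon: Polygon = None
    height: float = np.nan          # H_T, metres
    crown_width: float = np.nan     # W_C, metres
    crown_area: float = np.nan      # A_C, m^2
    crown_volume: float = np.nan    # V_C, m^3
    species: str = "unknown"
    crown_spectrum: np.ndarray = None
    flags: dict = field(default_factory=dict)


def new_feature_table(index, columns, values, provenance) -> pd.DataFrame:
    """Build a trees x features table carrying per-column provenance tags.

    Provenance (``band`` / ``index`` / ``PCA`` / ``MNF`` / ``ICA`` /
    ``shape`` / ``height`` / ``height_bin`` / ``intensity``) is stored in
    ``DataFrame.attrs["provenance"]``.
    """
    df = pd.DataFrame(values, index=index, columns=columns)
    if isinstance(provenance, dict):
        prov = provenance
    else:
        prov = dict(zip(columns, provenance))
    if set(prov) != set(columns):
        raise ValueError("provenance must cover every column exactly once")
    df.attrs["provenance"] = prov
    df.index.name = "tree_id"
    return df


def merge_feature_tables(left: pd.DataFrame, right: pd.DataFrame) -> pd.DataFrame:
    """Column-wise fusion of two feature tables on a shared tree index."""
    overlap = set(left.columns) & set(right.columns)
    if overlap:
        raise ValueError(f"duplicate feature names in fusion: {sorted(overlap)[:5]}")
    fused = left.join(right, how="inner")
    fused.attrs["provenance"] = {
        **left.attrs.get("provenance", {}),
        **right.attrs.get("provenance", {}),
    }
    return fused
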