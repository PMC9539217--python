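"""File formats for pipeline artifacts.

Point clouds travel as CSV (one row per point), cubes as ENVI BSQ (raw
float32 band-sequential binary plus a text header carrying the
wavelength list and georeferencing), vectors as GeoJSON.  The ENVI
reader/writer below covers exactly the subset of the header this
pipeline produces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import mapping, shape

from .containers import HyperspectralCube


def write_envi(cube: HyperspectralCube, base_path) -> Path:
    """Write ``<base>.bsq`` + ``<base>.hdr``; returns the header path."""
    base = Path(base_path)
    bsq = base.with_suffix(".bsq")
    hdr = base.with_suffix(".hdr")
    rows, cols, bands = cube.data.shape
    np.ascontiguousarray(
        np.transpose(cube.data.astype("<f4"), (2, 0, 1))
    ).tofile(bsq)
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    hdr_text = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"map info = {{projected, 1, 1, {cube.x0}, {cube.y0}, "
        f"{cube.gsd}, {cube.gsd}}}\n"
        f"wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr.write_text(hdr_text)
    return hdr


def _parse_header(text: str) -> dict:
    fields = {}
    key, buf = None, ""
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, val = (p.strip() for p in line.split("=", 1))
            if val.startswith("{") and "}" not in val:
                buf = val
                continue
            fields[key.lower()] = val.strip("{} ")
            key = None
        else:
            buf += " " + line
            if "}" in line:
                fields[key.lower()] = buf.strip("{} ")
                key = None
                buf = ""
    return fields


def read_envi(base_path) -> HyperspectralCube:
    base = Path(base_path)
    hdr = base.with_suffix(".hdr")
    bsq = base.with_suffix(".bsq")
    fields = _parse_header(hdr.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    if int(fields.get("data type", 4)) != 4:
        raise ValueError("only float32 (data type 4) is supported")
    data = np.fromfile(bsq, dtype="<f4").reshape(bands, rows, cols)
    wavelengths = np.array(
        [float(w) for w in fields["wavelength"].split(",")]
    )
    map_info = [p.strip() for p in fields["map info"].split(",")]
    x0, y0, gsd = float(map_info[3]), float(map_info[4]), float(map_info[5])
    return HyperspectralCube(
        data=np.transpose(data, (1, 2, 0)),
        wavelengths=wavelengths,
        x0=x0, y0=y0, gsd=gsd,
    )


def write_crowns_geojson(trees, path) -> None:
    feats = []
    for t in trees:
        feats.append(
            {
                "type": "Feature",
                "geometry": (
                    mapping(t.crown_polygon)
                    if t.crown_polygon is not None else None
                ),
                "properties": {
                    "tree_id": int(t.tree_id),
                    "apex_x": float(t.apex_xy[0]),
                    "apex_y": float(t.apex_xy[1]),
                    "H_T": float(t.height),
                    "W_C": float(t.crown_width),
                    "A_C": float(t.crown_area),
                    "V_C": float(t.crown_volume),
                    "species": str(t.species),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_crowns_geojson(path):
    """Returns a list of (properties, shapely geometry) pairs."""
    with open(path) as fh:
        fc = json.load(fh)
    out = []
    for feat in fc["features"]:
        geom = shape(feat["geometry"]) if feat["geometry"] else None
        out.append((feat["properties"], geom))
    return out
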