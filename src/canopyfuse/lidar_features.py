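"""Per-tree LiDAR feature catalog: exactly 60 named features.

Three echo-class partitions are used throughout — total (all returns),
first returns and second returns, written ``0`` / ``1`` / ``2`` in the
feature names.  Per partition the catalog holds 9 height statistics,
5 relative-height-bin proportions and 5 intensity statistics; the three
crown shape ratios (crown width / area / volume over tree height)
complete the 60.  The four raw structural parameters H_T, W_C, A_C and
V_C stay on the tree record and are deliberately not feature columns —
3 + 27 + 15 + 15 is the only decomposition consistent with the total.

Statistics use the sample standard deviation (n-1), Fisher-Pearson g1
skewness and excess kurtosis g2; percentiles interpolate linearly.  A
statistic whose preconditions fail (too few points, zero mean for the
CV) is reported as 0 and the tree/partition is flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import TreeRecord, new_feature_table

PARTITIONS = (0, 1, 2)  # total, first echo, second echo
BIN_EDGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
BIN_NAMES = ("0_20", "20_40", "40_60", "60_80", "80_100")


def echo_partition(tree: TreeRecord, n: int) -> np.ndarray:
    """Boolean mask over the tree's points for echo class ``n``
    (0 = all returns, 1 = first returns, 2 = second returns)."""
    rn = tree.points.return_number
    if n == 0:
        return np.ones(len(rn), dtype=bool)
    return rn == n


def shape_ratios(tree: TreeRecord):
    """(R_W/H, R_A/H, R_V/H): crown width / area / volume over height."""
    if not np.isfinite(tree.height) or tree.height <= 0:
        raise ValueError("tree height must be positive (run crown_metrics)")
    return (
        tree.crown_width / tree.height,
        tree.crown_area / tree.height,
        tree.crown_volume / tree.height,
    )


def _moment_stats(values: np.ndarray, flags: set, prefix: str):
    """mean, std, CV, skewness, kurtosis with the missingness policy."""
    out = {}
    n = len(values)
    if n == 0:
        flags.add(prefix)
        return {f"{prefix}_{s}": 0.0 for s in ("mean", "std", "CV", "S", "K")}
    mean = float(np.mean(values))
    out[f"{prefix}_mean"] = mean
    if n >= 2:
        std = float(np.std(values, ddof=1))
    else:
        std = 0.0
        flags.add(f"{prefix}_std")
    out[f"{prefix}_std"] = std
    if mean != 0:
        out[f"{prefix}_CV"] = std / mean
    else:
        out[f"{prefix}_CV"] = 0.0
        flags.add(f"{prefix}_CV")
    if n >= 3 and std > 0:
        out[f"{prefix}_S"] = float(sps.skew(values, bias=False))
    else:
        out[f"{prefix}_S"] = 0.0
        flags.add(f"{prefix}_S")
    if n >= 4 and std > 0:
        out[f"{prefix}_K"] = float(sps.kurtosis(values, bias=False))
    else:
        out[f"{prefix}_K"] = 0.0
        flags.add(f"{prefix}_K")
    return out


def height_stats(tree: TreeRecord, n: int, flags: set = None) -> dict:
    """9 height features for echo class ``n``: moments plus the 25/50/75/95
    height percentiles (linear interpolation)."""
    if flags is None:
        flags = set()
    h = tree.points.hag[echo_partition(tree, n)]
    prefix = f"H_{n}"
    out = _moment_stats(h, flags, prefix)
    if len(h) == 0:
        for q in (25, 50, 75, 95):
            out[f"{prefix}_{q}"] = 0.0
        flags.add(prefix)
    else:
        for q in (25, 50, 75, 95):
            out[f"{prefix}_{q}"] = float(np.percentile(h, q))
    return out


def height_bin_proportions(tree: TreeRecord, n: int, flags: set = None) -> dict:
    """Eq.-style relative-height bin proportions H_nP_m.

    Heights are normalised by the tree's H_T; bins are half-open
    [0,.2), [.2,.4), [.4,.6), [.6,.8) with the top bin [.8,1] closed, so
    the five fractions sum to 1 whenever the partition has points.
    """
    if flags is None:
        flags = set()
    h = tree.points.hag[echo_partition(tree, n)]
    prefix = f"H_{n}_P"
    if len(h) == 0 or tree.height <= 0:
        flags.add(prefix)
        return {f"{prefix}_{b}": 0.0 for b in BIN_NAMES}
    rel = np.clip(h / tree.height, 0.0, 1.0)
    counts = np.histogram(rel, bins=BIN_EDGES)[0]  # numpy closes the top bin
    fractions = counts / len(h)
    return {f"{prefix}_{b}": float(f) for b, f in zip(BIN_NAMES, fractions)}


def intensity_stats(tree: TreeRecord, n: int, flags: set = None) -> dict:
    """5 intensity features for echo class ``n`` (same conventions as the
    height moments)."""
    if flags is None:
        flags = set()
    i = tree.points.intensity[echo_partition(tree, n)]
    return _moment_stats(i, flags, f"I_{n}")


def lidar_feature_vector(tree: TreeRecord):
    """All 60 features for one tree plus its missingness flags."""
    flags: set = set()
    rwh, rah, rvh = shape_ratios(tree)
    feats = {"R_WH": rwh, "R_AH": rah, "R_VH": rvh}
    for n in PARTITIONS:
        feats.update(height_stats(tree, n, flags))
    for n in PARTITIONS:
        feats.update(height_bin_proportions(tree, n, flags))
    for n in PARTITIONS:
        feats.update(intensity_stats(tree, n, flags))
    return feats, flags


def assemble_lidar_features(trees):
    """Build the trees x 60 LiDAR feature table.

    Returns ``(table, flag_table)``; ``flag_table`` is a tree -> flagged
    feature-group sidecar keeping the main matrix rectangular.
    """
    rows, flag_rows, index = [], [], []
    for t in trees:
        feats, flags = lidar_feature_vector(t)
        rows.append(feats)
        flag_rows.append(sorted(flags))
        index.append(t.tree_id)
    if not rows:
        raise ValueError("no trees")
    columns = list(rows[0])
    assert len(columns) == 60
    values = {c: np.array([r[c] for r in rows]) for c in columns}
    prov = {}
    for c in columns:
        if c.startswith("R_"):
            prov[c] = "shape"
        elif "_P_" in c:
            prov[c] = "height_bin"
        elif c.startswith("H_"):
            prov[c] = "height"
        else:
            prov[c] = "intensity"
    table = new_feature_table(index, columns, values, prov)
    flag_table = pd.DataFrame(
        {"tree_id": index, "flagged": [";".join(f) for f in flag_rows]}
    ).set_index("tree_id")
    return table, flag_table
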