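"""Shared fixtures: one moderately sized synthetic stand processed through
the full chain (session-scoped, reused by most modules) plus small
special-purpose clouds built inline by the tests that need them."""

import numpy as np
import pandas as pd
import pytest

from canopyfuse import (
    assemble_hsi_features,
    assemble_lidar_features,
    crown_metrics,
    crown_outline,
    denoise,
    extract_crown_spectra,
    filter_ground,
    generate_scene,
    match_to_reference,
    merge_feature_tables,
    normalize_heights,
    segment_trees,
    smooth_spectra,
)
from canopyfuse.synthetic import scene_preset

SCENE_SEED = 42


@pytest.fixture(scope="session")
def sparse_scene():
    """Raw sparse-preset scene, scaled to 40 trees on 42x42 m for test
    runtime; crowns stay >= 3.5 m apart as in the preset."""
    cfg = scene_preset(
        "sparse", seed=SCENE_SEED, extent=(42.0, 42.0), n_trees=40,
        point_density=120.0,
    )
    cloud, cube, truth = generate_scene(cfg)
    return {"config": cfg, "cloud": cloud, "cube": cube, "truth": truth}


@pytest.fixture(scope="session")
def processed_scene(sparse_scene):
    """The sparse scene taken through denoise -> ground filter -> height
    normalization -> spectral smoothing -> segmentation -> crown metrics
    -> reference matching -> crown spectra."""
    cloud = normalize_heights(filter_ground(denoise(sparse_scene["cloud"])))
    cube = smooth_spectra(sparse_scene["cube"])
    trees = segment_trees(cloud)
    for t in trees:
        crown_outline(t)
        crown_metrics(t)
    truth = sparse_scene["truth"]
    match = match_to_reference(trees, truth)
    stems = truth.stems.reset_index(drop=True)
    for t in trees:
        si = match.assignments.get(t.tree_id)
        if si is not None:
            t.species = str(stems.loc[si, "species"])
    extract_crown_spectra(trees, cube)
    return {
        **sparse_scene,
        "cloud_norm": cloud,
        "cube_smooth": cube,
        "trees": trees,
        "match": match,
    }


@pytest.fixture(scope="session")
def labeled_trees(processed_scene):
    trees = [
        t for t in processed_scene["trees"]
        if t.species != "unknown" and t.crown_spectrum is not None
    ]
    labels = pd.Series({t.tree_id: t.species for t in trees})
    return trees, labels


@pytest.fixture(scope="session")
def feature_tables(processed_scene, labeled_trees):
    trees, labels = labeled_trees
    wl = processed_scene["cube_smooth"].wavelengths
    hsi, models = assemble_hsi_features(trees, wl, seed=1)
    lidar, flags = assemble_lidar_features(trees)
    lidar = lidar.loc[hsi.index]
    fused = merge_feature_tables(hsi, lidar)
    return {
        "HSI": hsi,
        "LiDAR": lidar,
        "HSI+LiDAR": fused,
        "labels": labels.loc[hsi.index],
        "models": models,
        "flags": flags,
    }


def make_cloud(x, y, z, intensity=None, return_number=None, num_returns=None,
               classification=None, hag=None):
    """Convenience constructor for small hand-built clouds."""
    from canopyfuse.containers import PointCloud, UNASSIGNED

    x = np.asarray(x, float)
    n = len(x)
    cloud = PointCloud(
        x=x,
        y=np.asarray(y, float),
        z=np.asarray(z, float),
        intensity=(np.asarray(intensity, float) if intensity is not None
                   else np.full(n, 100.0)),
        return_number=(np.asarray(return_number, int)
                       if return_number is not None else np.ones(n, int)),
        num_returns=(np.asarray(num_returns, int)
                     if num_returns is not None else np.ones(n, int)),
    )
    if classification is not None:
        cloud.classification = np.asarray(classification, np.uint8)
    if hag is not None:
        cloud.hag = np.asarray(hag, float)
    return cloud
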