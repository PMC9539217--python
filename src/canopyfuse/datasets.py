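"""Bundled reference data.

Three published per-source confusion matrices for a five-species mixed
stand (Juglans mandshurica JM, Larix gmelinii LG, Tilia amurensis TA,
Quercus mongolica QM, Ulmus pumila UP), one per feature source (HSI,
LiDAR, fused), plus the reference segmentation counts for the same plot.
They serve as fixed inputs for exercising the metrics engine.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .metrics import _validate_matrix

#: reference individual-tree segmentation counts for the same survey plot
SEGMENTATION_COUNTS = {"n_reference": 1040, "n_detected": 936, "n_correct": 880}

_TABLES = {
    "hsi": "table_hsi.csv",
    "lidar": "table_lidar.csv",
    "fused": "table_fused.csv",
}


def reference_confusion_matrix(source: str) -> pd.DataFrame:
    """Load a bundled confusion matrix: ``hsi``, ``lidar`` or ``fused``."""
    key = source.lower()
    if key not in _TABLES:
        raise KeyError(f"unknown reference table {source!r}; "
                       f"choose from {sorted(_TABLES)}")
    ref = resources.files("canopyfuse.data").joinpath(_TABLES[key])
    with resources.as_file(ref) as path:
        m = pd.read_csv(path, index_col=0)
    return _validate_matrix(m)
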