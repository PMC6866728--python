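"""Connected-component cluster extraction from statistic volumes.

Suprathreshold voxels are grouped with one of the three standard 3D
neighbourhood schemes (6 faces, 18 faces+edges, 26 faces+edges+corners) and
summarised into a cluster table: size, peak statistic, peak MNI coordinate
(via the NIfTI affine), and the atlas label at the peak.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volumes import AtlasLabelMap, StatMap

_ORDERS = {6: 1, 18: 2, 26: 3}

CLUSTER_COLUMNS = ["cluster_id", "size", "peak_stat", "peak_i", "peak_j",
                   "peak_k", "peak_x_mm", "peak_y_mm", "peak_z_mm",
                   "label_id", "label_name", "p_corr"]


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary structuring element for 6/18/26-neighbourhoods."""
    if connectivity not in _ORDERS:
        raise ValueError(f"connectivity must be one of {sorted(_ORDERS)}, "
                         f"got {connectivity}")
    return ndi.generate_binary_structure(3, _ORDERS[connectivity])


def label_components(suprathreshold: np.ndarray, connectivity: int = 26):
    """Label connected components; returns (label volume, n components)."""
    return ndi.label(suprathreshold, structure=connectivity_structure(connectivity))


def max_cluster_size(suprathreshold: np.ndarray, structure: np.ndarray) -> int:
    """Size of the largest connected component (0 if empty).

    Fast path used inside permutation loops.
    """
    if not suprathreshold.any():
        return 0
    labelled, n = ndi.label(suprathreshold, structure=structure)
    return int(np.bincount(labelled.ravel())[1:].max())


def label_clusters(stat_map: StatMap, threshold: float, connectivity: int = 26,
                   atlas: AtlasLabelMap | None = None,
                   corrected_p: dict[int, float] | None = None) -> pd.DataFrame:
    """Tabulate connected clusters of {voxel : statistic > threshold}.

    The peak is the maximum-statistic voxel of each cluster; ties break to
    the smallest linear (C-order) index so output is deterministic. Peak
    coordinates are affine-mapped voxel indices (MNI mm). Rows are ordered by
    decreasing size, then ascending peak linear index.

    ``corrected_p`` maps cluster sizes (or ids, see permutation module) is
    not consulted here; pass per-cluster p via the returned id ordering.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    data = stat_map.data
    supra = np.where(np.isfinite(data), data > threshold, False)
    labelled, n = label_components(supra, connectivity)
    rows = []
    flat_stat = data.ravel()
    flat_lab = labelled.ravel()
    for lab in range(1, n + 1):
        idxs = np.flatnonzero(flat_lab == lab)
        vals = flat_stat[idxs]
        peak_flat = int(idxs[int(np.argmax(vals))])  # argmax: first max wins
        ijk = np.unravel_index(peak_flat, data.shape)
        xyz = stat_map.affine @ np.array([ijk[0], ijk[1], ijk[2], 1.0])
        if atlas is not None:
            lab_id = int(atlas.labels[ijk])
            lab_name = atlas.name_at(ijk)
        else:
            lab_id, lab_name = 0, "unlabelled"
        rows.append({
            "cluster_id": lab,
            "size": int(idxs.size),
            "peak_stat": float(flat_stat[peak_flat]),
            "peak_i": int(ijk[0]), "peak_j": int(ijk[1]), "peak_k": int(ijk[2]),
            "peak_x_mm": float(xyz[0]), "peak_y_mm": float(xyz[1]),
            "peak_z_mm": float(xyz[2]),
            "label_id": lab_id, "label_name": lab_name,
            "p_corr": np.nan,
        })
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    if len(table):
        order = np.lexsort((table["peak_i"] * 0 + table.index,
                            -table["size"].to_numpy()))
        table = table.iloc[order].reset_index(drop=True)
    return table
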