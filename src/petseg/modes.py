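"""Optional segmentation behaviors: label avoidance, splitting, necrotic mode.

*Label avoidance* keeps a new segmentation from overwriting existing lesion
labels: walking outward along each column, the first node that lands inside a
voxel carrying a different nonzero label starts a rejection tail (+rej for all
deeper nodes). *Splitting* separates adjacent lesions with similar uptake by
penalizing nodes that fall into foreign watershed basins of the
above-threshold uptake: a "strong" (smoothed-marker) watershed contributes the
full rejection constant and a "weak" (raw-marker) watershed half of it.
*Necrotic mode* disables seed recentering and the running-minimum background
rejection, both of which misfire inside cold necrotic cores.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .cost_field import REJ
from .errors import SeedError
from .mesh_graph import ColumnGraph
from .volume_io import LabelVolume, ScalarVolume

#: sigma (mm) of the smoothing that defines the "strong" watershed markers
STRONG_SMOOTH_MM = 3.0


def _node_voxel_indices(graph: ColumnGraph, vol) -> tuple[np.ndarray, np.ndarray]:
    """Nearest voxel index of every node; (indices (n,3), valid mask)."""
    pos = graph.node_positions().reshape(-1, 3)
    idx = np.rint((pos - np.asarray(vol.origin)) / np.asarray(vol.spacing)).astype(int)
    valid = np.all((idx >= 0) & (idx < np.asarray(vol.shape)), axis=1)
    return idx, valid


def label_avoidance_costs(graph: ColumnGraph, existing: LabelVolume,
                          own_label: int, rej: float = REJ) -> np.ndarray:
    """Per-node term rejecting every level at or beyond first foreign-label contact."""
    idx, valid = _node_voxel_indices(graph, existing)
    labels = np.zeros(len(idx), dtype=np.int64)
    labels[valid] = existing.data[idx[valid, 0], idx[valid, 1], idx[valid, 2]]
    labels = labels.reshape(graph.n_column, graph.n_node)
    foreign = (labels != 0) & (labels != own_label)
    # Monotone tail: once a column touches a foreign label, it stays rejected.
    tail = np.maximum.accumulate(foreign, axis=1)
    return np.where(tail, rej, 0.0)


def _watershed_partition(vol: ScalarVolume, mask: np.ndarray,
                         smooth_mm: float) -> np.ndarray:
    img = vol.data
    if smooth_mm > 0:
        sigma_vox = [smooth_mm / s for s in vol.spacing]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    peaks = peak_local_max(np.where(mask, img, -np.inf), min_distance=1,
                           exclude_border=False)
    markers = np.zeros(vol.shape, dtype=np.int32)
    for n, p in enumerate(peaks, start=1):
        markers[tuple(p)] = n
    markers, _ = ndimage.label(markers > 0)
    return watershed(-img, markers, mask=mask)


def splitting_costs(graph: ColumnGraph, vol: ScalarVolume, th: float,
                    center, rej: float = REJ) -> np.ndarray:
    """Per-node penalty for watershed basins not containing the seed.

    Voxels below Th are excluded from the watershed entirely (they do not
    affect the segmentation). Nodes in a foreign basin of the strong
    (smoothed) watershed receive +rej, of the weak (unsmoothed) watershed
    +rej/2; the terms accumulate.
    """
    mask = vol.data >= th
    seed_idx = tuple(np.rint((np.asarray(center) - np.asarray(vol.origin))
                             / np.asarray(vol.spacing)).astype(int))
    if (np.any(np.asarray(seed_idx) < 0)
            or np.any(np.asarray(seed_idx) >= np.asarray(vol.shape))
            or not mask[seed_idx]):
        raise SeedError("seed uptake is below the threshold; cannot split")

    idx, valid = _node_voxel_indices(graph, vol)
    out = np.zeros(graph.n_column * graph.n_node)
    for smooth_mm, penalty in ((STRONG_SMOOTH_MM, rej), (0.0, rej / 2.0)):
        basins = _watershed_partition(vol, mask, smooth_mm)
        seed_basin = basins[seed_idx]
        if seed_basin == 0:  # seed voxel unassigned (flat plateau edge): nearest basin
            lab_idx = ndimage.distance_transform_edt(
                basins == 0, sampling=vol.spacing, return_distances=False,
                return_indices=True)
            seed_basin = basins[tuple(lab_idx[:, seed_idx[0], seed_idx[1], seed_idx[2]])]
        node_basin = np.zeros(len(idx), dtype=np.int64)
        node_basin[valid] = basins[idx[valid, 0], idx[valid, 1], idx[valid, 2]]
        out += np.where((node_basin != 0) & (node_basin != seed_basin), penalty, 0.0)
    return out.reshape(graph.n_column, graph.n_node)


def necrotic_config(base_config):
    """Necrotic-lesion variant of a configuration.

    Disables recentering (the hottest voxel is on the rim, not the center) and
    the r2 background-rejection term (the running-minimum test triggers inside
    the cold core), keeping the r1 inner-level rejection.
    """
    return replace(base_config, recenter=False, use_background_reject=False,
                   necrotic=True)
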