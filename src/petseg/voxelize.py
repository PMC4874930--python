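"""Boundary mesh to label volume conversion, cleanup, merging, gap closing.

The deformed boundary mesh is star-shaped around the graph center by
construction (one node per radial column), so the inside test is radial: a
voxel center belongs to the lesion iff its distance from the center does not
exceed the surface radius along its direction. The direction's triangle is
found on the unit sphere (the cone spanned by a triangle's deformed vertices
equals the cone of its unit directions, since deformation is a per-vertex
positive radial scaling), and the exact ray/triangle-plane intersection gives
the surface radius.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import GridMismatchError, PetsegError, SeedError
from .osf_solver import SurfaceSolution
from .volume_io import LabelVolume, ScalarVolume, _check_grids

#: inclusive tolerance (mm) of the radial inside test
_RADIAL_TOL = 1e-6

_CROSS_3D = ndimage.generate_binary_structure(3, 1)  # 6-connectivity cross


def mesh_to_labels(solution: SurfaceSolution, grid: ScalarVolume,
                   label: int = 1) -> LabelVolume:
    """Label every voxel whose center lies inside the closed boundary mesh."""
    mesh = solution.boundary_mesh
    if not mesh.is_closed():
        raise PetsegError("boundary mesh is not a closed surface")
    center = np.asarray(solution.center, dtype=np.float64)
    verts = mesh.vertices - center
    radii = np.linalg.norm(verts, axis=1)
    if np.any(radii <= 0):
        raise PetsegError("boundary mesh vertex coincides with the center")
    dirs = verts / radii[:, None]
    tris = mesh.triangles

    out = np.zeros(grid.shape, dtype=np.uint16)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    r_max = radii.max()
    lo = np.maximum(np.ceil((center - r_max - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.floor((center + r_max - origin) / spacing).astype(int),
                    np.asarray(grid.shape) - 1)
    if np.any(hi < lo):
        return LabelVolume(out, grid.spacing, grid.origin)
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    x = origin + idx * spacing - center
    dist = np.linalg.norm(x, axis=1)

    inside = np.zeros(len(x), dtype=bool)
    at_center = dist < 1e-12
    inside |= at_center

    todo = ~at_center
    u = np.zeros_like(x)
    u[todo] = x[todo] / dist[todo, None]

    # Per-triangle direction matrices: candidate lookup via unit centroids,
    # cone membership via inverse of [p1 p2 p3].
    tri_dirs = dirs[tris]  # (F, 3verts, 3)
    m_inv = np.linalg.inv(tri_dirs.transpose(0, 2, 1))  # columns are p-vectors
    tri_world = verts[tris]
    w_inv = np.linalg.inv(tri_world.transpose(0, 2, 1))
    centroids = tri_dirs.mean(axis=1)
    centroids /= np.linalg.norm(centroids, axis=1)[:, None]
    tree = cKDTree(centroids)

    k = min(24, len(tris))
    pending = np.nonzero(todo)[0]
    if pending.size:
        _, cand = tree.query(u[pending], k=k)
        cand = np.atleast_2d(cand)
        assigned = np.full(pending.size, -1, dtype=np.int64)
        for rank in range(k):
            open_mask = assigned < 0
            if not open_mask.any():
                break
            t_idx = cand[open_mask, rank]
            b = np.einsum("pij,pj->pi", m_inv[t_idx], u[pending[open_mask]])
            ok = np.all(b >= -1e-9, axis=1)
            sel = np.nonzero(open_mask)[0][ok]
            assigned[sel] = t_idx[ok]
        for p in np.nonzero(assigned < 0)[0]:  # rare fallback: full scan
            b = m_inv @ u[pending[p]]
            hits = np.nonzero(np.all(b >= -1e-9, axis=1))[0]
            assigned[p] = hits[0]
        lam = np.einsum("pij,pj->pi", w_inv[assigned], u[pending])
        denom = lam.sum(axis=1)
        # denom > 0 is guaranteed for directions inside the cone; a
        # non-positive value can only be numerical noise far outside.
        surf_r = np.where(denom > 1e-15, 1.0 / np.where(denom > 1e-15, denom, 1.0), 0.0)
        inside[pending] = dist[pending] <= surf_r + _RADIAL_TOL

    sel = idx[inside]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = label
    return LabelVolume(out, grid.spacing, grid.origin)


def cleanup_components(labels: LabelVolume, seed) -> LabelVolume:
    """Keep only the 6-connected labeled component containing the seed voxel."""
    seed_idx = np.rint(labels.world_to_index(np.asarray(seed, dtype=np.float64)))
    seed_idx = seed_idx.astype(int)
    if np.any(seed_idx < 0) or np.any(seed_idx >= np.asarray(labels.shape)):
        raise SeedError(f"seed {np.asarray(seed).tolist()} outside the label grid")
    if labels.data[tuple(seed_idx)] == 0:
        raise SeedError("seed voxel is not labeled; cannot identify the main component")
    comp, _ = ndimage.label(labels.data > 0, structure=_CROSS_3D)
    keep = comp == comp[tuple(seed_idx)]
    out = np.where(keep, labels.data, 0).astype(np.uint16)
    return LabelVolume(out, labels.spacing, labels.origin)


def merge_or(segmentations, label: int = 1) -> LabelVolume:
    """Logical OR of label volumes on a shared grid (multi-center lesions)."""
    if not segmentations:
        raise PetsegError("nothing to merge")
    first = segmentations[0]
    mask = np.zeros(first.shape, dtype=bool)
    for seg in segmentations:
        _check_grids(first, seg, "segmentations to merge")
        mask |= seg.data > 0
    return LabelVolume(np.where(mask, label, 0).astype(np.uint16),
                       first.spacing, first.origin)


def close_gaps(labels: LabelVolume, enable: bool = True) -> LabelVolume:
    """Fill one-voxel-wide gaps between voxels of the same label.

    Morphological closing with a 3x3x3 cross per label, restricted so a fill
    voxel never bridges different labels: voxels claimed by two labels'
    closings or 6-adjacent to a foreign label stay background.
    """
    if not enable:
        return LabelVolume(labels.data.copy(), labels.spacing, labels.origin)
    data = labels.data
    values = [int(v) for v in np.unique(data) if v != 0]
    bg = data == 0
    fills = {}
    for v in values:
        mask = data == v
        # closing = dilation then erosion; erode with border_value=1 so the
        # volume edge does not count as background and unfill gap voxels there
        dil = ndimage.binary_dilation(mask, structure=_CROSS_3D)
        closed = ndimage.binary_erosion(dil, structure=_CROSS_3D, border_value=1)
        touches_foreign = ndimage.binary_dilation((data != v) & ~bg,
                                                  structure=_CROSS_3D)
        fills[v] = closed & bg & ~touches_foreign
    claimed = np.zeros(data.shape, dtype=np.int8)
    for v in values:
        claimed += fills[v].astype(np.int8)
    out = data.copy()
    for v in values:
        out[fills[v] & (claimed == 1)] = v
    return LabelVolume(out, labels.spacing, labels.origin)
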