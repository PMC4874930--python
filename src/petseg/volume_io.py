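"""Scalar/label volume containers and physical-space sampling.

All geometry is metric: world coordinates in mm, axis order (x, y, z)
fastest-to-slowest, voxel centers at ``origin + index * spacing``. Oblique
direction matrices are rejected; the graph parameters that drive the
segmentation (column radius, node gap, recentering radius) are metric, so a
consistent axis-aligned world frame is required.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .errors import GridMismatchError, VolumeIOError

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


@dataclass
class ScalarVolume:
    """A 3D uptake grid (typically SUV) with voxel spacing and origin in mm.

    ``data`` is indexed ``[x, y, z]``; a voxel's physical center is
    ``origin + index * spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.data.ndim != 3:
            raise VolumeIOError(f"volume data must be 3D, got {self.data.ndim}D")
        if any(n < 2 for n in self.data.shape):
            raise VolumeIOError(f"volume needs >= 2 voxels per axis, got {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeIOError("volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent(self) -> np.ndarray:
        """(2, 3) physical hull of voxel centers: [origin, origin + (shape-1)*spacing]."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return np.stack([lo, hi])

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel-index coordinates of physical points (mm)."""
        points = np.asarray(points, dtype=np.float64)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index, dtype=np.float64)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where a physical point lies inside the voxel-center hull."""
        idx = self.world_to_index(points)
        shape = np.asarray(self.shape)
        return np.all((idx >= 0.0) & (idx <= shape - 1), axis=-1)


@dataclass
class LabelVolume:
    """Non-negative integer labels on the grid of an associated ScalarVolume."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise VolumeIOError(f"label data must be integer, got {self.data.dtype}")
        if self.data.min(initial=0) < 0:
            raise VolumeIOError("labels must be non-negative")
        self.data = self.data.astype(np.uint16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)


def _check_grids(a, b, what: str = "volumes") -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing) or not np.allclose(a.origin, b.origin):
        raise GridMismatchError(f"{what} are not on the same grid")


def _check_path(path: str) -> None:
    if not os.path.exists(path):
        raise VolumeIOError(f"file not found: {path}")
    low = str(path).lower()
    if not low.endswith(_SUPPORTED_SUFFIXES):
        raise VolumeIOError(f"unsupported volume format (expected .nii/.nii.gz/.nrrd): {path}")


def _from_sitk(img: sitk.Image):
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise VolumeIOError(
            "only axis-aligned volumes are supported; direction matrix is oblique: "
            f"{direction.tolist()}"
        )
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise VolumeIOError(f"invalid 'spacing' metadata in file: {spacing}")
    # SimpleITK arrays are (z, y, x); transpose to (x, y, z).
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return data, tuple(spacing), tuple(img.GetOrigin())


def read_volume(path: str) -> ScalarVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd) scalar volume."""
    _check_path(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - exercised via corrupt files
        raise VolumeIOError(f"unreadable volume file {path}: {exc}") from exc
    data, spacing, origin = _from_sitk(img)
    return ScalarVolume(np.ascontiguousarray(data, dtype=np.float64), spacing, origin)


def read_labels(path: str) -> LabelVolume:
    """Read a label volume (unsigned integer NIfTI/NRRD)."""
    _check_path(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover
        raise VolumeIOError(f"unreadable label file {path}: {exc}") from exc
    data, spacing, origin = _from_sitk(img)
    rounded = np.rint(data)
    if not np.allclose(data, rounded) or rounded.min() < 0:
        raise VolumeIOError(f"label file {path} does not contain non-negative integers")
    return LabelVolume(rounded.astype(np.uint16), spacing, origin)


def write_volume(vol: ScalarVolume | LabelVolume, path: str) -> None:
    """Write a volume as NIfTI or NRRD, preserving spacing and origin."""
    low = str(path).lower()
    if not low.endswith(_SUPPORTED_SUFFIXES):
        raise VolumeIOError(f"unsupported output format: {path}")
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.uint16)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))


def sample_uptake(vol: ScalarVolume, points: np.ndarray) -> np.ndarray | float:
    """Trilinear uptake at physical points (mm); points outside the grid give 0.

    Out-of-volume samples return background-like 0.0 so that graph columns
    extending past the scan edge do not inflate shell statistics.
    """
    pts = np.asarray(points, dtype=np.float64)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    idx = vol.world_to_index(pts)
    inside = np.all((idx >= 0.0) & (idx <= np.asarray(vol.shape) - 1), axis=-1)
    out = np.zeros(len(pts))
    if inside.any():
        coords = idx[inside].T
        out[inside] = map_coordinates(vol.data, coords, order=1, mode="nearest")
    return float(out[0]) if scalar else out
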