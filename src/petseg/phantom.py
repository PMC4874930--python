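"""Synthetic PET lesion phantoms with known ground truth.

Scenes emulate the situations the segmentation method targets: spherical (or
ellipsoidal) hot lesions of configurable radius and uptake on a uniform
background, optionally with cold necrotic cores, blurred by the scanner
point-spread function (Gaussian, FWHM 5--7 mm as in clinical OSEM
reconstructions) and optionally degraded by additive Gaussian noise. Ground
truth is the pre-blur lesion mask, one label per lesion. The default grid is
96^3 voxels at 2 mm spacing with background uptake 1.0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import PetsegError
from .volume_io import LabelVolume, ScalarVolume

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


@dataclass
class Lesion:
    """One spherical/ellipsoidal lesion: center (mm), radius (mm, scalar or
    per-axis), peak uptake, optional cold core for necrotic lesions."""

    center: tuple[float, float, float]
    radius: float | tuple[float, float, float]
    peak: float
    core_radius: float | None = None
    core_uptake: float | None = None  # defaults to the scene background


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background: float = 1.0
    lesions: list = field(default_factory=list)
    psf_fwhm_mm: float = 6.0
    noise_sigma: float = 0.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background < 0:
            raise PetsegError("background uptake must be >= 0")
        for les in self.lesions:
            r = np.atleast_1d(np.asarray(les.radius, dtype=float))
            if np.any(r <= 0):
                raise PetsegError("lesion radii must be positive")
            if les.peak <= self.background:
                raise PetsegError("lesion peak must exceed the background uptake")


def _ellipsoid_mask(spec: PhantomSpec, center, radius) -> np.ndarray:
    origin = np.zeros(3)
    axes = [origin[a] + np.arange(spec.shape[a]) * spec.spacing[a] for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    c = np.asarray(center, dtype=float)
    r = np.broadcast_to(np.atleast_1d(np.asarray(radius, dtype=float)), (3,))
    q = ((gx - c[0]) / r[0]) ** 2 + ((gy - c[1]) / r[1]) ** 2 + ((gz - c[2]) / r[2]) ** 2
    return q <= 1.0 + 1e-12


def generate(spec: PhantomSpec) -> tuple[ScalarVolume, LabelVolume]:
    """Render a phantom scene; returns (uptake volume, ground-truth labels)."""
    data = np.full(spec.shape, float(spec.background))
    truth = np.zeros(spec.shape, dtype=np.uint16)
    for k, les in enumerate(spec.lesions, start=1):
        mask = _ellipsoid_mask(spec, les.center, les.radius)
        if np.any(truth[mask] != 0):
            raise PetsegError(
                "ground-truth lesions with distinct labels overlap: ambiguous truth")
        data[mask] = les.peak
        truth[mask] = k
        if les.core_radius is not None:
            core = _ellipsoid_mask(spec, les.center, les.core_radius)
            cu = spec.background if les.core_uptake is None else les.core_uptake
            data[core] = cu
    if spec.psf_fwhm_mm > 0:
        sigma_vox = [spec.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in spec.spacing]
        data = gaussian_filter(data, sigma=sigma_vox)
    rng = np.random.default_rng(spec.seed)
    if spec.poisson_noise:
        scale = 100.0  # counts per uptake unit; optional, not the default model
        data = rng.poisson(np.maximum(data, 0.0) * scale) / scale
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    vol = ScalarVolume(data, spec.spacing, (0.0, 0.0, 0.0))
    return vol, LabelVolume(truth, spec.spacing, (0.0, 0.0, 0.0))


def single_sphere_scene(radius_mm: float = 10.0, contrast_ratio: float = 4.0,
                        psf_fwhm_mm: float = 5.0, noise_sigma: float = 0.0,
                        seed: int = 0) -> tuple[ScalarVolume, LabelVolume, np.ndarray]:
    """One centered sphere; returns (volume, truth, lesion center in mm)."""
    spec = PhantomSpec(psf_fwhm_mm=psf_fwhm_mm, noise_sigma=noise_sigma, seed=seed)
    # Snap the lesion center to a voxel center so that seeding "at the center"
    # carries no sub-voxel grid offset.
    mid = (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing) / 2.0
    center = tuple(np.round(mid / np.asarray(spec.spacing)) * np.asarray(spec.spacing))
    spec.lesions = [Lesion(center=center, radius=radius_mm,
                           peak=spec.background * contrast_ratio)]
    vol, truth = generate(spec)
    return vol, truth, np.asarray(center)


def adjacent_pair_scene(separation_mm: float, contrast_ratio: float = 4.0,
                        seed: int = 0, psf_fwhm_mm: float = 6.0,
                        radius_mm: float | None = None,
                        contrast_ratio_2: float | None = None):
    """Two-lesion scene for splitting / label-avoidance experiments.

    ``separation_mm`` is the center-to-center distance along x. The default
    radius shrinks with the separation (min(5, 0.45*separation)) so the
    ground-truth spheres can never overlap. Returns
    (volume, truth, center_a, center_b).
    """
    if separation_mm <= 0:
        raise PetsegError("separation must be positive")
    if radius_mm is None:
        radius_mm = min(5.0, 0.45 * separation_mm)
    spec = PhantomSpec(psf_fwhm_mm=psf_fwhm_mm, seed=seed)
    mid = (np.asarray(spec.shape) - 1) * np.asarray(spec.spacing) / 2.0
    mid = np.round(mid / np.asarray(spec.spacing)) * np.asarray(spec.spacing)
    ca = mid - np.array([separation_mm / 2.0, 0.0, 0.0])
    cb = mid + np.array([separation_mm / 2.0, 0.0, 0.0])
    peak_a = spec.background * contrast_ratio
    peak_b = spec.background * (contrast_ratio_2 or contrast_ratio)
    spec.lesions = [
        Lesion(center=tuple(ca), radius=radius_mm, peak=peak_a),
        Lesion(center=tuple(cb), radius=radius_mm, peak=peak_b),
    ]
    vol, truth = generate(spec)
    return vol, truth, ca, cb
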