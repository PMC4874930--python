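"""Shell statistics: recentering, radial median profile, landmarks, threshold.

A shell Omega_j is the set of all column nodes at radial level j. Its median
uptake up_Omega(j) forms a robust radial profile of the lesion: the profile
peaks near the center (``pe``) and levels off into background at the "knee"
(``kn``). Both landmarks drive an adaptive threshold

    Th = kn + Th% * (pe - kn),   Th% = 0.8 * exp(-0.15 * gamma^1.5),

with gamma = pe/kn the peak-to-knee contrast. At gamma = 2 this is roughly a
50% threshold; high-contrast lesions get a relatively lower threshold, which
mimics how radiation oncologists trace boundaries closer to background than a
fixed 50%-of-max isocontour would.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np

from .errors import DegenerateProfileError, SeedError
from .mesh_graph import ColumnGraph
from .volume_io import ScalarVolume, sample_uptake

#: floor applied to a non-positive knee uptake so gamma = pe/kn stays finite
KNEE_FLOOR = 1e-6


def recenter(vol: ScalarVolume, user_point, radius: float = 7.0,
             enabled: bool = True) -> np.ndarray:
    """Move a user seed to the hottest voxel center within ``radius`` mm.

    Ties are broken by smallest distance to the user point, then lexicographic
    voxel index. With ``enabled=False`` (necrotic lesions) the user point is
    returned unchanged.
    """
    point = np.asarray(user_point, dtype=np.float64)
    if not vol.contains(point):
        raise SeedError(f"seed point {point.tolist()} lies outside the volume")
    if not enabled:
        return point
    spacing = np.asarray(vol.spacing)
    origin = np.asarray(vol.origin)
    lo = np.maximum(np.ceil((point - radius - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.floor((point + radius - origin) / spacing).astype(int),
                    np.asarray(vol.shape) - 1)
    if np.any(hi < lo):
        raise SeedError(f"no voxel center within {radius} mm of seed {point.tolist()}")
    ix, iy, iz = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
    idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    centers = origin + idx * spacing
    d2 = np.sum((centers - point) ** 2, axis=1)
    near = d2 <= radius**2 + 1e-12
    if not near.any():
        raise SeedError(f"no voxel center within {radius} mm of seed {point.tolist()}")
    idx, centers, d2 = idx[near], centers[near], d2[near]
    uptake = vol.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2, -uptake))
    return centers[order[0]]


@dataclass
class ShellProfile:
    """Radial shell-median profile with detected landmarks.

    ``grad`` is the central difference up_shell[j+1] - up_shell[j-1]; it is
    undefined (NaN sentinel) at the innermost and outermost levels, and all
    landmark scans are restricted to the interior levels 1..n_node-2.
    ``grad_mod`` is the running-maximum modification that never decreases
    beyond j_low.
    """

    up_shell: np.ndarray
    grad: np.ndarray
    grad_mod: np.ndarray | None = None
    j_low: int | None = None
    j_hi: int | None = None
    j_knee: int | None = None
    pe: float | None = None
    kn: float | None = None
    gamma: float | None = None
    th: float | None = None

    @property
    def n_node(self) -> int:
        return len(self.up_shell)


def sample_node_uptake(graph: ColumnGraph, vol: ScalarVolume) -> np.ndarray:
    """(n_column, n_node) trilinear uptake at every graph node."""
    pos = graph.node_positions()
    flat = sample_uptake(vol, pos.reshape(-1, 3))
    return np.asarray(flat).reshape(graph.n_column, graph.n_node)


def make_profile(up_shell: np.ndarray) -> ShellProfile:
    """Build a ShellProfile (medians given, gradients computed)."""
    up_shell = np.asarray(up_shell, dtype=np.float64)
    n = len(up_shell)
    grad = np.full(n, np.nan)
    grad[1:-1] = up_shell[2:] - up_shell[:-2]
    return ShellProfile(up_shell=up_shell, grad=grad)


def shell_profile(graph: ColumnGraph, vol: ScalarVolume,
                  node_uptake: np.ndarray | None = None) -> ShellProfile:
    """Median uptake per shell and its central-difference gradient."""
    if node_uptake is None:
        node_uptake = sample_node_uptake(graph, vol)
    return make_profile(np.median(node_uptake, axis=0))


def find_landmarks(profile: ShellProfile) -> ShellProfile:
    """Detect pe, j_low, j_hi, j_knee and kn on a shell profile.

    The steepest-descent level j_low minimizes the center-bias weighted
    gradient ((n_node-(j+1))/n_node) * grad[j]; the linear weight guards
    against outside objects appearing in the profile. grad_mod is the running
    maximum of the gradient beyond j_low; j_hi is the first level where it
    reaches min(0, its maximum); the knee sits where grad_mod is closest to
    0.75*grad_mod[j_hi] + 0.25*grad_mod[j_low]. All argmin/argmax ties take
    the smallest index.
    """
    up, grad = profile.up_shell, profile.grad
    n = profile.n_node
    js = np.arange(1, n - 1)  # interior levels; extreme shells are not considered
    g = grad[js]
    scale = max(1.0, float(np.max(np.abs(up))))
    if np.all(np.isnan(g)) or (up.max() - up.min()) <= 1e-9 * scale:
        raise DegenerateProfileError(
            "shell profile is flat: no boundary evidence around the seed")
    pe = float(np.max(up[js]))
    weights = (n - (js + 1)) / n
    j_low = int(js[np.argmin(weights * g)])

    grad_mod = grad.copy()
    for j in range(j_low + 1, n - 1):
        grad_mod[j] = max(grad[j], grad_mod[j - 1])
    target_hi = min(0.0, float(np.max(grad_mod[j_low:n - 1])))
    rel = np.nonzero(grad_mod[j_low:n - 1] >= target_hi)[0]
    j_hi = int(j_low + rel[0])
    knee_target = 0.75 * grad_mod[j_hi] + 0.25 * grad_mod[j_low]
    band = np.arange(j_low, j_hi + 1)
    j_knee = int(band[np.argmin(np.abs(grad_mod[band] - knee_target))])
    kn = float(up[j_knee])

    profile.grad_mod = grad_mod
    profile.pe, profile.kn = pe, kn
    profile.j_low, profile.j_hi, profile.j_knee = j_low, j_hi, j_knee
    return profile


def threshold_fraction(gamma: float) -> float:
    """Adaptive threshold fraction Th% = 0.8 * exp(-0.15 * gamma^1.5)."""
    return 0.8 * exp(-0.15 * gamma**1.5)


def compute_threshold(pe: float, kn: float, mode: str = "adaptive") -> float:
    """Threshold uptake Th = kn + Th% * (pe - kn).

    ``mode`` selects the adaptive fraction of the contrast gamma = pe/kn, or
    the fixed 40%/50% variants on the same (kn, pe) scale. A non-positive knee
    (possible on noise-free zero background) is clamped to a small positive
    floor to keep gamma finite.
    """
    kn = max(float(kn), KNEE_FLOOR)
    if pe < kn:
        raise DegenerateProfileError(f"peak uptake {pe} below knee uptake {kn}")
    if mode == "adaptive":
        th_pct = threshold_fraction(pe / kn)
    elif mode == "fixed40":
        th_pct = 0.4
    elif mode == "fixed50":
        th_pct = 0.5
    else:
        raise ValueError(f"unknown threshold mode: {mode!r}")
    return kn + th_pct * (pe - kn)
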