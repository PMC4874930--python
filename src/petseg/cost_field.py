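"""Per-node boundary costs: histogram-envelope background term, linear
foreground term, and rejection of trivial or runaway solutions.

Below the threshold Th a node is costed by the monotone envelope of the
normalized uptake histogram of the spherical search region (likeliness of
being background); exactly at Th the cost is 0; above Th the cost rises
linearly to 1 at the center uptake. A large constant ``rej`` is added to nodes
too close to the center (j < j_min) and to nodes on columns whose uptake has
already dipped below the region median on the way out (running minimum), which
rejects trivial shrinkage and leakage into unrelated objects.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, SeedError
from .mesh_graph import ColumnGraph
from .volume_io import ScalarVolume, sample_uptake

#: rejection constant, far above the 0..1 base cost range
REJ = 6.0
#: innermost node levels always rejected
J_MIN = 3
#: tolerance for "uptake equals Th"
_TH_TOL = 1e-12


@dataclass
class EnvelopeFunction:
    """Right-to-left monotone increasing envelope of a normalized histogram.

    Evaluated per uptake bin; values are non-increasing with increasing
    uptake, with maximum 1.
    """

    bin_edges: np.ndarray  # (B+1,)
    values: np.ndarray  # (B,)

    def __call__(self, up) -> np.ndarray | float:
        up = np.asarray(up, dtype=np.float64)
        idx = np.searchsorted(self.bin_edges, up, side="right") - 1
        idx = np.clip(idx, 0, len(self.values) - 1)
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out


def monotone_envelope(hist: np.ndarray) -> np.ndarray:
    """Running maximum from the right: env[b] = max(hist[b:])."""
    h = np.asarray(hist, dtype=np.float64)
    return np.maximum.accumulate(h[::-1])[::-1]


def region_samples(vol: ScalarVolume, center, r: float,
                   step_mm: float = 1.0) -> np.ndarray:
    """Isotropically resampled uptake inside the r-sphere around ``center``.

    Sampling uses a uniform ``step_mm`` lattice (matching the node gap) so the
    histogram and region median are independent of the scan's anisotropic
    voxel grid. Only lattice points inside the volume are kept.
    """
    center = np.asarray(center, dtype=np.float64)
    offs = np.arange(-r, r + step_mm / 2, step_mm)
    gx, gy, gz = np.meshgrid(offs, offs, offs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    pts = pts[np.sum(pts**2, axis=1) <= r**2 + 1e-9]
    pts = center + pts
    pts = pts[vol.contains(pts)]
    if len(pts) == 0:
        raise SeedError("search-region sphere does not intersect the volume")
    return np.asarray(sample_uptake(vol, pts))


def envelope_from_samples(samples: np.ndarray, n_bins: int = 100) -> EnvelopeFunction:
    """Normalized 100-bin histogram on [0, region max], then its envelope."""
    samples = np.asarray(samples, dtype=np.float64)
    top = float(samples.max())
    if top <= 0:
        top = 1.0
    hist, edges = np.histogram(samples, bins=n_bins, range=(0.0, top))
    h = hist / hist.max()
    return EnvelopeFunction(bin_edges=edges, values=monotone_envelope(h))


def build_histogram_envelope(vol: ScalarVolume, center, r: float,
                             step_mm: float = 1.0, n_bins: int = 100) -> EnvelopeFunction:
    return envelope_from_samples(region_samples(vol, center, r, step_mm), n_bins)


def base_cost(up, th: float, env: EnvelopeFunction, center_uptake: float) -> np.ndarray:
    """Base boundary cost: envelope below Th, 0 at Th, linear to 1 at center uptake."""
    if center_uptake <= th:
        raise SeedError(
            f"center uptake {center_uptake:.4g} does not exceed threshold {th:.4g}: "
            "seed is not inside a hot region")
    up = np.asarray(up, dtype=np.float64)
    scalar = up.ndim == 0
    up = np.atleast_1d(up)
    linear = np.maximum((up - th) / (center_uptake - th), 0.0)
    below = up < th - _TH_TOL
    out = np.where(below, env(up), linear)
    return float(out[0]) if scalar else out


def reject_cost(node_uptake: np.ndarray, region_median: float,
                j_min: int = J_MIN, rej: float = REJ,
                use_background_reject: bool = True) -> np.ndarray:
    """Rejection term per node.

    r1: node level j < j_min. r2: j > j_min and the running minimum of the
    column's uptake from the center out has fallen below the region median.
    ``use_background_reject=False`` (necrotic mode) disables r2, whose
    running-minimum test falsely triggers inside cold necrotic cores.
    """
    up = np.asarray(node_uptake, dtype=np.float64)
    n_col, n_node = up.shape
    j = np.arange(n_node)
    out = np.zeros_like(up)
    out[:, j < j_min] = rej
    if use_background_reject:
        running_min = np.minimum.accumulate(up, axis=1)
        r2 = (j[None, :] > j_min) & (running_min < region_median)
        out[r2] = rej
    return out


@dataclass
class CostField:
    """Total per-node cost c = base + reject + extra (refinement/mode terms)."""

    base: np.ndarray
    reject: np.ndarray
    extra: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=np.float64)
        self.reject = np.asarray(self.reject, dtype=np.float64)
        if self.extra is None:
            self.extra = np.zeros_like(self.base)
        self.extra = np.asarray(self.extra, dtype=np.float64)
        if not (self.base.shape == self.reject.shape == self.extra.shape):
            raise GridMismatchError("cost component shapes differ")

    @property
    def shape(self):
        return self.base.shape

    def total(self) -> np.ndarray:
        return self.base + self.reject + self.extra


def assemble_costs(graph: ColumnGraph, base: np.ndarray, reject: np.ndarray,
                   extra_terms=()) -> CostField:
    """Sum base, reject and any mode/refinement terms into a CostField."""
    expected = (graph.n_column, graph.n_node)
    extra = np.zeros(expected)
    for term in extra_terms:
        term = np.asarray(term, dtype=np.float64)
        if term.shape != expected:
            raise GridMismatchError(
                f"extra cost term shape {term.shape} != graph shape {expected}")
        extra += term
    if np.asarray(base).shape != expected or np.asarray(reject).shape != expected:
        raise GridMismatchError("cost component shape does not match graph")
    return CostField(base=base, reject=reject, extra=extra)
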