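"""End-to-end lesion segmentation: seed -> graph -> statistics -> costs ->
optimal surface -> label volume, plus scripted JEI refinement sessions."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import jei_refine, modes
from .cost_field import (CostField, J_MIN, REJ, base_cost, envelope_from_samples,
                         region_samples, reject_cost)
from .errors import SeedError
from .mesh_graph import build_graph, build_sphere_mesh
from .osf_solver import solve
from .shell_stats import (compute_threshold, find_landmarks, recenter,
                          sample_node_uptake, shell_profile)
from .volume_io import LabelVolume, ScalarVolume, sample_uptake
from .voxelize import cleanup_components, close_gaps, mesh_to_labels, merge_or


@dataclass
class SegmentationConfig:
    """Tunable parameters of the base algorithm and its modes."""

    radius_mm: float = 60.0  # column radius r
    gap_mm: float = 1.0  # node spacing
    mesh_level: int = 4  # octahedron subdivisions; level 4 -> 1026 columns
    sc: int = 5  # hard smoothness (node levels)
    sp: float = 0.005  # soft smoothness (cost per level difference)
    threshold_mode: str = "adaptive"  # adaptive | fixed40 | fixed50
    recenter: bool = True
    recenter_radius_mm: float = 7.0
    use_background_reject: bool = True  # the r2 running-minimum term
    j_min: int = J_MIN
    rej: float = REJ
    split: bool = False
    close_gaps: bool = False
    necrotic: bool = False
    label: int = 1


@dataclass
class SegmentationResult:
    labels: LabelVolume
    session: jei_refine.Session
    report: dict
    center: np.ndarray


def start_session(vol: ScalarVolume, seed_mm, config: SegmentationConfig | None = None,
                  existing_labels: LabelVolume | None = None) -> tuple[jei_refine.Session, dict]:
    """Run the base pipeline up to the initial optimal surface."""
    cfg = config or SegmentationConfig()
    if cfg.necrotic:
        cfg = modes.necrotic_config(cfg)

    center = recenter(vol, seed_mm, radius=cfg.recenter_radius_mm, enabled=cfg.recenter)
    mesh = build_sphere_mesh(cfg.mesh_level)
    graph = build_graph(mesh, center, r=cfg.radius_mm, gap=cfg.gap_mm,
                        sc=cfg.sc, sp=cfg.sp)
    node_uptake = sample_node_uptake(graph, vol)
    profile = find_landmarks(shell_profile(graph, vol, node_uptake))
    th = compute_threshold(profile.pe, profile.kn, mode=cfg.threshold_mode)
    profile.gamma = profile.pe / max(profile.kn, 1e-6)
    profile.th = th

    samples = region_samples(vol, center, cfg.radius_mm, step_mm=cfg.gap_mm)
    env = envelope_from_samples(samples)
    region_median = float(np.median(samples))

    center_uptake = float(sample_uptake(vol, center))
    if cfg.necrotic:
        # A cold necrotic center cannot normalize the foreground cost; fall
        # back to the shell peak, which equals the center uptake for hot cores.
        center_uptake = max(center_uptake, profile.pe)
    if center_uptake <= th:
        raise SeedError(
            f"center uptake {center_uptake:.4g} <= threshold {th:.4g}; "
            "the seed does not sit inside a hot region")

    reject = reject_cost(node_uptake, region_median, j_min=cfg.j_min, rej=cfg.rej,
                         use_background_reject=cfg.use_background_reject)
    mode_extra = np.zeros_like(node_uptake)
    if existing_labels is not None:
        mode_extra += modes.label_avoidance_costs(graph, existing_labels,
                                                  cfg.label, rej=cfg.rej)
    if cfg.split:
        mode_extra += modes.splitting_costs(graph, vol, th, center, rej=cfg.rej)

    session = jei_refine.Session(
        graph=graph, vol=vol, node_uptake=node_uptake, env=env, reject=reject,
        mode_extra=mode_extra, center_uptake=center_uptake, th=th, label=cfg.label)
    report = {
        "seed_mm": [float(x) for x in np.asarray(seed_mm, dtype=float)],
        "center_mm": [float(x) for x in center],
        "center_uptake": center_uptake,
        "pe": profile.pe, "kn": profile.kn, "gamma": profile.gamma,
        "threshold": th, "threshold_mode": cfg.threshold_mode,
        "j_low": profile.j_low, "j_hi": profile.j_hi, "j_knee": profile.j_knee,
        "region_median": region_median,
        "objective": session.solution.objective,
        "n_column": graph.n_column, "n_node": graph.n_node,
    }
    return session, report


def labels_from_session(session: jei_refine.Session, vol: ScalarVolume,
                        cfg: SegmentationConfig) -> LabelVolume:
    labels = mesh_to_labels(session.solution, vol, label=cfg.label)
    labels = cleanup_components(labels, session.graph.center)
    if cfg.close_gaps:
        labels = close_gaps(labels, enable=True)
    return labels


def segment(vol: ScalarVolume, seed_mm, config: SegmentationConfig | None = None,
            existing_labels: LabelVolume | None = None) -> SegmentationResult:
    """Segment one lesion from a single seed point."""
    cfg = config or SegmentationConfig()
    session, report = start_session(vol, seed_mm, cfg, existing_labels)
    labels = labels_from_session(session, vol, cfg)
    report["voxel_count"] = int(np.count_nonzero(labels.data))
    return SegmentationResult(labels=labels, session=session, report=report,
                              center=session.graph.center)


def segment_many(vol: ScalarVolume, seeds, config: SegmentationConfig | None = None,
                 existing_labels: LabelVolume | None = None):
    """Segment several seeds of the same lesion label and OR-merge the results."""
    cfg = config or SegmentationConfig()
    results = [segment(vol, s, cfg, existing_labels) for s in seeds]
    merged = merge_or([r.labels for r in results], label=cfg.label)
    if cfg.close_gaps:
        merged = close_gaps(merged, enable=True)
    return merged, results


def apply_actions(session: jei_refine.Session, actions) -> jei_refine.Session:
    """Replay a scripted action log: dicts with 'kind' (global|local|undo)
    and, for refinements, 'point' [x, y, z] in mm."""
    for k, act in enumerate(actions):
        kind = act.get("kind")
        if kind == "global":
            jei_refine.global_refine(session, act["point"])
        elif kind == "local":
            jei_refine.local_refine(session, act["point"])
        elif kind == "undo":
            jei_refine.undo(session)
        else:
            raise ValueError(f"action {k}: unknown kind {kind!r}")
    return session
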