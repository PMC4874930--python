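import numpy as np
import pytest

from petseg import jei_refine
from petseg.errors import SeedError
from petseg.jei_refine import (find_similar_columns, global_refine,
                               local_refine, notch, undo)
from petseg.volume_io import sample_uptake


def test_notch_shape():
    js = np.arange(10)
    n = notch(js, center_level=4, depth=3.0, width=1.0)
    assert n[4] == pytest.approx(-3.0)       # full depth at the target
    assert np.all(n <= 0.0)                   # never increases cost
    assert n[2] == n[6] == pytest.approx(-3.0 * (1 - 2 / 2))
    wide = notch(js, center_level=4, depth=3.0, width=4.0)
    assert np.all(wide <= n + 1e-12)          # wider well is deeper off-center


def test_radially_symmetric_scene_matches_all_nearby_columns(sphere_session):
    session, _ = sphere_session
    i_a = 0
    j_a = int(session.solution.levels[i_a])
    matched, depths = find_similar_columns(session, (i_a, j_a))
    near = [i for i, d in depths.items() if 0 < d <= 5]
    assert set(matched) == set(near)
    # identical radial profiles -> every match sits at the anchor level
    assert all(j == j_a for j in matched.values())


def test_scaled_pattern_is_dissimilar(sphere_session):
    # Doubling a column's uptake makes smc = S against th_sim = 0.1*S, so the
    # similarity test must reject it. Scale the whole BFS neighborhood so the
    # closing step cannot re-include columns through similar neighbors.
    session, _ = sphere_session
    i_a = 0
    j_a = int(session.solution.levels[i_a])
    from petseg.mesh_graph import bfs_depths
    depths = bfs_depths(session.graph, i_a, max_depth=5)
    scaled = [i for i, d in depths.items() if d > 0]
    session.node_uptake = session.node_uptake.copy()
    session.node_uptake[scaled, :] *= 2.0
    matched, _ = find_similar_columns(session, (i_a, j_a))
    assert not matched


def test_level_band_constraint_excludes_far_levels(sphere_session):
    session, _ = sphere_session
    i_a = 0
    j_a = int(session.solution.levels[i_a])
    matched, depths = find_similar_columns(session, (i_a, j_a))
    for i, j in matched.items():
        assert abs(j - j_a) <= depths[i]


def test_local_refine_anchors_exact_level(sphere_session):
    session, _ = sphere_session
    point = session.graph.center + np.array([8.0, 0.0, 0.0])
    local_refine(session, point)
    i_lp, j_lp = session.actions[-1].anchor
    assert session.solution.levels[i_lp] == j_lp
    # costs outside the matched set and anchor column are untouched
    touched = set(session.actions[-1].matched) | {i_lp}
    untouched = [i for i in range(session.graph.n_column) if i not in touched]
    assert np.all(session.local_extra[untouched] == 0.0)


def test_local_refine_pulls_boundary_inward(sphere_session):
    session, _ = sphere_session
    before = session.solution.levels.copy()
    point = session.graph.center + np.array([7.0, 0.0, 0.0])
    local_refine(session, point)
    i_lp, j_lp = session.actions[-1].anchor
    assert j_lp < before[i_lp]
    assert session.solution.levels[i_lp] == j_lp


def test_global_refine_sets_threshold_and_anchors(sphere_session):
    session, _ = sphere_session
    point = session.graph.center + np.array([0.0, 12.5, 0.0])
    u = float(sample_uptake(session.vol, point))
    global_refine(session, point)
    assert session.th == pytest.approx(u)
    i_th, j_th = session.actions[-1].anchor
    assert session.solution.levels[i_th] == j_th


def test_repeated_global_refine_overrides_previous(sphere_session):
    session, _ = sphere_session
    p1 = session.graph.center + np.array([0.0, 12.0, 0.0])
    p2 = session.graph.center + np.array([11.0, 0.0, 0.0])
    global_refine(session, p1)
    global_refine(session, p2)
    after_two = (session.th, session.solution.levels.copy(),
                 session.global_extra.copy())
    undo(session)
    undo(session)
    global_refine(session, p2)
    assert session.th == after_two[0]
    np.testing.assert_array_equal(session.solution.levels, after_two[1])
    np.testing.assert_array_equal(session.global_extra, after_two[2])


def test_global_refine_above_center_uptake_errors(sphere_session):
    session, _ = sphere_session
    with pytest.raises(SeedError):
        global_refine(session, session.graph.center)  # uptake == center uptake


def test_undo_restores_bit_exact(sphere_session):
    session, _ = sphere_session
    lev0 = session.solution.levels.copy()
    obj0 = session.solution.objective
    th0 = session.th
    local_refine(session, session.graph.center + np.array([8.0, 0.0, 0.0]))
    global_refine(session, session.graph.center + np.array([0.0, 12.5, 0.0]))
    undo(session)
    undo(session)
    np.testing.assert_array_equal(session.solution.levels, lev0)
    assert session.solution.objective == obj0
    assert session.th == th0
    assert np.all(session.local_extra == 0.0)
    assert np.all(session.global_extra == 0.0)
    assert not session.actions


def test_undo_on_empty_stack_warns_and_keeps_state(sphere_session):
    session, _ = sphere_session
    lev0 = session.solution.levels.copy()
    with pytest.warns(UserWarning):
        undo(session)
    np.testing.assert_array_equal(session.solution.levels, lev0)


def test_action_replay_reproduces_levels(sphere_scene, small_cfg):
    from petseg import pipeline
    vol, _, center = sphere_scene
    actions = [
        {"kind": "local", "point": (center + [8.0, 0, 0]).tolist()},
        {"kind": "global", "point": (center + [0, 12.5, 0]).tolist()},
        {"kind": "undo"},
        {"kind": "local", "point": (center + [0, 0, 8.0]).tolist()},
    ]
    s1, _ = pipeline.start_session(vol, center, small_cfg)
    pipeline.apply_actions(s1, actions)
    s2, _ = pipeline.start_session(vol, center, small_cfg)
    pipeline.apply_actions(s2, actions)
    np.testing.assert_array_equal(s1.solution.levels, s2.solution.levels)
    assert s1.th == s2.th


def test_anchored_column_costs_not_further_changed(sphere_session):
    session, _ = sphere_session
    p = session.graph.center + np.array([8.0, 0.0, 0.0])
    local_refine(session, p)
    i_lp, _ = session.actions[-1].anchor
    col_costs = session.local_extra[i_lp].copy()
    # a second nearby refinement must leave the anchored column untouched
    local_refine(session, session.graph.center + np.array([7.5, 2.0, 0.0]))
    np.testing.assert_array_equal(session.local_extra[i_lp], col_costs)
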