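"""The screening/filtering/classification pipeline and its invariants."""

import json

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tsmode import (Change, Geometry, InternalCoordinate, NormalMode,
                    NotATransitionStateError, ScreenConfig, analyze_trajectory,
                    analyze_ts, detect_changes, evaluate_snapshot,
                    filter_correlated, kabsch_rmsd, read_report, select_frames,
                    write_report)
from tsmode.fixtures import make_model_ts, make_path
from tsmode.internals import CoordinateSnapshot
from tsmode.molgraph import Bond, MolecularGraph

from conftest import random_rotation


# ---------------------------------------------------------------------------
# Kabsch RMSD and frame selection
# ---------------------------------------------------------------------------

def test_kabsch_zero_on_identical_and_rigid_copies():
    geom = make_model_ts("sn2").geometry
    assert kabsch_rmsd(geom, geom) == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(23)
    moved = geom.transformed(rotation=random_rotation(rng),
                             translation=rng.uniform(-8, 8, 3))
    assert kabsch_rmsd(geom, moved) == pytest.approx(0.0, abs=1e-9)


def test_kabsch_matches_scipy_alignment_oracle():
    # independent oracle: scipy's align_vectors solves the same problem
    rng = np.random.default_rng(7)
    a = Geometry(["C", "N", "O", "H"], rng.uniform(-2, 2, (4, 3)))
    shifted = a.coords.copy()
    shifted[2] += [0.4, -0.1, 0.2]
    b = Geometry(list(a.elements), shifted)
    rot, rssd = Rotation.align_vectors(
        b.coords - b.coords.mean(axis=0), a.coords - a.coords.mean(axis=0))
    oracle = rssd / np.sqrt(len(a))
    assert kabsch_rmsd(a, b) == pytest.approx(oracle, abs=1e-9)


def test_kabsch_symmetric():
    rng = np.random.default_rng(9)
    a = Geometry(["C"] * 5, rng.uniform(-2, 2, (5, 3)))
    b = Geometry(["C"] * 5, rng.uniform(-2, 2, (5, 3)))
    assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-12)


def test_select_frames_two_frame_trajectory():
    frames = make_path(make_model_ts("sn2"), 2)
    assert select_frames(frames, "endpoints") == (0, 1)
    assert select_frames(frames, "max_rmsd") == (0, 1)


def test_select_frames_monotone_path_returns_endpoints():
    frames = make_path(make_model_ts("sn2"), 7)
    assert select_frames(frames, "max_rmsd") == (0, 6)


def test_select_frames_overshooting_path():
    # frame 1 overshoots: the most diverse pair is not the endpoints
    base = make_model_ts("sn2").geometry
    f0 = base
    f1 = Geometry(list(base.elements),
                  base.coords + np.outer(np.arange(len(base)), [0.3, 0, 0]))
    f2 = Geometry(list(base.elements),
                  base.coords + np.outer(np.arange(len(base)), [0.1, 0, 0]))
    frames = [f0, f1, f2]
    assert select_frames(frames, "max_rmsd") == (0, 1)
    assert select_frames(frames, "endpoints") == (0, 2)


def test_select_frames_needs_two():
    with pytest.raises(ValueError):
        select_frames([make_model_ts("sn2").geometry])


# ---------------------------------------------------------------------------
# threshold screening
# ---------------------------------------------------------------------------

def _bond_snapshots(values_a, values_b, elements):
    coords = [InternalCoordinate("bond", (i, i + 1))
              for i in range(len(values_a))]
    # chain geometry: positions are irrelevant to screening except elements
    geom = Geometry(elements, [[1.5 * k, 0, 0] for k in range(len(elements))])
    sa = CoordinateSnapshot(coords, np.array(values_a), 0)
    sb = CoordinateSnapshot(coords, np.array(values_b), 1)
    return sa, sb, coords, geom


def test_bond_threshold_boundary():
    sa, sb, coords, geom = _bond_snapshots([1.5, 1.5], [1.91, 1.89],
                                           ["C", "C", "C"])
    out = detect_changes(sa, sb, coords, geom, ScreenConfig())
    assert [c.coord.atoms for c in out] == [(0, 1)]  # +0.41 in, +0.39 out
    assert out[0].classification == "bond_break"
    assert out[0].provenance == "primary"


def test_fallback_tier_recovers_small_dihedral():
    coords = [InternalCoordinate("bond", (0, 1)),
              InternalCoordinate("dihedral", (0, 1, 2, 3))]
    geom = Geometry(["C", "C", "C", "C"], [[1.5 * k, 0, 0] for k in range(4)])
    sa = CoordinateSnapshot(coords, np.array([1.5, 10.0]), 0)
    sb = CoordinateSnapshot(coords, np.array([1.6, 22.0]), 1)  # 12 deg twist
    out = detect_changes(sa, sb, coords, geom, ScreenConfig())
    assert len(out) == 1
    assert out[0].coord.kind == "dihedral"
    assert out[0].provenance == "fallback"


def test_fallback_does_not_fire_when_primary_flags():
    coords = [InternalCoordinate("bond", (0, 1)),
              InternalCoordinate("dihedral", (0, 1, 2, 3))]
    geom = Geometry(["C", "C", "C", "C"], [[1.5 * k, 0, 0] for k in range(4)])
    sa = CoordinateSnapshot(coords, np.array([1.5, 10.0]), 0)
    sb = CoordinateSnapshot(coords, np.array([2.0, 22.0]), 1)
    out = detect_changes(sa, sb, coords, geom, ScreenConfig())
    # the 12-deg dihedral stays below its primary 20-deg threshold
    assert [c.coord.kind for c in out] == ["bond"]
    assert all(c.provenance == "primary" for c in out)


def test_proton_pairing_adds_partner_formation():
    # O0-H1 breaks by +0.45; H1-N2 forms by -0.25 (between 0.2 and 0.4)
    coords = [InternalCoordinate("bond", (0, 1)),
              InternalCoordinate("bond", (1, 2))]
    geom = Geometry(["O", "H", "N"], [[0, 0, 0], [1.0, 0, 0], [2.4, 0, 0]])
    sa = CoordinateSnapshot(coords, np.array([0.98, 1.45]), 0)
    sb = CoordinateSnapshot(coords, np.array([1.43, 1.20]), 1)
    out = detect_changes(sa, sb, coords, geom, ScreenConfig())
    by_atoms = {c.coord.atoms: c for c in out}
    assert by_atoms[(0, 1)].classification == "bond_break"
    assert by_atoms[(0, 1)].provenance == "primary"
    assert by_atoms[(1, 2)].classification == "bond_form"
    assert by_atoms[(1, 2)].provenance == "proton_pairing"


def test_proton_pairing_ignores_heavy_partners():
    # same deltas, but the shared atom is carbon: no pairing
    coords = [InternalCoordinate("bond", (0, 1)),
              InternalCoordinate("bond", (1, 2))]
    geom = Geometry(["O", "C", "N"], [[0, 0, 0], [1.4, 0, 0], [2.9, 0, 0]])
    sa = CoordinateSnapshot(coords, np.array([1.40, 1.45]), 0)
    sb = CoordinateSnapshot(coords, np.array([1.85, 1.20]), 1)
    out = detect_changes(sa, sb, coords, geom, ScreenConfig())
    assert [c.coord.atoms for c in out] == [(0, 1)]


def test_threshold_monotonicity_nested_detection(sn2):
    from tsmode.vibmode import displace_along_mode, select_imaginary
    from tsmode.molgraph import build_graph
    from tsmode.internals import enumerate_internals
    mode, _ = select_imaginary(sn2.modes)
    pair = displace_along_mode(sn2.geometry, mode, 0.5)
    graph = build_graph(sn2.geometry, ts_mode=True)
    internals = enumerate_internals(graph)
    sa = evaluate_snapshot(internals, pair.reverse, 0)
    sb = evaluate_snapshot(internals, pair.forward, 1)
    prev: set = None
    for thresh in (0.5, 0.4, 0.3, 0.2, 0.1):
        cfg = ScreenConfig(bond_thresh=thresh)
        flagged = {c.coord for c in
                   detect_changes(sa, sb, internals, pair.forward, cfg)
                   if c.coord.kind == "bond" and c.provenance == "primary"}
        if prev is not None:
            assert prev <= flagged
        prev = flagged


# ---------------------------------------------------------------------------
# correlated-motion filtering
# ---------------------------------------------------------------------------

def test_sn2_angles_filtered_as_bond_consequence(sn2):
    report = analyze_ts(sn2.geometry, sn2.modes)
    kinds = [c.coord.kind for c in report.changes]
    assert kinds == ["bond", "bond"]


def test_heaviest_dihedral_retained_per_axis():
    graph = MolecularGraph(
        ["F", "C", "C", "F", "H", "H"],
        [Bond(0, 1), Bond(1, 2), Bond(2, 3), Bond(1, 4), Bond(2, 5)])
    ff = Change(InternalCoordinate("dihedral", (0, 1, 2, 3)), 25.0,
                "rotation", "primary")
    hh = Change(InternalCoordinate("dihedral", (4, 1, 2, 5)), 28.0,
                "rotation", "primary")
    out = filter_correlated([ff, hh], graph)
    assert out == [ff]


def test_angles_survive_without_bond_changes():
    graph = MolecularGraph(["C", "C", "C"], [Bond(0, 1), Bond(1, 2)])
    ang = Change(InternalCoordinate("angle", (0, 1, 2)), 15.0,
                 "angle_change", "primary")
    assert filter_correlated([ang], graph) == [ang]


def test_filtering_soundness_no_shared_atoms(model_ts):
    report = analyze_ts(model_ts.geometry, model_ts.modes)
    bond_atoms = {a for c in report.changes if c.coord.kind == "bond"
                  for a in c.coord.atoms}
    for c in report.changes:
        if c.coord.kind != "bond":
            assert not (set(c.coord.atoms) & bond_atoms)


# ---------------------------------------------------------------------------
# full pipelines
# ---------------------------------------------------------------------------

def test_not_a_ts_error_surfaces():
    geom = make_model_ts("sn2").geometry
    positive = [NormalMode(100.0, np.ones((len(geom), 3)))]
    with pytest.raises(NotATransitionStateError):
        analyze_ts(geom, positive)


def test_swap_symmetry_negated_mode(model_ts):
    fwd = analyze_ts(model_ts.geometry, model_ts.modes)
    neg_modes = [NormalMode(m.frequency, -m.displacements)
                 for m in model_ts.modes]
    rev = analyze_ts(model_ts.geometry, neg_modes)
    assert rev.mode_class == fwd.mode_class
    swap = {"bond_break": "bond_form", "bond_form": "bond_break"}
    a = {c.coord: c for c in fwd.changes}
    b = {c.coord: c for c in rev.changes}
    assert a.keys() == b.keys()
    for coord, ca in a.items():
        cb = b[coord]
        assert cb.delta == pytest.approx(-ca.delta, abs=1e-9)
        assert cb.classification == swap.get(ca.classification,
                                             ca.classification)


def test_reports_are_deterministic(tmp_path, model_ts):
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    write_report(analyze_ts(model_ts.geometry, model_ts.modes), p1)
    write_report(analyze_ts(model_ts.geometry, model_ts.modes), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_report_round_trip(tmp_path, sn2):
    report = analyze_ts(sn2.geometry, sn2.modes)
    p = tmp_path / "r.json"
    write_report(report, p)
    back = read_report(p)
    assert back.to_dict() == report.to_dict()
    doc = json.loads(p.read_text())
    assert doc["schema_version"] == 1


def test_trajectory_matches_mode_analysis(sn2):
    direct = analyze_ts(sn2.geometry, sn2.modes)
    frames = make_path(sn2, 11)
    traj = analyze_trajectory(frames)
    assert traj.mode_class == direct.mode_class
    assert ({(c.coord, c.classification) for c in traj.changes
             if c.coord.kind == "bond"}
            == {(c.coord, c.classification) for c in direct.changes
                if c.coord.kind == "bond"})


def test_two_frame_qrc_pair_classifies_identically(model_ts):
    direct = analyze_ts(model_ts.geometry, model_ts.modes)
    traj = analyze_trajectory(make_path(model_ts, 2))
    assert traj.mode_class == direct.mode_class
    assert {c.coord for c in traj.changes} == {c.coord for c in direct.changes}


def test_trajectory_invariant_under_per_frame_rigid_motion(sn2):
    plain = analyze_trajectory(make_path(sn2, 11))
    moved = analyze_trajectory(make_path(sn2, 11, rigid_motion_seed=99))
    assert moved.mode_class == plain.mode_class
    assert ({(c.coord, c.classification) for c in moved.changes}
            == {(c.coord, c.classification) for c in plain.changes})


def test_identical_frames_yield_none():
    geom = make_model_ts("sn2").geometry
    report = analyze_trajectory([geom, geom, geom])
    assert report.changes == []
    assert report.mode_class == "none"


def test_zero_change_report_serializes_none(tmp_path):
    geom = make_model_ts("sn2").geometry
    report = analyze_trajectory([geom, geom])
    p = tmp_path / "none.json"
    write_report(report, p)
    assert json.loads(p.read_text())["mode_class"] == "none"
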