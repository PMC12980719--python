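"""Transition-state mode characterization in internal coordinates.

The pipeline compares two frames (forward/reverse mode displacements, or two
frames picked from an IRC/QRC trajectory), screens internal-coordinate
changes against kind-specific thresholds with a 50% fallback tier for
low-magnitude modes, pairs correlated proton transfers at a secondary
reduced threshold, filters geometric-consequence motion, classifies the mode
(bond change / hindered rotation / pyramidal inversion), and emits a
machine-readable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .elements import mass as atomic_mass
from .geometry import Geometry
from .internals import (CoordinateSnapshot, InternalCoordinate, delta_internal,
                        enumerate_internals, evaluate_internal,
                        evaluate_snapshot)
from .molgraph import GraphConfig, MolecularGraph, build_graph
from .vibmode import NormalMode, displace_along_mode, select_imaginary

__all__ = [
    "ScreenConfig",
    "Change",
    "ChangeReport",
    "kabsch_rmsd",
    "select_frames",
    "detect_changes",
    "filter_correlated",
    "classify_mode",
    "analyze_ts",
    "analyze_trajectory",
    "write_report",
    "read_report",
]

SCHEMA_VERSION = 1
_KIND_RANK = {"bond": 0, "angle": 1, "dihedral": 2}
PLANARITY_ANGLE_SUM = 354.0  # deg; a flat 3-coordinate center sums to 360


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for flagging meaningful internal-coordinate changes.

    Defaults: 0.4 Angstrom for bonds, 10 deg for angles, 20 deg for
    dihedrals; when nothing is flagged, one retry with all thresholds
    halved accommodates low-magnitude modes such as hindered rotations.
    ``proton_factor`` sets the secondary reduced threshold (as a fraction of
    ``bond_thresh``) used to pair the partner event of a proton transfer.
    """

    bond_thresh: float = 0.4        # Angstrom
    angle_thresh: float = 10.0      # degrees
    dihedral_thresh: float = 20.0   # degrees
    fallback_factor: float = 0.5
    proton_factor: float = 0.5
    max_fallbacks: int = 1

    def __post_init__(self) -> None:
        for name in ("bond_thresh", "angle_thresh", "dihedral_thresh",
                     "fallback_factor", "proton_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fallback_factor >= 1:
            raise ValueError("fallback_factor must be < 1")

    def threshold(self, kind: str, tier_factor: float = 1.0) -> float:
        base = {"bond": self.bond_thresh, "angle": self.angle_thresh,
                "dihedral": self.dihedral_thresh}[kind]
        return base * tier_factor


@dataclass(frozen=True)
class Change:
    """One screened internal-coordinate change."""

    coord: InternalCoordinate
    delta: float
    classification: str   # bond_break|bond_form|angle_change|rotation|inversion
    provenance: str       # primary|fallback|proton_pairing

    def to_dict(self, elements: Sequence[str] | None = None) -> dict:
        doc = self.coord.to_dict(elements)
        doc.update(delta=round(float(self.delta), 6),
                   classification=self.classification,
                   provenance=self.provenance)
        return doc


@dataclass
class ChangeReport:
    """Structured output of one analysis run."""

    changes: list[Change]
    mode_class: str                      # bond_change|rotation|inversion|mixed|none
    frames_used: list
    graphs: dict[str, MolecularGraph]
    extra_imaginaries: list[float] = field(default_factory=list)
    file_paths: dict[str, str] = field(default_factory=dict)
    elements: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "mode_class": self.mode_class,
            "changes": [c.to_dict(self.elements or None) for c in self.changes],
            "frames_used": list(self.frames_used),
            "extra_imaginaries": [float(f) for f in self.extra_imaginaries],
            "graphs": {k: g.to_dict() for k, g in sorted(self.graphs.items())},
            "file_paths": dict(self.file_paths),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ChangeReport":
        graphs = {k: MolecularGraph.from_dict(g)
                  for k, g in doc.get("graphs", {}).items()}
        elements = []
        if "ts" in graphs:
            elements = list(graphs["ts"].elements)
        changes = [
            Change(InternalCoordinate(c["kind"], tuple(c["atoms"])),
                   float(c["delta"]), c["classification"], c["provenance"])
            for c in doc["changes"]
        ]
        return cls(changes, doc["mode_class"], list(doc["frames_used"]),
                   graphs, [float(f) for f in doc.get("extra_imaginaries", [])],
                   dict(doc.get("file_paths", {})), elements)


# ---------------------------------------------------------------------------
# frame comparison
# ---------------------------------------------------------------------------

def kabsch_rmsd(geom_a: Geometry, geom_b: Geometry) -> float:
    """Minimum RMSD after optimal superposition (translation + proper
    rotation), over all atoms in input order."""
    if len(geom_a) != len(geom_b):
        raise ValueError("atom count mismatch")
    pa = geom_a.coords - geom_a.coords.mean(axis=0)
    pb = geom_b.coords - geom_b.coords.mean(axis=0)
    h = pa.T @ pb
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rot = u @ d @ vt
    diff = pa @ rot - pb
    return float(np.sqrt((diff ** 2).sum() / len(geom_a)))


def select_frames(trajectory: Sequence[Geometry],
                  strategy: str = "max_rmsd") -> tuple[int, int]:
    """Indices of the comparison pair: trajectory endpoints, or the pair
    maximizing Kabsch RMSD (ties broken by earliest pair)."""
    if len(trajectory) < 2:
        raise ValueError("need at least two frames")
    if strategy == "endpoints":
        return 0, len(trajectory) - 1
    if strategy != "max_rmsd":
        raise ValueError(f"unknown strategy {strategy!r}")
    best = (0, 1)
    best_val = -1.0
    for a in range(len(trajectory)):
        for b in range(a + 1, len(trajectory)):
            v = kabsch_rmsd(trajectory[a], trajectory[b])
            if v > best_val + 1e-12:
                best, best_val = (a, b), v
    return best


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _bond_classification(delta: float) -> str:
    return "bond_break" if delta > 0 else "bond_form"


def _initial_classification(kind: str, delta: float) -> str:
    if kind == "bond":
        return _bond_classification(delta)
    return "angle_change" if kind == "angle" else "rotation"


def _sort_changes(changes: list[Change]) -> list[Change]:
    return sorted(changes, key=lambda c: (_KIND_RANK[c.coord.kind],
                                          -abs(c.delta), c.coord.atoms))


def detect_changes(snapshot_a: CoordinateSnapshot,
                   snapshot_b: CoordinateSnapshot,
                   internals: Sequence[InternalCoordinate],
                   geometry_b: Geometry | None = None,
                   config: ScreenConfig | None = None) -> list[Change]:
    """Threshold screening of deltas between two snapshots.

    Tier one applies the default thresholds; if nothing at all is flagged,
    a single retry with thresholds scaled by ``fallback_factor`` follows
    (provenance "fallback").  Proton pairing then ensures every flagged
    hydrogen-containing bond cleavage has its partner formation (and vice
    versa) at the secondary threshold ``proton_factor * bond_thresh``.
    """
    config = config or ScreenConfig()
    if list(snapshot_a.coords) != list(internals) or \
            list(snapshot_b.coords) != list(internals):
        raise ValueError("snapshots must be evaluated on the given internals")
    deltas = {c: delta_internal(c, float(va), float(vb))
              for c, va, vb in zip(internals, snapshot_a.values,
                                   snapshot_b.values)}

    flagged: dict[InternalCoordinate, Change] = {}
    tiers = [("primary", 1.0)]
    tiers += [("fallback", config.fallback_factor)] * config.max_fallbacks
    for provenance, factor in tiers:
        for coord, d in deltas.items():
            if abs(d) >= config.threshold(coord.kind, factor):
                flagged[coord] = Change(coord, d,
                                        _initial_classification(coord.kind, d),
                                        provenance)
        if flagged:
            break

    elements = list(geometry_b.elements) if geometry_b is not None else None

    def _is_h(idx: int) -> bool:
        return elements is not None and elements[idx] == "H"

    # correlated proton transfer: pair each flagged H-containing break with
    # its sub-threshold formation partner on the same hydrogen (and mirror)
    if elements is not None:
        secondary = config.proton_factor * config.bond_thresh
        for change in list(flagged.values()):
            if change.coord.kind != "bond":
                continue
            hydrogens = [a for a in change.coord.atoms if _is_h(a)]
            for h in hydrogens:
                want_form = change.classification == "bond_break"
                for coord, d in deltas.items():
                    if coord.kind != "bond" or coord in flagged:
                        continue
                    if h not in coord.atoms:
                        continue
                    if want_form and d <= -secondary:
                        flagged[coord] = Change(coord, d, "bond_form",
                                                "proton_pairing")
                    elif not want_form and d >= secondary:
                        flagged[coord] = Change(coord, d, "bond_break",
                                                "proton_pairing")
    return _sort_changes(list(flagged.values()))


def filter_correlated(changes: Sequence[Change], graph: MolecularGraph,
                      masses: Sequence[float] | None = None) -> list[Change]:
    """Drop coupled motion so each reported change is independent.

    Angles/dihedrals touching any atom of a flagged bond change are a
    geometric consequence of that change and are removed; equivalent
    dihedrals sharing a rotation axis are reduced to the one with the
    heaviest terminal atoms.
    """
    if masses is None:
        masses = [atomic_mass(el) for el in graph.elements]
    bond_changes = [c for c in changes if c.coord.kind == "bond"]
    bond_atoms = {a for c in bond_changes for a in c.coord.atoms}

    survivors = [c for c in changes
                 if c.coord.kind == "bond"
                 or not (set(c.coord.atoms) & bond_atoms)]

    by_axis: dict[tuple[int, int], list[Change]] = {}
    out: list[Change] = []
    for c in survivors:
        if c.coord.kind == "dihedral":
            i, j, k, l = c.coord.atoms
            by_axis.setdefault(tuple(sorted((j, k))), []).append(c)
        else:
            out.append(c)
    for axis in sorted(by_axis):
        group = by_axis[axis]
        def rank(c: Change):
            i, j, k, l = c.coord.atoms
            term = sorted((masses[i], masses[l]), reverse=True)
            return (-(term[0] + term[1]), -term[0], c.coord.atoms)
        out.append(min(group, key=rank))
    return _sort_changes(out)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _improper(center: int, nbrs: Sequence[int], geom: Geometry) -> float:
    """Signed out-of-plane dihedral of a 3-coordinate center: planes
    (n0,n1,n2) vs (n1,n2,center); zero when the center is coplanar."""
    coord = InternalCoordinate("dihedral", (nbrs[0], nbrs[1], nbrs[2], center))
    # canonicalization may reverse the tuple; evaluate on the raw ordering
    xyz = geom.coords
    from .internals import UndefinedGeometryError  # local to avoid cycle noise
    import math
    b1 = xyz[nbrs[1]] - xyz[nbrs[0]]
    b2 = xyz[nbrs[2]] - xyz[nbrs[1]]
    b3 = xyz[center] - xyz[nbrs[2]]
    n2 = np.linalg.norm(b2)
    c1, c2 = np.cross(b1, b2), np.cross(b2, b3)
    if n2 < 1e-10 or np.linalg.norm(c1) < 1e-10 or np.linalg.norm(c2) < 1e-10:
        raise UndefinedGeometryError("degenerate improper")
    x = float(np.dot(c1, c2))
    y = float(np.dot(np.cross(c1, c2), b2) / n2)
    ang = math.degrees(math.atan2(y, x))
    return ang if ang > -180.0 else ang + 360.0


def _angle_sum(center: int, nbrs: Sequence[int], geom: Geometry) -> float:
    total = 0.0
    for a in range(3):
        for b in range(a + 1, 3):
            total += evaluate_internal(
                InternalCoordinate("angle", (nbrs[a], center, nbrs[b])), geom)
    return total


def detect_inversions(graph: MolecularGraph, frame_a: Geometry,
                      frame_b: Geometry, exclude_atoms: set[int],
                      config: ScreenConfig) -> list[Change]:
    """Pyramidal-inversion scan over 3-coordinate centers.

    A center inverts when its angle sum crosses (or touches) the planarity
    band of 354 deg between the frames, or when the improper out-of-plane
    dihedral flips sign with a circular change beyond ``dihedral_thresh``.
    """
    out: list[Change] = []
    adj = graph.adjacency()
    for center, nbrs in adj.items():
        if len(nbrs) != 3 or center in exclude_atoms:
            continue
        try:
            s_a = _angle_sum(center, nbrs, frame_a)
            s_b = _angle_sum(center, nbrs, frame_b)
            d_a = _improper(center, nbrs, frame_a)
            d_b = _improper(center, nbrs, frame_b)
        except Exception:
            continue
        delta = (d_b - d_a + 180.0) % 360.0 - 180.0
        sum_crossing = min(s_a, s_b) <= PLANARITY_ANGLE_SUM <= max(s_a, s_b)
        sign_flip = (d_a * d_b < 0 and abs(delta) >= config.dihedral_thresh)
        if sum_crossing or sign_flip:
            coord = InternalCoordinate(
                "dihedral", (nbrs[0], nbrs[1], nbrs[2], center))
            out.append(Change(coord, float(delta), "inversion", "primary"))
    return out


def classify_mode(changes: Sequence[Change], graph: MolecularGraph,
                  frames: tuple[Geometry, Geometry],
                  config: ScreenConfig | None = None
                  ) -> tuple[str, list[Change]]:
    """Assign the overall mode class and append inversion events.

    Bond changes dominate; a lone surviving torsion is a hindered rotation;
    a 3-coordinate center passing through planarity is a pyramidal
    inversion; combinations are "mixed"; nothing at all is "none".
    """
    config = config or ScreenConfig()
    changes = list(changes)
    bond_atoms = {a for c in changes if c.coord.kind == "bond"
                  for a in c.coord.atoms}
    inversions = detect_inversions(graph, frames[0], frames[1], bond_atoms,
                                   config)
    existing = {c.coord for c in changes}
    changes += [c for c in inversions if c.coord not in existing]

    has_bond = any(c.classification in ("bond_break", "bond_form")
                   for c in changes)
    has_rot = any(c.classification == "rotation" for c in changes)
    has_inv = any(c.classification == "inversion" for c in changes)
    has_angle = any(c.classification == "angle_change" for c in changes)
    if has_bond:
        mode = "mixed" if (has_rot or has_inv) else "bond_change"
    elif has_rot and has_inv:
        mode = "mixed"
    elif has_rot:
        mode = "rotation"
    elif has_inv:
        mode = "inversion"
    elif has_angle:
        mode = "mixed"
    else:
        mode = "none"
    return mode, _sort_changes(changes)


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def analyze_ts(geometry: Geometry, modes: Sequence[NormalMode],
               config: ScreenConfig | None = None,
               graph_config: GraphConfig | None = None,
               amplitude: float = 0.5,
               reactant: Geometry | None = None,
               product: Geometry | None = None,
               total_charge: int = 0,
               write_displaced: str | Path | None = None,
               file_paths: dict[str, str] | None = None) -> ChangeReport:
    """Full normal-mode characterization of a transition-state geometry.

    Selects the imaginary mode, displaces forward/reverse, perceives the TS
    graph with extended (transition-state) thresholds, enumerates internal
    coordinates (augmented by reactant/product graphs when given), screens
    and filters the deltas, and classifies the mode.  Deterministic for
    fixed inputs and configuration.
    """
    config = config or ScreenConfig()
    graph_config = graph_config or GraphConfig()
    mode, extra_imag = select_imaginary(modes)
    pair = displace_along_mode(geometry, mode, amplitude,
                               write_path=write_displaced)
    graphs = {"ts": build_graph(geometry, graph_config, ts_mode=True,
                                total_charge=total_charge)}
    augment = []
    for name, geom in (("reactant", reactant), ("product", product)):
        if geom is not None:
            graphs[name] = build_graph(geom, graph_config, ts_mode=False,
                                       total_charge=total_charge)
            augment.append(graphs[name])
    internals = enumerate_internals(graphs["ts"], augment)
    snap_rev = evaluate_snapshot(internals, pair.reverse, frame_id=0)
    snap_fwd = evaluate_snapshot(internals, pair.forward, frame_id=1)
    detected = detect_changes(snap_rev, snap_fwd, internals, pair.forward,
                              config)
    filtered = filter_correlated(detected, graphs["ts"])
    mode_class, changes = classify_mode(filtered, graphs["ts"],
                                        (pair.reverse, pair.forward), config)
    fp = dict(file_paths or {})
    if write_displaced is not None:
        fp["displaced"] = str(write_displaced)
    return ChangeReport(changes, mode_class, ["reverse", "forward"], graphs,
                        extra_imag, fp, list(geometry.elements))


def _ts_proxy_index(frames: Sequence[Geometry]) -> int:
    """Frame nearest the midpoint of the cumulative Kabsch-RMSD arc length."""
    arcs = [0.0]
    for a, b in zip(frames, frames[1:]):
        arcs.append(arcs[-1] + kabsch_rmsd(a, b))
    half = arcs[-1] / 2.0
    return int(np.argmin([abs(x - half) for x in arcs]))


def analyze_trajectory(frames: Sequence[Geometry], strategy: str = "max_rmsd",
                       config: ScreenConfig | None = None,
                       graph_config: GraphConfig | None = None,
                       total_charge: int = 0,
                       file_paths: dict[str, str] | None = None
                       ) -> ChangeReport:
    """Characterize an IRC/QRC trajectory.

    The comparison pair comes from ``select_frames``; the graph is built
    (with extended thresholds) on the frame nearest the trajectory midpoint
    as a TS proxy and augmented with both endpoint graphs so coordinates
    fully formed only at the ends are still tracked.
    """
    config = config or ScreenConfig()
    graph_config = graph_config or GraphConfig()
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    n0 = len(frames[0])
    for f in frames[1:]:
        if len(f) != n0 or f.elements != frames[0].elements:
            raise ValueError("inconsistent atoms across frames")
    ia, ib = select_frames(frames, strategy)
    proxy = _ts_proxy_index(frames)
    graphs = {
        "ts": build_graph(frames[proxy], graph_config, ts_mode=True,
                          total_charge=total_charge),
        "first": build_graph(frames[0], graph_config, ts_mode=False,
                             total_charge=total_charge),
        "last": build_graph(frames[-1], graph_config, ts_mode=False,
                            total_charge=total_charge),
    }
    internals = enumerate_internals(graphs["ts"],
                                    [graphs["first"], graphs["last"]])
    snap_a = evaluate_snapshot(internals, frames[ia], frame_id=ia)
    snap_b = evaluate_snapshot(internals, frames[ib], frame_id=ib)
    detected = detect_changes(snap_a, snap_b, internals, frames[ib], config)
    filtered = filter_correlated(detected, graphs["ts"])
    mode_class, changes = classify_mode(filtered, graphs["ts"],
                                        (frames[ia], frames[ib]), config)
    return ChangeReport(changes, mode_class, [ia, ib], graphs, [],
                        dict(file_paths or {}), list(frames[0].elements))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_report(report: ChangeReport, path: str | Path) -> None:
    """Serialize a report as stable, versioned JSON (lossless round trip)."""
    Path(path).write_text(json.dumps(report.to_dict(), indent=1,
                                     sort_keys=True) + "\n")


def read_report(path: str | Path) -> ChangeReport:
    return ChangeReport.from_dict(json.loads(Path(path).read_text()))
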