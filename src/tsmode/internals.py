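"""Internal coordinates: enumeration from graph topology and evaluation.

Bonds, angles and dihedrals are enumerated exhaustively from connectivity
(optionally augmented with reactant/product graphs so that forming bonds
missing from a TS graph still get a coordinate), deduplicated under the
canonical orientation first-index < last-index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .geometry import Geometry
from .molgraph import MolecularGraph

__all__ = [
    "InternalCoordinate",
    "CoordinateSnapshot",
    "enumerate_internals",
    "evaluate_internal",
    "evaluate_snapshot",
    "delta_internal",
]

NEAR_LINEAR_DEG = 175.0


class UndefinedGeometryError(ValueError):
    """Coincident points or a zero-length axis make the coordinate undefined."""


@dataclass(frozen=True)
class InternalCoordinate:
    """A bond (i,j), angle (i,j,k) with center j, or dihedral (i,j,k,l)
    about the j-k axis, in canonical orientation (first index < last)."""

    kind: str           # "bond" | "angle" | "dihedral"
    atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        expect = {"bond": 2, "angle": 3, "dihedral": 4}
        if self.kind not in expect:
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        if len(self.atoms) != expect[self.kind]:
            raise ValueError(f"{self.kind} needs {expect[self.kind]} atoms")
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError("atom indices must be distinct")
        if self.atoms[0] > self.atoms[-1]:
            object.__setattr__(self, "atoms", tuple(reversed(self.atoms)))

    def label(self, elements: Sequence[str] | None = None) -> str:
        if elements is None:
            return "-".join(str(a) for a in self.atoms)
        return "-".join(f"{elements[a]}{a}" for a in self.atoms)

    def to_dict(self, elements: Sequence[str] | None = None) -> dict:
        doc = {"kind": self.kind, "atoms": list(self.atoms)}
        if elements is not None:
            doc["elements"] = [elements[a] for a in self.atoms]
        return doc


@dataclass
class CoordinateSnapshot:
    """Values of an internal-coordinate list evaluated on one frame."""

    coords: list[InternalCoordinate]
    values: np.ndarray
    frame_id: int | None = None

    def value_of(self, coord: InternalCoordinate) -> float:
        return float(self.values[self.coords.index(coord)])


def enumerate_internals(graph: MolecularGraph,
                        augment_graphs: Iterable[MolecularGraph] = ()
                        ) -> list[InternalCoordinate]:
    """All bonds, angles and dihedrals implied by the (augmented) topology.

    The bond set is the union of the main graph's edges with those of any
    augmenting graphs (matched by atom index); angles and dihedrals follow
    from the union adjacency.
    """
    edges = set(graph.edge_set)
    for aug in augment_graphs:
        if aug.n_atoms != graph.n_atoms:
            raise ValueError("augment graph atom count mismatch "
                             f"({aug.n_atoms} != {graph.n_atoms})")
        edges |= aug.edge_set

    adj: dict[int, set[int]] = {i: set() for i in range(graph.n_atoms)}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)

    out: set[InternalCoordinate] = set()
    for i, j in edges:
        out.add(InternalCoordinate("bond", (i, j)))
    for center, nbrs in adj.items():
        snbrs = sorted(nbrs)
        for a in range(len(snbrs)):
            for b in range(a + 1, len(snbrs)):
                out.add(InternalCoordinate("angle", (snbrs[a], center, snbrs[b])))
    for j, k in edges:
        for i in adj[j] - {k}:
            for l in adj[k] - {j}:
                if i == l:
                    continue
                out.add(InternalCoordinate("dihedral", (i, j, k, l)))
    return sorted(out, key=lambda c: ({"bond": 0, "angle": 1, "dihedral": 2}[c.kind],
                                      c.atoms))


def evaluate_internal(coord: InternalCoordinate, geometry: Geometry) -> float:
    """Value of one coordinate on one frame: Angstrom for bonds, degrees
    otherwise; dihedrals are signed in (-180, 180]."""
    xyz = geometry.coords
    if max(coord.atoms) >= len(geometry):
        raise IndexError("coordinate references atoms outside geometry")
    if coord.kind == "bond":
        i, j = coord.atoms
        return float(np.linalg.norm(xyz[i] - xyz[j]))
    if coord.kind == "angle":
        i, j, k = coord.atoms
        v1, v2 = xyz[i] - xyz[j], xyz[k] - xyz[j]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-10 or n2 < 1e-10:
            raise UndefinedGeometryError("coincident points in angle")
        c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
        return math.degrees(math.acos(c))
    i, j, k, l = coord.atoms
    b1, b2, b3 = xyz[j] - xyz[i], xyz[k] - xyz[j], xyz[l] - xyz[k]
    n2 = np.linalg.norm(b2)
    if n2 < 1e-10:
        raise UndefinedGeometryError("zero-length dihedral axis")
    c1 = np.cross(b1, b2)
    c2 = np.cross(b2, b3)
    if np.linalg.norm(c1) < 1e-10 or np.linalg.norm(c2) < 1e-10:
        raise UndefinedGeometryError("collinear atoms in dihedral")
    # standard atan2 construction; sign follows the right-hand rule about j->k
    x = float(np.dot(c1, c2))
    y = float(np.dot(np.cross(c1, c2), b2) / n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def evaluate_snapshot(coords: Sequence[InternalCoordinate], geometry: Geometry,
                      frame_id: int | None = None) -> CoordinateSnapshot:
    values = np.array([evaluate_internal(c, geometry) for c in coords])
    return CoordinateSnapshot(list(coords), values,
                              frame_id if frame_id is not None else geometry.frame_id)


def delta_internal(coord: InternalCoordinate, value_a: float,
                   value_b: float) -> float:
    """Signed change value_b - value_a; dihedrals use the minimal circular
    difference in (-180, 180] so 170 -> -170 reads as +20, not -340."""
    d = value_b - value_a
    if coord.kind == "dihedral":
        d = (d + 180.0) % 360.0 - 180.0
        if d == -180.0:
            d = 180.0
    return float(d)
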