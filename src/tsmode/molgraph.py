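"""Molecular graph perception from Cartesian coordinates.

Connectivity is assigned by a two-pass distance criterion on van der Waals
radii sums: pairs well below the per-class threshold are accepted directly,
borderline pairs must pass geometric validation (acute-angle and
ring-diagonal checks), and for transition-state geometries a second pass with
uniformly scaled thresholds picks up elongated forming/breaking bonds.
Bond orders and formal charges are then optimized by a beam search over
single/double/triple adjustments that minimizes valence deviation first and
formal charge second, with Kekule seeding for aromatic rings and metal-ligand
bonds pinned to order one.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .elements import element, is_metal
from .geometry import Geometry

__all__ = [
    "Bond",
    "GraphConfig",
    "MolecularGraph",
    "pair_threshold",
    "bond_class",
    "build_connectivity",
    "validate_candidate",
    "assign_bond_orders",
    "build_graph",
]

ALLOWED_ORDERS = (1, 1.5, 2, 3)


@dataclass(frozen=True)
class Bond:
    """An edge of the molecular graph, canonical with i < j."""

    i: int
    j: int
    order: float = 1.0
    dative: bool = False

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond endpoints must differ")
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)
        if self.order not in ALLOWED_ORDERS:
            raise ValueError(f"bond order {self.order} not in {ALLOWED_ORDERS}")

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j)


def _canonical(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class GraphConfig:
    """Tunable parameters of graph perception.

    ``factor_table`` multiplies the summed vdW radii per bond class; all
    factors sit in the 0.38-0.7 band, tighter for covalent bonds and looser
    for metal-ligand contacts.  ``direct_accept`` is the fraction of the
    threshold below which a pair is bonded without geometric validation.
    ``ts_scale`` is the uniform second-pass extension used for
    transition-state geometries.
    """

    factor_table: dict[str, float] = field(default_factory=lambda: {
        "H-X": 0.42,
        "nonmetal-nonmetal": 0.52,
        "metal-ligand": 0.65,
        "metal-metal": 0.70,
    })
    direct_accept: float = 0.6
    angle_min_metal: float = 15.0    # degrees
    angle_min_nonmetal: float = 30.0
    ts_scale: float = 1.4
    beam_width: int = 8
    ring_diagonal_ratio: float = 1.2
    iteration_cap: int = 200
    valence_weight: float = 4.0      # w_v > w_q: valence dominates charge
    charge_weight: float = 1.0
    aromatic_ring_sizes: tuple[int, ...] = (5, 6, 7)
    aromatic_planarity_tol: float = 0.15  # Angstrom out-of-plane

    def __post_init__(self) -> None:
        if not (0.0 < self.direct_accept < 1.0):
            raise ValueError("direct_accept must lie in (0, 1)")
        if self.ts_scale < 1.0:
            raise ValueError("ts_scale must be >= 1")
        for cls, f in self.factor_table.items():
            if not (0.38 <= f <= 0.7):
                raise ValueError(f"factor for {cls} outside [0.38, 0.7]")
        if self.valence_weight <= self.charge_weight:
            raise ValueError("valence weight must exceed charge weight")


@dataclass
class MolecularGraph:
    """Atoms + bonds (+ orders, dative flags) + formal charges of one frame."""

    elements: list[str]
    bonds: list[Bond]
    formal_charges: list[int] = field(default_factory=list)
    total_charge: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.formal_charges:
            self.formal_charges = [0] * len(self.elements)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < len(self.elements) and 0 <= b.j < len(self.elements)):
                raise ValueError(f"bond {b.key} references invalid atoms")
            if b.key in seen:
                raise ValueError(f"duplicate bond {b.key}")
            seen.add(b.key)
        self.bonds = sorted(self.bonds, key=lambda b: b.key)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return {b.key for b in self.bonds}

    def neighbors(self, i: int) -> list[int]:
        out = [b.j if b.i == i else b.i for b in self.bonds if i in b.key]
        return sorted(out)

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return {i: sorted(v) for i, v in adj.items()}

    def bond_order(self, i: int, j: int) -> float:
        key = _canonical(i, j)
        for b in self.bonds:
            if b.key == key:
                return b.order
        raise KeyError(f"no bond {key}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            g.add_node(i, element=el, formal_charge=self.formal_charges[i])
        for b in self.bonds:
            g.add_edge(b.i, b.j, order=b.order, dative=b.dative)
        return g

    def to_dict(self) -> dict:
        """Stable serialized form (schema documented in docs/methods.md)."""
        return {
            "schema_version": 1,
            "atoms": [
                {"index": i, "element": el, "formal_charge": self.formal_charges[i]}
                for i, el in enumerate(self.elements)
            ],
            "bonds": [
                {"i": b.i, "j": b.j, "order": b.order, "dative": b.dative}
                for b in self.bonds
            ],
            "adjacency": {str(i): v for i, v in self.adjacency().items()},
            "total_charge": self.total_charge,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MolecularGraph":
        elements = [a["element"] for a in doc["atoms"]]
        charges = [int(a["formal_charge"]) for a in doc["atoms"]]
        bonds = [Bond(b["i"], b["j"], b["order"], b["dative"])
                 for b in doc["bonds"]]
        return cls(elements, bonds, charges, int(doc["total_charge"]),
                   dict(doc.get("metadata", {})))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def bond_class(el_a: str, el_b: str) -> str:
    """Classify an element pair for threshold selection."""
    ma, mb = is_metal(el_a), is_metal(el_b)
    if ma and mb:
        return "metal-metal"
    if ma or mb:
        return "metal-ligand"
    if el_a.capitalize() == "H" or el_b.capitalize() == "H":
        return "H-X"
    return "nonmetal-nonmetal"


def pair_threshold(el_a: str, el_b: str, config: GraphConfig | None = None,
                   scale: float = 1.0) -> float:
    """Bonding distance threshold for an element pair, in Angstrom.

    threshold = scale * factor(class) * (r_vdw(a) + r_vdw(b)); symmetric.
    """
    config = config or GraphConfig()
    if scale < 1.0:
        raise ValueError("scale must be >= 1")
    rsum = element(el_a).vdw_radius + element(el_b).vdw_radius
    return scale * config.factor_table[bond_class(el_a, el_b)] * rsum


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(c))


def validate_candidate(candidate: tuple[int, int],
                       partial_bonds: Iterable[tuple[int, int]],
                       geometry: Geometry,
                       config: GraphConfig | None = None) -> bool:
    """Geometric screen for a borderline bond candidate.

    Rejects the candidate when it makes an implausibly acute angle with an
    already-accepted bond at either endpoint (< 15 deg at metal centers,
    < 30 deg otherwise), or when it closes a three-membered ring / cuts a
    chord across an existing four-membered ring while being longer than
    ``ring_diagonal_ratio`` times the mean of the ring's existing bonds.
    """
    config = config or GraphConfig()
    a, b = candidate
    adj: dict[int, set[int]] = {}
    for i, j in partial_bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    xyz = geometry.coords
    d_ab = float(np.linalg.norm(xyz[a] - xyz[b]))

    for end, other in ((a, b), (b, a)):
        limit = (config.angle_min_metal if is_metal(geometry.elements[end])
                 else config.angle_min_nonmetal)
        for nb in adj.get(end, ()):
            if nb == other:
                continue
            ang = _angle_deg(xyz[other] - xyz[end], xyz[nb] - xyz[end])
            if ang < limit:
                return False

    common = adj.get(a, set()) & adj.get(b, set())
    for c in common:  # candidate closes a 3-ring a-b-c
        side = 0.5 * (np.linalg.norm(xyz[a] - xyz[c]) +
                      np.linalg.norm(xyz[b] - xyz[c]))
        if d_ab > config.ring_diagonal_ratio * side:
            return False
    for x, y in itertools.combinations(sorted(common), 2):
        # a-x-b-y is an existing 4-ring; candidate a-b is its chord
        sides = [np.linalg.norm(xyz[a] - xyz[x]), np.linalg.norm(xyz[x] - xyz[b]),
                 np.linalg.norm(xyz[b] - xyz[y]), np.linalg.norm(xyz[y] - xyz[a])]
        if d_ab > config.ring_diagonal_ratio * float(np.mean(sides)):
            return False
    return True


def build_connectivity(geometry: Geometry, config: GraphConfig | None = None,
                       ts_mode: bool = False) -> MolecularGraph:
    """Perceive connectivity (all orders 1) from interatomic distances.

    Pass one runs at scale 1.0; with ``ts_mode`` a second pass at
    ``config.ts_scale`` adds (never removes) validated elongated bonds.
    Always returns a graph, whatever the geometry.
    """
    config = config or GraphConfig()
    if len(geometry) < 1:
        raise ValueError("geometry must contain at least one atom")
    n = len(geometry)
    xyz = geometry.coords
    dmat = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    base_thresh = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base_thresh[i, j] = pair_threshold(
                geometry.elements[i], geometry.elements[j], config)

    accepted: set[tuple[int, int]] = set()
    scales = [1.0, config.ts_scale] if ts_mode else [1.0]
    for scale in scales:
        direct: list[tuple[float, int, int]] = []
        borderline: list[tuple[float, int, int]] = []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in accepted:
                    continue
                thr = scale * base_thresh[i, j]
                d = dmat[i, j]
                if d < config.direct_accept * thr:
                    direct.append((d, i, j))
                elif d < thr:
                    borderline.append((d, i, j))
        for _, i, j in sorted(direct):
            accepted.add((i, j))
        for _, i, j in sorted(borderline):
            if validate_candidate((i, j), accepted, geometry, config):
                accepted.add((i, j))

    bonds = [Bond(i, j) for i, j in sorted(accepted)]
    return MolecularGraph(list(geometry.elements), bonds)


# ---------------------------------------------------------------------------
# bond order / formal charge optimization
# ---------------------------------------------------------------------------

def _nearest_valence(total: float, allowed: tuple[int, ...]) -> int:
    return min(allowed, key=lambda v: (abs(total - v), v))


def _formal_charge(total_order: float, allowed: tuple[int, ...]) -> float:
    return total_order - _nearest_valence(total_order, allowed)


def _atom_penalties(elements: Sequence[str], order_of: dict[tuple[int, int], float],
                    config: GraphConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-nonmetal-atom penalty contributions and formal charges.

    Metal-ligand bonds are excluded from the ligand atom's valence sum:
    the donor pair is the ligand's own, so a carbonyl carbon still counts
    as the triply bonded carbon of free CO.
    """
    n = len(elements)
    metal = [is_metal(el) for el in elements]
    sums = np.zeros(n)
    for (i, j), o in order_of.items():
        if metal[i] or metal[j]:
            continue
        sums[i] += o
        sums[j] += o
    pen = np.zeros(n)
    charges = np.zeros(n)
    for i, el in enumerate(elements):
        data = element(el)
        if data.is_metal:
            continue
        dev = min(abs(sums[i] - v) for v in data.allowed_valences)
        q = _formal_charge(sums[i], data.allowed_valences)
        charges[i] = q
        pen[i] = config.valence_weight * dev + config.charge_weight * abs(q)
    return pen, charges


def _pattern_penalty(elements: Sequence[str],
                     order_of: dict[tuple[int, int], float],
                     total_charge: int, config: GraphConfig) -> float:
    pen, charges = _atom_penalties(elements, order_of, config)
    penalty = float(pen.sum())
    # residual w.r.t. the requested total charge lands on the metals (or is
    # simply penalized when there are none), at w_q per unit
    residual = total_charge - float(charges.sum())
    penalty += config.charge_weight * abs(residual)
    return penalty


def _plane_deviation(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return float(np.max(np.abs(centered @ vt[2])))


def _aromatic_candidate_rings(graph: MolecularGraph, geometry: Geometry | None,
                              config: GraphConfig) -> list[list[int]]:
    """Rings of size 5-7 of 2-/3-connected C/N/O/S atoms, near-planar."""
    g = nx.Graph(list(graph.edge_set))
    if g.number_of_edges() == 0:
        return []
    adj = graph.adjacency()
    rings: list[list[int]] = []
    for cyc in nx.minimum_cycle_basis(g):
        if len(cyc) not in config.aromatic_ring_sizes:
            continue
        if any(graph.elements[i] not in ("C", "N", "O", "S") for i in cyc):
            continue
        if any(not 2 <= len(adj[i]) <= 3 for i in cyc):
            continue
        sub = g.subgraph(cyc)
        try:
            ordered = nx.cycle_basis(sub)[0]
        except IndexError:
            continue
        if len(ordered) != len(cyc):
            continue
        if geometry is not None:
            if _plane_deviation(geometry.coords[ordered]) > config.aromatic_planarity_tol:
                continue
        rings.append(ordered)
    return rings


def _kekule_seed(ring: list[int], order_of: dict[tuple[int, int], float]) -> None:
    if len(ring) % 2:
        return  # odd rings keep single bonds; the optimizer places the doubles
    for k in range(len(ring)):
        key = _canonical(ring[k], ring[(k + 1) % len(ring)])
        if key in order_of:
            order_of[key] = 2.0 if k % 2 == 0 else 1.0


def assign_bond_orders(graph: MolecularGraph, geometry: Geometry | None = None,
                       total_charge: int = 0,
                       config: GraphConfig | None = None) -> MolecularGraph:
    """Optimize bond orders and formal charges on an established topology.

    Beam search over single/double/triple adjustments on non-metal bonds:
    the atoms with the worst valence description are targeted at each step
    and the ``beam_width`` lowest-penalty patterns are retained, with
    penalty = sum over atoms of w_v * valence_deviation + w_q * |charge|.
    Metal-ligand bonds stay at order one and are labelled dative when the
    donor atom's valence is already satisfied without them.  Kekule rings
    whose alternation survives are rewritten to uniform order 1.5.
    """
    config = config or GraphConfig()
    elements = graph.elements
    metal_keys = {b.key for b in graph.bonds
                  if is_metal(elements[b.i]) or is_metal(elements[b.j])}
    free_keys = sorted(b.key for b in graph.bonds if b.key not in metal_keys)

    base: dict[tuple[int, int], float] = {b.key: 1.0 for b in graph.bonds}
    rings = _aromatic_candidate_rings(graph, geometry, config)
    seeded = dict(base)
    for ring in rings:
        _kekule_seed(ring, seeded)

    def state_orders(state: tuple[float, ...]) -> dict[tuple[int, int], float]:
        orders = dict(base)
        for key, o in zip(free_keys, state):
            orders[key] = o
        return orders

    def penalty(state: tuple[float, ...]) -> float:
        return _pattern_penalty(elements, state_orders(state), total_charge, config)

    start_states = {tuple(base[k] for k in free_keys),
                    tuple(seeded[k] for k in free_keys)}
    beam = sorted(start_states, key=lambda s: (penalty(s), s))
    best = beam[0]
    best_pen = penalty(best)
    converged = False
    incident: dict[int, list[int]] = {}
    for idx, (i, j) in enumerate(free_keys):
        incident.setdefault(i, []).append(idx)
        incident.setdefault(j, []).append(idx)

    for _ in range(config.iteration_cap):
        prev_best_pen = best_pen
        candidates: set[tuple[float, ...]] = set()
        for state in beam:
            pen, _ = _atom_penalties(elements, state_orders(state), config)
            if pen.max() <= 0:
                continue
            worst = np.flatnonzero(pen == pen.max())
            for atom in worst:
                for bidx in incident.get(int(atom), ()):
                    for delta in (-1.0, 1.0):
                        new_o = state[bidx] + delta
                        if not 1.0 <= new_o <= 3.0:
                            continue
                        cand = list(state)
                        cand[bidx] = new_o
                        candidates.add(tuple(cand))
        if not candidates:
            converged = True
            break
        pool = sorted(set(beam) | candidates, key=lambda s: (penalty(s), s))
        beam = pool[:config.beam_width]
        new_best = beam[0]
        new_pen = penalty(new_best)
        if new_pen < best_pen or (new_pen == best_pen and new_best < best):
            best, best_pen = new_best, new_pen
        lowest_candidate = min(penalty(c) for c in candidates)
        if lowest_candidate >= prev_best_pen:
            converged = True
            break

    orders = state_orders(best)

    # rewrite surviving Kekule alternation to aromatic order 1.5
    for ring in rings:
        if len(ring) % 2:
            continue
        ring_orders = [orders[_canonical(ring[k], ring[(k + 1) % len(ring)])]
                       for k in range(len(ring))]
        alternating = (all(o in (1.0, 2.0) for o in ring_orders) and
                       all(ring_orders[k] != ring_orders[(k + 1) % len(ring)]
                           for k in range(len(ring))))
        if alternating:
            for k in range(len(ring)):
                orders[_canonical(ring[k], ring[(k + 1) % len(ring)])] = 1.5

    # final formal charges from the optimized (possibly aromatic) orders
    _, charges_f = _atom_penalties(elements, orders, config)
    charges = [int(round(q)) for q in charges_f]
    metal_idx = [i for i, el in enumerate(elements) if is_metal(el)]
    residual = total_charge - sum(charges)
    if residual != 0:
        if metal_idx:
            charges[metal_idx[0]] += residual
        else:
            # keep the charge-sum invariant; flagged so callers can inspect
            anchor = max(range(len(charges)), key=lambda i: (abs(charges[i]), -i))
            charges[anchor] += residual

    # dative labelling: donor satisfied without counting the M-L bond
    nonmetal_orders = {k: o for k, o in orders.items() if k not in metal_keys}
    sums_wo_metal = np.zeros(len(elements))
    for (i, j), o in nonmetal_orders.items():
        sums_wo_metal[i] += o
        sums_wo_metal[j] += o
    bonds_out: list[Bond] = []
    for key in sorted(orders):
        if key in metal_keys:
            i, j = key
            donor = j if is_metal(elements[i]) else i
            dative = False
            if not is_metal(elements[donor]):
                allowed = element(elements[donor]).allowed_valences
                dative = min(abs(sums_wo_metal[donor] - v) for v in allowed) == 0
            bonds_out.append(Bond(key[0], key[1], 1.0, dative))
        else:
            bonds_out.append(Bond(key[0], key[1], orders[key], False))

    metadata = dict(graph.metadata)
    metadata["bond_order_converged"] = converged
    if residual != 0 and not metal_idx:
        metadata["charge_residual_assigned"] = residual
    return MolecularGraph(list(elements), bonds_out, charges, total_charge, metadata)


def build_graph(geometry: Geometry, config: GraphConfig | None = None,
                ts_mode: bool = False, total_charge: int = 0) -> MolecularGraph:
    """Connectivity perception followed by bond-order/charge optimization."""
    config = config or GraphConfig()
    conn = build_connectivity(geometry, config, ts_mode=ts_mode)
    return assign_bond_orders(conn, geometry, total_charge, config)
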