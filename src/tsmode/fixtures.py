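"""Programmatic model systems: transition states with synthetic imaginary
modes, equilibrium molecules with known graphs, and interpolated paths.

Everything the test surface needs is generated here from textbook geometry;
no external data is read.  Geometry parameters are chosen once so that the
model TSs behave like their real counterparts under the default
configuration: the elongated S N 2 axial bonds (2.3 / 2.0 Angstrom) are
invisible at equilibrium thresholds but picked up by the transition-state
pass, and the synthetic modes produce internal-coordinate changes that clear
the default screening thresholds at the default displacement amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry
from .internals import InternalCoordinate
from .molgraph import Bond, MolecularGraph
from .tsanalysis import Change
from .vibmode import NormalMode, displace_along_mode

__all__ = [
    "FixtureSpec",
    "make_model_ts",
    "make_equilibrium_molecule",
    "make_path",
    "EQUILIBRIUM_NAMES",
    "MODEL_TS_KINDS",
]

MODEL_TS_KINDS = ("sn2", "inversion", "rotation")

TET = math.degrees(math.acos(-1.0 / 3.0))  # 109.471 deg


@dataclass
class FixtureSpec:
    """A model TS plus the reference outcome of its analysis.

    ``expected_changes`` carry the identity (kind, atoms) and classification
    of each reference event; their ``delta`` fields are set to the change
    realized at the default amplitude, for inspection only — comparisons key
    on coordinate identity and classification.
    """

    name: str
    geometry: Geometry
    modes: list[NormalMode]
    expected_changes: list[Change]
    expected_class: str


def _dummy_modes(n_atoms: int) -> list[NormalMode]:
    """Two small positive-frequency modes so imaginary-mode selection is
    always exercised on realistic multi-mode input."""
    d1 = np.zeros((n_atoms, 3))
    d1[:, 0] = 0.1 + 0.01 * np.arange(n_atoms)
    d2 = np.zeros((n_atoms, 3))
    d2[:, 1] = 0.1
    d2[:, 2] = -0.05
    return [NormalMode(62.0, d1), NormalMode(118.0, d2)]


def _sn2() -> FixtureSpec:
    # trigonal-planar CH3 at the origin; leaving Cl and incoming F on +/- z.
    # 2.3 / 2.0 Angstrom sit between the 1.0x and 1.4x bonding thresholds.
    r_ch = 1.08
    atoms = ["C", "H", "H", "H", "Cl", "F"]
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        phi = 2.0 * math.pi * k / 3.0
        coords.append([r_ch * math.cos(phi), r_ch * math.sin(phi), 0.0])
    coords.append([0.0, 0.0, 2.3])    # Cl, elongated breaking bond
    coords.append([0.0, 0.0, -2.0])   # F, elongated forming bond
    geom = Geometry(atoms, np.array(coords), comment="model sn2 ts")

    # axial carbon motion with counter-motion of the axial partners and a
    # slight umbrella response of the hydrogens
    disp = np.zeros((6, 3))
    disp[0] = (0.0, 0.0, -1.0)   # C toward F
    disp[1:4] = (0.0, 0.0, 0.2)  # H umbrella
    disp[4] = (0.0, 0.0, 0.5)    # Cl recoil
    disp[5] = (0.0, 0.0, -0.3)   # F advance
    modes = [NormalMode(-500.0, disp)] + _dummy_modes(6)

    expected = [
        Change(InternalCoordinate("bond", (0, 4)), 1.5, "bond_break", "primary"),
        Change(InternalCoordinate("bond", (0, 5)), -0.7, "bond_form", "primary"),
    ]
    return FixtureSpec("sn2", geom, modes, expected, "bond_change")


def _inversion() -> FixtureSpec:
    # planar NH3: N at the centroid of three hydrogens, H-N-H = 120 deg
    r_nh = 1.01
    atoms = ["N", "H", "H", "H"]
    coords = [[0.0, 0.0, 0.0]]
    for k in range(3):
        phi = 2.0 * math.pi * k / 3.0
        coords.append([r_nh * math.cos(phi), r_nh * math.sin(phi), 0.0])
    geom = Geometry(atoms, np.array(coords), comment="planar ammonia ts")

    disp = np.zeros((4, 3))
    disp[0] = (0.0, 0.0, -1.0)    # N out of plane
    disp[1:] = (0.0, 0.0, 0.24)   # H counter-motion
    modes = [NormalMode(-500.0, disp)] + _dummy_modes(4)

    expected = [
        Change(InternalCoordinate("dihedral", (1, 2, 3, 0)), 0.0,
               "inversion", "primary"),
    ]
    return FixtureSpec("inversion", geom, modes, expected, "inversion")


def _rotation() -> FixtureSpec:
    # eclipsed F-H2C-CH2-F; the imaginary mode is a rigid torsion of the
    # far CH2F group about the C-C axis against the stationary near group.
    r_cc, r_cf, r_ch = 1.54, 1.36, 1.09
    sin_t, cos_t = math.sin(math.radians(TET)), -math.cos(math.radians(TET))
    atoms = ["C", "C", "F", "H", "H", "F", "H", "H"]
    coords = [[0.0, 0.0, 0.0], [0.0, 0.0, r_cc]]
    phis = [0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0]
    for r, phi in zip((r_cf, r_ch, r_ch), phis):  # on C0, pointing -z
        coords.append([r * sin_t * math.cos(phi), r * sin_t * math.sin(phi),
                       -r * cos_t])
    for r, phi in zip((r_cf, r_ch, r_ch), phis):  # on C1, eclipsing
        coords.append([r * sin_t * math.cos(phi), r * sin_t * math.sin(phi),
                       r_cc + r * cos_t])
    geom = Geometry(atoms, np.array(coords), comment="eclipsed fcc f ts")

    disp = np.zeros((8, 3))
    for idx in (5, 6, 7):  # rigid rotation field about z: d = w x r
        x, y, _ = coords[idx]
        disp[idx] = (-y, x, 0.0)
    modes = [NormalMode(-500.0, disp)] + _dummy_modes(8)

    expected = [
        Change(InternalCoordinate("dihedral", (2, 0, 1, 5)), 42.6,
               "rotation", "primary"),
    ]
    return FixtureSpec("rotation", geom, modes, expected, "rotation")


def make_model_ts(kind: str) -> FixtureSpec:
    """One of the model transition states: ``sn2`` (concerted break+form),
    ``inversion`` (planar ammonia), ``rotation`` (hindered torsion)."""
    builders = {"sn2": _sn2, "inversion": _inversion, "rotation": _rotation}
    if kind not in builders:
        raise ValueError(f"unknown model TS kind {kind!r}; "
                         f"choose from {MODEL_TS_KINDS}")
    return builders[kind]()


# ---------------------------------------------------------------------------
# equilibrium molecules with known graphs
# ---------------------------------------------------------------------------

def _ring(n: int, radius: float, z: float = 0.0) -> list[list[float]]:
    return [[radius * math.cos(2 * math.pi * k / n),
             radius * math.sin(2 * math.pi * k / n), z] for k in range(n)]


def _tetra_dirs() -> np.ndarray:
    return np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                    dtype=float) / math.sqrt(3.0)


def _equilibrium_library() -> dict[str, tuple[Geometry, list[Bond]]]:
    lib: dict[str, tuple[Geometry, list[Bond]]] = {}

    # water: r(O-H) = 0.96, H-O-H = 104.5
    th = math.radians(104.5 / 2.0)
    lib["water"] = (
        Geometry(["O", "H", "H"],
                 [[0, 0, 0],
                  [0.96 * math.sin(th), 0, 0.96 * math.cos(th)],
                  [-0.96 * math.sin(th), 0, 0.96 * math.cos(th)]]),
        [Bond(0, 1), Bond(0, 2)],
    )

    dirs = _tetra_dirs()
    lib["methane"] = (
        Geometry(["C"] + ["H"] * 4,
                 np.vstack([[0, 0, 0], 1.09 * dirs])),
        [Bond(0, k) for k in range(1, 5)],
    )

    # staggered ethane along z
    c1, c2 = np.array([0, 0, 0.0]), np.array([0, 0, 1.54])
    rows = [c1, c2]
    st, ct = math.sin(math.radians(TET)), -math.cos(math.radians(TET))
    for k in range(3):
        phi = 2 * math.pi * k / 3
        rows.append(c1 + 1.09 * np.array([st * math.cos(phi),
                                          st * math.sin(phi), -ct]))
    for k in range(3):
        phi = 2 * math.pi * k / 3 + math.pi / 3  # staggered
        rows.append(c2 + 1.09 * np.array([st * math.cos(phi),
                                          st * math.sin(phi), ct]))
    lib["ethane"] = (
        Geometry(["C", "C"] + ["H"] * 6, np.array(rows)),
        [Bond(0, 1)] + [Bond(0, k) for k in (2, 3, 4)]
        + [Bond(1, k) for k in (5, 6, 7)],
    )

    # planar ethene in the xz plane, C=C along z
    a = math.radians(121.3)
    hx, hz = 1.09 * math.sin(a), 1.09 * math.cos(a)
    lib["ethene"] = (
        Geometry(["C", "C", "H", "H", "H", "H"],
                 [[0, 0, 0], [0, 0, 1.33],
                  [hx, 0, hz], [-hx, 0, hz],
                  [hx, 0, 1.33 - hz], [-hx, 0, 1.33 - hz]]),
        [Bond(0, 1, 2.0), Bond(0, 2), Bond(0, 3), Bond(1, 4), Bond(1, 5)],
    )

    lib["ethyne"] = (
        Geometry(["C", "C", "H", "H"],
                 [[0, 0, 0], [0, 0, 1.20], [0, 0, -1.06], [0, 0, 2.26]]),
        [Bond(0, 1, 3.0), Bond(0, 2), Bond(1, 3)],
    )

    # D6h benzene: r(C-C) = 1.39 -> ring radius 1.39; H radius 1.39 + 1.09
    ring_c = _ring(6, 1.39)
    ring_h = _ring(6, 1.39 + 1.09)
    ring_bonds = [Bond(k, (k + 1) % 6, 1.5) for k in range(6)]
    lib["benzene"] = (
        Geometry(["C"] * 6 + ["H"] * 6, np.array(ring_c + ring_h)),
        ring_bonds + [Bond(k, k + 6) for k in range(6)],
    )

    # pyramidal ammonia: H-N-H = 107
    half = math.radians(107.0)
    # place H ring below N; solve ring radius from the H-N-H angle
    # |H_i - H_j| = 2 r sin(60deg_step/2) relation handled numerically
    r_nh = 1.01
    # ring radius rho and height h with rho^2 + h^2 = r_nh^2 and
    # angle(H-N-H) = 107 for adjacent ring positions (120 deg apart)
    # cos(107) = (h^2 - rho^2/2) / r_nh^2
    c107 = math.cos(half)
    rho2 = 2.0 * (1.0 - c107) * r_nh ** 2 / 3.0
    rho = math.sqrt(rho2)
    h = math.sqrt(r_nh ** 2 - rho2)
    nh3 = [[0, 0, 0]] + [[rho * math.cos(2 * math.pi * k / 3),
                          rho * math.sin(2 * math.pi * k / 3), -h]
                         for k in range(3)]
    lib["ammonia"] = (
        Geometry(["N", "H", "H", "H"], np.array(nh3)),
        [Bond(0, k) for k in range(1, 4)],
    )

    # methanol: staggered, C-O 1.43, O-H 0.96, C-O-H 108.5
    c = np.array([0, 0, 0.0])
    o = np.array([0, 0, 1.43])
    boh = math.radians(108.5)
    oh = o + 0.96 * np.array([math.sin(boh), 0, -math.cos(boh)])
    rows = [c, o, oh]
    for k in range(3):
        phi = 2 * math.pi * k / 3 + math.pi  # staggered w.r.t. the O-H
        rows.append(c + 1.09 * np.array([st * math.cos(phi),
                                         st * math.sin(phi), -ct]))
    lib["methanol"] = (
        Geometry(["C", "O", "H", "H", "H", "H"], np.array(rows)),
        [Bond(0, 1), Bond(1, 2), Bond(0, 3), Bond(0, 4), Bond(0, 5)],
    )

    lib["co2"] = (
        Geometry(["C", "O", "O"],
                 [[0, 0, 0], [0, 0, 1.16], [0, 0, -1.16]]),
        [Bond(0, 1, 2.0), Bond(0, 2, 2.0)],
    )

    # octahedral Cr(CO)6: Cr-C 1.91, C-O 1.14; M-C order 1, C(-)=O(+) triple
    axes = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
    rows = [[0.0, 0.0, 0.0]]
    elements = ["Cr"]
    bonds: list[Bond] = []
    for k, ax in enumerate(axes):
        rows.append(list(1.91 * ax))
        rows.append(list((1.91 + 1.14) * ax))
        elements += ["C", "O"]
        ci, oi = 1 + 2 * k, 2 + 2 * k
        bonds.append(Bond(0, ci, 1.0, dative=False))
        bonds.append(Bond(ci, oi, 3.0))
    lib["hexacarbonyl"] = (Geometry(elements, np.array(rows)), bonds)
    return lib


EQUILIBRIUM_NAMES = tuple(sorted(_equilibrium_library().keys()))


def make_equilibrium_molecule(name: str) -> tuple[Geometry, MolecularGraph]:
    """Textbook geometry plus the reference edge/order assignment."""
    lib = _equilibrium_library()
    if name not in lib:
        raise ValueError(f"unknown molecule {name!r}; "
                         f"choose from {EQUILIBRIUM_NAMES}")
    geom, bonds = lib[name]
    ref = MolecularGraph(list(geom.elements), list(bonds))
    return geom, ref


# ---------------------------------------------------------------------------
# interpolated paths
# ---------------------------------------------------------------------------

def make_path(fixture: FixtureSpec, n_frames: int, amplitude: float = 0.5,
              rigid_motion_seed: int | None = None) -> list[Geometry]:
    """Linear interpolation from the reverse- to the forward-displaced
    structure through the TS (odd ``n_frames`` puts the TS mid-path).

    With ``rigid_motion_seed`` each frame additionally receives a random
    rigid rotation + translation, exercising superposition-based frame
    comparison without changing any internal coordinate.
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    mode = fixture.modes[0]
    pair = displace_along_mode(fixture.geometry, mode, amplitude)
    rng = (np.random.default_rng(rigid_motion_seed)
           if rigid_motion_seed is not None else None)
    frames: list[Geometry] = []
    for k in range(n_frames):
        t = k / (n_frames - 1)
        xyz = (1.0 - t) * pair.reverse.coords + t * pair.forward.coords
        geom = Geometry(list(fixture.geometry.elements), xyz,
                        comment=f"{fixture.name} path frame {k}", frame_id=k)
        if rng is not None:
            geom = geom.transformed(rotation=_random_rotation(rng),
                                    translation=rng.uniform(-5.0, 5.0, 3))
        frames.append(geom)
    return frames


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR with determinant fix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
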