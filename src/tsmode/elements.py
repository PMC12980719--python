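"""Per-element data used for graph perception.

The van der Waals radii are the consistent periodic-table-wide compilation of
Alvarez (Dalton Trans., 2013, 42, 8617), frozen here so that distance
thresholds are reproducible regardless of any external library version.
Masses are standard atomic weights (amu). ``allowed_valences`` lists the
valence states a neutral nonmetal atom may adopt, in order of preference;
metals have no valence constraint and are instead handled by fixing
metal-ligand bond orders and absorbing residual charge.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ElementData:
    """Static properties of one element."""

    symbol: str
    number: int
    mass: float          # amu
    vdw_radius: float    # Angstrom
    is_metal: bool
    allowed_valences: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0 or self.mass <= 0:
            raise ValueError(f"nonpositive radius/mass for {self.symbol}")
        if not self.is_metal and not self.allowed_valences:
            raise ValueError(f"nonmetal {self.symbol} needs allowed valences")


# symbol: (Z, mass, vdw radius)
_RAW: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 1.20), "He": (2, 4.003, 1.43),
    "Li": (3, 6.94, 2.12), "Be": (4, 9.012, 1.98),
    "B": (5, 10.81, 1.91), "C": (6, 12.011, 1.77),
    "N": (7, 14.007, 1.66), "O": (8, 15.999, 1.50),
    "F": (9, 18.998, 1.46), "Ne": (10, 20.180, 1.58),
    "Na": (11, 22.990, 2.50), "Mg": (12, 24.305, 2.51),
    "Al": (13, 26.982, 2.25), "Si": (14, 28.085, 2.19),
    "P": (15, 30.974, 1.90), "S": (16, 32.06, 1.89),
    "Cl": (17, 35.45, 1.82), "Ar": (18, 39.948, 1.83),
    "K": (19, 39.098, 2.73), "Ca": (20, 40.078, 2.62),
    "Sc": (21, 44.956, 2.58), "Ti": (22, 47.867, 2.46),
    "V": (23, 50.942, 2.42), "Cr": (24, 51.996, 2.45),
    "Mn": (25, 54.938, 2.45), "Fe": (26, 55.845, 2.44),
    "Co": (27, 58.933, 2.40), "Ni": (28, 58.693, 2.40),
    "Cu": (29, 63.546, 2.38), "Zn": (30, 65.38, 2.39),
    "Ga": (31, 69.723, 2.32), "Ge": (32, 72.630, 2.29),
    "As": (33, 74.922, 1.88), "Se": (34, 78.971, 1.82),
    "Br": (35, 79.904, 1.86), "Kr": (36, 83.798, 2.25),
    "Rb": (37, 85.468, 3.21), "Sr": (38, 87.62, 2.84),
    "Y": (39, 88.906, 2.75), "Zr": (40, 91.224, 2.52),
    "Nb": (41, 92.906, 2.56), "Mo": (42, 95.95, 2.45),
    "Tc": (43, 97.0, 2.44), "Ru": (44, 101.07, 2.46),
    "Rh": (45, 102.906, 2.44), "Pd": (46, 106.42, 2.15),
    "Ag": (47, 107.868, 2.53), "Cd": (48, 112.414, 2.49),
    "In": (49, 114.818, 2.43), "Sn": (50, 118.710, 2.42),
    "Sb": (51, 121.760, 2.47), "Te": (52, 127.60, 1.99),
    "I": (53, 126.904, 2.04), "Xe": (54, 131.293, 2.06),
    "Cs": (55, 132.905, 3.48), "Ba": (56, 137.327, 3.03),
    "La": (57, 138.905, 2.98), "Ce": (58, 140.116, 2.88),
    "Pr": (59, 140.908, 2.92), "Nd": (60, 144.242, 2.95),
    "Pm": (61, 145.0, 2.90), "Sm": (62, 150.36, 2.90),
    "Eu": (63, 151.964, 2.87), "Gd": (64, 157.25, 2.83),
    "Tb": (65, 158.925, 2.79), "Dy": (66, 162.500, 2.87),
    "Ho": (67, 164.930, 2.81), "Er": (68, 167.259, 2.83),
    "Tm": (69, 168.934, 2.79), "Yb": (70, 173.045, 2.80),
    "Lu": (71, 174.967, 2.74), "Hf": (72, 178.49, 2.63),
    "Ta": (73, 180.948, 2.53), "W": (74, 183.84, 2.57),
    "Re": (75, 186.207, 2.49), "Os": (76, 190.23, 2.48),
    "Ir": (77, 192.217, 2.41), "Pt": (78, 195.084, 2.29),
    "Au": (79, 196.967, 2.32), "Hg": (80, 200.592, 2.45),
    "Tl": (81, 204.38, 2.47), "Pb": (82, 207.2, 2.60),
    "Bi": (83, 208.980, 2.54), "Po": (84, 209.0, 1.97),
    "At": (85, 210.0, 2.02), "Rn": (86, 222.0, 2.20),
}

# Metals: s-block (except H), d-block, f-block, plus the post-transition
# elements Al/Ga/In/Tl/Sn/Pb/Bi.  Needed for angle-validation class and for
# fixing metal-ligand bond orders.
_NONMETALS = {
    "H", "He", "B", "C", "N", "O", "F", "Ne", "Si", "P", "S", "Cl", "Ar",
    "Ge", "As", "Se", "Br", "Kr", "Sb", "Te", "I", "Xe", "Po", "At", "Rn",
}

_VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,), "He": (0,), "B": (3,), "C": (4,), "N": (3,), "O": (2,),
    "F": (1,), "Ne": (0,), "Si": (4,), "P": (3, 5), "S": (2, 4, 6),
    "Cl": (1,), "Ar": (0,), "Ge": (4,), "As": (3, 5), "Se": (2, 4, 6),
    "Br": (1,), "Kr": (0, 2), "Sb": (3, 5), "Te": (2, 4, 6), "I": (1,),
    "Xe": (0, 2, 4), "Po": (2, 4), "At": (1,), "Rn": (0,),
}

PERIODIC_TABLE: dict[str, ElementData] = {
    sym: ElementData(
        symbol=sym,
        number=z,
        mass=mass,
        vdw_radius=rvdw,
        is_metal=sym not in _NONMETALS,
        allowed_valences=_VALENCES.get(sym, ()),
    )
    for sym, (z, mass, rvdw) in _RAW.items()
}


class UnknownElementError(KeyError):
    """Raised when an element symbol is not in the frozen table."""


def element(symbol: str) -> ElementData:
    """Look up :class:`ElementData` by symbol (case-normalized)."""
    key = symbol.capitalize()
    try:
        return PERIODIC_TABLE[key]
    except KeyError:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}") from None


def is_metal(symbol: str) -> bool:
    return element(symbol).is_metal


def mass(symbol: str) -> float:
    return element(symbol).mass


def vdw_radius(symbol: str) -> float:
    return element(symbol).vdw_radius
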