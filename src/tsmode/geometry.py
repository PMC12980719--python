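"""Cartesian geometries and XYZ file I/O.

A :class:`Geometry` is an ordered list of atoms (element symbol + position in
Angstrom) with an optional comment retained from the XYZ comment line.
Multi-frame XYZ files (concatenated blocks) map to a list of geometries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .elements import PERIODIC_TABLE, UnknownElementError


class XYZParseError(ValueError):
    """Malformed XYZ input; message carries the offending line number."""


@dataclass
class Atom:
    index: int
    element: str
    position: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if self.element.capitalize() not in PERIODIC_TABLE:
            raise UnknownElementError(self.element)
        self.element = self.element.capitalize()


@dataclass
class Geometry:
    """One molecular frame: elements + Cartesian coordinates in Angstrom."""

    elements: list[str]
    coords: np.ndarray          # shape (n, 3)
    comment: str = ""
    frame_id: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValueError("coords shape must be (n_atoms, 3)")
        self.elements = [el.capitalize() for el in self.elements]
        for el in self.elements:
            if el not in PERIODIC_TABLE:
                raise UnknownElementError(el)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def atoms(self) -> list[Atom]:
        return [Atom(i, el, self.coords[i]) for i, el in enumerate(self.elements)]

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Geometry":
        """Return a rigidly moved copy (rotation applied before translation)."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return Geometry(list(self.elements), xyz, self.comment, self.frame_id)


def read_xyz(path: str | Path) -> list[Geometry]:
    """Parse a (possibly multi-frame) XYZ file into one Geometry per frame.

    Raises :class:`XYZParseError` naming the line number on malformed count
    lines, unknown element symbols, or frames with inconsistent atom counts.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Geometry] = []
    ln = 0
    n_expected: int | None = None
    while ln < len(lines):
        if not lines[ln].strip():  # tolerate blank separator lines
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise XYZParseError(f"line {ln + 1}: expected atom count, got "
                                f"{lines[ln]!r}") from None
        if natoms <= 0:
            raise XYZParseError(f"line {ln + 1}: atom count must be positive")
        if n_expected is None:
            n_expected = natoms
        elif natoms != n_expected:
            raise XYZParseError(
                f"line {ln + 1}: frame has {natoms} atoms, previous frames "
                f"have {n_expected}")
        if ln + 1 + natoms >= len(lines) + 1 and ln + 1 + natoms > len(lines):
            raise XYZParseError(f"line {ln + 1}: truncated frame")
        comment = lines[ln + 1] if ln + 1 < len(lines) else ""
        elements: list[str] = []
        rows: list[list[float]] = []
        for k in range(natoms):
            idx = ln + 2 + k
            if idx >= len(lines):
                raise XYZParseError(f"line {idx + 1}: truncated frame")
            parts = lines[idx].split()
            if len(parts) < 4:
                raise XYZParseError(f"line {idx + 1}: expected 'El x y z'")
            sym = parts[0].capitalize()
            if sym not in PERIODIC_TABLE:
                raise XYZParseError(f"line {idx + 1}: unknown element "
                                    f"symbol {parts[0]!r}")
            try:
                rows.append([float(v) for v in parts[1:4]])
            except ValueError:
                raise XYZParseError(
                    f"line {idx + 1}: non-numeric coordinate") from None
            elements.append(sym)
        frames.append(Geometry(elements, np.array(rows), comment,
                               frame_id=len(frames)))
        ln += 2 + natoms
    if not frames:
        raise XYZParseError("line 1: empty XYZ file")
    return frames


def write_xyz(path: str | Path, geometries: Geometry | Sequence[Geometry]) -> None:
    """Write one or more frames as a concatenated XYZ file."""
    if isinstance(geometries, Geometry):
        geometries = [geometries]
    out: list[str] = []
    for geom in geometries:
        out.append(str(len(geom)))
        out.append(geom.comment or "")
        for el, (x, y, z) in zip(geom.elements, geom.coords):
            out.append(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(out) + "\n")
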