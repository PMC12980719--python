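"""Vibrational modes: parsing, imaginary-mode selection, displacement.

The mode file format is deliberately minimal so any electronic-structure
parser can be adapted to it: blocks of

    freq <value-in-cm-1>
    x y z          (one displacement 3-vector per atom)

with '#' comments ignored.  A negative frequency denotes an imaginary mode.
Displaced geometries are the classic quick-reaction-coordinate construction:
TS +/- amplitude * normalized mode, where the mode is normalized so that its
largest per-atom norm is one, making the amplitude the Cartesian displacement
(in Angstrom) of the most-moving atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import Geometry, write_xyz


class ModeParseError(ValueError):
    pass


class NotATransitionStateError(ValueError):
    """No imaginary (negative) frequency present."""


@dataclass
class NormalMode:
    """Frequency in cm^-1 (negative = imaginary) + per-atom displacement."""

    frequency: float
    displacements: np.ndarray  # (n_atoms, 3), dimensionless direction

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.ndim != 2 or self.displacements.shape[1] != 3:
            raise ValueError("displacements must have shape (n_atoms, 3)")
        if not np.any(self.displacements):
            raise ValueError("mode displacements are all zero")

    @property
    def is_imaginary(self) -> bool:
        return self.frequency < 0.0

    @property
    def n_atoms(self) -> int:
        return self.displacements.shape[0]

    def normalized(self) -> np.ndarray:
        """Displacement field scaled so the largest per-atom norm is one."""
        norms = np.linalg.norm(self.displacements, axis=1)
        return self.displacements / norms.max()


@dataclass
class DisplacedPair:
    """Forward/reverse displaced geometries; their midpoint is the TS."""

    forward: Geometry
    reverse: Geometry
    amplitude: float


def read_modes(path: str | Path, n_atoms: int | None = None) -> list[NormalMode]:
    """Parse the documented mode format; order preserved.

    If ``n_atoms`` is given, every block must match it exactly.
    """
    lines = [ln.split("#", 1)[0].strip() for ln in
             Path(path).read_text().splitlines()]
    modes: list[NormalMode] = []
    freq: float | None = None
    rows: list[list[float]] = []

    def flush(line_no: int) -> None:
        nonlocal freq, rows
        if freq is None:
            return
        if not rows:
            raise ModeParseError(f"line {line_no}: mode block with no "
                                 "displacement vectors")
        modes.append(NormalMode(freq, np.array(rows)))
        freq, rows = None, []

    for no, ln in enumerate(lines, start=1):
        if not ln:
            continue
        if ln.lower().startswith("freq"):
            flush(no)
            parts = ln.split()
            if len(parts) != 2:
                raise ModeParseError(f"line {no}: expected 'freq <value>'")
            try:
                freq = float(parts[1])
            except ValueError:
                raise ModeParseError(f"line {no}: bad frequency "
                                     f"{parts[1]!r}") from None
        else:
            if freq is None:
                raise ModeParseError(f"line {no}: displacement before any "
                                     "'freq' header")
            parts = ln.split()
            if len(parts) != 3:
                raise ModeParseError(f"line {no}: expected 'x y z'")
            try:
                rows.append([float(v) for v in parts])
            except ValueError:
                raise ModeParseError(f"line {no}: non-numeric "
                                     "displacement") from None
    flush(len(lines) + 1)
    if not modes:
        raise ModeParseError("no mode blocks found")
    if n_atoms is not None:
        for m in modes:
            if m.n_atoms != n_atoms:
                raise ModeParseError(
                    f"mode has {m.n_atoms} displacement vectors, geometry "
                    f"has {n_atoms} atoms")
    return modes


def write_modes(path: str | Path, modes: Sequence[NormalMode]) -> None:
    out: list[str] = []
    for m in modes:
        out.append(f"freq {m.frequency:.4f}")
        for x, y, z in m.displacements:
            out.append(f"{x:14.8f} {y:14.8f} {z:14.8f}")
    Path(path).write_text("\n".join(out) + "\n")


def select_imaginary(modes: Sequence[NormalMode]
                     ) -> tuple[NormalMode, list[float]]:
    """The most negative-frequency mode, plus any further imaginary
    frequencies as diagnostics.  Raises when no frequency is negative."""
    if not modes:
        raise ValueError("empty mode list")
    imag = sorted((m for m in modes if m.is_imaginary),
                  key=lambda m: m.frequency)
    if not imag:
        raise NotATransitionStateError(
            "no imaginary frequency: structure is not a first-order saddle")
    return imag[0], [m.frequency for m in imag[1:]]


def displace_along_mode(geometry: Geometry, mode: NormalMode,
                        amplitude: float = 0.5,
                        write_path: str | Path | None = None) -> DisplacedPair:
    """TS +/- amplitude * mode (max-atom-norm normalization).

    The most-moving atom travels exactly ``amplitude`` Angstrom in each
    direction; the forward/reverse midpoint reproduces the input geometry.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if mode.n_atoms != len(geometry):
        raise ValueError("mode/geometry atom count mismatch")
    d = mode.normalized()
    fwd = Geometry(list(geometry.elements), geometry.coords + amplitude * d,
                   comment=f"tsmode forward a={amplitude}")
    rev = Geometry(list(geometry.elements), geometry.coords - amplitude * d,
                   comment=f"tsmode reverse a={amplitude}")
    pair = DisplacedPair(fwd, rev, amplitude)
    if write_path is not None:
        write_xyz(write_path, [fwd, rev])
    return pair
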