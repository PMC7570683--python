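"""Volumetric scalar fields with Gaussian-cube I/O.

A :class:`ScalarField` carries a regular (possibly non-orthogonal) grid —
origin, three step vectors, voxel counts — a value array, and the atom sites
of the molecule the field belongs to. It is the common carrier for electron
densities, spin densities and every derived local descriptor.

Cube conventions followed on read: two comment lines; line 3 holds natoms and
the origin (a negative natoms flags an orbital cube, in which case one extra
index line after the atom block is consumed); lines 4–6 hold voxel counts and
axis vectors; values are listed with the last (z) axis varying fastest.
Lengths are in bohr. On write a single canonical dialect is emitted: positive
natoms, z-fastest ordering, six values per line in scientific notation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from .errors import FormatError, GridMismatchError, InvariantError
from .units import BOHR_PER_ANGSTROM

__all__ = ["AtomSite", "ScalarField", "read_cube", "write_cube", "read_xyz"]

#: Recognised quantity tags for ScalarField.quantity.
QUANTITIES = (
    "density",
    "spin_density",
    "fukui_plus",
    "fukui_minus",
    "fukui_zero",
    "dual",
    "parr_plus",
    "parr_minus",
    "parr_dual",
)

#: Tolerance (bohr, absolute) under which two grids count as identical.
GRID_TOL = 1e-8

_SYMBOLS = {
    1: "H", 2: "He", 3: "Li", 4: "Be", 5: "B", 6: "C", 7: "N", 8: "O",
    9: "F", 10: "Ne", 11: "Na", 12: "Mg", 13: "Al", 14: "Si", 15: "P",
    16: "S", 17: "Cl", 18: "Ar", 19: "K", 20: "Ca", 26: "Fe", 29: "Cu",
    30: "Zn", 35: "Br", 53: "I",
}
_NUMBERS = {v: k for k, v in _SYMBOLS.items()}


@dataclass(frozen=True)
class AtomSite:
    """One atom: element symbol, nuclear charge and position in bohr."""

    element: str
    nuclear_charge: float
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.nuclear_charge > 0:
            raise InvariantError(f"atom {self.element}: nuclear charge must be > 0")
        if not all(math.isfinite(x) for x in self.position):
            raise InvariantError(f"atom {self.element}: non-finite position")

    @classmethod
    def from_number(cls, z: int, position: Sequence[float]) -> "AtomSite":
        sym = _SYMBOLS.get(int(round(z)), f"Z{int(round(z))}")
        return cls(element=sym, nuclear_charge=float(z), position=tuple(map(float, position)))


@dataclass
class ScalarField:
    """A scalar quantity sampled on a regular 3-D grid.

    Attributes
    ----------
    origin : (3,) array, bohr — position of the first grid point.
    axes : (3, 3) array, bohr — rows are the three grid step vectors.
    values : 3-D array with shape equal to the voxel counts.
    atoms : atom sites the field belongs to.
    quantity : tag describing what the values are (see ``QUANTITIES``).
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray
    atoms: list[AtomSite] = field(default_factory=list)
    quantity: str = "density"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvariantError("values must be a 3-D array")
        if self.voxel_volume <= 0:
            raise InvariantError("det(axes) must be positive (left-handed or singular grid)")
        if self.quantity not in QUANTITIES:
            raise InvariantError(f"unknown quantity tag {self.quantity!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume element det(axes) in bohr³."""
        return float(np.linalg.det(self.axes))

    def integrate(self) -> float:
        """Midpoint-rule integral Σ values · det(axes)."""
        return float(self.values.sum() * self.voxel_volume)

    def grid_points(self) -> np.ndarray:
        """Cartesian coordinates of every grid point, shape (nx, ny, nz, 3)."""
        nx, ny, nz = self.shape
        i = np.arange(nx)[:, None, None, None]
        j = np.arange(ny)[None, :, None, None]
        k = np.arange(nz)[None, None, :, None]
        return (
            self.origin
            + i * self.axes[0]
            + j * self.axes[1]
            + k * self.axes[2]
        )

    def compatible_with(self, other: "ScalarField", tol: float = GRID_TOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, rtol=0, atol=tol)
            and np.allclose(self.axes, other.axes, rtol=0, atol=tol)
        )

    def require_compatible(self, other: "ScalarField", tol: float = GRID_TOL) -> None:
        """Raise :class:`GridMismatchError` naming the first differing component."""
        if self.shape != other.shape:
            raise GridMismatchError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.origin, other.origin, rtol=0, atol=tol):
            raise GridMismatchError(
                f"origin mismatch: {self.origin.tolist()} vs {other.origin.tolist()}"
            )
        if not np.allclose(self.axes, other.axes, rtol=0, atol=tol):
            raise GridMismatchError("axes mismatch")

    def with_values(self, values: np.ndarray, quantity: str) -> "ScalarField":
        """New field on the same grid/atoms with different values and tag."""
        return ScalarField(
            origin=self.origin.copy(),
            axes=self.axes.copy(),
            values=np.asarray(values, dtype=float),
            atoms=list(self.atoms),
            quantity=quantity,
        )


# ---------------------------------------------------------------------------
# cube I/O


def read_cube(source: str | Path | IO[str], quantity: str = "density") -> ScalarField:
    """Parse a Gaussian cube file into a :class:`ScalarField`.

    Negative-natoms (orbital) headers are accepted: the orbital-index line is
    consumed and, if it names several orbitals, only the first data block
    layout is assumed (one value per point per orbital is not supported).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = text.splitlines()
    if len(lines) < 6:
        raise FormatError("cube file too short for a header")
    try:
        head = lines[2].split()
        natoms_signed = int(head[0])
        origin = np.array([float(x) for x in head[1:4]])
        axis_rows = []
        counts = []
        for ln in lines[3:6]:
            parts = ln.split()
            counts.append(int(parts[0]))
            axis_rows.append([float(x) for x in parts[1:4]])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed cube header: {exc}") from exc
    natoms = abs(natoms_signed)
    axes = np.array(axis_rows)
    shape = tuple(counts)

    atom_lines = lines[6 : 6 + natoms]
    if len(atom_lines) < natoms:
        raise FormatError(f"expected {natoms} atom lines, found {len(atom_lines)}")
    atoms = []
    for ln in atom_lines:
        parts = ln.split()
        z = float(parts[0])
        pos = [float(x) for x in parts[2:5]]
        atoms.append(AtomSite.from_number(int(round(z)), pos))

    data_start = 6 + natoms
    if natoms_signed < 0:
        data_start += 1  # orbital-index line

    flat: list[float] = []
    for ln in lines[data_start:]:
        flat.extend(float(x) for x in ln.split())
    expected = shape[0] * shape[1] * shape[2]
    if len(flat) != expected:
        raise FormatError(
            f"cube value block truncated or padded: expected {expected} values, "
            f"found {len(flat)}"
        )
    values = np.array(flat).reshape(shape)
    return ScalarField(origin=origin, axes=axes, values=values, atoms=atoms, quantity=quantity)


def write_cube(field_: ScalarField, target: str | Path | IO[str]) -> None:
    """Write the canonical cube dialect (positive natoms, bohr, z-fastest)."""
    out = []
    out.append("cdftkit scalar field")
    out.append(f"quantity: {field_.quantity}")
    o = field_.origin
    # full float precision in the header so grids survive a round-trip exactly
    out.append(f"{len(field_.atoms):5d} {o[0]: .16E} {o[1]: .16E} {o[2]: .16E}")
    for n, ax in zip(field_.shape, field_.axes):
        out.append(f"{n:5d} {ax[0]: .16E} {ax[1]: .16E} {ax[2]: .16E}")
    for a in field_.atoms:
        x, y, z = a.position
        out.append(
            f"{int(round(a.nuclear_charge)):5d} {a.nuclear_charge: .6f}"
            f" {x: .16E} {y: .16E} {z: .16E}"
        )
    flat = field_.values.reshape(-1)
    for start in range(0, flat.size, 6):
        out.append(" ".join(f"{v: .11E}" for v in flat[start : start + 6]))
    text = "\n".join(out) + "\n"
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text)


def read_xyz(source: str | Path | IO[str]) -> list[AtomSite]:
    """Read an XYZ file (angstrom); positions are converted to bohr."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = [ln for ln in text.splitlines()]
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"bad XYZ header: {exc}") from exc
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise FormatError(f"XYZ file lists {n} atoms but has {len(body)} atom lines")
    atoms = []
    for ln in body:
        parts = ln.split()
        sym = parts[0]
        pos = tuple(float(x) * BOHR_PER_ANGSTROM for x in parts[1:4])
        z = _NUMBERS.get(sym.capitalize())
        if z is None:
            raise FormatError(f"unknown element symbol {sym!r} in XYZ file")
        atoms.append(AtomSite(element=sym.capitalize(), nuclear_charge=float(z), position=pos))
    return atoms
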