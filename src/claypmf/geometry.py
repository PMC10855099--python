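"""Triclinic-cell geometry: lattice construction, minimum-image distances,
centers of mass and the basal-oxygen surface plane.

The simulation cell of a 2:1 clay is triclinic; lattice vectors follow the
standard crystallographic convention (``a`` along x, ``b`` in the xy plane).
The reaction coordinate of the desorption analysis is measured along the
Cartesian z axis relative to the plane of the basal oxygen atoms (Ob), taken
as the instantaneous arithmetic mean of their z coordinates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import ATOMIC_MASSES

__all__ = [
    "TriclinicCell",
    "AtomRecord",
    "Snapshot",
    "build_cell",
    "basal_spacing",
    "min_image_distance",
    "center_of_mass",
    "surface_z",
]

#: Closed set of structural roles; adsorbate atoms use the ``atrazine:<name>``
#: form (e.g. ``atrazine:N3``), where <name> is a per-molecule atom label.
STRUCTURAL_ROLES = frozenset({"Ob", "Si", "Al", "Mg", "Ca1", "Ca2", "Ow", "Hw"})

#: Adsorbate atom labels that may appear at most once per snapshot.
UNIQUE_ATRAZINE_LABELS = frozenset({"N1", "N3", "Cl", "Ce", "Ci"})


class GeometryError(ValueError):
    """Invalid cell parameters or snapshot contents."""


def _validate_role(role: str) -> None:
    if role in STRUCTURAL_ROLES:
        return
    if role.startswith("atrazine:") and len(role) > len("atrazine:"):
        return
    raise GeometryError(
        f"unknown atom role {role!r}; expected one of {sorted(STRUCTURAL_ROLES)} "
        "or 'atrazine:<name>'"
    )


@dataclass(frozen=True)
class TriclinicCell:
    """A triclinic periodic cell.

    Attributes
    ----------
    a, b, c : float
        Edge lengths in Å.
    alpha, beta, gamma : float
        Cell angles in degrees (alpha between b and c, beta between a and c,
        gamma between a and b).
    lattice_vectors : np.ndarray, shape (3, 3)
        Row i is lattice vector i in Å, in the convention a || x, b in xy.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    lattice_vectors: np.ndarray = field(repr=False, compare=False)

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (triple product of the lattice vectors)."""
        return float(abs(np.linalg.det(self.lattice_vectors)))


def build_cell(a: float, b: float, c: float,
               alpha: float, beta: float, gamma: float) -> TriclinicCell:
    """Construct a :class:`TriclinicCell` from lengths (Å) and angles (deg).

    Raises
    ------
    GeometryError
        If any length is non-positive, any angle outside (0°, 180°), or the
        angle combination does not close into a positive-volume cell.
    """
    for name, val in (("a", a), ("b", b), ("c", c)):
        if not val > 0:
            raise GeometryError(f"cell length {name} must be > 0, got {val}")
    for name, val in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not 0.0 < val < 180.0:
            raise GeometryError(
                f"cell angle {name} must lie in (0, 180) degrees, got {val}")

    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    sg = math.sin(math.radians(gamma))
    v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if v2 <= 0.0:
        raise GeometryError(
            f"angles ({alpha}, {beta}, {gamma}) do not define a cell of "
            "positive volume")
    v = math.sqrt(v2)

    avec = np.array([a, 0.0, 0.0])
    bvec = np.array([b * cg, b * sg, 0.0])
    cvec = np.array([c * cb, c * (ca - cb * cg) / sg, c * v / sg])
    return TriclinicCell(a, b, c, alpha, beta, gamma,
                         np.vstack([avec, bvec, cvec]))


def cell_parameters(cell: TriclinicCell) -> tuple[float, float, float, float, float, float]:
    """Recover (a, b, c, alpha, beta, gamma) from the lattice vectors."""
    av, bv, cv = cell.lattice_vectors
    a, b, c = (float(np.linalg.norm(x)) for x in (av, bv, cv))

    def ang(u, v):
        return math.degrees(math.acos(float(np.dot(u, v)) /
                                      (np.linalg.norm(u) * np.linalg.norm(v))))

    return a, b, c, ang(bv, cv), ang(av, cv), ang(av, bv)


def basal_spacing(cell: TriclinicCell) -> float:
    """Basal (layer-repeat) spacing d001 = c·sin(beta) in Å."""
    return cell.c * math.sin(math.radians(cell.beta))


def min_image_distance(p: Sequence[float], q: Sequence[float],
                       cell: TriclinicCell) -> float:
    """Minimum-image distance |p - q| (Å) under 3-D periodicity.

    Reduces the fractional separation to the central cell, then searches the
    27 neighbouring images — exact for separations below half the shortest
    cell height.
    """
    d = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    m = cell.lattice_vectors.T  # columns are lattice vectors
    frac = np.linalg.solve(m, d)
    frac -= np.round(frac)
    shifts = np.array([(i, j, k)
                       for i in (-1, 0, 1)
                       for j in (-1, 0, 1)
                       for k in (-1, 0, 1)], dtype=float)
    cart = (m @ (frac[:, None] + shifts.T)).T
    return float(np.min(np.linalg.norm(cart, axis=1)))


@dataclass
class AtomRecord:
    """One atom: element symbol, structural role, position (Å) and mass (amu).

    The mass defaults to the standard atomic weight of ``element``.
    """

    element: str
    role: str
    position: np.ndarray
    mass: float | None = None

    def __post_init__(self):
        _validate_role(self.role)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise GeometryError("position must be a 3-vector")
        if self.mass is None:
            try:
                self.mass = ATOMIC_MASSES[self.element]
            except KeyError:
                raise GeometryError(
                    f"no standard mass for element {self.element!r}; "
                    "pass mass explicitly") from None
        if not self.mass > 0:
            raise GeometryError(f"mass must be > 0, got {self.mass}")


@dataclass
class Snapshot:
    """A periodic configuration: cell, role-tagged atoms and a time stamp.

    ``surf_indices`` marks which Ob atoms form the adsorbing sheet used as
    the surface reference; if None, every Ob atom belongs to it.
    """

    cell: TriclinicCell
    atoms: list[AtomRecord]
    time: float = 0.0
    surf_indices: list[int] | None = None

    def __post_init__(self):
        seen: set[str] = set()
        for at in self.atoms:
            if at.role.startswith("atrazine:"):
                label = at.role.split(":", 1)[1]
                if label in UNIQUE_ATRAZINE_LABELS:
                    if label in seen:
                        raise GeometryError(
                            f"atrazine atom {label} appears more than once")
                    seen.add(label)
        for unique_role in ("Ca1", "Ca2"):
            if sum(1 for at in self.atoms if at.role == unique_role) > 1:
                raise GeometryError(f"more than one {unique_role} atom")

    def indices_with_role(self, role: str) -> list[int]:
        return [i for i, at in enumerate(self.atoms) if at.role == role]

    def single_atom(self, role: str) -> AtomRecord:
        """The unique atom with ``role``; raises if absent or duplicated."""
        idx = self.indices_with_role(role)
        if len(idx) != 1:
            raise GeometryError(
                f"expected exactly one atom with role {role!r}, found {len(idx)}")
        return self.atoms[idx[0]]

    def atrazine_atoms(self, heavy_only: bool = True) -> list[AtomRecord]:
        out = [at for at in self.atoms if at.role.startswith("atrazine:")]
        if heavy_only:
            out = [at for at in out if at.element != "H"]
        return out

    def water_oxygen_indices(self) -> list[int]:
        return self.indices_with_role("Ow")


def center_of_mass(atoms: Iterable[AtomRecord]) -> np.ndarray:
    """Mass-weighted mean position (Å) of ``atoms``.

    No periodic unwrapping is performed: the caller must supply a connected
    periodic image of the molecule.
    """
    atoms = list(atoms)
    if not atoms:
        raise GeometryError("center_of_mass of an empty atom list")
    masses = np.array([at.mass for at in atoms])
    pos = np.array([at.position for at in atoms])
    return (masses[:, None] * pos).sum(axis=0) / masses.sum()


def surface_z(snapshot: Snapshot) -> float:
    """Mean Cartesian z (Å) of the adsorbing-sheet basal oxygens."""
    if snapshot.surf_indices is not None:
        idx = list(snapshot.surf_indices)
        for i in idx:
            if snapshot.atoms[i].role != "Ob":
                raise GeometryError(
                    f"surf index {i} is a {snapshot.atoms[i].role}, not Ob")
    else:
        idx = snapshot.indices_with_role("Ob")
    if not idx:
        raise GeometryError("snapshot has no basal oxygen (Ob) atoms")
    return float(np.mean([snapshot.atoms[i].position[2] for i in idx]))
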