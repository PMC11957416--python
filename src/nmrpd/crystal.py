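"""Unit cells, space-group symmetry and elementary crystallographic arithmetic.

Everything downstream (pattern simulation, intermolecular distances,
structure comparison) works on :class:`CrystalStructure`: a unit cell, an
explicit space-group operator list, and the asymmetric-unit atom sites.
Angles are degrees at every public interface; radians are internal only.
"""

from __future__ import annotations

import dataclasses
import functools
import math
from dataclasses import dataclass

import gemmi
import numpy as np

AVOGADRO = 6.02214076e23

__all__ = [
    "UnitCell",
    "SpaceGroup",
    "AtomSite",
    "CrystalStructure",
    "InvalidCellError",
    "cell_volume",
    "calc_density",
    "expand_symmetry",
    "d_spacing",
    "two_theta",
    "space_group_from_symbol",
    "space_group_from_triplets",
    "BUILTIN_SPACE_GROUPS",
]


class InvalidCellError(ValueError):
    """Raised for degenerate cell metrics (non-positive volume)."""


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell constants: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError(f"non-positive cell length in {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError(f"cell angle {ang} outside (0, 180)")
        if self.volume() <= 0:
            raise InvalidCellError(f"non-positive cell volume for {self}")

    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            raise InvalidCellError(f"degenerate metric for {self}")
        return self.a * self.b * self.c * math.sqrt(arg)

    @functools.cached_property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix M with cartesian = M @ fractional (PDB convention, Å)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        v = self.volume()
        return np.array(
            [
                [self.a, self.b * math.cos(ga), self.c * math.cos(be)],
                [0.0, self.b * math.sin(ga),
                 self.c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)],
                [0.0, 0.0, v / (self.a * self.b * math.sin(ga))],
            ]
        )

    @functools.cached_property
    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix)

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional -> cartesian (Å); accepts (..., 3) arrays."""
        return np.asarray(frac, dtype=float) @ self.orthogonalization_matrix.T

    def fractionalize(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.fractionalization_matrix.T

    @functools.cached_property
    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G* such that 1/d² = h·G*·h."""
        m = self.orthogonalization_matrix
        g = m.T @ m
        return np.linalg.inv(g)


@dataclass(frozen=True)
class SymOp:
    """One space-group operator x' = R x + t (fractional coordinates)."""

    rot: tuple  # 3x3 nested tuple of ints
    tran: tuple  # 3 floats (fractions)

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        op = gemmi.Op(triplet)
        den = float(gemmi.Op.DEN)
        rot = tuple(tuple(int(round(x / den)) for x in row) for row in op.rot)
        tran = tuple(x / den for x in op.tran)
        return cls(rot, tran)

    def triplet(self) -> str:
        den = gemmi.Op.DEN
        op = gemmi.Op()
        op.rot = [[int(round(x * den)) for x in row] for row in self.rot]
        op.tran = [int(round(x * den)) for x in self.tran]
        return op.triplet()

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, float) @ np.asarray(self.rot, float).T + np.asarray(self.tran)


@dataclass(frozen=True)
class SpaceGroup:
    """Space group as an explicit operator list.

    ``polar_axes`` are the axes along which the origin floats (e.g. b in
    P2₁); ``discrete_shifts`` are the permissible discrete origin changes,
    used when comparing structures.
    """

    symbol: str
    operators: tuple  # tuple of SymOp
    polar_axes: frozenset = frozenset()
    centrosymmetric: bool = False
    discrete_shifts: tuple = ((0.0, 0.0, 0.0),)

    @property
    def n_operators(self) -> int:
        return len(self.operators)


def _sg(symbol, triplets, polar, centro, shifts):
    return SpaceGroup(
        symbol=symbol,
        operators=tuple(SymOp.from_triplet(t) for t in triplets),
        polar_axes=frozenset(polar),
        centrosymmetric=centro,
        discrete_shifts=tuple(shifts),
    )


def _half_shifts(axes):
    """All 0/½ combinations over the given axes (others fixed at 0)."""
    out = []
    for mask in range(1 << len(axes)):
        s = [0.0, 0.0, 0.0]
        for i, ax in enumerate(axes):
            if mask >> i & 1:
                s[ax] = 0.5
        out.append(tuple(s))
    return out


#: Built-in settings covering the monoclinic groups of this problem class.
BUILTIN_SPACE_GROUPS = {
    "P1": _sg("P1", ["x,y,z"], {0, 1, 2}, False, [(0.0, 0.0, 0.0)]),
    "P21": _sg("P21", ["x,y,z", "-x,y+1/2,-z"], {1}, False, _half_shifts([0, 2])),
    "P21/c": _sg(
        "P21/c",
        ["x,y,z", "-x,y+1/2,-z+1/2", "-x,-y,-z", "x,-y+1/2,z+1/2"],
        set(), True, _half_shifts([0, 1, 2]),
    ),
    "P21/n": _sg(
        "P21/n",
        ["x,y,z", "-x+1/2,y+1/2,-z+1/2", "-x,-y,-z", "x+1/2,-y+1/2,z+1/2"],
        set(), True, _half_shifts([0, 1, 2]),
    ),
    "P21/a": _sg(
        "P21/a",
        ["x,y,z", "-x+1/2,y+1/2,-z", "-x,-y,-z", "x+1/2,-y+1/2,z"],
        set(), True, _half_shifts([0, 1, 2]),
    ),
}


def space_group_from_symbol(symbol: str) -> SpaceGroup:
    """Look up a built-in space group by Hermann–Mauguin symbol."""
    key = symbol.replace(" ", "")
    for k, sg in BUILTIN_SPACE_GROUPS.items():
        if k.replace("/", "").lower() == key.replace("/", "").lower():
            return sg
        if k.lower() == key.lower():
            return sg
    raise KeyError(
        f"space group {symbol!r} has no built-in operator table; "
        "supply explicit operators (e.g. _symmetry_equiv_pos_as_xyz)"
    )


def space_group_from_triplets(triplets, symbol="?") -> SpaceGroup:
    """Build a SpaceGroup from explicit 'x,y,z'-style operator strings.

    Centrosymmetry and polar axes are derived from the operator list:
    an axis is polar when every operator leaves that coordinate's
    rotation row equal to the identity row.
    """
    ops = tuple(SymOp.from_triplet(t) for t in triplets)
    centro = any(
        np.array_equal(np.asarray(op.rot), -np.eye(3, dtype=int)) for op in ops
    )
    polar = set()
    for ax in range(3):
        ident_row = np.eye(3, dtype=int)[ax]
        if all(np.array_equal(np.asarray(op.rot)[ax], ident_row) for op in ops):
            polar.add(ax)
    # known symbol -> reuse curated discrete shift set
    try:
        builtin = space_group_from_symbol(symbol)
        if builtin.n_operators == len(ops):
            return builtin
    except KeyError:
        pass
    return SpaceGroup(symbol=symbol, operators=ops,
                      polar_axes=frozenset(polar), centrosymmetric=centro,
                      discrete_shifts=tuple(_half_shifts([0, 1, 2])))


@dataclass
class AtomSite:
    """One asymmetric-unit atom."""

    label: str
    element: str
    frac: tuple
    occupancy: float = 1.0
    molecule_id: str = "mol1"

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside (0, 1]")
        if gemmi.Element(self.element).atomic_number == 0:
            raise ValueError(f"unknown element {self.element!r}")


@dataclass
class CrystalStructure:
    """Cell + space group + asymmetric-unit sites.

    ``z`` is formula units per cell and ``mr`` the formula mass (g/mol);
    both are only needed for density arithmetic and may be left at their
    defaults otherwise.
    """

    cell: UnitCell
    space_group: SpaceGroup
    asym_sites: list
    z: int = 0
    mr: float = 0.0

    def __post_init__(self) -> None:
        if self.z == 0:
            self.z = self.space_group.n_operators

    def frac_coords(self) -> np.ndarray:
        return np.array([s.frac for s in self.asym_sites], dtype=float).reshape(-1, 3)

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            cell=self.cell,
            space_group=self.space_group,
            asym_sites=[dataclasses.replace(s, frac=tuple(s.frac)) for s in self.asym_sites],
            z=self.z,
            mr=self.mr,
        )


def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in Å³ (general triclinic formula)."""
    return cell.volume()


def calc_density(structure: CrystalStructure) -> float:
    """Calculated crystal density ρ = Z·M_r / (N_A·V) in g·cm⁻³."""
    if structure.mr <= 0 or structure.z < 1:
        raise ValueError("density needs mr > 0 and z >= 1")
    v_cm3 = cell_volume(structure.cell) * 1e-24
    return structure.z * structure.mr / (AVOGADRO * v_cm3)


def expand_symmetry(structure: CrystalStructure, tol: float = 1e-3):
    """Apply every space-group operator to every asymmetric site.

    Returns a list of AtomSite covering one unit cell, coordinates wrapped
    to [0,1). Images that coincide within ``tol`` fractional (special
    positions) are merged.
    """
    if not structure.asym_sites:
        raise ValueError("asymmetric unit is empty")
    out = []
    for site in structure.asym_sites:
        images = []
        for op in structure.space_group.operators:
            x = op.apply(np.asarray(site.frac, float)) % 1.0
            dup = False
            for y in images:
                d = x - y
                d -= np.round(d)
                if np.max(np.abs(d)) < tol:
                    dup = True
                    break
            if not dup:
                images.append(x)
        for k, x in enumerate(images):
            out.append(
                AtomSite(
                    label=site.label if len(images) == 1 and k == 0 else f"{site.label}#{k}",
                    element=site.element,
                    frac=tuple(x),
                    occupancy=site.occupancy,
                    molecule_id=site.molecule_id,
                )
            )
    return out


def d_spacing(cell: UnitCell, hkl) -> float:
    """Interplanar spacing d(hkl) in Å from the reciprocal metric tensor."""
    h = np.asarray(hkl, dtype=float)
    if not np.any(h):
        raise ValueError("hkl must not be (0,0,0)")
    inv_d2 = float(h @ cell.reciprocal_metric @ h)
    return 1.0 / math.sqrt(inv_d2)


class ReflectionOutOfRange(ValueError):
    """Bragg condition unsatisfiable: λ/(2d) > 1."""


def two_theta(d: float, wavelength: float) -> float:
    """Bragg angle 2θ in degrees for spacing d (Å) at the given wavelength."""
    s = wavelength / (2.0 * d)
    if s > 1.0:
        raise ReflectionOutOfRange(f"λ/2d = {s:.4f} > 1 for d = {d} Å")
    return math.degrees(2.0 * math.asin(s))
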