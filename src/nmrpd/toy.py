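"""Deterministic toy molecular crystal for tests and demonstrations.

The fixture emulates the problem class of an organic salt with one cation
and one small tetrahedral anion per asymmetric unit in a polar monoclinic
group: a planar six-membered carbon ring carrying an exocyclic
C(ring)—CH₂—S—CH₃ chain (three rotatable torsions) plus a rigid BF₄⁻
anion, packed in P2₁.  Auto-detected degrees of freedom:
(3+3+3) + (3+3+0) = 15, the parameter count of the real benchmark
compounds.  Geometry is idealized (regular hexagon, ideal tetrahedron) —
the fixture is synthetic, not a deposited structure.

``make_toy_crystal`` is byte-deterministic for a given spec and returns
the structure together with the generating fragments and DOF vector,
which serve as ground truth for solver-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .crystal import CrystalStructure, SpaceGroup, UnitCell, space_group_from_symbol
from .fragments import DOFVector, FragmentModel, detect_torsions, perceive_bonds, realize_all

__all__ = ["ToyCrystalSpec", "make_toy_crystal", "toy_fragments", "GenerationError"]


class GenerationError(RuntimeError):
    """Requested placement produces intermolecular clashes."""


def _nerf(a, b, c, r, theta_deg, phi_deg):
    """Place atom at distance r from a, angle theta at a w.r.t. b, and
    dihedral phi about the b–a axis w.r.t. c (natural extension of
    reference frame)."""
    a, b, c = map(np.asarray, (a, b, c))
    th, ph = math.radians(theta_deg), math.radians(phi_deg)
    bc = a - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - c, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * math.cos(th),
                  r * math.sin(th) * math.cos(ph),
                  r * math.sin(th) * math.sin(ph)])
    return a + d[0] * bc + d[1] * m + d[2] * n


def _cation_geometry():
    """Idealized cation: C6 ring (bond 1.39 Å), CH₂–S–CH₃ chain, H atoms."""
    rad = 1.39  # hexagon circumradius equals the bond length
    labels, elements, xyz = [], [], []
    ring = []
    for k in range(6):
        ang = math.radians(60.0 * k)
        p = np.array([rad * math.cos(ang), rad * math.sin(ang), 0.0])
        ring.append(p)
        labels.append(f"C{k + 1}")
        elements.append("C")
        xyz.append(p)
    c7 = _nerf(ring[0], ring[1], ring[2], 1.50, 120.0, 180.0)
    labels.append("C7"); elements.append("C"); xyz.append(c7)
    s = _nerf(c7, ring[0], ring[1], 1.80, 109.5, 115.0)
    labels.append("S1"); elements.append("S"); xyz.append(s)
    c8 = _nerf(s, c7, ring[0], 1.80, 100.0, 180.0)
    labels.append("C8"); elements.append("C"); xyz.append(c8)
    # ring hydrogens on C2..C6 (C1 bears the chain)
    for k in range(1, 6):
        h = _nerf(ring[k], ring[(k + 1) % 6], ring[(k + 2) % 6], 1.08, 120.0, 180.0)
        labels.append(f"H{k + 1}"); elements.append("H"); xyz.append(h)
    for phi, name in ((120.0, "H71"), (-120.0, "H72")):
        h = _nerf(c7, s, c8, 1.08, 109.5, phi)
        labels.append(name); elements.append("H"); xyz.append(h)
    for phi, name in ((60.0, "H81"), (180.0, "H82"), (300.0, "H83")):
        h = _nerf(c8, s, c7, 1.08, 109.5, phi)
        labels.append(name); elements.append("H"); xyz.append(h)
    return labels, elements, np.array(xyz)


def _anion_geometry():
    """Ideal tetrahedral BF₄⁻, B—F 1.39 Å."""
    t = 1.39 / math.sqrt(3.0)
    dirs = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], float) * t
    labels = ["B1", "F1", "F2", "F3", "F4"]
    elements = ["B", "F", "F", "F", "F"]
    xyz = np.vstack([np.zeros(3), dirs])
    return labels, elements, xyz


def _build_fragment(name, labels, elements, xyz):
    xyz = xyz - xyz.mean(axis=0)
    bonds = perceive_bonds(elements, xyz)
    torsions = detect_torsions(len(labels), bonds)
    return FragmentModel(name=name, labels=labels, elements=elements,
                         coords=xyz, bonds=bonds, torsions=torsions)


def toy_fragments():
    """The two fragment models of the toy crystal (cation, anion)."""
    cat = _build_fragment("cation", *_cation_geometry())
    an = _build_fragment("anion", *_anion_geometry())
    return [cat, an]


# Default placement: chosen once (deterministic clash-free packing with the
# shortest intermolecular F···C contact in the usable 2.5-6 Å window).
_DEFAULT_PLACEMENT = DOFVector(
    translations=np.array([[0.403893, 0.386267, 0.198563],
                           [0.867210, 0.875393, 0.457685]]),
    quaternions=np.array([[0.465553, 0.612679, -0.611045, 0.185763],
                          [0.324939, 0.607382, 0.018161, 0.724688]]),
    torsions=[np.array([353.358828, 143.392586, 279.339847]), np.zeros(0)],
)


@dataclass
class ToyCrystalSpec:
    """Parameters of the toy crystal generator."""

    cell: UnitCell = field(default_factory=lambda: UnitCell(6.0, 7.5, 14.0, 90.0, 95.0, 90.0))
    space_group: SpaceGroup = field(default_factory=lambda: space_group_from_symbol("P21"))
    placement: DOFVector = field(default_factory=lambda: _DEFAULT_PLACEMENT.copy())
    min_contact: float = 2.0  # Å, clash threshold between molecules
    seed: int = 0


def _formula_mass(fragments) -> float:
    return sum(gemmi.Element(e).weight for f in fragments for e in f.elements)


def _min_intermolecular_contact(structure: CrystalStructure) -> float:
    from .solver import _image_distances  # shared periodic-distance core

    frac = structure.frac_coords()
    mols = np.array([s.molecule_id for s in structure.asym_sites])
    idx = np.arange(len(mols))
    d = _image_distances(structure.cell, structure.space_group, frac, mols,
                         idx, idx, cutoff=8.0)
    return float(d[0]) if d.size else float("inf")


def make_toy_crystal(spec: ToyCrystalSpec | None = None):
    """Build the toy CrystalStructure.

    Returns (structure, fragments, placement DOF).  Raises
    :class:`GenerationError` if the requested placement puts any two
    molecules closer than ``spec.min_contact``.
    """
    spec = spec or ToyCrystalSpec()
    fragments = toy_fragments()
    dof = spec.placement.copy()
    # normalize quaternions so hand-entered defaults are exact unit rotations
    dof.quaternions /= np.linalg.norm(dof.quaternions, axis=1, keepdims=True)
    sites = realize_all(fragments, dof, spec.cell)
    structure = CrystalStructure(
        cell=spec.cell, space_group=spec.space_group, asym_sites=sites,
        z=spec.space_group.n_operators, mr=_formula_mass(fragments),
    )
    dmin = _min_intermolecular_contact(structure)
    if dmin < spec.min_contact:
        raise GenerationError(
            f"placement produces an intermolecular contact of {dmin:.2f} Å "
            f"(< {spec.min_contact} Å); adjust the placement DOF"
        )
    return structure, fragments, dof
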