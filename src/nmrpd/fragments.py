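"""Direct-space model parameterization: rigid fragments with free torsions.

A molecule is a rigid body (3 translational + 3 rotational degrees of
freedom) plus one degree of freedom per rotatable torsion.  The DOF vector
maps onto asymmetric-unit fractional coordinates via :func:`realize`:
torsion rotations are applied first (in declared order), then the
quaternion rotation about the fragment centroid, then the centroid is
placed at the fractional translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .crystal import AtomSite, CrystalStructure, UnitCell

log = logging.getLogger(__name__)

__all__ = [
    "Torsion",
    "FragmentModel",
    "DOFVector",
    "count_dof",
    "realize",
    "realize_all",
    "randomize",
    "fragment_from_structure",
    "perceive_bonds",
]

#: covalent-radius scale factor for bond perception
BOND_TOL = 1.15


@dataclass(frozen=True)
class Torsion:
    """Rotatable bond: axis (i, j) atom indices; ``moving`` is the set of
    atom indices on the j side that the rotation carries."""

    axis: tuple
    moving: tuple


@dataclass
class FragmentModel:
    """Rigid fragment: atoms in a local cartesian frame (Å) + torsions."""

    name: str
    labels: list
    elements: list
    coords: np.ndarray  # (n, 3) local cartesian, centroid at origin
    bonds: list
    torsions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.coords) or len(self.elements) != len(self.coords):
            raise ValueError("labels/elements/coords length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_torsions(self) -> int:
        return len(self.torsions)


@dataclass
class DOFVector:
    """Per-fragment placement parameters.

    translations: (n_frag, 3) fractional; quaternions: (n_frag, 4) unit
    (w, x, y, z); torsions: list of per-fragment angle arrays in degrees
    (offsets from the stored fragment geometry).
    """

    translations: np.ndarray
    quaternions: np.ndarray
    torsions: list

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, float))
        self.quaternions = np.atleast_2d(np.asarray(self.quaternions, float))
        self.torsions = [np.asarray(t, float) for t in self.torsions]

    def flatten(self) -> np.ndarray:
        parts = []
        for i in range(len(self.translations)):
            parts.extend([self.translations[i], self.quaternions[i], self.torsions[i]])
        return np.concatenate(parts)

    @classmethod
    def unflatten(cls, vec: np.ndarray, fragments) -> "DOFVector":
        vec = np.asarray(vec, float)
        trans, quats, tors = [], [], []
        k = 0
        for frag in fragments:
            trans.append(vec[k:k + 3]); k += 3
            quats.append(vec[k:k + 4]); k += 4
            tors.append(vec[k:k + frag.n_torsions]); k += frag.n_torsions
        if k != len(vec):
            raise ValueError(f"DOF vector length {len(vec)} != expected {k}")
        return cls(np.array(trans), np.array(quats), tors)

    def copy(self) -> "DOFVector":
        return DOFVector(self.translations.copy(), self.quaternions.copy(),
                         [t.copy() for t in self.torsions])


def count_dof(fragments) -> int:
    """Scalar optimizer degrees of freedom: Σ (3 + 3 + n_torsions)."""
    if not fragments:
        raise ValueError("empty fragment list")
    return sum(6 + f.n_torsions for f in fragments)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from a (w, x, y, z) quaternion (normalized first)."""
    q = np.asarray(q, float)
    n = np.linalg.norm(q)
    if abs(n - 1.0) > 1e-9:
        log.warning("quaternion norm %.3g != 1; renormalizing", n)
        if n == 0:
            raise ValueError("zero quaternion")
    w, x, y, z = q / n
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (non-unit) axis vector."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


def realize_cartesian(fragment: FragmentModel, torsion_angles) -> np.ndarray:
    """Local coordinates with torsions applied (centroid restored to origin)."""
    xyz = fragment.coords.copy()
    for tor, ang in zip(fragment.torsions, np.atleast_1d(torsion_angles)):
        if ang == 0.0:
            continue
        i, j = tor.axis
        rot = _axis_rotation(xyz[j] - xyz[i], float(ang))
        idx = list(tor.moving)
        xyz[idx] = (xyz[idx] - xyz[i]) @ rot.T + xyz[i]
    xyz -= xyz.mean(axis=0)
    return xyz


def realize(fragment: FragmentModel, translation, quaternion, torsion_angles,
            cell: UnitCell, molecule_id: str | None = None):
    """Render one fragment to asymmetric-unit AtomSites (fractional coords)."""
    xyz = realize_cartesian(fragment, torsion_angles)
    xyz = xyz @ quat_to_matrix(quaternion).T
    frac = cell.fractionalize(xyz) + np.asarray(translation, float)
    mol = molecule_id or fragment.name
    return [
        AtomSite(label=lab, element=el, frac=tuple(f), molecule_id=mol)
        for lab, el, f in zip(fragment.labels, fragment.elements, frac)
    ]


def realize_all(fragments, dof: DOFVector, cell: UnitCell):
    """Render every fragment of a DOF vector; concatenated AtomSite list."""
    sites = []
    for i, frag in enumerate(fragments):
        sites.extend(
            realize(frag, dof.translations[i], dof.quaternions[i], dof.torsions[i], cell)
        )
    return sites


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation (Shoemake's method), returned as (w, x, y, z)."""
    u1, u2, u3 = rng.random(3)
    a, b = np.sqrt(1 - u1), np.sqrt(u1)
    return np.array([a * np.sin(2 * np.pi * u2), a * np.cos(2 * np.pi * u2),
                     b * np.sin(2 * np.pi * u3), b * np.cos(2 * np.pi * u3)])


def randomize(fragments, rng_seed) -> DOFVector:
    """Random starting model: uniform translations in [0,1)³, uniform
    orientations on the quaternion sphere, torsions uniform in [0°, 360°)."""
    rng = np.random.default_rng(rng_seed)
    trans = rng.random((len(fragments), 3))
    quats = np.array([random_quaternion(rng) for _ in fragments])
    tors = [rng.random(f.n_torsions) * 360.0 for f in fragments]
    return DOFVector(trans, quats, tors)


def perceive_bonds(elements, coords) -> list:
    """Bond list by the covalent-radius-sum × 1.15 distance heuristic."""
    coords = np.asarray(coords, float)
    radii = np.array([gemmi.Element(e).covalent_r for e in elements])
    bonds = []
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            cut = BOND_TOL * (radii[i] + radii[j])
            if np.linalg.norm(coords[i] - coords[j]) <= cut:
                bonds.append((i, j))
    return bonds


def _adjacency(n, bonds):
    adj = {i: set() for i in range(n)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _component(start, adj, blocked_edge):
    """Connected component of ``start`` with one edge removed."""
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if {u, v} == set(blocked_edge):
                continue
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def detect_torsions(n_atoms, bonds) -> list:
    """Rotatable torsions: acyclic single bonds with at least one further
    atom on each side (ring bonds and bonds to terminal atoms excluded)."""
    adj = _adjacency(n_atoms, bonds)
    torsions = []
    for i, j in sorted(tuple(sorted(b)) for b in bonds):
        if len(adj[i]) < 2 or len(adj[j]) < 2:
            continue  # terminal bond
        side_j = _component(j, adj, (i, j))
        if i in side_j:
            continue  # ring bond
        moving = tuple(sorted(side_j - {j}))
        if not moving:
            continue
        torsions.append(Torsion(axis=(i, j), moving=moving))
    return torsions


def fragment_from_structure(structure: CrystalStructure, molecule_id: str,
                            detect: bool = True):
    """Extract one molecule as a FragmentModel plus its generating DOF.

    The returned (fragment, translation, quaternion, torsion_angles) round
    trips: realizing the fragment with those parameters reproduces the
    input sites.
    """
    sites = [s for s in structure.asym_sites if s.molecule_id == molecule_id]
    if not sites:
        raise ValueError(f"no atoms with molecule_id={molecule_id!r}")
    frac = np.array([s.frac for s in sites], float)
    cart = structure.cell.orthogonalize(frac)
    centroid_frac = frac.mean(axis=0)
    local = cart - cart.mean(axis=0)
    bonds = perceive_bonds([s.element for s in sites], local)
    adj = _adjacency(len(sites), bonds)
    comp = _component(0, adj, (-1, -2))
    if len(comp) != len(sites):
        raise ValueError(
            f"molecule {molecule_id!r}: bond graph disconnected "
            f"({len(comp)}/{len(sites)} atoms reachable)"
        )
    torsions = detect_torsions(len(sites), bonds) if detect else []
    frag = FragmentModel(
        name=molecule_id,
        labels=[s.label for s in sites],
        elements=[s.element for s in sites],
        coords=local,
        bonds=bonds,
        torsions=torsions,
    )
    translation = centroid_frac
    quaternion = np.array([1.0, 0.0, 0.0, 0.0])
    torsion_angles = np.zeros(len(torsions))
    return frag, translation, quaternion, torsion_angles
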