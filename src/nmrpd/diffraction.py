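"""Kinematic powder-pattern simulation.

Reflections are enumerated up to a 2θ limit, merged under the Laue group
derived from the space-group operators, screened for systematic absences,
and given |F|² from IT92 Cromer–Mann form factors.  The pattern is the sum
of multiplicity × Lorentz-polarization × |F|² peaks convolved with a
constant-FWHM pseudo-Voigt profile — the same idealization used both for
fabricating degraded "observed" data and for the model response inside the
cost function.

Conventions (applied identically to observed and calculated patterns):
Cu Kα1 λ = 1.540598 Å, no Kα2, global isotropic B = 3 Å², no background,
no preferred orientation, profile truncated at ±6 FWHM, pattern normalized
to a maximum of 10⁴ counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .crystal import CrystalStructure, UnitCell, expand_symmetry, two_theta

log = logging.getLogger(__name__)

CU_KA1 = 1.540598  # Å
DEFAULT_B_ISO = 3.0  # Å², global isotropic displacement
PATTERN_MAX = 1.0e4  # counts after normalization
PROFILE_TRUNCATION = 6.0  # ± this many FWHM

__all__ = [
    "Reflection",
    "PowderPattern",
    "ProfileConfig",
    "GridSpec",
    "generate_reflections",
    "structure_factor",
    "structure_factors",
    "simulate_pattern",
    "profile_matrix",
    "lorentz_polarization",
    "CU_KA1",
]


@dataclass(frozen=True)
class Reflection:
    hkl: tuple
    d: float
    two_theta: float
    multiplicity: int
    f2: float = 0.0


@dataclass
class GridSpec:
    """Uniform 2θ grid; defaults follow the simulated-data protocol
    (4–50° 2θ, 0.01° step)."""

    start: float = 4.0
    stop: float = 50.0
    step: float = 0.01

    def grid(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


@dataclass
class ProfileConfig:
    fwhm: float = 0.5  # degrees 2θ
    eta: float = 0.5  # pseudo-Voigt mixing; 0 = Gaussian, 1 = Lorentzian
    lp_correction: bool = True

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")


@dataclass
class PowderPattern:
    two_theta: np.ndarray
    intensity: np.ndarray
    wavelength: float = CU_KA1
    fwhm: float | None = None

    def __post_init__(self) -> None:
        self.two_theta = np.asarray(self.two_theta, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.two_theta.shape != self.intensity.shape:
            raise ValueError("grid/intensity length mismatch")
        steps = np.diff(self.two_theta)
        if len(steps) and (np.any(steps <= 0) or np.ptp(steps) > 1e-6):
            raise ValueError("2θ grid must be strictly increasing and uniform")

    @property
    def step(self) -> float:
        return float(self.two_theta[1] - self.two_theta[0])


def _laue_rotations(space_group) -> np.ndarray:
    """Unique rotation parts ± inversion: the Laue group acting on hkl."""
    rots = {tuple(np.asarray(op.rot).ravel()) for op in space_group.operators}
    rots |= {tuple((-np.asarray(r).reshape(3, 3)).ravel()) for r in [np.array(r).reshape(3, 3) for r in rots]}
    return np.array([np.array(r).reshape(3, 3) for r in sorted(rots)])


def _is_absent(hkl: np.ndarray, space_group) -> bool:
    """General systematic-absence test: h·R = h with non-integer h·t."""
    for op in space_group.operators:
        rot = np.asarray(op.rot)
        if np.array_equal(hkl @ rot, hkl):
            phase = float(hkl @ np.asarray(op.tran))
            if abs(phase - round(phase)) > 1e-9:
                return True
    return False


def generate_reflections(structure: CrystalStructure, wavelength: float = CU_KA1,
                         two_theta_max: float = 50.0, two_theta_min: float = 0.0):
    """Unique, present reflections with 2θ in range, with multiplicities.

    Merging uses the Laue symmetry implied by the operator list (Friedel
    pairs always merged); the canonical representative of each orbit is
    its lexicographically largest member.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    cell = structure.cell
    d_min = wavelength / (2.0 * np.sin(np.radians(two_theta_max / 2.0)))
    gstar = cell.reciprocal_metric
    # conservative index bounds: |h_i| <= a_i* axis length / d_min
    bounds = [int(np.floor(1.0 / (d_min * np.sqrt(gstar[i, i])))) + 1 for i in range(3)]
    laue = _laue_rotations(structure.space_group)
    seen = set()
    out = []
    hs = np.array([
        (h, k, l)
        for h in range(-bounds[0], bounds[0] + 1)
        for k in range(-bounds[1], bounds[1] + 1)
        for l in range(-bounds[2], bounds[2] + 1)
        if (h, k, l) != (0, 0, 0)
    ])
    inv_d2 = np.einsum("ni,ij,nj->n", hs, gstar, hs)
    keep = inv_d2 <= 1.0 / d_min**2
    for hkl, inv in zip(hs[keep], inv_d2[keep]):
        key = tuple(hkl)
        if key in seen:
            continue
        orbit = {tuple(hkl @ rot) for rot in laue}
        seen |= orbit
        d = 1.0 / np.sqrt(inv)
        tt = two_theta(d, wavelength)
        if tt > two_theta_max or tt < two_theta_min:
            continue
        h_np = np.asarray(hkl)
        if _is_absent(h_np, structure.space_group):
            continue
        rep = max(orbit)
        out.append(Reflection(hkl=rep, d=float(d), two_theta=float(tt),
                              multiplicity=len(orbit)))
    out.sort(key=lambda r: r.two_theta)
    return out


class MissingScatteringFactor(KeyError):
    pass


def _form_factor(element: str, stol2: np.ndarray) -> np.ndarray:
    """IT92 4-term Cromer–Mann X-ray form factor at (sinθ/λ)² values."""
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise MissingScatteringFactor(element)
    it92 = el.it92
    return np.array([it92.calculate_sf(float(s)) for s in np.atleast_1d(stol2)])


def structure_factors(reflections, sites, cell: UnitCell,
                      b_iso: float = DEFAULT_B_ISO) -> np.ndarray:
    """|F(hkl)|² for each reflection from a full-cell site list.

    F = Σ_j occ_j f_j(sinθ/λ) exp(−B sin²θ/λ²) exp(2πi h·x_j).
    """
    if not reflections:
        return np.zeros(0)
    hkls = np.array([r.hkl for r in reflections], float)
    stol = np.array([1.0 / (2.0 * r.d) for r in reflections])
    stol2 = stol**2
    frac = np.array([s.frac for s in sites], float)
    occ = np.array([s.occupancy for s in sites])
    elements = [s.element for s in sites]
    debye = np.exp(-b_iso * stol2)
    f_by_elem = {e: _form_factor(e, stol2) for e in set(elements)}
    fvals = np.array([f_by_elem[e] for e in elements])  # (n_sites, n_refl)
    phase = np.exp(2j * np.pi * (hkls @ frac.T))  # (n_refl, n_sites)
    f_complex = (phase * (occ[:, None] * fvals).T).sum(axis=1) * debye
    return np.abs(f_complex) ** 2


def structure_factor(reflection: Reflection, sites, cell: UnitCell,
                     b_iso: float = DEFAULT_B_ISO) -> float:
    """|F|² of a single reflection (see :func:`structure_factors`)."""
    return float(structure_factors([reflection], sites, cell, b_iso)[0])


def lorentz_polarization(two_theta_deg: np.ndarray) -> np.ndarray:
    """LP(θ) = (1 + cos²2θ) / (sin²θ · cosθ) for unpolarized radiation."""
    tt = np.radians(np.asarray(two_theta_deg, float))
    th = tt / 2.0
    return (1.0 + np.cos(tt) ** 2) / (np.sin(th) ** 2 * np.cos(th))


def _pseudo_voigt(x: np.ndarray, fwhm: float, eta: float) -> np.ndarray:
    """Unit-area pseudo-Voigt profile on offsets x (degrees)."""
    hwhm = fwhm / 2.0
    gauss = np.exp(-np.log(2.0) * (x / hwhm) ** 2) * np.sqrt(np.log(2.0) / np.pi) / hwhm
    lorentz = (hwhm / np.pi) / (x**2 + hwhm**2)
    return eta * lorentz + (1.0 - eta) * gauss


def profile_matrix(grid: np.ndarray, positions: np.ndarray,
                   profile: ProfileConfig):
    """Sparse (n_grid × n_refl) matrix of truncated unit-area peak shapes.

    The pattern for any intensity vector I is then ``M @ I`` — peak
    positions depend only on the (fixed) cell, so the matrix is
    precomputed once per solve.
    """
    from scipy.sparse import csc_matrix

    step = grid[1] - grid[0]
    half = PROFILE_TRUNCATION * profile.fwhm
    rows, cols, vals = [], [], []
    for j, pos in enumerate(positions):
        lo = int(np.ceil((pos - half - grid[0]) / step))
        hi = int(np.floor((pos + half - grid[0]) / step))
        lo, hi = max(lo, 0), min(hi, len(grid) - 1)
        if hi < lo:
            continue
        idx = np.arange(lo, hi + 1)
        rows.append(idx)
        cols.append(np.full(len(idx), j))
        vals.append(_pseudo_voigt(grid[idx] - pos, profile.fwhm, profile.eta))
    if not rows:
        return csc_matrix((len(grid), len(positions)))
    return csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(grid), len(positions)),
    )


def peak_intensities(reflections, profile: ProfileConfig) -> np.ndarray:
    """m · LP · |F|² per reflection (the integrated peak intensities)."""
    if not reflections:
        return np.zeros(0)
    mult = np.array([r.multiplicity for r in reflections], float)
    f2 = np.array([r.f2 for r in reflections])
    if profile.lp_correction:
        lp = lorentz_polarization(np.array([r.two_theta for r in reflections]))
    else:
        lp = 1.0
    return mult * lp * f2


def simulate_pattern(structure: CrystalStructure, profile: ProfileConfig | None = None,
                     grid_spec: GridSpec | None = None, wavelength: float = CU_KA1,
                     b_iso: float = DEFAULT_B_ISO, normalize: bool = True) -> PowderPattern:
    """Simulate the powder pattern of a structure on a uniform 2θ grid."""
    profile = profile or ProfileConfig()
    grid_spec = grid_spec or GridSpec()
    grid = grid_spec.grid()
    # generate slightly beyond the window so truncated tails enter it
    margin = PROFILE_TRUNCATION * profile.fwhm
    reflections = generate_reflections(
        structure, wavelength,
        two_theta_max=grid_spec.stop + margin,
        two_theta_min=max(grid_spec.start - margin, 0.5),
    )
    if not reflections:
        warnings.warn("no reflections in range; returning an all-zero pattern")
        return PowderPattern(grid, np.zeros_like(grid), wavelength, profile.fwhm)
    cell_sites = expand_symmetry(structure)
    f2 = structure_factors(reflections, cell_sites, structure.cell, b_iso)
    reflections = [
        Reflection(r.hkl, r.d, r.two_theta, r.multiplicity, float(v))
        for r, v in zip(reflections, f2)
    ]
    m = profile_matrix(grid, np.array([r.two_theta for r in reflections]), profile)
    y = m @ peak_intensities(reflections, profile)
    if normalize and y.max() > 0:
        y = y * (PATTERN_MAX / y.max())
    return PowderPattern(grid, y, wavelength, profile.fwhm)
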