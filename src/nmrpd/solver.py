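"""Composite cost function and parallel-tempering structure solver.

The cost of a trial structure is

    CF = s1·χ²_profile + s2·χ²_restraint + s3·χ²_antibump + s4·χ²_imd

where χ²_imd penalizes deviations of model intermolecular distances from
ssNMR-derived targets beyond a penalty-free half-width δ:

    χ²_imd = Σ_i [ max(0, |d_i − d_i0| − δ_i) / σ_i ]²

with d_i the n-th nearest periodic/symmetry-aware contact between the
restraint's atom selections.  s4 = 0 reduces the engine to a "normal run"
driven by the diffraction profile alone.  χ²_restraint (flexible internal
geometry) is identically zero for rigid-body + torsion models; its slot is
kept for parity with the full cost-function definition, as is the
bond-valence term (weight fixed at zero, no slot).

The global optimizer is parallel tempering: a ladder of Metropolis walkers
at geometrically spaced temperatures with periodic replica exchange; a
"trial" is one cost evaluation, counted across all replicas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

import gemmi

from .crystal import CrystalStructure, SpaceGroup, UnitCell
from .diffraction import (
    DEFAULT_B_ISO,
    GridSpec,
    PowderPattern,
    ProfileConfig,
    generate_reflections,
    lorentz_polarization,
    profile_matrix,
)
from .fragments import DOFVector, randomize, realize_all

log = logging.getLogger(__name__)

__all__ = [
    "CostWeights",
    "CostBreakdown",
    "OptimizerConfig",
    "RunResult",
    "CostContext",
    "nth_intermolecular_distance",
    "chi2_imd",
    "chi2_profile",
    "antibump",
    "solve",
]

#: anti-bump threshold factor on the van-der-Waals radius sum
ANTIBUMP_VDW_FACTOR = 0.7
DEFAULT_DISTANCE_CUTOFF = 10.0  # Å


@dataclass(frozen=True)
class CostWeights:
    """Scale factors s1..s4 of the cost-function terms."""

    s1: float = 1.0  # profile fit
    s2: float = 0.0  # geometric restraints (zero for rigid models)
    s3: float = 100.0  # anti-bump
    s4: float = 0.0  # intermolecular-distance (ssNMR) term

    def __post_init__(self) -> None:
        if min(self.s1, self.s2, self.s3, self.s4) < 0:
            raise ValueError("cost weights must be non-negative")


@dataclass(frozen=True)
class CostBreakdown:
    chi2_profile: float
    chi2_restraint: float
    chi2_antibump: float
    chi2_imd: float
    total: float


@dataclass
class OptimizerConfig:
    n_runs: int = 20
    n_trials: int = 20000
    n_replicas: int = 8
    t_min: float | None = None  # None -> auto-scaled from the initial cost
    t_max: float | None = None
    swap_interval: int = 100
    seed: int = 0
    amp_translation: float = 0.05  # fractional, coldest replica
    amp_rotation: float = 10.0  # degrees
    amp_torsion: float = 20.0  # degrees
    whole_fragment_prob: float = 0.2
    flip_prob: float = 0.1  # discrete 180° principal-axis flip moves
    quench_fraction: float = 0.4  # share of each run spent on basin hopping
    n_sessions: int = 2  # alternating tempering/basin-hopping blocks
    reseed_interval: int = 150  # sweeps between fresh-model injections

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.n_runs < 1 or self.n_replicas < 1:
            raise ValueError("counts must be positive")
        if self.t_min is not None and self.t_max is not None and not self.t_min < self.t_max:
            raise ValueError("t_min must be < t_max")


@dataclass
class RunResult:
    run_index: int
    seed: int
    best_dof: DOFVector
    best_cost: CostBreakdown
    best_trial: int


# ---------------------------------------------------------------------------
# intermolecular distances


def _match_selection(sites, selection: str) -> np.ndarray:
    """Indices of sites matching a selector: exact label first, else element."""
    labels = np.array([s.label for s in sites])
    idx = np.nonzero(labels == selection)[0]
    if idx.size:
        return idx
    elements = np.array([s.element for s in sites])
    idx = np.nonzero(elements == selection)[0]
    if idx.size:
        return idx
    raise ValueError(f"selector {selection!r} matches no atom")


def _translation_range(cell: UnitCell, cutoff: float) -> list:
    """Lattice translations needed to cover a distance cutoff (relative to
    the nearest image; +1 guards against cell obliquity)."""
    gstar = cell.reciprocal_metric
    return [int(np.ceil(cutoff * np.sqrt(gstar[i, i]))) + 1 for i in range(3)]


def _image_distances(cell, sg, frac, mols, idx_a, idx_b, cutoff):
    """Sorted distances from central idx_a atoms to all periodic/symmetry
    images of idx_b atoms, intramolecular (same molecule image) excluded.

    Each pair difference is recentred to its nearest lattice image before
    the shift enumeration, so coordinates need not be wrapped.
    """
    orth = cell.orthogonalization_matrix
    na, nb, nc = _translation_range(cell, cutoff)
    shifts = np.array([
        (i, j, k)
        for i in range(-na, na + 1)
        for j in range(-nb, nb + 1)
        for k in range(-nc, nc + 1)
    ], float)
    xa = frac[idx_a]  # (A, 3)
    dists = []
    for oi, op in enumerate(sg.operators):
        xb = op.apply(frac[idx_b])  # (B, 3)
        delta0 = xa[:, None, :] - xb[None, :, :]  # (A, B, 3)
        base = np.round(delta0)
        # (A, B, S, 3) fractional separation over nearest-image neighbourhood
        delta = (delta0 - base)[:, :, None, :] - shifts[None, None, :, :]
        cart = delta @ orth.T
        d = np.sqrt((cart**2).sum(axis=-1))  # (A, B, S)
        if oi == 0:
            same_mol = (mols[idx_a][:, None] == mols[idx_b][None, :])
            total_zero = np.all(
                base[:, :, None, :] + shifts[None, None, :, :] == 0, axis=-1)
            d = np.where(same_mol[:, :, None] & total_zero, np.inf, d)
        dists.append(d.ravel())
    d = np.concatenate(dists)
    d = d[d <= cutoff]
    d.sort()
    return d


def nth_intermolecular_distance(structure: CrystalStructure, sel_a: str, sel_b: str,
                                rank: int = 1,
                                cutoff: float = DEFAULT_DISTANCE_CUTOFF) -> float:
    """The rank-th smallest intermolecular distance between two selections.

    Distances run from selection-A atoms in the central asymmetric unit to
    selection-B atoms in every symmetry/lattice image, pairs within the
    same molecule image excluded, deduplicated within 10⁻⁶ Å.  If fewer
    than ``rank`` contacts exist inside ``cutoff`` the cutoff value is
    returned (saturating) and the event logged.
    """
    sites = structure.asym_sites
    frac = structure.frac_coords()
    mols = np.array([s.molecule_id for s in sites])
    idx_a = _match_selection(sites, sel_a)
    idx_b = _match_selection(sites, sel_b)
    d = _image_distances(structure.cell, structure.space_group, frac, mols,
                         idx_a, idx_b, cutoff)
    if d.size:
        uniq = [d[0]]
        for x in d[1:]:
            if x - uniq[-1] > 1e-6:
                uniq.append(x)
        if rank <= len(uniq):
            return float(uniq[rank - 1])
    log.info("rank-%d %s..%s contact beyond %.1f Å cutoff; saturating",
             rank, sel_a, sel_b, cutoff)
    return float(cutoff)


# ---------------------------------------------------------------------------
# cost terms


def chi2_imd(distances, restraints) -> float:
    """χ²_imd = Σ [max(0, |d − d0| − δ)/σ]² over the restraint table."""
    total = 0.0
    for d, r in zip(distances, restraints, strict=True):
        excess = abs(d - r.d0) - r.delta
        if excess > 0:
            total += (excess / r.sigma) ** 2
    return total


def chi2_profile(observed: PowderPattern, calculated: PowderPattern) -> float:
    """Weighted profile disagreement with closed-form optimal scale.

    χ² = Σ w_i (y_obs,i − s·y_calc,i)² with w_i = 1/max(y_obs,i, 1) and s
    the closed-form optimal scale, so the statistic is invariant to the
    normalization of either pattern.
    """
    if observed.two_theta.shape != calculated.two_theta.shape or \
            not np.allclose(observed.two_theta, calculated.two_theta, atol=1e-9):
        raise ValueError("observed and calculated patterns use different grids")
    return _chi2_profile_arrays(observed.intensity, calculated.intensity,
                                _profile_weights(observed.intensity))


def _profile_weights(y_obs: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(y_obs, 1.0)


def _chi2_profile_arrays(y_obs, y_calc, w) -> float:
    denom = float(np.sum(w * y_calc * y_calc))
    s = float(np.sum(w * y_obs * y_calc)) / denom if denom > 0 else 0.0
    r = y_obs - s * y_calc
    return float(np.sum(w * r * r))


def _vdw_radii(elements) -> np.ndarray:
    return np.array([gemmi.Element(e).vdw_r for e in elements])


def antibump(sites, cell: UnitCell, sg: SpaceGroup,
             vdw_factor: float = ANTIBUMP_VDW_FACTOR,
             include_h: bool = False) -> float:
    """Quadratic short-contact penalty between molecules.

    For every intermolecular pair closer than r_min = vdw_factor × (sum of
    van der Waals radii): ((r_min − d)/r_min)².  Pairs are enumerated as
    (central asymmetric atom, symmetry/lattice image), so each contact is
    counted from both ends; the factor is absorbed by the s3 scale.
    """
    elems = [s.element for s in sites]
    keep = np.array([include_h or e != "H" for e in elems])
    if not keep.any():
        return 0.0
    frac = np.array([s.frac for s in sites], float)[keep]
    mols = np.array([s.molecule_id for s in sites])[keep]
    radii = _vdw_radii([e for e, k in zip(elems, keep) if k])
    return _antibump_arrays(frac, mols, radii, cell, sg, vdw_factor)


_NEIGHBOR_SHIFTS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], float
)


def _antibump_arrays(frac, mols, radii, cell, sg, vdw_factor) -> float:
    orth = cell.orthogonalization_matrix
    rmin = vdw_factor * (radii[:, None] + radii[None, :])  # (n, n)
    total = 0.0
    for oi, op in enumerate(sg.operators):
        xb = op.apply(frac)
        delta = frac[:, None, :] - xb[None, :, :]
        base = np.round(delta)
        # (n, n, 27, 3): nearest cell and its neighbours
        d4 = delta[:, :, None, :] - (base[:, :, None, :] + _NEIGHBOR_SHIFTS)
        cart = d4 @ orth.T
        d = np.sqrt((cart**2).sum(axis=-1))
        if oi == 0:
            same = mols[:, None] == mols[None, :]
            zero = np.all(base[:, :, None, :] + _NEIGHBOR_SHIFTS == 0, axis=-1)
            d = np.where(same[:, :, None] & zero, np.inf, d)
        close = d < rmin[:, :, None]
        if close.any():
            dd = d[close]
            rr = np.broadcast_to(rmin[:, :, None], d.shape)[close]
            total += float(np.sum(((rr - dd) / rr) ** 2))
    return total


# ---------------------------------------------------------------------------
# evaluation context (precomputes everything the per-trial loop needs)


class CostContext:
    """Precomputed machinery for evaluating CF(dof) on a fixed cell.

    The cell and space group never change during a solve, so reflection
    geometry (positions, multiplicities, LP) and the sparse peak-profile
    matrix are computed once; each trial only recomputes |F|², the profile
    matvec, restraint distances and the anti-bump sum.
    """

    def __init__(self, observed: PowderPattern, fragments, cell: UnitCell,
                 space_group: SpaceGroup, restraints=(),
                 weights: CostWeights | None = None,
                 profile: ProfileConfig | None = None,
                 b_iso: float = DEFAULT_B_ISO,
                 distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF):
        self.observed = observed
        self.fragments = list(fragments)
        self.cell = cell
        self.space_group = space_group
        self.restraints = list(restraints)
        self.weights = weights or CostWeights()
        self.b_iso = b_iso
        self.distance_cutoff = distance_cutoff
        if profile is None:
            fwhm = observed.fwhm if observed.fwhm else 0.5
            profile = ProfileConfig(fwhm=fwhm)
        self.profile = profile

        grid = observed.two_theta
        step = float(grid[1] - grid[0])
        spec = GridSpec(float(grid[0]), float(grid[-1]), step)
        probe = CrystalStructure(cell=cell, space_group=space_group, asym_sites=[])
        margin = 6.0 * profile.fwhm
        self.reflections = generate_reflections(
            probe, observed.wavelength,
            two_theta_max=spec.stop + margin,
            two_theta_min=max(spec.start - margin, 0.5),
        )
        positions = np.array([r.two_theta for r in self.reflections])
        self._pm = profile_matrix(grid, positions, profile)
        mult = np.array([r.multiplicity for r in self.reflections], float)
        lp = lorentz_polarization(positions) if profile.lp_correction else 1.0
        self._mlp = mult * lp
        self._w = _profile_weights(observed.intensity)
        self._y_obs = observed.intensity

        # flattened atom bookkeeping
        self._labels, self._elements, self._mols = [], [], []
        for frag in self.fragments:
            self._labels += list(frag.labels)
            self._elements += list(frag.elements)
            self._mols += [frag.name] * frag.n_atoms
        self._mols = np.array(self._mols)
        self._heavy = np.array([e != "H" for e in self._elements])
        self._vdw = _vdw_radii([e for e in self._elements])[self._heavy]

        # per-element form factors × Debye-Waller on the reflection list
        stol2 = np.array([1.0 / (4.0 * r.d * r.d) for r in self.reflections])
        debye = np.exp(-b_iso * stol2)
        uniq = sorted(set(self._elements))
        f_elem = {
            e: np.array([gemmi.Element(e).it92.calculate_sf(float(s)) for s in stol2]) * debye
            for e in uniq
        }
        self._f_atoms = np.array([f_elem[e] for e in self._elements])  # (n_at, n_refl)
        self._hkls = np.array([r.hkl for r in self.reflections], float)
        self._ops_rot = np.array([op.rot for op in space_group.operators], float)
        self._ops_tran = np.array([op.tran for op in space_group.operators], float)

        # restraint selections resolved against the flattened site list
        class _Stub:
            def __init__(self, label, element):
                self.label, self.element = label, element

        stubs = [_Stub(l, e) for l, e in zip(self._labels, self._elements)]
        self._restraint_idx = [
            (_match_selection(stubs, r.selection_a), _match_selection(stubs, r.selection_b))
            for r in self.restraints
        ]
        # precomputed periodic-image machinery for the per-trial loop
        na, nb, nc = _translation_range(cell, distance_cutoff)
        self._dist_shifts = np.array([
            (i, j, k)
            for i in range(-na, na + 1)
            for j in range(-nb, nb + 1)
            for k in range(-nc, nc + 1)
        ], float)
        self._orth = cell.orthogonalization_matrix
        self._same_mol = [
            self._mols[ia][:, None] == self._mols[ib][None, :]
            for ia, ib in self._restraint_idx
        ]
        self._fractionalization = cell.fractionalization_matrix
        mol_codes = {m: i for i, m in enumerate(dict.fromkeys(self._mols))}
        self._mol_int = np.array([mol_codes[m] for m in self._mols], np.int64)

    # -- evaluation -------------------------------------------------------

    def _asym_frac(self, dof: DOFVector) -> np.ndarray:
        from .fragments import quat_to_matrix, realize_cartesian

        out = []
        for i, frag in enumerate(self.fragments):
            xyz = realize_cartesian(frag, dof.torsions[i])
            xyz = xyz @ quat_to_matrix(dof.quaternions[i]).T
            out.append(xyz @ self._fractionalization.T + dof.translations[i])
        return np.vstack(out)

    def _pattern_chi2(self, frac: np.ndarray) -> float:
        # full-cell coordinates: apply every operator (no special-position
        # handling; solver models occupy general positions)
        cellfrac = np.einsum("oij,nj->noi", self._ops_rot, frac) + self._ops_tran[None, :, :]
        phase = np.exp(2j * np.pi * (self._hkls @ cellfrac.reshape(-1, 3).T))
        # (n_refl, n_at, n_ops) -> sum ops, weight by per-atom f
        n_at = frac.shape[0]
        phase = phase.reshape(len(self._hkls), n_at, -1).sum(axis=2)
        f = (phase * self._f_atoms.T).sum(axis=1)
        f2 = np.abs(f) ** 2
        y_calc = self._pm @ (self._mlp * f2)
        return _chi2_profile_arrays(self._y_obs, y_calc, self._w)

    def _distances(self, frac: np.ndarray):
        from ._kernels import image_distance_list

        out = []
        for r, (ia, ib), same in zip(self.restraints, self._restraint_idx,
                                     self._same_mol):
            d = image_distance_list(
                np.ascontiguousarray(frac[ia]), np.ascontiguousarray(frac[ib]),
                same, self._ops_rot, self._ops_tran, self._orth,
                self._dist_shifts, self.distance_cutoff)
            d.sort()
            if d.size:
                uniq = d[np.concatenate([[True], np.diff(d) > 1e-6])]
                out.append(float(uniq[r.rank - 1]) if r.rank <= len(uniq)
                           else self.distance_cutoff)
            else:
                out.append(self.distance_cutoff)
        return out

    def evaluate(self, dof: DOFVector) -> CostBreakdown:
        from ._kernels import antibump_sum

        frac = self._asym_frac(dof)
        w = self.weights
        c_prof = self._pattern_chi2(frac) if w.s1 > 0 else 0.0
        c_ab = antibump_sum(np.ascontiguousarray(frac[self._heavy]),
                            self._mol_int[self._heavy], self._vdw,
                            self._ops_rot, self._ops_tran, self._orth,
                            ANTIBUMP_VDW_FACTOR) if w.s3 > 0 else 0.0
        c_imd = chi2_imd(self._distances(frac), self.restraints) \
            if (w.s4 > 0 and self.restraints) else 0.0
        c_rest = 0.0  # rigid fragments: internal geometry never deviates
        total = w.s1 * c_prof + w.s2 * c_rest + w.s3 * c_ab + w.s4 * c_imd
        return CostBreakdown(c_prof, c_rest, c_ab, c_imd, total)

    def structure(self, dof: DOFVector) -> CrystalStructure:
        """Render a DOF vector to a CrystalStructure (for export/scoring)."""
        sites = realize_all(self.fragments, dof, self.cell)
        return CrystalStructure(cell=self.cell, space_group=self.space_group,
                                asym_sites=sites)


# ---------------------------------------------------------------------------
# parallel tempering


def _apply_rotation(new: DOFVector, fi: int, frag, rng, amp_r, fractionalization):
    """Rotate fragment fi by a random small rotation about either its
    centroid or a randomly chosen pivot atom (pivot kept fixed, so e.g. a
    ring can reorient around an already-placed anchor atom)."""
    from .fragments import quat_to_matrix, realize_cartesian

    q_old = new.quaternions[fi]
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    half = np.radians(rng.normal(0.0, amp_r)) / 2.0
    dq = np.concatenate([[np.cos(half)], np.sin(half) * axis])
    new.quaternions[fi] = _quat_mul(dq, q_old)
    if rng.random() < 0.5 and frag.n_atoms > 1:
        a = rng.integers(frag.n_atoms)
        xyz = realize_cartesian(frag, new.torsions[fi])
        v = quat_to_matrix(q_old) @ xyz[a]
        new.translations[fi] += fractionalization @ (v - quat_to_matrix(dq) @ v)


def _apply_flip(new: DOFVector, fi: int, frag, rng, fractionalization):
    """Rotate fragment fi by 180° about one of its principal inertia axes
    or a random bond direction, pivoting on a random atom.  Escapes the
    near-degenerate false minima that quasi-symmetric fragments (rings,
    tetrahedra) produce."""
    from .fragments import quat_to_matrix, realize_cartesian

    q_old = new.quaternions[fi]
    xyz = realize_cartesian(frag, new.torsions[fi]) @ quat_to_matrix(q_old).T
    if frag.bonds and rng.random() < 0.5:
        i, j = frag.bonds[rng.integers(len(frag.bonds))]
        axis = xyz[j] - xyz[i]
        axis = axis / np.linalg.norm(axis)
    else:
        inertia = xyz.T @ xyz
        _, vecs = np.linalg.eigh(inertia)
        axis = vecs[:, rng.integers(3)]
    dq = np.concatenate([[0.0], axis])  # 180° rotation about axis
    new.quaternions[fi] = _quat_mul(dq, q_old)
    a = rng.integers(frag.n_atoms)
    v = xyz[a]
    new.translations[fi] += fractionalization @ (v - quat_to_matrix(dq) @ v)


def _propose(dof: DOFVector, fragments, rng, amp_t, amp_r, amp_tor,
             whole_prob, fractionalization, flip_prob=0.0) -> DOFVector:
    new = dof.copy()
    fi = rng.integers(len(fragments))
    frag = fragments[fi]
    # multi-scale moves: log-uniform amplitude factor spanning one decade,
    # so a single ladder covers both coarse placement and fine settling
    f = 10.0 ** rng.uniform(-1.0, 0.3)
    amp_t, amp_r, amp_tor = f * amp_t, f * amp_r, f * amp_tor
    u = rng.random()
    if u < flip_prob:
        _apply_flip(new, fi, frag, rng, fractionalization)
    elif u < flip_prob + whole_prob:
        new.translations[fi] += rng.normal(0.0, amp_t, 3)
        _apply_rotation(new, fi, frag, rng, amp_r, fractionalization)
    else:
        n_slots = 3 + 1 + frag.n_torsions  # 3 trans, 1 rotation, torsions
        slot = rng.integers(n_slots)
        if slot < 3:
            new.translations[fi, slot] += rng.normal(0.0, amp_t)
        elif slot == 3:
            _apply_rotation(new, fi, frag, rng, amp_r, fractionalization)
        else:
            jump = 180.0 if rng.random() < 0.3 else 0.0  # cross-barrier flips
            new.torsions[fi][slot - 4] += jump + rng.normal(0.0, amp_tor)
    new.translations[fi] %= 1.0
    return new


def _quat_mul(a, b):
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    out = np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])
    return out / np.linalg.norm(out)


def _single_run(context: CostContext, config: OptimizerConfig, run_index: int,
                seed: int) -> RunResult:
    rng = np.random.default_rng(seed)
    frags = context.fragments
    fmat = context.cell.fractionalization_matrix
    start = randomize(frags, rng_seed=rng.integers(2**31))
    c0 = context.evaluate(start)
    t_max = config.t_max if config.t_max is not None else 0.05 * max(c0.total, 1e-6)
    t_min = config.t_min if config.t_min is not None else 1e-4 * max(c0.total, 1e-6)
    nr = config.n_replicas
    temps = np.geomspace(t_min, t_max, nr)
    states = [start.copy() for _ in range(nr)]
    costs = [c0] * nr
    best_dof, best_cost, best_trial = start.copy(), c0, 0
    scale = np.sqrt(temps / temps[0])

    trial = 0

    def pt_segment(budget):
        # standard parallel tempering on the replica ladder; the hottest
        # replica is periodically reseeded with a fresh random model so a
        # steady stream of new basins feeds the ladder
        nonlocal best_dof, best_cost, best_trial, trial
        for _ in range(budget):
            trial += 1
            if config.reseed_interval and trial % (config.reseed_interval * nr) == 0:
                fresh = randomize(frags, rng_seed=int(rng.integers(2**31)))
                states[nr - 1] = fresh
                costs[nr - 1] = context.evaluate(fresh)
                continue  # the reseed evaluation consumes this trial
            k = (trial - 1) % nr
            cand = _propose(states[k], frags, rng,
                            config.amp_translation * scale[k],
                            config.amp_rotation * scale[k],
                            config.amp_torsion * scale[k],
                            config.whole_fragment_prob, fmat,
                            flip_prob=config.flip_prob)
            c = context.evaluate(cand)
            dc = c.total - costs[k].total
            if dc <= 0 or rng.random() < np.exp(-dc / temps[k]):
                states[k], costs[k] = cand, c
                if c.total < best_cost.total:
                    best_dof, best_cost, best_trial = cand.copy(), c, trial
            if trial % config.swap_interval == 0:
                for k2 in range(nr - 1):
                    d = (1.0 / temps[k2] - 1.0 / temps[k2 + 1]) * \
                        (costs[k2].total - costs[k2 + 1].total)
                    if d >= 0 or rng.random() < np.exp(d):
                        states[k2], states[k2 + 1] = states[k2 + 1], states[k2]
                        costs[k2], costs[k2 + 1] = costs[k2 + 1], costs[k2]

    def relax(state, cost, budget):
        # two-stage greedy settle: coarse then fine move amplitudes
        nonlocal best_dof, best_cost, best_trial, trial
        for q in range(budget):
            trial += 1
            amp = 0.02 if q < budget // 2 else 0.006
            cand = _propose(state, frags, rng, amp, 300.0 * amp, 600.0 * amp,
                            config.whole_fragment_prob, fmat)
            c = context.evaluate(cand)
            if c.total < cost.total:
                state, cost = cand, c
                if c.total < best_cost.total:
                    best_dof, best_cost, best_trial = cand.copy(), c, trial
        return state, cost

    def bh_session(budget, n_relax=400):
        # basin hopping from the best state: greedy relaxation interleaved
        # with discrete jumps (180° torsion flips, fragment flips) that
        # cross the pseudo-symmetry barriers of quasi-symmetric fragments
        nonlocal best_dof, best_cost, best_trial, trial
        state, cost = relax(best_dof.copy(), best_cost,
                            min(n_relax, budget))
        remaining = budget - min(n_relax, budget)
        while remaining >= n_relax + 1:
            cand = state.copy()
            fi = int(rng.integers(len(frags)))
            if frags[fi].n_torsions and rng.random() < 0.5:
                ti = int(rng.integers(frags[fi].n_torsions))
                cand.torsions[fi][ti] += 180.0
            else:
                _apply_flip(cand, fi, frags[fi], rng, fmat)
            if rng.random() < 0.3 and frags[fi].n_torsions:
                ti = int(rng.integers(frags[fi].n_torsions))
                cand.torsions[fi][ti] += 180.0
            trial += 1
            c = context.evaluate(cand)
            cand, c = relax(cand, c, n_relax)
            remaining -= n_relax + 1
            if c.total < cost.total:
                state, cost = cand, c

    # alternate broad search and basin-hopping harvests; replicas persist
    # across segments so the search resumes where it left off
    n_bh_total = int(config.quench_fraction * config.n_trials)
    n_pt_total = config.n_trials - n_bh_total
    n_sessions = max(config.n_sessions, 1)
    for s in range(n_sessions):
        pt_segment(n_pt_total // n_sessions)
        bh_session(n_bh_total // n_sessions)
    pt_left = config.n_trials - trial
    if pt_left > 0:
        pt_segment(pt_left)
    return RunResult(run_index=run_index, seed=seed, best_dof=best_dof,
                     best_cost=best_cost, best_trial=best_trial)


def solve(observed: PowderPattern, fragments, cell: UnitCell,
          space_group: SpaceGroup, restraints=(),
          weights: CostWeights | None = None,
          config: OptimizerConfig | None = None,
          context: CostContext | None = None):
    """Run the parallel-tempering solver; one RunResult per run.

    Fully reproducible: run r uses the seed ``config.seed + r`` so runs
    with identical configuration pair across weight settings.
    """
    config = config or OptimizerConfig()
    if context is None:
        context = CostContext(observed, fragments, cell, space_group,
                              restraints, weights)
    results = []
    for r in range(config.n_runs):
        results.append(_single_run(context, config, r, config.seed + r))
        log.info("run %d/%d: best CF %.4g at trial %d", r + 1, config.n_runs,
                 results[-1].best_cost.total, results[-1].best_trial)
    return results
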