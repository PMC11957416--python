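"""Cost-function terms, the periodic distance evaluator and the optimizer
contracts (determinism, reduction to a normal run)."""

import numpy as np
import pytest

from nmrpd.crystal import AtomSite, CrystalStructure, UnitCell, space_group_from_symbol
from nmrpd.diffraction import PowderPattern
from nmrpd.nmr import DistanceRestraint
from nmrpd.solver import (
    CostContext,
    CostWeights,
    OptimizerConfig,
    antibump,
    chi2_imd,
    chi2_profile,
    nth_intermolecular_distance,
    solve,
)


# ---------------------------------------------------------------------------
# nth intermolecular distance


def test_p1_periodic_image_distance(p1_two_atom):
    """Atoms at x=0 and x=0.6 in a 10 Å cell: nearest image is 4 Å."""
    assert nth_intermolecular_distance(p1_two_atom, "A1", "B1") == pytest.approx(4.0, abs=1e-9)
    assert nth_intermolecular_distance(p1_two_atom, "A1", "B1", rank=2) == pytest.approx(6.0, abs=1e-9)


def test_self_selection_excludes_zero_distance(p1_two_atom):
    """selA = selB returns the nearest periodic image, never 0."""
    d = nth_intermolecular_distance(p1_two_atom, "A1", "A1")
    assert d == pytest.approx(10.0, abs=1e-9)


def test_rank_beyond_cutoff_saturates(p1_two_atom):
    d = nth_intermolecular_distance(p1_two_atom, "A1", "B1", rank=500, cutoff=8.0)
    assert d == 8.0


def _supercell_oracle(structure, sel_a, sel_b, rank, cutoff=10.0):
    """Exhaustive 3×3×3-supercell enumeration (independent of the
    implementation's recentring/shift logic)."""
    from nmrpd.solver import _match_selection

    sites = structure.asym_sites
    frac = structure.frac_coords()
    orth = structure.cell.orthogonalization_matrix
    ia = _match_selection(sites, sel_a)
    ib = _match_selection(sites, sel_b)
    mols = [s.molecule_id for s in sites]
    dists = []
    for i in ia:
        xi = frac[i] @ orth.T
        for oi, op in enumerate(structure.space_group.operators):
            for j in ib:
                xj = op.apply(frac[j])
                for a in range(-3, 4):
                    for b in range(-3, 4):
                        for c in range(-3, 4):
                            if oi == 0 and (a, b, c) == (0, 0, 0) and mols[i] == mols[j]:
                                continue
                            d = np.linalg.norm(xi - (xj + [a, b, c]) @ orth.T)
                            if d <= cutoff:
                                dists.append(d)
    dists.sort()
    uniq = []
    for d in dists:
        if not uniq or d - uniq[-1] > 1e-6:
            uniq.append(d)
    return uniq[rank - 1] if rank <= len(uniq) else cutoff


def test_distance_matches_supercell_oracle(toy_structure):
    for sel_a, sel_b, rank in [("F", "C", 1), ("F", "C7", 1), ("B", "B", 1),
                               ("B", "B", 2), ("S", "F", 3)]:
        got = nth_intermolecular_distance(toy_structure, sel_a, sel_b, rank)
        assert got == pytest.approx(
            _supercell_oracle(toy_structure, sel_a, sel_b, rank), abs=1e-9)


def test_distance_oracle_random_configurations(toy_fragments):
    """50 random placements, ranks up to 3, vs the supercell oracle."""
    from nmrpd.fragments import randomize, realize_all

    cell = UnitCell(6.0, 7.5, 14.0, 90, 95, 90)
    sg = space_group_from_symbol("P21")
    rng = np.random.default_rng(5)
    checked = 0
    for seed in range(50):
        dof = randomize(toy_fragments, seed)
        st = CrystalStructure(cell=cell, space_group=sg,
                              asym_sites=realize_all(toy_fragments, dof, cell))
        sel_a, sel_b = [("F", "C"), ("B", "B"), ("S", "B")][seed % 3]
        rank = seed % 3 + 1
        got = nth_intermolecular_distance(st, sel_a, sel_b, rank)
        assert got == pytest.approx(
            _supercell_oracle(st, sel_a, sel_b, rank), abs=1e-9)
        checked += 1
    assert checked == 50


def test_context_distances_agree_with_public_evaluator(toy_structure, toy_fragments, toy_dof,
                                                       toy_pattern_broad):
    """The JIT distance kernel inside CostContext reproduces the reference
    numpy implementation."""
    restraints = [
        DistanceRestraint("F", "C1", 3.0), DistanceRestraint("B", "B", 4.0, rank=2),
        DistanceRestraint("F", "C7", 3.0),
    ]
    ctx = CostContext(toy_pattern_broad, toy_fragments, toy_structure.cell,
                      toy_structure.space_group, restraints, CostWeights(s4=1.0))
    frac = ctx._asym_frac(toy_dof)
    got = ctx._distances(frac)
    for r, d in zip(restraints, got):
        assert d == pytest.approx(
            nth_intermolecular_distance(toy_structure, r.selection_a,
                                        r.selection_b, r.rank), abs=1e-9)


# ---------------------------------------------------------------------------
# cost terms


def test_chi2_imd_piecewise_form():
    r = DistanceRestraint("A", "B", d0=5.0, sigma=1.0, delta=0.3)
    assert chi2_imd([5.0], [r]) == 0.0
    assert chi2_imd([5.3], [r]) == 0.0  # boundary of the penalty-free range
    assert chi2_imd([4.7], [r]) == 0.0
    assert chi2_imd([6.3], [r]) == pytest.approx(1.0)
    assert chi2_imd([3.2], [r]) == pytest.approx(((1.8 - 0.3) / 1.0) ** 2)
    r2 = DistanceRestraint("A", "B", d0=5.0, sigma=2.0, delta=0.0)
    assert chi2_imd([6.0], [r2]) == pytest.approx(0.25)


def test_chi2_imd_continuity_at_penalty_boundary():
    r = DistanceRestraint("A", "B", d0=5.0, sigma=1.0, delta=0.3)
    eps = 1e-8
    assert chi2_imd([5.3 + eps], [r]) < 1e-12


def test_chi2_profile_identity_and_scale_invariance():
    tt = np.arange(4.0, 10.0, 0.01)
    y = np.exp(-((tt - 6) ** 2)) * 1e4
    a = PowderPattern(tt, y)
    b = PowderPattern(tt, 2.0 * y)
    assert chi2_profile(a, a) == 0.0
    assert chi2_profile(a, b) == pytest.approx(0.0, abs=1e-18)
    flat = PowderPattern(tt, np.zeros_like(y))
    w = 1.0 / np.maximum(y, 1.0)
    assert chi2_profile(a, flat) == pytest.approx(float(np.sum(w * y * y)))


def test_chi2_profile_grid_mismatch():
    a = PowderPattern(np.arange(4, 10, 0.01), np.ones(600))
    b = PowderPattern(np.arange(5, 11, 0.01), np.ones(600))
    with pytest.raises(ValueError):
        chi2_profile(a, b)


def test_antibump_cases(toy_structure):
    """Well-separated toy packing scores 0; synthetic clash matches the
    hand-computed quadratic penalty."""
    st = toy_structure
    assert antibump(st.asym_sites, st.cell, st.space_group) == 0.0

    cell = UnitCell(20, 20, 20)
    sg = space_group_from_symbol("P1")
    sites = [AtomSite("C1", "C", (0.0, 0.0, 0.0), molecule_id="m1"),
             AtomSite("C2", "C", (0.05, 0.0, 0.0), molecule_id="m2")]
    import gemmi

    rmin = 0.7 * 2 * gemmi.Element("C").vdw_r  # vdW radius of C, 1.70 Å
    expected = 2 * ((rmin - 1.0) / rmin) ** 2  # counted from both ends
    assert antibump(sites, cell, sg) == pytest.approx(expected, rel=1e-9)


def test_antibump_monotone_in_distance():
    cell = UnitCell(20, 20, 20)
    sg = space_group_from_symbol("P1")
    vals = []
    for x in (0.05, 0.07, 0.09, 0.11):
        sites = [AtomSite("C1", "C", (0.0, 0.0, 0.0), molecule_id="m1"),
                 AtomSite("C2", "C", (x, 0.0, 0.0), molecule_id="m2")]
        vals.append(antibump(sites, cell, sg))
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[-1] >= 0.0


def test_jit_antibump_matches_reference(toy_fragments, toy_pattern_broad, toy_structure):
    """JIT anti-bump kernel vs the numpy reference on random clashes."""
    from nmrpd.fragments import randomize, realize_all

    cell = toy_structure.cell
    sg = toy_structure.space_group
    ctx = CostContext(toy_pattern_broad, toy_fragments, cell, sg, [],
                      CostWeights())
    for seed in range(5):
        dof = randomize(toy_fragments, seed)
        sites = realize_all(toy_fragments, dof, cell)
        ref = antibump(sites, cell, sg)
        got = ctx.evaluate(dof).chi2_antibump
        assert got == pytest.approx(ref, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# total cost and the solver


def test_total_cost_at_truth_is_zero(toy_structure, toy_fragments, toy_dof,
                                     toy_pattern_sharp):
    from nmrpd.compare import auto_restraints

    restraints = auto_restraints(toy_structure, [("F", "C7", 1), ("B", "B", 1)])
    ctx = CostContext(toy_pattern_sharp, toy_fragments, toy_structure.cell,
                      toy_structure.space_group, restraints,
                      CostWeights(s4=1e5))
    c = ctx.evaluate(toy_dof)
    assert c.chi2_profile == pytest.approx(0.0, abs=1e-12)
    assert c.chi2_imd == 0.0
    assert c.chi2_antibump == 0.0
    assert c.total == pytest.approx(0.0, abs=1e-9)


def test_s4_zero_reduces_to_normal_run(toy_structure, toy_fragments,
                                       toy_pattern_sharp):
    """With s4=0 the breakdown equals the no-restraint context exactly."""
    from nmrpd.fragments import randomize

    restraints = [DistanceRestraint("F", "C7", 3.0)]
    ctx_r = CostContext(toy_pattern_sharp, toy_fragments, toy_structure.cell,
                        toy_structure.space_group, restraints, CostWeights(s4=0.0))
    ctx_n = CostContext(toy_pattern_sharp, toy_fragments, toy_structure.cell,
                        toy_structure.space_group, [], CostWeights())
    for seed in (1, 2, 3):
        dof = randomize(toy_fragments, seed)
        assert ctx_r.evaluate(dof).total == pytest.approx(
            ctx_n.evaluate(dof).total, rel=1e-12)


def test_total_linear_in_weights(toy_structure, toy_fragments, toy_pattern_broad):
    from nmrpd.fragments import randomize

    restraints = [DistanceRestraint("F", "C7", 3.0)]
    dof = randomize(toy_fragments, 9)
    parts = {}
    for s4 in (1.0, 2.0):
        ctx = CostContext(toy_pattern_broad, toy_fragments, toy_structure.cell,
                          toy_structure.space_group, restraints,
                          CostWeights(s1=1.0, s3=100.0, s4=s4))
        parts[s4] = ctx.evaluate(dof)
    c1, c2 = parts[1.0], parts[2.0]
    assert c1.chi2_imd == pytest.approx(c2.chi2_imd)
    assert c2.total - c1.total == pytest.approx(c1.chi2_imd, rel=1e-9)
    assert c1.total == pytest.approx(
        c1.chi2_profile + 100.0 * c1.chi2_antibump + 1.0 * c1.chi2_imd, rel=1e-12)


def test_imd_never_raises_cost_of_satisfying_structure(toy_structure, toy_fragments,
                                                       toy_dof, toy_pattern_sharp):
    """Any s4 leaves the cost of a structure inside all δ windows unchanged."""
    from nmrpd.compare import auto_restraints

    restraints = auto_restraints(toy_structure,
                                 [("F", "C7", 1), ("B", "B", 1), ("B", "B", 2)])
    totals = []
    for s4 in (0.0, 1e4, 1e5, 1e6):
        ctx = CostContext(toy_pattern_sharp, toy_fragments, toy_structure.cell,
                          toy_structure.space_group, restraints, CostWeights(s4=s4))
        totals.append(ctx.evaluate(toy_dof).total)
    assert max(totals) - min(totals) < 1e-9


def test_solver_determinism_and_monotone_best(toy_structure, toy_fragments,
                                              toy_pattern_sharp):
    """Same seed → bit-identical best DOF; the best cost never exceeds the
    starting cost and decreases through the run."""
    ctx = CostContext(toy_pattern_sharp, toy_fragments, toy_structure.cell,
                      toy_structure.space_group, [], CostWeights())
    cfg = OptimizerConfig(n_runs=2, n_trials=600, seed=77)
    a = solve(toy_pattern_sharp, toy_fragments, toy_structure.cell,
              toy_structure.space_group, [], CostWeights(), cfg, context=ctx)
    b = solve(toy_pattern_sharp, toy_fragments, toy_structure.cell,
              toy_structure.space_group, [], CostWeights(), cfg, context=ctx)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.best_dof.flatten(), rb.best_dof.flatten())
        assert ra.best_cost.total == rb.best_cost.total
        assert ra.best_trial == rb.best_trial
    # paired seeds: run r of any config uses seed base+r
    assert [r.seed for r in a] == [77, 78]


def test_solver_improves_on_start(toy_structure, toy_fragments, toy_pattern_sharp):
    from nmrpd.fragments import randomize

    ctx = CostContext(toy_pattern_sharp, toy_fragments, toy_structure.cell,
                      toy_structure.space_group, [], CostWeights())
    cfg = OptimizerConfig(n_runs=1, n_trials=1500, seed=3)
    res = solve(toy_pattern_sharp, toy_fragments, toy_structure.cell,
                toy_structure.space_group, [], CostWeights(), cfg, context=ctx)[0]
    rng = np.random.default_rng(3)
    start = randomize(toy_fragments, rng_seed=int(rng.integers(2**31)))
    assert res.best_cost.total < ctx.evaluate(start).total
    assert 0 <= res.best_trial <= 1500


def test_weights_validation():
    with pytest.raises(ValueError):
        CostWeights(s1=-1.0)
    with pytest.raises(ValueError):
        OptimizerConfig(n_trials=0)
    with pytest.raises(ValueError):
        OptimizerConfig(t_min=5.0, t_max=1.0)
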