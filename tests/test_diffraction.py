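"""Reflection generation, structure factors and pattern simulation."""

import numpy as np
import pytest

from nmrpd.crystal import AtomSite, CrystalStructure, UnitCell, space_group_from_symbol
from nmrpd.diffraction import (
    CU_KA1,
    GridSpec,
    ProfileConfig,
    Reflection,
    generate_reflections,
    lorentz_polarization,
    simulate_pattern,
    structure_factor,
    structure_factors,
)


def _p21_structure():
    return CrystalStructure(
        cell=UnitCell(6, 7.5, 14, 90, 95, 90),
        space_group=space_group_from_symbol("P21"),
        asym_sites=[AtomSite("C1", "C", (0.13, 0.27, 0.08))],
    )


def test_screw_axis_absences_p21():
    """0k0 with odd k is extinct under the 2₁ screw."""
    refl = generate_reflections(_p21_structure(), CU_KA1, 50.0)
    hkls = {r.hkl for r in refl}
    assert not any(h == 0 and l == 0 and k % 2 for h, k, l in hkls)
    assert any(h == 0 and l == 0 and k % 2 == 0 for h, k, l in hkls)


def test_glide_plane_absences_p21c():
    st = CrystalStructure(
        cell=UnitCell(6, 7.5, 14, 90, 95, 90),
        space_group=space_group_from_symbol("P21/c"),
        asym_sites=[AtomSite("C1", "C", (0.13, 0.27, 0.08))],
    )
    hkls = {r.hkl for r in generate_reflections(st, CU_KA1, 50.0)}
    assert not any(k == 0 and l % 2 for h, k, l in hkls)  # c glide: h0l, l odd
    assert not any(h == 0 and l == 0 and k % 2 for h, k, l in hkls)


def test_cubic_enumeration_matches_bruteforce():
    """Primitive cubic a=5: the unique reflection set within 30° 2θ equals
    a brute-force enumeration of lattice points inside the Ewald limit."""
    st = CrystalStructure(
        cell=UnitCell(5, 5, 5),
        space_group=space_group_from_symbol("P1"),
        asym_sites=[AtomSite("C1", "C", (0.1, 0.2, 0.3))],
    )
    refl = generate_reflections(st, 1.5406, 30.0)
    smax = 2 * 5 * np.sin(np.radians(15.0)) / 1.5406
    brute = set()
    for h in range(-4, 5):
        for k in range(-4, 5):
            for l in range(-4, 5):
                if (h, k, l) == (0, 0, 0):
                    continue
                if np.sqrt(h * h + k * k + l * l) <= smax:
                    brute.add(frozenset([(h, k, l), (-h, -k, -l)]))
    got = set()
    for r in refl:
        h, k, l = r.hkl
        got.add(frozenset([(h, k, l), (-h, -k, -l)]))
        assert np.sqrt(h * h + k * k + l * l) <= smax + 1e-9
    assert got == brute
    assert sum(r.multiplicity for r in refl) == sum(len(fs) for fs in brute)


def test_structure_factor_single_atom_at_origin():
    """|F|² of one atom equals f(sinθ/λ)², independent of hkl phase."""
    import gemmi

    cell = UnitCell(8, 8, 8)
    site = [AtomSite("C1", "C", (0.0, 0.0, 0.0))]
    for hkl in [(1, 0, 0), (2, 1, 0), (3, 1, 2)]:
        d = 8.0 / np.linalg.norm(hkl)
        r = Reflection(hkl=hkl, d=d, two_theta=0.0, multiplicity=1)
        stol2 = 1.0 / (4 * d * d)
        f = gemmi.Element("C").it92.calculate_sf(stol2) * np.exp(-3.0 * stol2)
        assert structure_factor(r, site, cell) == pytest.approx(f * f, rel=1e-10)


def test_structure_factor_destructive_interference():
    """Two identical atoms ½ apart along c kill odd-l 00l reflections."""
    cell = UnitCell(8, 8, 8)
    sites = [AtomSite("C1", "C", (0.1, 0.2, 0.0)),
             AtomSite("C2", "C", (0.1, 0.2, 0.5))]
    for l, expect_zero in [(1, True), (2, False), (3, True)]:
        r = Reflection(hkl=(0, 0, l), d=8.0 / l, two_theta=0.0, multiplicity=1)
        f2 = structure_factor(r, sites, cell)
        if expect_zero:
            assert f2 == pytest.approx(0.0, abs=1e-18)
        else:
            assert f2 > 1.0


def test_structure_factors_against_direct_complex_sum(rng):
    """Random 5-atom cell vs an independent term-by-term complex sum."""
    import gemmi

    cell = UnitCell(7, 9, 11, 90, 104, 90)
    elements = ["C", "N", "O", "S", "F"]
    fracs = rng.random((5, 3))
    occs = rng.uniform(0.5, 1.0, 5)
    sites = [AtomSite(f"X{i}", e, tuple(f), occupancy=o)
             for i, (e, f, o) in enumerate(zip(elements, fracs, occs))]
    refl = [Reflection(hkl=tuple(h), d=float(
        1 / np.sqrt(np.asarray(h, float) @ cell.reciprocal_metric @ np.asarray(h, float))),
        two_theta=0.0, multiplicity=1)
        for h in [(1, 2, 3), (-2, 0, 4), (3, -1, 1)]]
    got = structure_factors(refl, sites, cell, b_iso=3.0)
    for r, f2 in zip(refl, got):
        stol2 = 1.0 / (4 * r.d**2)
        total = 0j
        for s in sites:
            f = gemmi.Element(s.element).it92.calculate_sf(stol2)
            phase = 2j * np.pi * np.dot(r.hkl, s.frac)
            total += s.occupancy * f * np.exp(-3.0 * stol2) * np.exp(phase)
        assert f2 == pytest.approx(abs(total) ** 2, rel=1e-8)


def test_pattern_grid_has_4601_points(toy_pattern_sharp):
    assert len(toy_pattern_sharp.two_theta) == 4601
    assert toy_pattern_sharp.two_theta[0] == pytest.approx(4.0)
    assert toy_pattern_sharp.two_theta[-1] == pytest.approx(50.0)
    assert toy_pattern_sharp.intensity.max() == pytest.approx(1e4)


def test_peaks_at_bragg_positions(toy_structure, toy_pattern_sharp):
    """Local maxima sit within half a step of strong isolated reflections."""
    refl = generate_reflections(toy_structure, CU_KA1, 50.0, 4.0)
    refl.sort(key=lambda r: -r.f2 if r.f2 else 0)
    y = toy_pattern_sharp.intensity
    tt = toy_pattern_sharp.two_theta
    # strongest low-angle reflection, guaranteed isolated at fwhm 0.1°
    iso = [r for r in refl if r.two_theta < 12.0]
    pos = iso[0].two_theta if iso else refl[0].two_theta
    window = (tt > pos - 0.3) & (tt < pos + 0.3)
    peak_tt = tt[window][np.argmax(y[window])]
    assert abs(peak_tt - pos) <= 0.005 + 1e-9


def test_fwhm_doubling_conserves_area(toy_structure):
    """Doubling the FWHM halves isolated peak height, conserves area."""
    g = GridSpec(4.0, 20.0, 0.01)
    p1 = simulate_pattern(toy_structure, ProfileConfig(fwhm=0.1), g, normalize=False)
    p2 = simulate_pattern(toy_structure, ProfileConfig(fwhm=0.2), g, normalize=False)
    a1 = np.trapezoid(p1.intensity, p1.two_theta)
    a2 = np.trapezoid(p2.intensity, p2.two_theta)
    assert a2 == pytest.approx(a1, rel=0.01)
    # isolated first peak height ratio ~ 2
    assert p1.intensity.max() / p2.intensity.max() == pytest.approx(2.0, rel=0.05)


def test_friedel_pairs_merged(toy_structure):
    refl = generate_reflections(toy_structure, CU_KA1, 30.0)
    keys = [r.hkl for r in refl]
    assert len(keys) == len(set(keys))
    negs = {tuple(-np.array(k)) for k in keys}
    assert not negs & set(keys) or all(
        tuple(-np.array(k)) not in keys for k in keys if any(np.array(k)))


def test_lp_correction_form():
    tt = np.array([20.0, 40.0])
    th = np.radians(tt / 2)
    expected = (1 + np.cos(np.radians(tt)) ** 2) / (np.sin(th) ** 2 * np.cos(th))
    assert np.allclose(lorentz_polarization(tt), expected)


def test_empty_structure_warns_and_zero_pattern():
    st = CrystalStructure(
        cell=UnitCell(3, 3, 3),
        space_group=space_group_from_symbol("P1"),
        asym_sites=[AtomSite("C1", "C", (0, 0, 0))],
    )
    with pytest.warns(UserWarning):
        pat = simulate_pattern(st, ProfileConfig(fwhm=0.5),
                               GridSpec(4.0, 10.0, 0.01))
    assert np.all(pat.intensity == 0)
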