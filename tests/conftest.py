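import numpy as np
import pytest

from nmrpd.crystal import CrystalStructure, UnitCell, space_group_from_symbol
from nmrpd.diffraction import GridSpec, ProfileConfig, simulate_pattern
from nmrpd.toy import ToyCrystalSpec, make_toy_crystal


@pytest.fixture(scope="session")
def toy():
    """(structure, fragments, generating DOF) of the deterministic fixture."""
    return make_toy_crystal(ToyCrystalSpec())


@pytest.fixture(scope="session")
def toy_structure(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_fragments(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_dof(toy):
    return toy[2]


@pytest.fixture(scope="session")
def toy_pattern_sharp(toy_structure):
    """High-resolution (fwhm 0.1°) pattern of the toy crystal."""
    return simulate_pattern(toy_structure, ProfileConfig(fwhm=0.1), GridSpec())


@pytest.fixture(scope="session")
def toy_pattern_broad(toy_structure):
    """Heavily degraded (fwhm 1.5°) pattern of the toy crystal."""
    return simulate_pattern(toy_structure, ProfileConfig(fwhm=1.5), GridSpec())


@pytest.fixture()
def p1_two_atom():
    """Minimal P1 structure: two single-atom molecules on the a axis."""
    from nmrpd.crystal import AtomSite

    cell = UnitCell(10.0, 10.0, 10.0, 90.0, 90.0, 90.0)
    return CrystalStructure(
        cell=cell,
        space_group=space_group_from_symbol("P1"),
        asym_sites=[
            AtomSite("A1", "C", (0.0, 0.0, 0.0), molecule_id="m1"),
            AtomSite("B1", "N", (0.6, 0.0, 0.0), molecule_id="m2"),
        ],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250928)
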