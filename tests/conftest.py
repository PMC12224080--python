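import numpy as np
import pytest

from xtalbench.core import UnitCell
from xtalbench.synthetic import (
    FixtureSpec,
    make_toy_structure,
    simulate_reflections,
)


def random_cell(rng: np.random.Generator) -> UnitCell:
    """Random valid triclinic cell (angles kept away from degeneracy)."""
    lengths = rng.uniform(4.0, 15.0, size=3)
    angles = rng.uniform(70.0, 110.0, size=3)
    return UnitCell(*lengths, *angles)


@pytest.fixture(scope="session")
def p21c_structure():
    return make_toy_structure(
        FixtureSpec(seed=3, spacegroup="P21/c", n_heavy_atoms=5, d_min=0.9)
    )


@pytest.fixture(scope="session")
def p21c_reflections(p21c_structure):
    return simulate_reflections(
        p21c_structure, d_min=0.9, noise_fraction=0.0, seed=1
    )


@pytest.fixture(scope="session")
def p1_structure():
    return make_toy_structure(
        FixtureSpec(seed=7, spacegroup="P1", n_heavy_atoms=4)
    )


MINIMAL_CIF = """\
data_minimal
_cell_length_a 6.0
_cell_length_b 7.0
_cell_length_c 8.0
_cell_angle_alpha 90.0
_cell_angle_beta 100.0
_cell_angle_gamma 90.0
loop_
_space_group_symop_operation_xyz
'x, y, z'
'-x, y+1/2, -z+1/2'
'-x, -y, -z'
'x, -y+1/2, z+1/2'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
_atom_site_occupancy
_atom_site_U_iso_or_equiv
C1 C 0.100000 0.200000 0.300000 1.0000 0.01000
N1 N 0.150000 0.250000 0.450000 1.0000 0.01200
O1 O 0.300000 0.150000 0.250000 1.0000 0.01100
"""


@pytest.fixture()
def minimal_cif_text():
    return MINIMAL_CIF
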