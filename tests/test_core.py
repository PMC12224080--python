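import numpy as np
import pytest

from xtalbench.core import (
    AtomSite,
    CrystalStructure,
    SpaceGroup,
    SymmetryOperation,
    UnitCell,
    apply_symmetry,
    cell_volume,
    d_spacing,
    expand_to_p1,
    metric_tensor,
    orthogonalization_matrix,
    transform_adp,
    adp_cif_to_cartesian,
)
from xtalbench.io import parse_symop_xyz
from xtalbench.synthetic import make_spacegroup

from conftest import random_cell


class TestOrthogonalization:
    @pytest.mark.parametrize(
        "cell, expected",
        [
            (UnitCell(5, 5, 5), np.diag([5.0, 5.0, 5.0])),
            (UnitCell(2, 3, 4), np.diag([2.0, 3.0, 4.0])),
        ],
    )
    def test_orthogonal_cells_are_diagonal(self, cell, expected):
        assert np.allclose(orthogonalization_matrix(cell), expected)

    def test_hexagonal_b_axis_column(self):
        m = orthogonalization_matrix(UnitCell(2, 2, 3, 90, 90, 120))
        assert np.allclose(m[:, 1], [-1.0, np.sqrt(3.0), 0.0])

    def test_metric_tensor_reproduced_for_random_cells(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            cell = random_cell(rng)
            m = orthogonalization_matrix(cell)
            ca, cb, cg = np.cos(np.radians(cell.angles))
            a, b, c = cell.lengths
            g_expected = np.array(
                [
                    [a * a, a * b * cg, a * c * cb],
                    [a * b * cg, b * b, b * c * ca],
                    [a * c * cb, b * c * ca, c * c],
                ]
            )
            assert np.allclose(m.T @ m, g_expected, rtol=1e-10)

    def test_degenerate_cell_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(5, 5, 5, 1e-9, 90, 90)
        with pytest.raises(ValueError):
            UnitCell(0, 5, 5)


class TestCellVolume:
    def test_cubic(self):
        assert cell_volume(UnitCell(5, 5, 5)) == pytest.approx(125.0)

    def test_hexagonal_analytic(self):
        v = cell_volume(UnitCell(2, 2, 3, 90, 90, 120))
        assert v == pytest.approx(4.0 * 3.0 * np.sin(np.radians(120)), rel=1e-10)
        assert v == pytest.approx(10.3923, abs=1e-4)

    def test_triclinic_matches_determinant(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            cell = random_cell(rng)
            det = np.linalg.det(orthogonalization_matrix(cell))
            assert cell_volume(cell) == pytest.approx(abs(det), rel=1e-12)


class TestDSpacing:
    def test_cubic_axial(self):
        assert d_spacing(UnitCell(5, 5, 5), (1, 0, 0)) == pytest.approx(5.0)

    def test_cubic_diagonal(self):
        assert d_spacing(UnitCell(5, 5, 5), (1, 1, 0)) == pytest.approx(
            5.0 / np.sqrt(2.0), abs=1e-4
        )

    def test_triclinic_matches_reciprocal_basis_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            cell = random_cell(rng)
            h = rng.integers(-6, 7, size=3)
            if not h.any():
                h = np.array([1, 0, 0])
            m_inv_t = np.linalg.inv(orthogonalization_matrix(cell)).T
            oracle = 1.0 / np.linalg.norm(m_inv_t @ h)
            assert d_spacing(cell, h) == pytest.approx(oracle, rel=1e-12)

    def test_friedel_symmetric(self):
        rng = np.random.default_rng(3)
        cell = random_cell(rng)
        for _ in range(50):
            h = rng.integers(-8, 9, size=3)
            if not h.any():
                continue
            assert d_spacing(cell, h) == pytest.approx(d_spacing(cell, -h))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            d_spacing(UnitCell(5, 5, 5), (0, 0, 0))


class TestSymmetryOperations:
    def test_apply_identity(self):
        op = parse_symop_xyz("x,y,z")
        assert np.allclose(apply_symmetry(op, [0.1, 0.2, 0.3]), [0.1, 0.2, 0.3])

    def test_apply_inversion(self):
        op = parse_symop_xyz("-x,-y,-z")
        assert np.allclose(apply_symmetry(op, [0.1, 0.2, 0.3]), [-0.1, -0.2, -0.3])

    def test_apply_screw_no_wrapping(self):
        op = parse_symop_xyz("-x, y+1/2, -z")
        assert np.allclose(apply_symmetry(op, [0.25, 0.0, 0.1]), [-0.25, 0.5, -0.1])

    def test_rotation_determinant_validated(self):
        with pytest.raises(ValueError):
            SymmetryOperation(((1, 0, 0), (0, 1, 0), (0, 0, 0)), (0, 0, 0))

    def test_composition_closure(self):
        for name in ("P-1", "P21", "P21/c"):
            assert make_spacegroup(name).is_closed()

    def test_group_requires_identity(self):
        inv = parse_symop_xyz("-x,-y,-z")
        with pytest.raises(ValueError):
            SpaceGroup("broken", (inv,))


class TestExpandToP1:
    def _structure(self, sg_name, frac):
        return CrystalStructure(
            UnitCell(8, 9, 10, 90, 95, 90),
            make_spacegroup(sg_name),
            [AtomSite("C1", "C", frac, u_iso=0.01)],
        )

    def test_general_position_p_minus_1(self):
        assert len(expand_to_p1(self._structure("P-1", [0.1, 0.2, 0.3]))) == 2

    def test_origin_special_position_merges(self):
        assert len(expand_to_p1(self._structure("P-1", [0.0, 0.0, 0.0]))) == 1

    def test_general_position_p21c(self):
        assert len(expand_to_p1(self._structure("P21/c", [0.13, 0.21, 0.34]))) == 4

    def test_invariant_under_preapplied_operation(self):
        s = self._structure("P21/c", [0.13, 0.21, 0.34])
        base = sorted(tuple(np.round(a.frac, 6)) for a in expand_to_p1(s))
        for op in s.spacegroup.operations:
            moved = s.copy()
            moved.sites[0].frac = apply_symmetry(op, moved.sites[0].frac) % 1.0
            other = sorted(tuple(np.round(a.frac, 6)) for a in expand_to_p1(moved))
            assert np.allclose(np.array(base), np.array(other), atol=1e-5)


class TestAdpTransforms:
    def test_cif_cartesian_round_trip(self):
        from xtalbench.core import adp_cartesian_to_cif

        rng = np.random.default_rng(5)
        cell = random_cell(rng)
        u6 = np.array([0.02, 0.03, 0.025, 0.002, -0.001, 0.0015])
        u_cart = adp_cif_to_cartesian(u6, cell)
        assert np.allclose(u_cart, u_cart.T)
        assert np.allclose(adp_cartesian_to_cif(u_cart, cell), u6, atol=1e-12)

    def test_identity_operation_preserves_adp(self):
        cell = UnitCell(8, 9, 10, 90, 95, 90)
        op = parse_symop_xyz("x,y,z")
        u6 = np.array([0.02, 0.03, 0.025, 0.002, -0.001, 0.0015])
        assert np.allclose(transform_adp(op, u6, cell), u6)
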