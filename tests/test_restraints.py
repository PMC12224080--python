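import numpy as np
import pytest

from xtalbench.connectivity import perceive_bonds
from xtalbench.restraints import (
    Restraint,
    RestraintSet,
    SU_PROFILES,
    apply_tma_correction,
    evaluate_restraints,
    generate_restraints,
)
from xtalbench.synthetic import FixtureSpec, make_toy_structure


def right_angle_chain():
    from xtalbench.connectivity import BondGraph

    labels = ["C1", "C2", "C3"]
    coords = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    graph = BondGraph.from_edges(["C", "C", "C"], coords, [(0, 1), (1, 2)])
    return labels, coords, graph


class TestGenerateRestraints:
    def test_right_angle_chain(self):
        labels, coords, graph = right_angle_chain()
        rs = generate_restraints(labels, coords, graph)
        bonds = rs.by_kind("bond_12")
        angles = rs.by_kind("angle_13")
        assert len(bonds) == 2 and len(angles) == 1
        assert all(b.target == pytest.approx(1.0) for b in bonds)
        assert angles[0].target == pytest.approx(np.sqrt(2.0), abs=1e-6)
        assert bonds[0].su == SU_PROFILES["tight"]["bond"]
        assert angles[0].su == SU_PROFILES["tight"]["angle"]

    def test_water_hydrogen_angle_excluded(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]])
        graph = perceive_bonds(["O", "H", "H"], coords)
        rs = generate_restraints(["O1", "H1", "H2"], coords, graph)
        assert len(rs.by_kind("bond_12")) == 2
        assert len(rs.by_kind("angle_13")) == 0

    def test_counts_edges_plus_pairs(self):
        s = make_toy_structure(FixtureSpec(seed=17, n_heavy_atoms=7, n_hydrogens=2))
        coords = s.cart_coords()
        labels = [a.label for a in s.sites]
        graph = perceive_bonds([a.element for a in s.sites], coords)
        from xtalbench.connectivity import angle_pairs

        rs = generate_restraints(labels, coords, graph)
        n_expected = len(graph.edges()) + len(angle_pairs(graph, exclude_hydrogen=True))
        assert len(rs) == n_expected

    def test_zero_residual_on_generating_structure(self):
        s = make_toy_structure(FixtureSpec(seed=18, n_heavy_atoms=6))
        coords = s.cart_coords()
        labels = [a.label for a in s.sites]
        graph = perceive_bonds([a.element for a in s.sites], coords)
        rs = generate_restraints(labels, coords, graph)
        assert np.allclose(evaluate_restraints(rs, labels, coords), 0.0, atol=1e-12)

    def test_three_ring_keeps_bond_only(self):
        # equilateral triangle: every 1-3 pair is also a bond
        coords = 1.5 * np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0]]
        )
        graph = perceive_bonds(["C", "C", "C"], coords)
        assert len(graph.edges()) == 3
        rs = generate_restraints(["C1", "C2", "C3"], coords, graph)
        assert len(rs.by_kind("bond_12")) == 3
        assert len(rs.by_kind("angle_13")) == 0

    def test_mismatched_graph_raises(self):
        labels, coords, graph = right_angle_chain()
        with pytest.raises(ValueError):
            generate_restraints(labels[:2], coords[:2], graph)


class TestRestraintValidation:
    def test_duplicate_rejected(self):
        r = Restraint("bond_12", ("C1", "C2"), 1.5, 0.0005)
        r2 = Restraint("bond_12", ("C2", "C1"), 1.6, 0.0005)
        with pytest.raises(ValueError, match="duplicate"):
            RestraintSet([r, r2])

    def test_same_atom_rejected(self):
        with pytest.raises(ValueError):
            Restraint("bond_12", ("C1", "C1"), 1.5, 0.0005)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            Restraint("bond_12", ("C1", "C2"), -1.5, 0.0005)
        with pytest.raises(ValueError):
            Restraint("bond_12", ("C1", "C2"), 1.5, 0.0)


class TestTmaCorrection:
    def test_zero_delta_unchanged(self):
        labels, coords, graph = right_angle_chain()
        rs = generate_restraints(labels, coords, graph)
        out = apply_tma_correction(rs, 0.0, labels, coords, graph)
        for a, b in zip(rs.restraints, out.restraints):
            assert a.target == pytest.approx(b.target, abs=1e-15)

    def test_bond_targets_shift_exactly(self):
        s = make_toy_structure(FixtureSpec(seed=19, n_heavy_atoms=6))
        coords = s.cart_coords()
        labels = [a.label for a in s.sites]
        graph = perceive_bonds([a.element for a in s.sites], coords)
        rs = generate_restraints(labels, coords, graph)
        out = apply_tma_correction(rs, 0.0005, labels, coords, graph)
        for a, b in zip(rs.by_kind("bond_12"), out.by_kind("bond_12")):
            assert b.target - a.target == pytest.approx(0.0005, abs=1e-12)

    def test_right_angle_first_order_matches_exact(self):
        labels, coords, graph = right_angle_chain()
        rs = generate_restraints(labels, coords, graph)
        delta = 0.0005
        out = apply_tma_correction(rs, delta, labels, coords, graph)
        target = out.by_kind("angle_13")[0].target
        exact = np.sqrt(2.0 * (1.0 + delta) ** 2)
        assert target == pytest.approx(exact, abs=1e-6)
        assert target == pytest.approx(1.41492, abs=1e-5)

    def test_first_order_accuracy_random_geometries(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            d1, d2 = rng.uniform(1.2, 1.6, size=2)
            theta = rng.uniform(np.radians(60), np.radians(170))
            delta = rng.uniform(-0.002, 0.002)
            apex = np.zeros(3)
            p1 = np.array([d1, 0.0, 0.0])
            p2 = d2 * np.array([np.cos(theta), np.sin(theta), 0.0])
            coords = np.stack([p1, apex, p2])
            from xtalbench.connectivity import BondGraph

            graph = BondGraph.from_edges(["C", "C", "C"], coords,
                                         [(0, 1), (1, 2)])
            labels = ["C1", "C2", "C3"]
            rs = generate_restraints(labels, coords, graph)
            out = apply_tma_correction(rs, delta, labels, coords, graph)
            scaled1 = p1 * (1 + delta / d1)
            scaled2 = p2 * (1 + delta / d2)
            exact = np.linalg.norm(scaled1 - scaled2)
            approx = out.by_kind("angle_13")[0].target
            assert abs(approx - exact) < 1e-6

    def test_missing_apex_raises(self):
        labels, coords, graph = right_angle_chain()
        rs = RestraintSet([Restraint("angle_13", ("C1", "C9"), 2.0, 0.002)], "x")
        with pytest.raises(ValueError):
            apply_tma_correction(rs, 0.0005, labels, coords, graph)
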