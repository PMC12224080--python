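import numpy as np
import pytest

from xtalbench.compare import rmscd
from xtalbench.connectivity import perceive_bonds
from xtalbench.core import (
    AtomSite,
    CrystalStructure,
    SpaceGroup,
    UnitCell,
    expand_to_p1,
)
from xtalbench.io import parse_symop_xyz
from xtalbench.refine import (
    RefinementOptions,
    calc_structure_factors,
    delta_r1,
    form_factor,
    r1_factor,
    refine,
    scale_factor,
)
from xtalbench.restraints import Restraint, RestraintSet, generate_restraints
from xtalbench.synthetic import (
    FixtureSpec,
    make_spacegroup,
    make_toy_structure,
    perturb_structure,
    simulate_reflections,
    unique_hkl,
)


def p1_group():
    return SpaceGroup("P 1", (parse_symop_xyz("x,y,z"),))


class TestFormFactor:
    def test_f0_close_to_z(self):
        assert form_factor("C", 0.0) == pytest.approx(6.0, rel=0.02)
        assert form_factor("O", 0.0) == pytest.approx(8.0, rel=0.02)

    @pytest.mark.parametrize("element", ["C", "N", "O"])
    def test_monotone_decreasing(self, element):
        s = np.linspace(0.0, 1.5, 200)
        f = form_factor(element, s)
        assert np.all(np.diff(f) < 0)
        assert np.all(f > 0)

    def test_oxygen_matches_direct_recompute(self):
        from xtalbench.refine import form_factor_coefficients

        a, b, c = form_factor_coefficients("O")
        s = 0.5
        oracle = sum(ai * np.exp(-bi * s**2) for ai, bi in zip(a, b)) + c
        assert form_factor("O", s) == pytest.approx(oracle, rel=1e-12)

    def test_unknown_element(self):
        with pytest.raises(ValueError):
            form_factor("Xq", 0.1)


class TestStructureFactors:
    def test_single_atom_at_origin(self):
        s = CrystalStructure(
            UnitCell(6, 6, 6),
            p1_group(),
            [AtomSite("C1", "C", [0.0, 0.0, 0.0], u_iso=0.0)],
        )
        hkl = np.array([[1, 0, 0], [2, 1, 0], [3, 2, 1]])
        f = calc_structure_factors(s, hkl)
        for h, fh in zip(hkl, f):
            d = 6.0 / np.linalg.norm(h) if np.allclose(h[1:], 0) else None
            assert abs(fh.imag) < 1e-12
            assert fh.real > 0

        expected = form_factor("C", 0.5 / 6.0)  # s = 1/(2d) for (1,0,0)
        assert f[0].real == pytest.approx(float(expected), rel=1e-10)

    def test_half_cell_shift_gives_phase_pi(self):
        s = CrystalStructure(
            UnitCell(6, 6, 6),
            p1_group(),
            [AtomSite("C1", "C", [0.5, 0.0, 0.0], u_iso=0.0)],
        )
        f = calc_structure_factors(s, np.array([[1, 0, 0]]))[0]
        expected = form_factor("C", 0.5 / 6.0)
        assert f.real == pytest.approx(-float(expected), rel=1e-10)
        assert abs(f.imag) < 1e-12

    def test_p21_screw_axis_absences(self):
        s = make_toy_structure(FixtureSpec(seed=13, spacegroup="P21", n_heavy_atoms=5))
        hkl = np.array([[0, k, 0] for k in range(1, 8)])
        f = np.abs(calc_structure_factors(s, hkl))
        ref = np.abs(calc_structure_factors(s, unique_hkl(s, 1.0))).max()
        odd = f[::2]  # k = 1, 3, 5, 7
        even = f[1::2]
        assert np.all(odd / ref < 1e-10)
        assert np.all(even / ref > 1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_sum_equals_p1_expansion(self, seed):
        sg = ["P-1", "P21", "P21/c"][seed % 3]
        s = make_toy_structure(FixtureSpec(seed=seed, spacegroup=sg, n_heavy_atoms=4))
        hkl = unique_hkl(s, 1.1)
        f_sym = calc_structure_factors(s, hkl)
        p1 = CrystalStructure(s.cell, p1_group(), expand_to_p1(s))
        f_p1 = calc_structure_factors(p1, hkl)
        scale = np.max(np.abs(f_sym))
        assert np.max(np.abs(f_sym - f_p1)) / scale < 1e-8

    def test_friedel_symmetry_without_anomalous(self, p21c_structure):
        hkl = unique_hkl(p21c_structure, 1.0)
        f_plus = np.abs(calc_structure_factors(p21c_structure, hkl))
        f_minus = np.abs(calc_structure_factors(p21c_structure, -hkl))
        assert np.allclose(f_plus, f_minus, rtol=1e-10)

    def test_friedel_broken_by_anomalous_in_acentric_group(self):
        # needs a non-centrosymmetric group: with an inversion centre the
        # Friedel pair equality holds even with f'' != 0
        s = make_toy_structure(FixtureSpec(seed=14, spacegroup="P21",
                                           n_heavy_atoms=5))
        hkl = unique_hkl(s, 1.0)
        anom = {"C": (0.01, 0.02), "N": (0.02, 0.03), "O": (0.03, 0.04)}
        f_plus = np.abs(calc_structure_factors(s, hkl, anomalous=anom))
        f_minus = np.abs(calc_structure_factors(s, -hkl, anomalous=anom))
        assert not np.allclose(f_plus, f_minus, rtol=1e-10)

    def test_missing_adp_raises(self):
        s = CrystalStructure(
            UnitCell(6, 6, 6), p1_group(), [AtomSite("C1", "C", [0.1, 0.1, 0.1])]
        )
        with pytest.raises(ValueError, match="ADP"):
            calc_structure_factors(s, np.array([[1, 0, 0]]))
        f = calc_structure_factors(s, np.array([[1, 0, 0]]), default_u_iso=0.01)
        assert np.isfinite(f[0].real)


class TestScaleAndR1:
    def test_scale_examples(self):
        fc = np.array([1.0, 2.0, 3.0])
        assert scale_factor(4.0 * fc, fc) == pytest.approx(4.0)
        assert scale_factor(fc, fc) == pytest.approx(1.0)

    def test_scale_inverse_property(self):
        rng = np.random.default_rng(0)
        fo = rng.uniform(1, 10, 20)
        fc = rng.uniform(1, 10, 20)
        k = scale_factor(fo, fc)
        assert scale_factor(fo, 2.0 * fc) == pytest.approx(k / 2.0)

    def test_scale_zero_fc_rejected(self):
        with pytest.raises(ValueError):
            scale_factor(np.ones(3), np.zeros(3))

    def test_r1_examples(self):
        assert r1_factor([10.0, 20.0], [10.0, 20.0]) == 0.0
        assert r1_factor([10.0, 20.0], [8.0, 22.0]) == pytest.approx(4.0 / 30.0)
        assert r1_factor([10.0, 20.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_r1_empty_rejected(self):
        with pytest.raises(ValueError):
            r1_factor([], [])


class TestRefine:
    def test_fixed_point(self, p21c_structure, p21c_reflections):
        res = refine(p21c_structure, p21c_reflections)
        assert res.r1 < 1e-6
        assert res.cycles_used <= 2
        assert res.converged

    def test_parameter_recovery(self, p21c_structure, p21c_reflections):
        pert = perturb_structure(p21c_structure, 0.05, seed=11)
        res = refine(pert, p21c_reflections)
        assert rmscd(res.structure, p21c_structure) < 1e-3
        assert res.r1 < 1e-6

    def test_r1_non_increasing_from_perturbed_start(
        self, p21c_structure, p21c_reflections
    ):
        pert = perturb_structure(p21c_structure, 0.03, seed=5)
        start = refine(pert, p21c_reflections,
                       options=RefinementOptions(max_cycles=1, damping=1e-6))
        full = refine(pert, p21c_reflections)
        assert full.r1 <= start.r1

    def test_wrong_tight_restraints_worsen_r1(self, p21c_structure, p21c_reflections):
        ur = refine(p21c_structure, p21c_reflections)
        labels = [s.label for s in p21c_structure.sites]
        cart = ur.structure.cart_coords()
        graph = perceive_bonds([s.element for s in p21c_structure.sites], cart)
        rs = generate_restraints(labels, cart, graph)
        wrong = RestraintSet(
            [Restraint(r.kind, r.atoms, r.target + 0.05, r.su) for r in rs.restraints],
            "wrong",
        )
        rr = refine(p21c_structure, p21c_reflections, wrong)
        assert rr.r1 > ur.r1
        assert rr.restraint_rms < 0.05  # the tight restraints are nearly enforced

    def test_loose_restraints_reproduce_unrestrained(
        self, p21c_structure, p21c_reflections
    ):
        pert = perturb_structure(p21c_structure, 0.04, seed=9)
        ur = refine(pert, p21c_reflections)
        labels = [s.label for s in p21c_structure.sites]
        cart = ur.structure.cart_coords()
        graph = perceive_bonds([s.element for s in p21c_structure.sites], cart)
        rs = generate_restraints(labels, cart, graph)
        loose = RestraintSet(
            [Restraint(r.kind, r.atoms, r.target, 1e6) for r in rs.restraints],
            "loose",
        )
        rr = refine(pert, p21c_reflections, loose)
        assert rmscd(rr.structure, ur.structure) < 1e-5

    def test_riding_hydrogens_follow_parent(self):
        s = make_toy_structure(
            FixtureSpec(seed=23, spacegroup="P-1", n_heavy_atoms=5, n_hydrogens=2)
        )
        refl = simulate_reflections(s, d_min=0.9, noise_fraction=0.0, seed=2)
        pert = perturb_structure(s, 0.03, seed=3)
        res = refine(pert, refl)
        assert rmscd(res.structure, s) < 1e-3
        # hydrogens recovered too (they rode back with their parents)
        assert rmscd(res.structure, s, include_hydrogen=True) < 2e-3
        # riding Uiso = multiplier x Ueq(parent)
        graph = perceive_bonds([a.element for a in s.sites], s.cart_coords())
        for i, site in enumerate(res.structure.sites):
            if site.is_hydrogen:
                parent = [j for j in graph.neighbors(i)
                          if not s.sites[j].is_hydrogen][0]
                from xtalbench.refine import _u_equiv

                assert site.u_iso == pytest.approx(
                    2.4 * _u_equiv(res.structure, parent), rel=1e-9
                )

    def test_invalid_options(self):
        with pytest.raises(ValueError):
            RefinementOptions(damping=0.0)
        with pytest.raises(ValueError):
            RefinementOptions(max_cycles=0)


class TestDeltaR1:
    def test_identical_results_zero(self, p21c_structure, p21c_reflections):
        ur = refine(p21c_structure, p21c_reflections)
        assert delta_r1(ur, ur) == 0.0

    def test_self_consistency(self, p21c_structure, p21c_reflections):
        pert = perturb_structure(p21c_structure, 0.05, seed=42)
        ur = refine(pert, p21c_reflections)
        labels = [s.label for s in p21c_structure.sites]
        cart = ur.structure.cart_coords()
        graph = perceive_bonds([s.element for s in p21c_structure.sites], cart)
        rs = generate_restraints(labels, cart, graph)
        rr = refine(pert, p21c_reflections, rs)
        assert abs(delta_r1(rr, ur)) < 1e-4

    def test_monotone_in_target_offset(self, p21c_structure, p21c_reflections):
        ur = refine(p21c_structure, p21c_reflections)
        labels = [s.label for s in p21c_structure.sites]
        cart = ur.structure.cart_coords()
        graph = perceive_bonds([s.element for s in p21c_structure.sites], cart)
        rs = generate_restraints(labels, cart, graph)
        values = []
        for off in (0.02, 0.04):
            shifted = RestraintSet(
                [Restraint(r.kind, r.atoms, r.target + off, r.su)
                 for r in rs.restraints],
                "off",
            )
            rr = refine(p21c_structure, p21c_reflections, shifted)
            values.append(delta_r1(rr, ur))
        assert 0 < values[0] < values[1]

    def test_mismatched_reflections_rejected(self, p21c_structure):
        r1 = simulate_reflections(p21c_structure, d_min=1.0, seed=1)
        r2 = simulate_reflections(p21c_structure, d_min=1.2, seed=1)
        a = refine(p21c_structure, r1)
        b = refine(p21c_structure, r2)
        with pytest.raises(ValueError):
            delta_r1(a, b)
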