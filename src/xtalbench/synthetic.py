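"""Deterministic toy crystal structures, rigid-body ADPs and simulated
diffraction data.

The generator emulates the regime of very low temperature, high-resolution
small-molecule work: a single connected organic molecule at a general
position, anisotropic ADPs produced by a small rigid-body (TLS) motion, and
Fo² simulated from the IAM structure-factor engine with optional fractional
Gaussian noise. Every stage of the pipeline is therefore testable with no
external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import (
    AtomSite,
    CrystalStructure,
    SpaceGroup,
    UnitCell,
    adp_cartesian_to_cif,
    orthogonalization_matrix,
    reciprocal_metric_tensor,
)
from .io import Reflection, ReflectionSet
from .io import parse_symop_xyz
from .refine import calc_structure_factors
from .thermal import TLSModel, rigid_body_adps
from .connectivity import perceive_bonds

__all__ = [
    "SPACE_GROUPS",
    "FixtureSpec",
    "make_toy_structure",
    "simulate_reflections",
    "perturb_structure",
    "default_tls",
    "TOY_PROFILES",
]

#: common small-molecule space groups, operations given explicitly
SPACE_GROUPS = {
    "P1": ["x, y, z"],
    "P-1": ["x, y, z", "-x, -y, -z"],
    "P21": ["x, y, z", "-x, y+1/2, -z"],
    "P21/c": ["x, y, z", "-x, y+1/2, -z+1/2", "-x, -y, -z", "x, -y+1/2, z+1/2"],
}

_MONOCLINIC = {"P21", "P21/c"}


def make_spacegroup(name: str) -> SpaceGroup:
    if name not in SPACE_GROUPS:
        raise ValueError(f"unknown space group {name!r}; choose from {sorted(SPACE_GROUPS)}")
    return SpaceGroup(name, tuple(parse_symop_xyz(s) for s in SPACE_GROUPS[name]))


@dataclass
class FixtureSpec:
    seed: int = 0
    spacegroup: str = "P1"
    n_heavy_atoms: int = 5
    n_hydrogens: int = 0
    n_molecules: int = 1  # >1 emulates multi-component asymmetric units
    elements: tuple = ("C", "N", "O")
    cell_margin: float = 6.0  # Å of padding around the molecule per axis
    noise_fraction: float = 0.0
    d_min: float = 0.8
    tls: TLSModel | None = None

    def __post_init__(self) -> None:
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if self.n_heavy_atoms < 1:
            raise ValueError("need at least one heavy atom")


def default_tls(rng: np.random.Generator, scale_t: float = 0.01,
                scale_l: float = 0.0005) -> TLSModel:
    """Small rigid-body motion typical of ~20 K data: T ≈ 0.01 Å², L around
    half a millirad² (libration corrections of a few 10⁻⁴ Å on bonds)."""
    def rand_psd(scale):
        a = rng.normal(size=(3, 3)) * scale
        return a @ a.T / 3.0

    t = scale_t * np.eye(3) + rand_psd(np.sqrt(scale_t) * 0.3)
    l = scale_l * np.eye(3) + rand_psd(np.sqrt(scale_l) * 0.3)
    s = rng.normal(size=(3, 3)) * np.sqrt(scale_t * scale_l) * 0.2
    s -= np.trace(s) / 3.0 * np.eye(3)
    return TLSModel(t, l, s, origin=np.zeros(3))


def _grow_molecule(rng: np.random.Generator, spec: FixtureSpec, max_tries: int = 200):
    """Connected molecule with bonds sampled from 1.2–1.6 Å and no
    non-bonded heavy-atom contact below 2.0 Å."""
    from .connectivity import covalent_radius

    n = spec.n_heavy_atoms
    elements = [str(rng.choice(spec.elements)) for _ in range(n)]
    elements[0] = "C"  # anchor on carbon for predictable bonding
    radii = [covalent_radius(e) for e in elements]
    for _ in range(max_tries):
        coords = [np.zeros(3)]
        parents = [-1]
        ok = True
        for i in range(1, n):
            placed = False
            for _try in range(50):
                parent = int(rng.integers(0, i))
                # within the 1.2-1.6 A organic range and always below the
                # bond-perception cutoff for this element pair
                rsum = radii[i] + radii[parent]
                length = rng.uniform(
                    max(1.2, 0.9 * rsum), min(1.6, 1.1 * rsum)
                )
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                pos = coords[parent] + length * v
                dists = np.linalg.norm(np.array(coords) - pos, axis=1)
                dists[parent] = np.inf
                if np.all(dists >= 2.0):
                    coords.append(pos)
                    parents.append(parent)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            elements = list(elements)
            coords = np.array(coords)
            # hydrogens on under-coordinated heavy atoms
            h_coords = []
            degree = np.bincount(
                [p for p in parents if p >= 0], minlength=n
            ) + np.array([1 if p >= 0 else 0 for p in parents])
            host_order = [i for i in range(n) for _ in range(max(0, 3 - int(degree[i])))]
            for j in range(spec.n_hydrogens):
                if j >= len(host_order):
                    break
                host = host_order[j]
                for _try in range(50):
                    v = rng.normal(size=3)
                    v /= np.linalg.norm(v)
                    pos = coords[host] + 1.0 * v
                    d_heavy = np.linalg.norm(coords - pos, axis=1)
                    d_heavy[host] = np.inf
                    d_h = (
                        np.linalg.norm(np.array(h_coords) - pos, axis=1)
                        if h_coords
                        else np.array([np.inf])
                    )
                    if np.all(d_heavy >= 1.7) and np.all(d_h >= 1.3):
                        h_coords.append(pos)
                        elements.append("H")
                        break
            if h_coords:
                coords = np.vstack([coords, np.array(h_coords)])
            return elements, coords
    raise RuntimeError(
        "could not pack a clash-free molecule; increase the cell or reduce atoms"
    )


def make_toy_structure(spec: FixtureSpec) -> CrystalStructure:
    """Deterministic toy structure in the requested space group.

    The molecule is centred, padded with ``cell_margin`` Å of empty space
    per axis, placed at a general position, and given anisotropic ADPs from
    the rigid-body TLS model (default: a small 20 K-like motion).
    """
    rng = np.random.default_rng(spec.seed)
    elements, cart = _grow_molecule(rng, spec)
    for _ in range(spec.n_molecules - 1):
        el2, c2 = _grow_molecule(rng, spec)
        offset = np.array([cart[:, 0].max() - c2[:, 0].min() + 3.5, 0.0, 0.0])
        elements = elements + el2
        cart = np.vstack([cart, c2 + offset])
    cart = cart - cart.mean(axis=0)

    extent = cart.max(axis=0) - cart.min(axis=0)
    lengths = extent + spec.cell_margin + rng.uniform(0, 1.0, size=3)
    if spec.spacegroup in _MONOCLINIC:
        angles = (90.0, rng.uniform(95.0, 110.0), 90.0)
    elif spec.spacegroup == "P1" or spec.spacegroup == "P-1":
        angles = tuple(rng.uniform(80.0, 100.0, size=3))
    else:
        angles = (90.0, 90.0, 90.0)
    cell = UnitCell(*lengths, *angles)
    sg = make_spacegroup(spec.spacegroup)

    m_inv = np.linalg.inv(orthogonalization_matrix(cell))
    shift = np.array([0.23, 0.31, 0.17]) + rng.uniform(-0.02, 0.02, size=3)
    frac = cart @ m_inv.T + shift

    tls = spec.tls or default_tls(rng)
    tls = TLSModel(tls.T, tls.L, tls.S, origin=cart.mean(axis=0))
    u_cart = rigid_body_adps(cart, tls)

    # hydrogens follow the constrained-isotropic convention of the
    # refinement engine: Uiso(H) = 2.4 x Ueq(bonded parent)
    graph = perceive_bonds(elements, cart)
    u_iso_h = {}
    for i, el in enumerate(elements):
        if el == "H":
            parents = [j for j in graph.neighbors(i) if elements[j] != "H"]
            host = parents[0] if parents else i
            u_iso_h[i] = 2.4 * float(np.trace(u_cart[host]) / 3.0)

    sites = []
    counters: dict[str, int] = {}
    for i, el in enumerate(elements):
        counters[el] = counters.get(el, 0) + 1
        u6 = adp_cartesian_to_cif(u_cart[i], cell)
        sites.append(
            AtomSite(
                label=f"{el}{counters[el]}",
                element=el,
                frac=frac[i],
                occupancy=1.0,
                u_iso=u_iso_h[i] if el == "H"
                else float(np.trace(u_cart[i]) / 3.0),
                u_aniso=None if el == "H" else u6,
            )
        )
    structure = CrystalStructure(cell, sg, sites)
    _assert_fixture_sane(structure)
    return structure


def _assert_fixture_sane(structure: CrystalStructure) -> None:
    cart = structure.cart_coords()
    heavy = np.array([not s.is_hydrogen for s in structure.sites])
    hc = cart[heavy]
    graph = perceive_bonds([s.element for s, h in zip(structure.sites, heavy) if h], hc)
    bonded = set(graph.edges())
    for i in range(len(hc)):
        for j in range(i + 1, len(hc)):
            if (i, j) not in bonded:
                assert np.linalg.norm(hc[i] - hc[j]) >= 2.0 - 1e-9


def unique_hkl(structure: CrystalStructure, d_min: float) -> np.ndarray:
    """All symmetry-unique reflections with d ≥ d_min (Friedel pairs merged)."""
    cell = structure.cell
    g_star = reciprocal_metric_tensor(cell)
    limits = np.ceil(np.array([cell.a, cell.b, cell.c]) / d_min).astype(int)
    rots = [op.rot_array for op in structure.spacegroup.operations]

    out = []
    for h in itertools.product(*(range(-l, l + 1) for l in limits)):
        hv = np.array(h)
        if not hv.any():
            continue
        if float(hv @ g_star @ hv) > 1.0 / d_min**2:
            continue
        # canonical representative over the Laue group (rotations ∪ Friedel)
        images = []
        for r in rots:
            ht = tuple(int(x) for x in hv @ r)
            images.append(ht)
            images.append(tuple(-x for x in ht))
        if tuple(h) == max(images):
            out.append(h)
    return np.array(sorted(out), dtype=int)


def simulate_reflections(
    structure: CrystalStructure,
    d_min: float = 0.8,
    noise_fraction: float = 0.0,
    seed: int = 0,
    sigma_floor: float | None = None,
) -> ReflectionSet:
    """Fo² = |F_calc|²·(1 + ε), ε ~ N(0, noise_fraction), for all unique
    reflections with d ≥ d_min; σ = noise_fraction·|F_calc|² + floor."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hkl = unique_hkl(structure, d_min)
    f = calc_structure_factors(structure, hkl, default_u_iso=0.01)
    fc_sq = np.abs(f) ** 2
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_fraction, size=len(fc_sq)) if noise_fraction else 0.0
    fo_sq = fc_sq * (1.0 + eps)
    floor = sigma_floor if sigma_floor is not None else max(
        1e-4 * float(np.median(fc_sq)), 1e-10
    )
    sigma = noise_fraction * fc_sq + floor
    refl = [
        Reflection(tuple(int(x) for x in h), float(fo), float(sg))
        for h, fo, sg in zip(hkl, fo_sq, sigma)
    ]
    return ReflectionSet(refl)


def perturb_structure(
    structure: CrystalStructure, amplitude: float, seed: int = 0
) -> CrystalStructure:
    """Isotropic Gaussian Cartesian displacement (sd = amplitude per axis)
    of the non-hydrogen atoms; hydrogens ride on their bonded parent."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    out = structure.copy()
    if amplitude == 0:
        return out
    rng = np.random.default_rng(seed)
    m_inv = np.linalg.inv(orthogonalization_matrix(structure.cell))

    # hydrogen parents from current geometry
    elements = [s.element for s in out.sites]
    graph = perceive_bonds(elements, out.cart_coords())
    shifts = {}
    for i, s in enumerate(out.sites):
        if not s.is_hydrogen:
            shifts[i] = rng.normal(0.0, amplitude, size=3)
    for i, s in enumerate(out.sites):
        if s.is_hydrogen:
            heavy = [j for j in graph.neighbors(i) if not out.sites[j].is_hydrogen]
            shifts[i] = shifts[heavy[0]] if heavy else np.zeros(3)
    for i, s in enumerate(out.sites):
        s.frac = s.frac + m_inv @ shifts[i]
    return out


#: seeded fixture profiles spanning the supported space groups, including a
#: two-molecule-ASU case for multi-component asymmetric units
TOY_PROFILES = {
    "p1_small": FixtureSpec(seed=11, spacegroup="P1", n_heavy_atoms=4),
    "p-1_medium": FixtureSpec(seed=12, spacegroup="P-1", n_heavy_atoms=6),
    "p21_medium": FixtureSpec(seed=13, spacegroup="P21", n_heavy_atoms=6),
    "p21c_medium": FixtureSpec(seed=14, spacegroup="P21/c", n_heavy_atoms=7),
    "p-1_two_mol": FixtureSpec(
        seed=15, spacegroup="P-1", n_heavy_atoms=4, n_hydrogens=2, n_molecules=2
    ),
}
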