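"""Bond perception, 1–3 pair enumeration, extended-connectivity invariants
and figure-of-merit atom matching.

Bonds are perceived with Cordero-style single-bond covalent radii and a
multiplicative tolerance; extended connectivity follows the Morgan-style
iterative neighbourhood refinement used for canonical atom ranking; atom
matching combines EC equality, positional similarity, mass and partial
charge into a single score and assigns greedily.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "BondGraph",
    "AtomMapping",
    "perceive_bonds",
    "angle_pairs",
    "extended_connectivity",
    "match_atoms",
    "MatchWeights",
]

#: bond accepted when d <= BOND_TOL * (r_cov_i + r_cov_j)
BOND_TOL = 1.15
MIN_BOND = 0.3


def covalent_radius(element: str) -> float:
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {element!r}")
    return el.covalent_r


def atomic_mass(element: str) -> float:
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {element!r}")
    return el.weight


@dataclass
class BondGraph:
    """Simple molecular graph over atom indices.

    ``graph`` is a networkx Graph whose nodes carry ``element`` and
    ``is_hydrogen`` and whose edges carry ``length`` (Å).
    """

    graph: nx.Graph

    @classmethod
    def from_edges(cls, elements, coords, edges) -> "BondGraph":
        """Explicit-topology constructor (edge lengths from the coordinates)."""
        coords = np.asarray(coords, dtype=float)
        g = nx.Graph()
        for i, e in enumerate(elements):
            g.add_node(i, element=e, is_hydrogen=e.upper() in ("H", "D"))
        for i, j in edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            g.add_edge(int(i), int(j),
                       length=float(np.linalg.norm(coords[i] - coords[j])))
        return cls(g)

    @property
    def n_atoms(self) -> int:
        return self.graph.number_of_nodes()

    def edges(self):
        return sorted((min(i, j), max(i, j)) for i, j in self.graph.edges)

    def bond_length(self, i: int, j: int) -> float:
        return self.graph.edges[i, j]["length"]

    def element(self, i: int) -> str:
        return self.graph.nodes[i]["element"]

    def is_hydrogen(self, i: int) -> bool:
        return self.graph.nodes[i]["is_hydrogen"]

    def neighbors(self, i: int):
        return sorted(self.graph.neighbors(i))


def perceive_bonds(elements, coords, tol: float = BOND_TOL) -> BondGraph:
    """Distance-criterion bond perception; hydrogens are kept monovalent
    (bonded to their nearest eligible heavy atom only)."""
    coords = np.asarray(coords, dtype=float)
    n = len(elements)
    radii = np.array([covalent_radius(e) for e in elements])
    is_h = np.array([e.upper() in ("H", "D") for e in elements])

    g = nx.Graph()
    for i, e in enumerate(elements):
        g.add_node(i, element=e, is_hydrogen=bool(is_h[i]))
    if n < 2:
        return BondGraph(g)

    d = cdist(coords, coords)
    cut = tol * (radii[:, None] + radii[None, :])
    cand = (d <= cut) & (d > MIN_BOND)
    np.fill_diagonal(cand, False)

    for i in range(n):
        if is_h[i]:
            continue
        for j in range(i + 1, n):
            if not is_h[j] and cand[i, j]:
                g.add_edge(i, j, length=float(d[i, j]))
    # hydrogens: one bond each, to the nearest eligible partner
    for i in np.nonzero(is_h)[0]:
        eligible = [j for j in range(n) if j != i and cand[i, j] and not is_h[j]]
        if not eligible:
            eligible = [j for j in range(n) if j != i and cand[i, j]]
        if eligible:
            j = min(eligible, key=lambda j: d[i, j])
            g.add_edge(int(i), int(j), length=float(d[i, j]))
    return BondGraph(g)


def angle_pairs(graph: BondGraph, exclude_hydrogen: bool = True) -> list:
    """Distinct 1–3 pairs (i, k) with apex j, one per bonded path i–j–k.

    With ``exclude_hydrogen`` (the default), pairs where any of i, j, k is a
    hydrogen are dropped — angles involving hydrogen are not restrained.
    """
    pairs = {}
    for j in graph.graph.nodes:
        nbrs = graph.neighbors(j)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = nbrs[a], nbrs[b]
                if exclude_hydrogen and (
                    graph.is_hydrogen(i) or graph.is_hydrogen(j) or graph.is_hydrogen(k)
                ):
                    continue
                key = (min(i, k), max(i, k))
                pairs.setdefault(key, key + (j,))
    return sorted(pairs.values())


def extended_connectivity(graph: BondGraph, max_iter: int = 100) -> np.ndarray:
    """Morgan-style extended-connectivity invariants.

    Seeded with (element, degree) and refined until the partition into
    equivalence classes stops changing. Returned class ids are dense ranks
    of permutation-invariant labels, so symmetric atoms share a value and
    the multiset of values is invariant under relabelling the input.
    """
    nodes = sorted(graph.graph.nodes)
    labels = {
        i: (graph.element(i), graph.graph.degree[i]) for i in nodes
    }
    ranks = _dense_ranks(labels, nodes)
    for _ in range(max_iter):
        new_labels = {
            i: (ranks[i], tuple(sorted(ranks[j] for j in graph.neighbors(i))))
            for i in nodes
        }
        new_ranks = _dense_ranks(new_labels, nodes)
        if len(set(new_ranks.values())) == len(set(ranks.values())):
            ranks = new_ranks
            break
        ranks = new_ranks
    return np.array([ranks[i] for i in nodes], dtype=int)


def _dense_ranks(labels: dict, nodes) -> dict:
    order = {lab: r for r, lab in enumerate(sorted(set(labels.values())))}
    return {i: order[labels[i]] for i in nodes}


@dataclass(frozen=True)
class MatchWeights:
    """Relative weights of the combined figure of merit (EC ≫ position ≫
    mass ≈ charge)."""

    ec: float = 100.0
    position: float = 10.0
    mass: float = 1.0
    charge: float = 1.0


@dataclass
class AtomMapping:
    """Bijection a_index → b_index over non-hydrogen atoms (hydrogens are
    appended by parent correspondence when present in both structures)."""

    pairs: dict
    score: dict

    def __len__(self) -> int:
        return len(self.pairs)

    def inverse(self) -> dict:
        return {v: k for k, v in self.pairs.items()}


def _formula(elements) -> dict:
    out: dict[str, int] = {}
    for e in elements:
        out[e.capitalize()] = out.get(e.capitalize(), 0) + 1
    return out


def match_atoms(
    elements_a,
    coords_a,
    elements_b,
    coords_b,
    charges_a=None,
    charges_b=None,
    weights: MatchWeights = MatchWeights(),
    superpose: bool = False,
) -> AtomMapping:
    """Match atoms of structure B onto structure A by a combined figure of
    merit (extended connectivity, position, mass, partial charge).

    Heavy atoms are assigned greedily on the score, ties broken by smallest
    Cartesian distance then label order; hydrogens are mapped afterwards by
    parent-atom correspondence.
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    heavy_a = [i for i, e in enumerate(elements_a) if e.upper() not in ("H", "D")]
    heavy_b = [i for i, e in enumerate(elements_b) if e.upper() not in ("H", "D")]
    fa = _formula([elements_a[i] for i in heavy_a])
    fb = _formula([elements_b[i] for i in heavy_b])
    if fa != fb:
        raise ValueError(f"non-hydrogen composition mismatch: {fa} vs {fb}")

    ga = perceive_bonds(elements_a, coords_a)
    gb = perceive_bonds(elements_b, coords_b)
    ec_a = extended_connectivity(ga)
    ec_b = extended_connectivity(gb)

    xb = coords_b
    if superpose:
        xb = _kabsch_superpose(coords_b, coords_a, heavy_b, heavy_a)

    # candidate costs over same-element heavy pairs
    entries = []
    for i in heavy_a:
        for j in heavy_b:
            if elements_a[i].capitalize() != elements_b[j].capitalize():
                continue
            dist = float(np.linalg.norm(coords_a[i] - xb[j]))
            cost = weights.ec * float(ec_a[i] != ec_b[j]) + weights.position * dist
            cost += weights.mass * abs(atomic_mass(elements_a[i]) - atomic_mass(elements_b[j]))
            if charges_a is not None and charges_b is not None:
                cost += weights.charge * abs(charges_a[i] - charges_b[j])
            entries.append((cost, dist, i, j))
    entries.sort()

    pairs: dict[int, int] = {}
    score: dict[int, float] = {}
    used_b: set[int] = set()
    for cost, _dist, i, j in entries:
        if i in pairs or j in used_b:
            continue
        pairs[i] = j
        used_b.add(j)
        score[i] = cost
    if len(pairs) != len(heavy_a):
        raise ValueError("could not establish a bijection on non-hydrogen atoms")

    # hydrogens by parent correspondence, nearest-first
    h_a = [i for i in range(len(elements_a)) if i not in heavy_a]
    for i in h_a:
        parents = ga.neighbors(i)
        if not parents or parents[0] not in pairs:
            continue
        pb = pairs[parents[0]]
        candidates = [j for j in gb.neighbors(pb) if gb.is_hydrogen(j) and j not in used_b]
        if not candidates:
            continue
        j = min(candidates, key=lambda j: float(np.linalg.norm(coords_a[i] - xb[j])))
        pairs[i] = j
        used_b.add(j)
        score[i] = float(np.linalg.norm(coords_a[i] - xb[j]))
    return AtomMapping(pairs, score)


def _kabsch_superpose(x, ref, idx_x, idx_ref) -> np.ndarray:
    """Best-fit superposition of x onto ref using the given index subsets."""
    p = x[idx_x] - x[idx_x].mean(axis=0)
    q = ref[idx_ref] - ref[idx_ref].mean(axis=0)
    h = p.T @ q
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (x - x[idx_x].mean(axis=0)) @ r.T + ref[idx_ref].mean(axis=0)
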