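"""Structure-specific distance restraints from optimized coordinates.

Every bonded pair receives a tight 1–2 distance restraint (default s.u.
0.0005 Å) and every angle not involving hydrogen a softer 1–3
distance restraint (default s.u. 0.002 Å), the targets being the distances
found in the optimized geometry. A thermal-motion correction can shift
bond targets by a constant elongation and propagate that elongation to the
1–3 targets through the law of cosines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import BondGraph, angle_pairs

__all__ = [
    "Restraint",
    "RestraintSet",
    "SU_PROFILES",
    "generate_restraints",
    "apply_tma_correction",
    "evaluate_restraints",
]

#: restraint standard-uncertainty profiles (Å): `tight` is the diagnostic
#: setting; `practical` is the looser setting for real-life refinements.
SU_PROFILES = {
    "tight": {"bond": 0.0005, "angle": 0.002},
    "practical": {"bond": 0.02, "angle": 0.03},
}


@dataclass(frozen=True)
class Restraint:
    kind: str  # "bond_12" | "angle_13"
    atoms: tuple  # ordered label pair
    target: float  # Å
    su: float  # Å

    def __post_init__(self) -> None:
        if self.kind not in ("bond_12", "angle_13"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.target <= 0 or self.su <= 0:
            raise ValueError("restraint target and s.u. must be positive")
        a, b = self.atoms
        if a.upper() == b.upper():
            raise ValueError("restraint atoms must be distinct")
        object.__setattr__(self, "atoms", (str(a), str(b)))

    @property
    def unordered_key(self) -> tuple:
        return tuple(sorted(a.upper() for a in self.atoms))


@dataclass
class RestraintSet:
    restraints: list
    source_tag: str = "unknown"

    def __post_init__(self) -> None:
        seen = set()
        for r in self.restraints:
            key = (r.kind, r.unordered_key)
            if key in seen:
                raise ValueError(f"duplicate restraint {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.restraints)

    def by_kind(self, kind: str) -> list:
        return [r for r in self.restraints if r.kind == kind]


def generate_restraints(
    labels,
    coords,
    graph: BondGraph,
    su_bond: float = SU_PROFILES["tight"]["bond"],
    su_angle: float = SU_PROFILES["tight"]["angle"],
    restrain_h_bonds: bool = True,
    restrain_h_angles: bool = False,
    source_tag: str = "optimized",
) -> RestraintSet:
    """One 1–2 restraint per bond and one 1–3 restraint per eligible angle,
    targets measured on the supplied Cartesian coordinates (Å).

    If a 1–3 pair is also bonded (three-membered ring), only the bond
    restraint is kept.
    """
    coords = np.asarray(coords, dtype=float)
    if graph.n_atoms != len(labels) or len(labels) != len(coords):
        raise ValueError("graph, labels and coordinates must be the same length")

    out: list[Restraint] = []
    bonded = set()
    for i, j in graph.edges():
        bonded.add((i, j))
        if not restrain_h_bonds and (graph.is_hydrogen(i) or graph.is_hydrogen(j)):
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        out.append(Restraint("bond_12", (labels[i], labels[j]), d, su_bond))

    for i, k, _j in angle_pairs(graph, exclude_hydrogen=not restrain_h_angles):
        if (min(i, k), max(i, k)) in bonded:
            continue  # 3-ring: the pair is already a bond restraint
        d = float(np.linalg.norm(coords[i] - coords[k]))
        out.append(Restraint("angle_13", (labels[i], labels[k]), d, su_angle))
    return RestraintSet(out, source_tag=source_tag)


def apply_tma_correction(
    restraints: RestraintSet,
    delta: float,
    labels,
    coords,
    graph: BondGraph,
) -> RestraintSet:
    """Shift bond targets by a constant thermal-motion elongation ``delta``
    and propagate it to 1–3 targets through the law of cosines.

    For a 1–3 distance D over bonds d₁, d₂ with apex angle θ, elongating
    both bonds by δ changes D to first order by
    ΔD = [(d₁ − d₂ cosθ) + (d₂ − d₁ cosθ)]·δ / D.
    The reference geometry supplies d₁, d₂ and θ for every 1–3 restraint.
    """
    coords = np.asarray(coords, dtype=float)
    index = {lab.upper(): i for i, lab in enumerate(labels)}

    # apex lookup: unordered 1-3 pair -> apex atom index
    apex = {}
    for i, k, j in angle_pairs(graph, exclude_hydrogen=False):
        apex[tuple(sorted((i, k)))] = j

    out = []
    for r in restraints.restraints:
        if r.kind == "bond_12":
            out.append(Restraint(r.kind, r.atoms, r.target + delta, r.su))
            continue
        try:
            i, k = (index[a.upper()] for a in r.atoms)
            j = apex[tuple(sorted((i, k)))]
        except KeyError as exc:
            raise ValueError(
                f"no apex geometry for 1-3 restraint {r.atoms}"
            ) from exc
        v1 = coords[i] - coords[j]
        v2 = coords[k] - coords[j]
        d1 = float(np.linalg.norm(v1))
        d2 = float(np.linalg.norm(v2))
        cos_t = float(v1 @ v2) / (d1 * d2)
        d13 = float(np.linalg.norm(coords[i] - coords[k]))
        dd = ((d1 - d2 * cos_t) + (d2 - d1 * cos_t)) * delta / d13
        out.append(Restraint(r.kind, r.atoms, r.target + dd, r.su))
    return RestraintSet(out, source_tag=restraints.source_tag + "+tma")


def evaluate_restraints(restraints: RestraintSet, labels, coords) -> np.ndarray:
    """Residuals (model distance − target) per restraint, in Å."""
    coords = np.asarray(coords, dtype=float)
    index = {lab.upper(): i for i, lab in enumerate(labels)}
    res = []
    for r in restraints.restraints:
        i, j = (index[a.upper()] for a in r.atoms)
        res.append(float(np.linalg.norm(coords[i] - coords[j])) - r.target)
    return np.array(res)
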