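"""RMSCD and geometry tables for scoring optimized against experimental
structures.

The root mean square Cartesian displacement between two structures sharing
a unit cell is

    RMSCD = sqrt( (1/n) Σᵢ |G·(r₁ᵢ − r₂ᵢ)|² )

with G the fractional→Cartesian matrix and every per-atom fractional
difference wrapped to the nearest periodic image. Hydrogens are omitted by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import AtomMapping, BondGraph, angle_pairs
from .core import CrystalStructure, orthogonalization_matrix

__all__ = ["ComparisonReport", "rmscd", "comparison_report", "geometry_tables"]

CELL_RTOL = 1e-4


@dataclass
class ComparisonReport:
    rmscd: float
    per_atom_displacements: dict
    n_atoms_compared: int
    rigid_shift_removed: bool = False


def _displacements(
    struct_a: CrystalStructure,
    struct_b: CrystalStructure,
    mapping: AtomMapping | None,
    include_hydrogen: bool,
    remove_rigid_shift: bool,
):
    if not struct_a.cell.isclose(struct_b.cell, rtol=CELL_RTOL):
        raise ValueError(
            "unit cells differ beyond tolerance; RMSCD is defined at a fixed cell"
        )
    m = orthogonalization_matrix(struct_a.cell)
    if mapping is None:
        if struct_a.n_sites != struct_b.n_sites:
            raise ValueError("structures differ in size and no mapping was given")
        pairs = {i: i for i in range(struct_a.n_sites)}
    else:
        pairs = mapping.pairs

    labels, disp = [], []
    for i, j in sorted(pairs.items()):
        sa, sb = struct_a.sites[i], struct_b.sites[j]
        if sa.is_hydrogen and not include_hydrogen:
            continue
        df = sa.frac - sb.frac
        df = (df + 0.5) % 1.0 - 0.5  # nearest image, component-wise
        labels.append(sa.label)
        disp.append(m @ df)
    if not disp:
        raise ValueError("no atoms to compare")
    disp = np.array(disp)
    if remove_rigid_shift:
        disp = disp - disp.mean(axis=0)
    return labels, disp


def rmscd(
    struct_a: CrystalStructure,
    struct_b: CrystalStructure,
    mapping: AtomMapping | None = None,
    include_hydrogen: bool = False,
    remove_rigid_shift: bool = False,
) -> float:
    """RMSCD in Å over mapped (by default non-hydrogen) atoms."""
    _labels, disp = _displacements(
        struct_a, struct_b, mapping, include_hydrogen, remove_rigid_shift
    )
    return float(np.sqrt(np.mean(np.sum(disp**2, axis=1))))


def comparison_report(
    struct_a: CrystalStructure,
    struct_b: CrystalStructure,
    mapping: AtomMapping | None = None,
    include_hydrogen: bool = False,
    remove_rigid_shift: bool = False,
) -> ComparisonReport:
    labels, disp = _displacements(
        struct_a, struct_b, mapping, include_hydrogen, remove_rigid_shift
    )
    norms = np.linalg.norm(disp, axis=1)
    return ComparisonReport(
        rmscd=float(np.sqrt(np.mean(norms**2))),
        per_atom_displacements=dict(zip(labels, norms.tolist())),
        n_atoms_compared=len(labels),
        rigid_shift_removed=remove_rigid_shift,
    )


def geometry_tables(labels, coords, graph: BondGraph):
    """Deterministically sorted bond and 1–3 distance tables (pandas)."""
    coords = np.asarray(coords, dtype=float)
    bond_rows = [
        {
            "atom1": labels[i],
            "atom2": labels[j],
            "distance": float(np.linalg.norm(coords[i] - coords[j])),
        }
        for i, j in graph.edges()
    ]
    angle_rows = [
        {
            "atom1": labels[i],
            "atom3": labels[k],
            "apex": labels[j],
            "distance": float(np.linalg.norm(coords[i] - coords[k])),
        }
        for i, k, j in angle_pairs(graph, exclude_hydrogen=False)
    ]
    bonds = pd.DataFrame(bond_rows, columns=["atom1", "atom2", "distance"])
    angles = pd.DataFrame(angle_rows, columns=["atom1", "atom3", "apex", "distance"])
    bonds = bonds.sort_values(["atom1", "atom2"], ignore_index=True)
    angles = angles.sort_values(["atom1", "atom3"], ignore_index=True)
    return bonds, angles
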