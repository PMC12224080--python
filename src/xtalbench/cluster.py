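"""Molecule-in-cluster generation.

The asymmetric unit (free atoms) is surrounded by a fixed shell of whole
symmetry-generated ASU copies: a copy enters the environment when any of
its atoms lies within a contact threshold (default 3.75 Å) of any free
atom. Copies are always complete — atoms are never clipped out of an
included image — which is what makes the shell usable as a rigid
environment for an external optimizer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import (
    CrystalStructure,
    apply_symmetry,
    orthogonalization_matrix,
)
from .io import write_xyz

logger = logging.getLogger(__name__)

__all__ = ["Cluster", "EnvironmentCopy", "build_cluster", "export_cluster_xyz"]

DEFAULT_THRESHOLD = 3.75
OVERLAP_TOL = 0.2


@dataclass
class EnvironmentCopy:
    """One whole symmetry image of the ASU: generating operation index,
    lattice translation and Cartesian coordinates."""

    op_index: int
    lattice: tuple
    cart: np.ndarray
    min_distance: float
    atom_indices: np.ndarray = None  # indices into the ASU site list

    def __post_init__(self) -> None:
        if self.atom_indices is None:
            self.atom_indices = np.arange(len(self.cart))


@dataclass
class Cluster:
    free_elements: list
    free_cart: np.ndarray
    env_copies: list
    threshold: float

    @property
    def n_free(self) -> int:
        return len(self.free_elements)

    @property
    def n_env_atoms(self) -> int:
        return sum(len(c.cart) for c in self.env_copies)

    def env_cart(self) -> np.ndarray:
        if not self.env_copies:
            return np.empty((0, 3))
        return np.vstack([c.cart for c in self.env_copies])


def _perpendicular_thicknesses(m: np.ndarray) -> np.ndarray:
    """Distance between opposite cell faces along each axis (robust search
    range for oblique cells): t_i = V / area(face spanned by the others)."""
    v = abs(np.linalg.det(m))
    a, b, c = m[:, 0], m[:, 1], m[:, 2]
    areas = np.array(
        [
            np.linalg.norm(np.cross(b, c)),
            np.linalg.norm(np.cross(c, a)),
            np.linalg.norm(np.cross(a, b)),
        ]
    )
    return v / areas


def build_cluster(
    structure: CrystalStructure,
    threshold: float = DEFAULT_THRESHOLD,
    include_hydrogen: bool = True,
) -> Cluster:
    """Enumerate symmetry copies of the whole ASU over a safe lattice range
    and keep those with any atom within ``threshold`` of a free atom.

    The identity copy with zero lattice translation (the ASU itself) is
    excluded. Atoms of an included copy that overlap a free atom within
    0.2 Å (special positions) are dropped with a warning.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    m = orthogonalization_matrix(structure.cell)
    frac = structure.frac_coords()
    elements = [s.element for s in structure.sites]
    is_h = np.array([s.is_hydrogen for s in structure.sites])
    free_cart = frac @ m.T

    contact_idx = np.arange(len(elements)) if include_hydrogen else np.nonzero(~is_h)[0]
    free_contact = free_cart[contact_idx]

    # search range: threshold + ASU diameter, in units of perpendicular thickness
    diam = float(cdist(free_cart, free_cart).max()) if len(free_cart) > 1 else 0.0
    thick = _perpendicular_thicknesses(m)
    n_range = np.ceil((threshold + diam) / thick).astype(int) + 1

    copies = []
    for i_op, op in enumerate(structure.spacegroup.operations):
        base = np.array([apply_symmetry(op, f) for f in frac])
        for lat in itertools.product(
            range(-n_range[0], n_range[0] + 1),
            range(-n_range[1], n_range[1] + 1),
            range(-n_range[2], n_range[2] + 1),
        ):
            if i_op == 0 and lat == (0, 0, 0) and op.is_identity():
                continue
            cart = (base + np.asarray(lat, dtype=float)) @ m.T
            d = cdist(free_contact, cart[contact_idx] if not include_hydrogen else cart)
            dmin = float(d.min()) if d.size else np.inf
            if dmin <= threshold:
                full_d = cdist(free_cart, cart)
                keep = np.arange(len(cart))
                overlap = np.nonzero(full_d.min(axis=0) < OVERLAP_TOL)[0]
                if overlap.size:
                    logger.warning(
                        "copy (op %d, %s): dropping %d atom(s) overlapping the ASU",
                        i_op,
                        lat,
                        overlap.size,
                    )
                    keep = np.setdiff1d(keep, overlap)
                    cart = cart[keep]
                    if cart.size == 0:
                        continue
                copies.append(EnvironmentCopy(i_op, tuple(lat), cart, dmin, keep))
    copies.sort(key=lambda c: (c.min_distance, c.op_index, c.lattice))
    return Cluster(elements, free_cart, copies, threshold)


def export_cluster_xyz(cluster: Cluster, comment: str = "") -> tuple:
    """XYZ text (free atoms first, then environment) plus the 1-based list
    of free-atom indices — the fixed-atom contract for external optimizers."""
    elements = list(cluster.free_elements)
    coords = [cluster.free_cart]
    for copy in cluster.env_copies:
        elements.extend(cluster.free_elements[i] for i in copy.atom_indices)
        coords.append(copy.cart)
    text = write_xyz(elements, np.vstack(coords), comment or
                     f"cluster threshold={cluster.threshold} free={cluster.n_free}")
    free_indices = list(range(1, cluster.n_free + 1))
    return text, free_indices
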