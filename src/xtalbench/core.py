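"""Unit-cell metrics, space-group algebra and coordinate transformations.

Everything downstream (structure factors, clusters, RMSCD) is built on the
conventions fixed here:

* fractional coordinates are the internal representation; Cartesian
  coordinates appear only at API boundaries;
* the orthogonalization matrix ``M`` puts the ``a`` axis along ``x`` and
  ``b`` in the ``x``–``y`` plane, so that ``M @ frac`` is a Cartesian
  vector in Å and ``M.T @ M`` is the direct metric tensor;
* symmetry operations act as ``R @ frac + t`` with *no* implicit mod-1
  wrapping — wrapping is always an explicit, separate step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np

__all__ = [
    "UnitCell",
    "SymmetryOperation",
    "SpaceGroup",
    "AtomSite",
    "CrystalStructure",
    "orthogonalization_matrix",
    "cell_volume",
    "d_spacing",
    "apply_symmetry",
    "expand_to_p1",
    "transform_adp",
    "adp_cif_to_cartesian",
    "adp_cartesian_to_cif",
]

#: fractional-coordinate tolerance for merging special-position duplicates
SPECIAL_POSITION_TOL = 1e-4


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        # degenerate (flat) cells have zero volume
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if v2 <= 1e-12:
            raise ValueError("degenerate unit cell (zero volume)")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma], dtype=float)

    def isclose(self, other: "UnitCell", rtol: float = 1e-4) -> bool:
        return bool(
            np.allclose(self.lengths, other.lengths, rtol=rtol)
            and np.allclose(self.angles, other.angles, rtol=rtol)
        )


def orthogonalization_matrix(cell: UnitCell) -> np.ndarray:
    """Fractional→Cartesian matrix with a∥x and b in the x–y plane.

    ``M.T @ M`` equals the direct metric tensor.
    """
    a, b, c = cell.a, cell.b, cell.c
    ca, cb, cg = (np.cos(np.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = np.sin(np.radians(cell.gamma))
    v = np.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
    return np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * v / sg],
        ]
    )


def cell_volume(cell: UnitCell) -> float:
    """Cell volume in Å³ (|det M|)."""
    return float(abs(np.linalg.det(orthogonalization_matrix(cell))))


def metric_tensor(cell: UnitCell) -> np.ndarray:
    """Direct metric tensor G = Mᵀ M."""
    m = orthogonalization_matrix(cell)
    return m.T @ m


def reciprocal_metric_tensor(cell: UnitCell) -> np.ndarray:
    return np.linalg.inv(metric_tensor(cell))


def reciprocal_lengths(cell: UnitCell) -> np.ndarray:
    """Lengths of the reciprocal axes a*, b*, c* in Å⁻¹."""
    return np.sqrt(np.diag(reciprocal_metric_tensor(cell)))


def d_spacing(cell: UnitCell, hkl) -> float:
    """Resolution d of reflection hkl in Å: 1/d² = hᵀ G* h."""
    h = np.asarray(hkl, dtype=float)
    if not np.any(h):
        raise ValueError("d-spacing undefined for (0,0,0)")
    inv_d2 = float(h @ reciprocal_metric_tensor(cell) @ h)
    return 1.0 / np.sqrt(inv_d2)


@dataclass(frozen=True)
class SymmetryOperation:
    """Space-group operation (R, t): rotation in the crystal basis plus a
    rational translation, kept exact for closure checks."""

    rotation: tuple  # 3x3 nested tuple of ints in {-1, 0, 1}
    translation: tuple  # 3-tuple of Fraction in [0, 1)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=int)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        det = int(round(np.linalg.det(r)))
        if det not in (-1, 1):
            raise ValueError("rotation determinant must be ±1")
        object.__setattr__(self, "rotation", tuple(tuple(int(x) for x in row) for row in r))
        t = tuple(Fraction(x) % 1 for x in self.translation)
        object.__setattr__(self, "translation", t)

    @property
    def rot_array(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=int)

    @property
    def trans_array(self) -> np.ndarray:
        return np.array([float(x) for x in self.translation])

    def is_identity(self) -> bool:
        return self.rot_array.tolist() == np.eye(3, dtype=int).tolist() and all(
            x == 0 for x in self.translation
        )

    def compose(self, other: "SymmetryOperation") -> "SymmetryOperation":
        """self ∘ other, translation reduced mod 1."""
        r = self.rot_array @ other.rot_array
        t = [
            (sum(Fraction(int(self.rotation[i][j])) * other.translation[j] for j in range(3))
             + self.translation[i]) % 1
            for i in range(3)
        ]
        return SymmetryOperation(tuple(map(tuple, r)), tuple(t))

    def __str__(self) -> str:  # xyz triplet, e.g. "-x, y+1/2, -z+1/2"
        names = "xyz"
        parts = []
        for i in range(3):
            s = ""
            for j in range(3):
                v = self.rotation[i][j]
                if v == 1:
                    s += ("+" if s else "") + names[j]
                elif v == -1:
                    s += "-" + names[j]
            t = self.translation[i]
            if t != 0:
                s += f"+{t}"
            parts.append(s)
        return ", ".join(parts)


IDENTITY_OP = SymmetryOperation(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0, 0, 0))


@dataclass(frozen=True)
class SpaceGroup:
    """Hermann–Mauguin label plus the explicit operation list (identity included)."""

    name: str
    operations: tuple

    def __post_init__(self) -> None:
        ops = tuple(self.operations)
        if not ops:
            raise ValueError("space group needs at least the identity operation")
        if not any(op.is_identity() for op in ops):
            raise ValueError("identity operation missing")
        object.__setattr__(self, "operations", ops)

    def __len__(self) -> int:
        return len(self.operations)

    def is_closed(self) -> bool:
        """Closure under composition modulo lattice translations."""
        ops = set(self.operations)
        return all(a.compose(b) in ops for a in self.operations for b in self.operations)


@dataclass
class AtomSite:
    """One atom of the asymmetric unit.

    ``u_iso`` is the isotropic displacement parameter in Å²; ``u_aniso``
    holds the six CIF-convention components (U11, U22, U33, U12, U13, U23)
    when the atom is anisotropic.
    """

    label: str
    element: str
    frac: np.ndarray
    occupancy: float = 1.0
    u_iso: float | None = None
    u_aniso: np.ndarray | None = None  # (U11, U22, U33, U12, U13, U23)
    partial_charge: float | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("atom label must be non-empty")
        self.frac = np.asarray(self.frac, dtype=float).copy()
        if self.frac.shape != (3,) or not np.all(np.isfinite(self.frac)):
            raise ValueError(f"bad fractional coordinates for {self.label}")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"occupancy of {self.label} must be in (0, 1]")
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, dtype=float).copy()
            if self.u_aniso.shape != (6,):
                raise ValueError("u_aniso must have 6 components (CIF order)")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "AtomSite":
        return replace(
            self,
            frac=self.frac.copy(),
            u_aniso=None if self.u_aniso is None else self.u_aniso.copy(),
        )


def _sym6_to_mat(u6: np.ndarray) -> np.ndarray:
    u11, u22, u33, u12, u13, u23 = u6
    return np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])


def _mat_to_sym6(m: np.ndarray) -> np.ndarray:
    return np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])


def adp_cif_to_cartesian(u6, cell: UnitCell) -> np.ndarray:
    """CIF-convention Uij → Cartesian 3×3 U tensor (Å²).

    U_cart = (M N) U_cif (M N)ᵀ with N = diag(a*, b*, c*).
    """
    m = orthogonalization_matrix(cell)
    n = np.diag(reciprocal_lengths(cell))
    a = m @ n
    return a @ _sym6_to_mat(np.asarray(u6, dtype=float)) @ a.T


def adp_cartesian_to_cif(u_cart: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Cartesian 3×3 U tensor → six CIF-convention Uij."""
    m = orthogonalization_matrix(cell)
    n = np.diag(reciprocal_lengths(cell))
    a_inv = np.linalg.inv(m @ n)
    return _mat_to_sym6(a_inv @ np.asarray(u_cart, dtype=float) @ a_inv.T)


def transform_adp(op: SymmetryOperation, u6, cell: UnitCell) -> np.ndarray:
    """Transform CIF-convention Uij by a symmetry operation.

    Works through the dimensionless β tensor (β = 2π² N U N, N = diag(a*)),
    which transforms exactly as β' = R β Rᵀ for integer rotations R.
    """
    n = np.diag(reciprocal_lengths(cell))
    n_inv = np.linalg.inv(n)
    beta = n @ _sym6_to_mat(np.asarray(u6, dtype=float)) @ n
    r = op.rot_array.astype(float)
    beta2 = r @ beta @ r.T
    return _mat_to_sym6(n_inv @ beta2 @ n_inv)


@dataclass
class CrystalStructure:
    """Unit cell + space group + asymmetric-unit atom sites."""

    cell: UnitCell
    spacegroup: SpaceGroup
    sites: list

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("structure needs at least one atom site")
        labels = [s.label.upper() for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError("atom labels must be unique (case-insensitive)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site(self, label: str) -> AtomSite:
        key = label.upper()
        for s in self.sites:
            if s.label.upper() == key:
                return s
        raise KeyError(f"no atom site labelled {label!r}")

    def frac_coords(self) -> np.ndarray:
        return np.array([s.frac for s in self.sites])

    def cart_coords(self) -> np.ndarray:
        return self.frac_coords() @ orthogonalization_matrix(self.cell).T

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(self.cell, self.spacegroup, [s.copy() for s in self.sites])


def apply_symmetry(op: SymmetryOperation, frac) -> np.ndarray:
    """R·frac + t, without mod-1 wrapping (wrap explicitly when needed)."""
    return op.rot_array.astype(float) @ np.asarray(frac, dtype=float) + op.trans_array


def wrap_frac(frac) -> np.ndarray:
    """Wrap fractional coordinates into [0, 1)."""
    return np.asarray(frac, dtype=float) % 1.0


def expand_to_p1(structure: CrystalStructure, merge_tol: float = SPECIAL_POSITION_TOL) -> list:
    """Replicate the ASU by every symmetry operation into one full cell.

    Coordinates are wrapped into [0, 1); copies of the same site that land
    on top of each other (special positions) are merged, so each orbit's
    multiplicity divides the group order. Anisotropic ADPs are rotated
    along with the sites.
    """
    out: list[AtomSite] = []
    for site in structure.sites:
        images: list[np.ndarray] = []
        for i_op, op in enumerate(structure.spacegroup.operations):
            f = wrap_frac(apply_symmetry(op, site.frac))
            dup = False
            for g in images:
                d = (f - g + 0.5) % 1.0 - 0.5
                if np.max(np.abs(d)) < merge_tol:
                    dup = True
                    break
            if dup:
                continue
            images.append(f)
            new = site.copy()
            new.frac = f
            new.label = f"{site.label}_{i_op}" if i_op else site.label
            if site.u_aniso is not None:
                new.u_aniso = transform_adp(op, site.u_aniso, structure.cell)
            out.append(new)
    return out
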