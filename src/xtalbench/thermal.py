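"""Rigid-body (TLS) analysis of anisotropic displacement parameters and
thermal-motion corrections to bond lengths.

A rigid molecule's ADPs follow U(r) = T + A L Aᵀ + A S + Sᵀ Aᵀ, where A is
the skew matrix of (r − origin), T (Å²) is the translation tensor, L (rad²)
the libration tensor and S (Å·rad) the screw tensor, made unique by
trace(S) = 0. Libration makes interatomic distances appear shorter; the
first-order correction moves each atom by Δr = ½(tr L·I − L)(r − origin),
which elongates bonds (by exactly λ·d for isotropic L = λI about the
centroid). The riding correction of Busing & Levy handles the common case
of a light atom riding on a heavier one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import perceive_bonds
from .core import CrystalStructure, adp_cif_to_cartesian, orthogonalization_matrix

__all__ = [
    "TLSModel",
    "TMACorrectionReport",
    "rigid_body_adps",
    "fit_tls",
    "libration_corrected_bonds",
    "riding_correction",
]

MIN_TLS_ATOMS = 7  # molecules with more than six atoms qualify for the fit


@dataclass
class TLSModel:
    T: np.ndarray  # 3x3 symmetric, Å²
    L: np.ndarray  # 3x3 symmetric, rad²
    S: np.ndarray  # 3x3, trace 0, Å·rad
    origin: np.ndarray  # Cartesian, Å

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        for m, name in ((self.T, "T"), (self.L, "L")):
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
        if abs(np.trace(self.S)) > 1e-8:
            raise ValueError("trace(S) must be zero")


@dataclass
class TMACorrectionReport:
    bonds: list  # (label_i, label_j, d_uncorrected, d_corrected, delta)
    mean_delta: float


def _skew(d: np.ndarray) -> np.ndarray:
    """A(d) with A·λ = λ × d."""
    return np.array(
        [[0.0, d[2], -d[1]], [-d[2], 0.0, d[0]], [d[1], -d[0], 0.0]]
    )


def rigid_body_adps(cart_coords, tls: TLSModel) -> np.ndarray:
    """Forward model: per-atom Cartesian U tensors from (T, L, S)."""
    coords = np.asarray(cart_coords, dtype=float)
    out = np.empty((len(coords), 3, 3))
    for i, r in enumerate(coords):
        a = _skew(r - tls.origin)
        out[i] = tls.T + a @ tls.L @ a.T + a @ tls.S + tls.S.T @ a.T
    return out


_SYM6 = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _u_to_6(u: np.ndarray) -> np.ndarray:
    return np.array([u[i, j] for i, j in _SYM6])


def _params_to_tls(p: np.ndarray, origin: np.ndarray) -> TLSModel:
    t = np.zeros((3, 3))
    l = np.zeros((3, 3))
    for k, (i, j) in enumerate(_SYM6):
        t[i, j] = t[j, i] = p[k]
        l[i, j] = l[j, i] = p[6 + k]
    s = np.array(
        [
            [p[12], p[13], p[14]],
            [p[15], p[16], p[17]],
            [p[18], p[19], -p[12] - p[16]],
        ]
    )
    return TLSModel(t, l, s, origin)


def fit_tls(
    structure: CrystalStructure,
    non_h_only: bool = True,
    origin: np.ndarray | None = None,
):
    """Linear least-squares fit of the 20 independent TLS parameters to the
    observed Cartesian Uij of (by default) the non-hydrogen atoms.

    Requires more than six qualifying atoms with anisotropic ADPs. Returns
    ``(TLSModel, residual)`` with residual = rms misfit over the 6N Uij
    components. The origin defaults to the centroid of the fitted atoms.
    """
    sel = [
        s
        for s in structure.sites
        if s.u_aniso is not None and (not non_h_only or not s.is_hydrogen)
    ]
    if len(sel) < MIN_TLS_ATOMS:
        raise ValueError(
            f"TLS analysis needs more than six atoms with anisotropic ADPs "
            f"(got {len(sel)})"
        )
    m = orthogonalization_matrix(structure.cell)
    coords = np.array([m @ s.frac for s in sel])
    if origin is None:
        origin = coords.mean(axis=0)

    obs = np.concatenate(
        [_u_to_6(adp_cif_to_cartesian(s.u_aniso, structure.cell)) for s in sel]
    )
    # the forward model is linear in the 20 parameters: build the design
    # matrix by evaluating it on unit parameter vectors
    design = np.empty((len(obs), 20))
    for k in range(20):
        p = np.zeros(20)
        p[k] = 1.0
        model = _params_to_tls(p, origin)
        us = rigid_body_adps(coords, model)
        design[:, k] = np.concatenate([_u_to_6(u) for u in us])

    sol, _res, rank, _sv = np.linalg.lstsq(design, obs, rcond=None)
    if rank < 20:
        raise ValueError(
            "rank-deficient TLS design matrix (degenerate geometry, e.g. a "
            "linear molecule)"
        )
    fitted = _params_to_tls(sol, origin)
    resid = float(np.sqrt(np.mean((design @ sol - obs) ** 2)))
    return fitted, resid


def libration_corrected_bonds(
    structure: CrystalStructure, tls: TLSModel
) -> TMACorrectionReport:
    """Bond lengths after the first-order libration correction.

    Each non-hydrogen atom is moved by Δr = ½(tr L·I − L)(r − origin);
    distances are recomputed and the per-bond elongation Δd reported along
    with its mean over non-hydrogen bonds.
    """
    m = orthogonalization_matrix(structure.cell)
    heavy = [s for s in structure.sites if not s.is_hydrogen]
    labels = [s.label for s in heavy]
    coords = np.array([m @ s.frac for s in heavy])
    corr_matrix = 0.5 * (np.trace(tls.L) * np.eye(3) - tls.L)
    corrected = coords + (coords - tls.origin) @ corr_matrix.T

    graph = perceive_bonds([s.element for s in heavy], coords)
    rows = []
    for i, j in graph.edges():
        d0 = float(np.linalg.norm(coords[i] - coords[j]))
        d1 = float(np.linalg.norm(corrected[i] - corrected[j]))
        rows.append((labels[i], labels[j], d0, d1, d1 - d0))
    mean_delta = float(np.mean([r[4] for r in rows])) if rows else 0.0
    return TMACorrectionReport(bonds=rows, mean_delta=mean_delta)


def riding_correction(d: float, u_parent, u_rider, bond_unit_vector) -> float:
    """Busing–Levy riding-motion corrected distance.

    d_corr = d + (⟨u²⊥⟩_rider − ⟨u²⊥⟩_parent)/(2d), where ⟨u²⊥⟩ is the sum
    of the two mean-square displacement components perpendicular to the
    bond: trace(U) − n̂ᵀUn̂. The correction may be negative when the parent
    moves more than the rider.
    """
    if d <= 0:
        raise ValueError("bond length must be positive")
    n = np.asarray(bond_unit_vector, dtype=float)
    n = n / np.linalg.norm(n)
    up = np.asarray(u_parent, dtype=float)
    ur = np.asarray(u_rider, dtype=float)
    perp_p = float(np.trace(up) - n @ up @ n)
    perp_r = float(np.trace(ur) - n @ ur @ n)
    return d + (perp_r - perp_p) / (2.0 * d)
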