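"""Independent-atom-model structure factors and restrained positional
least squares.

The engine minimizes

    Σ_h w_h (Fo²(h) − k·Fc²(h))²  +  Σ_r w_r (D_r − T_r)²

over the fractional coordinates of the non-hydrogen atoms (plus the overall
scale k, eliminated analytically every cycle), by Gauss–Newton with an
analytic Jacobian and optional step damping. ``w_h`` is the σ-based scheme
1/[σ² + (aP)² + bP] with P = (max(Fo²,0) + 2kFc²)/3; ``w_r`` is
``restraint_weight_scale · S / su²`` where S = mean(w_h·Fo⁴)/n bridges the
arbitrary intensity scale to the Å² scale of the restraint term, so that a
given s.u. means the same tightness on any dataset.

Hydrogen atoms ride: they are never refined, receive the positional shift
of their parent atom and an isotropic U equal to a fixed multiple of the
parent's equivalent U.

R1 is reported on amplitudes, R1 = Σ||Fo| − |Fc|| / Σ|Fo| with
|Fo| = √max(Fo², 0); ΔR1 = R1(restrained) − R1(unrestrained) is the
diagnostic penalty for enforcing a theory's geometry on the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .connectivity import perceive_bonds
from .core import (
    CrystalStructure,
    adp_cif_to_cartesian,
    orthogonalization_matrix,
    reciprocal_lengths,
    reciprocal_metric_tensor,
)
from .io import ReflectionSet
from .restraints import RestraintSet

__all__ = [
    "form_factor",
    "calc_structure_factors",
    "scale_factor",
    "r1_factor",
    "RefinementOptions",
    "RefinementResult",
    "refine",
    "delta_r1",
    "SingularNormalMatrixError",
]

TWO_PI = 2.0 * np.pi


class SingularNormalMatrixError(np.linalg.LinAlgError):
    pass


# --------------------------------------------------------------------------
# form factors (four-Gaussian IT92 / Cromer–Mann coefficients via gemmi)

def form_factor_coefficients(element: str):
    """(a[4], b[4], c) neutral-atom coefficients; f(0)=Σa+c ≈ Z."""
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {element!r}")
    it92 = el.it92
    return np.array(it92.a), np.array(it92.b), float(it92.c)


def form_factor(element: str, s) -> np.ndarray:
    """IAM scattering factor f(s) in electrons, s = sinθ/λ in Å⁻¹."""
    a, b, c = form_factor_coefficients(element)
    s2 = np.asarray(s, dtype=float) ** 2
    return np.sum(a * np.exp(-b * s2[..., None]), axis=-1) + c


# --------------------------------------------------------------------------
# structure factors

def _beta_matrices(structure: CrystalStructure, default_u_iso: float | None):
    """Per-atom (β aniso 3×3 or None, B_iso) for the Debye–Waller factor.

    β = 2π² N U_cif N (N = diag(a*,b*,c*)) so DW = exp(−hᵀβh); the image
    generated by (R, t) uses DW(Rᵀh), i.e. β' = RβRᵀ exactly.
    """
    n = np.diag(reciprocal_lengths(structure.cell))
    betas, b_isos = [], []
    for s in structure.sites:
        if s.u_aniso is not None:
            u11, u22, u33, u12, u13, u23 = s.u_aniso
            u = np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
            betas.append(2.0 * np.pi**2 * n @ u @ n)
            b_isos.append(0.0)
        else:
            u = s.u_iso if s.u_iso is not None else default_u_iso
            if u is None:
                raise ValueError(
                    f"atom {s.label} has no ADP and no default Uiso is configured"
                )
            betas.append(None)
            b_isos.append(8.0 * np.pi**2 * u)
    return betas, np.array(b_isos)


def calc_structure_factors(
    structure: CrystalStructure,
    hkl,
    anomalous: dict | None = None,
    default_u_iso: float | None = None,
    frac: np.ndarray | None = None,
    derivatives_for: list | None = None,
):
    """Symmetry-summed IAM structure factors F(h) (complex, electrons).

    F(h) = Σ_ops Σ_atoms occ·f(s)·DW·exp[2πi h·(R·r + t)].

    ``anomalous`` maps element → (f′, f″). With ``derivatives_for`` (a list
    of atom indices) the analytic ∂F/∂x per fractional coordinate is also
    returned as an (n_hkl, 3·len(list)) complex array.
    """
    h = np.asarray(hkl, dtype=float)
    h_int = np.atleast_2d(h)
    n_h = len(h_int)
    if frac is None:
        frac = structure.frac_coords()
    occ = np.array([s.occupancy for s in structure.sites])
    elements = [s.element for s in structure.sites]

    g_star = reciprocal_metric_tensor(structure.cell)
    stol2 = 0.25 * np.einsum("ij,jk,ik->i", h_int, g_star, h_int)  # (sinθ/λ)²

    # per-element scattering factors, incl. optional anomalous terms
    f_elem: dict[str, np.ndarray] = {}
    for el in set(elements):
        a, b, c = form_factor_coefficients(el)
        f = np.sum(a * np.exp(-b * stol2[:, None]), axis=1) + c
        f = f.astype(complex)
        if anomalous and el in anomalous:
            fp, fpp = anomalous[el]
            f = f + fp + 1j * fpp
        f_elem[el] = f
    f_atoms = np.stack([f_elem[el] for el in elements], axis=1)  # (n_h, m)

    betas, b_isos = _beta_matrices(structure, default_u_iso)

    F = np.zeros(n_h, dtype=complex)
    n_par = 0 if derivatives_for is None else 3 * len(derivatives_for)
    dF = np.zeros((n_h, n_par), dtype=complex) if n_par else None
    col_of = {a: 3 * i for i, a in enumerate(derivatives_for or [])}

    for op in structure.spacegroup.operations:
        r = op.rot_array.astype(float)
        t = op.trans_array
        hp = h_int @ r  # row vector hᵀR, used both in phase and DW
        phase = np.exp(TWO_PI * 1j * (hp @ frac.T + (h_int @ t)[:, None]))  # (n_h, m)
        dw = np.empty((n_h, len(elements)))
        for a_i in range(len(elements)):
            if betas[a_i] is not None:
                dw[:, a_i] = np.exp(-np.einsum("ij,jk,ik->i", hp, betas[a_i], hp))
            else:
                dw[:, a_i] = np.exp(-b_isos[a_i] * stol2)
        term = occ * f_atoms * dw * phase
        F += term.sum(axis=1)
        if dF is not None:
            for a_i, col in col_of.items():
                dF[:, col : col + 3] += TWO_PI * 1j * hp * term[:, a_i : a_i + 1]

    if dF is not None:
        return F, dF
    return F


# --------------------------------------------------------------------------
# scaling and agreement statistics

def scale_factor(fo_sq, fc_sq) -> float:
    """Least-squares intensity scale k: Fo² ≈ k·Fc²."""
    fo_sq = np.asarray(fo_sq, dtype=float)
    fc_sq = np.asarray(fc_sq, dtype=float)
    if fo_sq.shape != fc_sq.shape:
        raise ValueError("length mismatch")
    denom = float(fc_sq @ fc_sq)
    if denom == 0.0:
        raise ValueError("all calculated intensities are zero")
    return float(fo_sq @ fc_sq) / denom


def r1_factor(fo, fc) -> float:
    """R1 = Σ||Fo|−|Fc|| / Σ|Fo| on amplitudes."""
    fo = np.abs(np.asarray(fo, dtype=float))
    fc = np.abs(np.asarray(fc, dtype=float))
    if fo.size == 0:
        raise ValueError("empty input")
    denom = fo.sum()
    if denom <= 0:
        raise ValueError("sum of |Fo| must be positive")
    return float(np.abs(fo - fc).sum() / denom)


# --------------------------------------------------------------------------
# refinement

@dataclass
class RefinementOptions:
    mode: str = "unrestrained"  # or "restrained"
    max_cycles: int = 50
    convergence_tol: float = 0.01  # on max |shift|/esd
    damping: float = 1.0  # multiplies the Gauss–Newton step
    weight_a: float = 0.1
    weight_b: float = 0.0
    restraint_weight_scale: float = 1.0
    riding_h: bool = True
    h_u_multiplier: float = 2.4  # 3.0 for hydroxyl/methyl-type hydrogens
    default_u_iso: float | None = None
    anomalous: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must be in (0, 1]")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


@dataclass
class RefinementResult:
    structure: CrystalStructure
    r1: float
    wr2: float
    cycles_used: int
    max_shift_over_esd: float
    restraint_rms: float
    converged: bool
    scale: float
    reflections: ReflectionSet
    n_restraints: int = 0


def _polar_directions(spacegroup) -> np.ndarray:
    """Orthonormal basis (columns, fractional) of the floating-origin
    subspace: directions along which translating the whole structure leaves
    every |F| unchanged (e.g. all three axes in P1, the screw axis in P2₁).

    Found as the common eigenvector space of all rotation parts with
    eigenvalue +1, i.e. the null space of the stacked (Rᵢ − I)."""
    from scipy.linalg import null_space

    stacked = np.vstack(
        [op.rot_array - np.eye(3, dtype=int) for op in spacegroup.operations]
    )
    ns = null_space(stacked.astype(float))
    return ns  # shape (3, n_polar)


def _origin_rows(frac0, frac, polar, refined, n_par, weight):
    """Centroid restraints that pin the floating origin: one row per polar
    direction keeping the mean shift along it at zero."""
    n_dir = polar.shape[1]
    resid = np.zeros(n_dir)
    jac = np.zeros((n_dir, n_par))
    n_ref = len(refined)
    for d in range(n_dir):
        v = polar[:, d]
        drift = sum(float((frac[a] - frac0[a]) @ v) for a in refined) / n_ref
        resid[d] = -weight * drift
        for p, _a in enumerate(refined):
            jac[d, 3 * p : 3 * p + 3] = -weight * v / n_ref
    return resid, jac


def _weights(fo_sq, sigma, k_fc_sq, a, b) -> np.ndarray:
    p = (np.maximum(fo_sq, 0.0) + 2.0 * k_fc_sq) / 3.0
    return 1.0 / (sigma**2 + (a * p) ** 2 + b * np.maximum(p, 0.0))


def _resolve_restraint_pairs(restraints, labels):
    index = {lab.upper(): i for i, lab in enumerate(labels)}
    pairs = []
    for r in restraints.restraints:
        try:
            i, j = (index[a.upper()] for a in r.atoms)
        except KeyError as exc:
            raise KeyError(f"restraint atom {exc.args[0]} not in structure") from exc
        pairs.append((i, j, r.target, r.su))
    return pairs


def refine(
    structure: CrystalStructure,
    reflections: ReflectionSet,
    restraints: RestraintSet | None = None,
    options: RefinementOptions | None = None,
) -> RefinementResult:
    """Gauss–Newton positional refinement against Fo² with optional
    distance restraints; ADPs and occupancies are held fixed.

    Steps that would increase the objective are halved (up to 8 times)
    before being accepted, so the objective is non-increasing across
    accepted cycles. Convergence is declared when max |shift|/esd falls
    below ``convergence_tol`` or every Cartesian shift is below 1e-8 Å.
    """
    opts = options or RefinementOptions()
    if restraints is not None and len(restraints) == 0:
        restraints = None
    work = structure.copy()
    labels = [s.label for s in work.sites]
    m_orth = orthogonalization_matrix(work.cell)

    hkl = reflections.hkl_array()
    fo_sq = reflections.f_sq_array()
    sigma = reflections.sigma_array()

    # riding hydrogens: find parents from current geometry
    is_h = np.array([s.is_hydrogen for s in work.sites])
    refined = [i for i in range(len(labels)) if not is_h[i]]
    children: dict[int, list] = {i: [] for i in refined}
    if opts.riding_h and is_h.any():
        graph = perceive_bonds([s.element for s in work.sites], work.cart_coords())
        for i in np.nonzero(is_h)[0]:
            nbrs = [j for j in graph.neighbors(int(i)) if not is_h[j]]
            if nbrs:
                parent = nbrs[0]
                children[parent].append(int(i))
                u_eq = _u_equiv(work, parent)
                if u_eq is not None:
                    work.sites[int(i)].u_iso = opts.h_u_multiplier * u_eq
                    work.sites[int(i)].u_aniso = None

    rest_pairs = _resolve_restraint_pairs(restraints, labels) if restraints else []

    frac = work.frac_coords()
    frac0 = frac.copy()
    polar = _polar_directions(work.spacegroup)
    n_par = 3 * len(refined)
    cycles = 0
    converged = False
    max_shift_esd = np.inf

    for cycles in range(1, opts.max_cycles + 1):
        F, dF = calc_structure_factors(
            work,
            hkl,
            anomalous=opts.anomalous,
            default_u_iso=opts.default_u_iso,
            frac=frac,
            derivatives_for=refined,
        )
        # riding H: fold each hydrogen's derivative into its parent's columns
        if opts.riding_h and is_h.any():
            dF = _add_riding_derivatives(
                work, hkl, frac, refined, children, dF, opts
            )
        fc_sq = np.abs(F) ** 2
        k = scale_factor(fo_sq, fc_sq)
        w = _weights(fo_sq, sigma, k * fc_sq, opts.weight_a, opts.weight_b)
        sw = np.sqrt(w)

        resid = sw * (fo_sq - k * fc_sq)
        # ∂(k·Fc²)/∂x = k · 2 Re(conj(F)·∂F/∂x)  (scale treated as constant)
        jac = sw[:, None] * (-k * 2.0 * np.real(np.conj(F)[:, None] * dF))

        if rest_pairs:
            s_bridge = float(np.mean(w * fo_sq**2))
            r_resid, r_jac = _restraint_rows(
                frac, m_orth, rest_pairs, refined, children,
                opts.restraint_weight_scale * s_bridge,
            )
            resid = np.concatenate([resid, r_resid])
            jac = np.vstack([jac, r_jac])
        if polar.shape[1]:
            w_origin = 10.0 * float(np.sqrt(np.mean(np.sum(jac**2, axis=0))))
            o_resid, o_jac = _origin_rows(frac0, frac, polar, refined, n_par,
                                          w_origin)
            resid = np.concatenate([resid, o_resid])
            jac = np.vstack([jac, o_jac])

        objective = float(resid @ resid)
        normal = jac.T @ jac
        rhs = jac.T @ resid
        try:
            shift = np.linalg.solve(normal, -rhs)
        except np.linalg.LinAlgError as exc:
            raise SingularNormalMatrixError(
                "singular normal matrix; consider damping or more data"
            ) from exc
        # jac is ∂resid/∂x, so −(JᵀJ)⁻¹Jᵀr computed above is the full step
        shift = opts.damping * shift

        # parameter esds from the inverse normal matrix and the GoF
        dof = max(len(resid) - n_par, 1)
        gof_sq = objective / dof
        try:
            cov_diag = np.diag(np.linalg.inv(normal))
        except np.linalg.LinAlgError as exc:
            raise SingularNormalMatrixError(
                "singular normal matrix; consider damping or more data"
            ) from exc
        esd = np.sqrt(np.maximum(cov_diag * gof_sq, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.abs(shift) / esd
        max_shift_esd = float(np.nanmax(ratio)) if np.any(esd > 0) else 0.0

        # backtracking: accept only non-increasing objective
        step = shift.copy()
        accepted = False
        for _ in range(8):
            trial = _apply_shift(frac, step, refined, children)
            trial_obj = _objective(
                work, hkl, fo_sq, sigma, trial, rest_pairs, refined, children,
                m_orth, opts,
            )
            if trial_obj <= objective * (1.0 + 1e-12):
                frac = trial
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break

        max_cart_shift = float(
            np.max(np.linalg.norm((step.reshape(-1, 3) @ m_orth.T), axis=1))
        ) if len(step) else 0.0
        if max_shift_esd < opts.convergence_tol or max_cart_shift < 1e-8:
            converged = True
            break

    for i, s in enumerate(work.sites):
        s.frac = frac[i].copy()

    F = calc_structure_factors(
        work, hkl, anomalous=opts.anomalous, default_u_iso=opts.default_u_iso, frac=frac
    )
    fc_sq = np.abs(F) ** 2
    k = scale_factor(fo_sq, fc_sq)
    w = _weights(fo_sq, sigma, k * fc_sq, opts.weight_a, opts.weight_b)
    fo_amp = np.sqrt(np.maximum(fo_sq, 0.0))
    fc_amp = np.sqrt(k) * np.abs(F)
    r1 = r1_factor(fo_amp, fc_amp)
    wr2 = float(
        np.sqrt(np.sum(w * (fo_sq - k * fc_sq) ** 2) / np.sum(w * fo_sq**2))
    )
    rest_rms = 0.0
    if rest_pairs:
        d = _restraint_distances(frac, m_orth, rest_pairs)
        targets = np.array([t for _i, _j, t, _su in rest_pairs])
        rest_rms = float(np.sqrt(np.mean((d - targets) ** 2)))

    return RefinementResult(
        structure=work,
        r1=r1,
        wr2=wr2,
        cycles_used=cycles,
        max_shift_over_esd=max_shift_esd,
        restraint_rms=rest_rms,
        converged=converged,
        scale=k,
        reflections=reflections,
        n_restraints=len(rest_pairs),
    )


def _u_equiv(structure: CrystalStructure, i: int) -> float | None:
    s = structure.sites[i]
    if s.u_aniso is not None:
        u_cart = adp_cif_to_cartesian(s.u_aniso, structure.cell)
        return float(np.trace(u_cart) / 3.0)
    return s.u_iso


def _apply_shift(frac, shift, refined, children) -> np.ndarray:
    out = frac.copy()
    for p, a in enumerate(refined):
        d = shift[3 * p : 3 * p + 3]
        out[a] += d
        for h in children.get(a, []):
            out[h] += d
    return out


def _restraint_distances(frac, m_orth, rest_pairs) -> np.ndarray:
    d = []
    for i, j, _t, _su in rest_pairs:
        df = frac[i] - frac[j]
        df -= np.round(df)  # nearest image
        d.append(float(np.linalg.norm(m_orth @ df)))
    return np.array(d)


def _restraint_rows(frac, m_orth, rest_pairs, refined, children, w_scale):
    """Weighted residuals and Jacobian rows for the restraint term."""
    col_of = {}
    for p, a in enumerate(refined):
        col_of[a] = 3 * p
        for h in children.get(a, []):
            col_of[h] = 3 * p  # riding: hydrogen shifts with its parent
    n_par = 3 * len(refined)
    resid = np.zeros(len(rest_pairs))
    jac = np.zeros((len(rest_pairs), n_par))
    for row, (i, j, target, su) in enumerate(rest_pairs):
        df = frac[i] - frac[j]
        df -= np.round(df)
        dc = m_orth @ df
        d = float(np.linalg.norm(dc))
        sw = np.sqrt(w_scale / su**2)
        resid[row] = sw * (target - d)
        grad = m_orth.T @ dc / d  # ∂d/∂frac_i (= −∂d/∂frac_j)
        if i in col_of:
            jac[row, col_of[i] : col_of[i] + 3] += -sw * grad
        if j in col_of:
            jac[row, col_of[j] : col_of[j] + 3] += sw * grad
    return resid, jac


def _objective(work, hkl, fo_sq, sigma, frac, rest_pairs, refined, children,
               m_orth, opts) -> float:
    F = calc_structure_factors(
        work, hkl, anomalous=opts.anomalous, default_u_iso=opts.default_u_iso,
        frac=frac,
    )
    fc_sq = np.abs(F) ** 2
    k = scale_factor(fo_sq, fc_sq)
    w = _weights(fo_sq, sigma, k * fc_sq, opts.weight_a, opts.weight_b)
    obj = float(np.sum(w * (fo_sq - k * fc_sq) ** 2))
    if rest_pairs:
        s_bridge = float(np.mean(w * fo_sq**2))
        d = _restraint_distances(frac, m_orth, rest_pairs)
        for (i, j, target, su), dd in zip(rest_pairs, d):
            obj += opts.restraint_weight_scale * s_bridge / su**2 * (dd - target) ** 2
    return obj


def _add_riding_derivatives(work, hkl, frac, refined, children, dF, opts):
    """Add each riding hydrogen's ∂F/∂x into its parent's Jacobian columns."""
    riders = [h for hs in children.values() for h in hs]
    if not riders:
        return dF
    _, dF_h = calc_structure_factors(
        work, hkl, anomalous=opts.anomalous, default_u_iso=opts.default_u_iso,
        frac=frac, derivatives_for=riders,
    )
    col_h = {h: 3 * i for i, h in enumerate(riders)}
    out = dF.copy()
    for p, a in enumerate(refined):
        for h in children.get(a, []):
            out[:, 3 * p : 3 * p + 3] += dF_h[:, col_h[h] : col_h[h] + 3]
    return out


def delta_r1(restrained: RefinementResult, unrestrained: RefinementResult) -> float:
    """ΔR1 = R1(restrained) − R1(unrestrained), both against the same data."""
    if not np.array_equal(
        restrained.reflections.hkl_array(), unrestrained.reflections.hkl_array()
    ):
        raise ValueError("refinements were run against different reflection sets")
    return restrained.r1 - unrestrained.r1
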