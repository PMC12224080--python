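"""Readers and writers: CIF, SHELX HKLF-4 reflection files, restraint files, XYZ.

CIF reading is delegated to gemmi's CIF tokenizer; only the small core
subset needed for refinement is interpreted (cell, symmetry loop, atom
sites, anisotropic ADPs). Writing emits the same subset, so a written
structure re-reads identically to print precision.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from gemmi import cif

from .core import (
    AtomSite,
    CrystalStructure,
    SpaceGroup,
    SymmetryOperation,
    UnitCell,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Reflection",
    "ReflectionSet",
    "read_cif",
    "write_cif",
    "parse_symop_xyz",
    "format_symop_xyz",
    "read_shelx_hkl",
    "write_shelx_hkl",
    "write_restraint_file",
    "read_restraint_file",
    "read_xyz",
    "write_xyz",
    "CifParseError",
]

B_TO_U = 1.0 / (8.0 * np.pi**2)


class CifParseError(ValueError):
    """Raised when a required CIF item is missing or malformed."""


@dataclass(frozen=True)
class Reflection:
    """One Bragg reflection: Miller indices, Fo² and σ(Fo²)."""

    hkl: tuple
    f_sq: float
    sigma: float

    def __post_init__(self) -> None:
        if self.hkl == (0, 0, 0):
            raise ValueError("(0,0,0) is not a reflection")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ReflectionSet:
    reflections: list
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if not self.reflections:
            raise ValueError("empty reflection set")

    def __len__(self) -> int:
        return len(self.reflections)

    def hkl_array(self) -> np.ndarray:
        return np.array([r.hkl for r in self.reflections], dtype=int)

    def f_sq_array(self) -> np.ndarray:
        return np.array([r.f_sq for r in self.reflections])

    def sigma_array(self) -> np.ndarray:
        return np.array([r.sigma for r in self.reflections])


# --------------------------------------------------------------------------
# symmetry-operation triplets

_TERM_RE = re.compile(r"([+-]?)(\d+(?:/\d+)?|[xyz]|\d*\.\d+)", re.IGNORECASE)


def parse_symop_xyz(text: str) -> SymmetryOperation:
    """Parse an xyz triplet like ``-x, y+1/2, -z+1/2`` exactly (rational t)."""
    parts = text.lower().replace(" ", "").split(",")
    if len(parts) != 3:
        raise ValueError(f"symmetry operation needs 3 components: {text!r}")
    rot = np.zeros((3, 3), dtype=int)
    trans = [Fraction(0)] * 3
    axes = {"x": 0, "y": 1, "z": 2}
    for i, comp in enumerate(parts):
        if not comp:
            raise ValueError(f"empty component in {text!r}")
        pos = 0
        for m in _TERM_RE.finditer(comp):
            if m.start() != pos:
                raise ValueError(f"malformed token {comp[pos:]!r} in {text!r}")
            pos = m.end()
            sign = -1 if m.group(1) == "-" else 1
            tok = m.group(2)
            if tok in axes:
                rot[i, axes[tok]] += sign
            elif "." in tok:
                trans[i] += sign * Fraction(tok).limit_denominator(24)
            else:
                trans[i] += sign * Fraction(tok)
        if pos != len(comp):
            raise ValueError(f"malformed token {comp[pos:]!r} in {text!r}")
    return SymmetryOperation(tuple(map(tuple, rot)), tuple(t % 1 for t in trans))


def format_symop_xyz(op: SymmetryOperation) -> str:
    return str(op)


# --------------------------------------------------------------------------
# CIF

_SYMOP_TAGS = (
    "_space_group_symop_operation_xyz",
    "_symmetry_equiv_pos_as_xyz",
)


def _require(block, tag: str) -> float:
    val = block.find_value(tag)
    if val is None:
        raise CifParseError(f"missing required CIF item {tag}")
    return cif.as_number(val)


def read_cif(text: str) -> CrystalStructure:
    """Parse a small-molecule CIF into a :class:`CrystalStructure`.

    Requires cell lengths/angles, a symmetry-operation loop (either the
    ``_space_group_symop`` or legacy ``_symmetry_equiv`` tag) and an
    ``_atom_site`` loop. An ``_atom_site_aniso`` loop is attached by label.
    Accepts Uiso or Biso (B = 8π²U).
    """
    doc = cif.read_string(text)
    block = doc.sole_block()

    cell = UnitCell(
        _require(block, "_cell_length_a"),
        _require(block, "_cell_length_b"),
        _require(block, "_cell_length_c"),
        _require(block, "_cell_angle_alpha"),
        _require(block, "_cell_angle_beta"),
        _require(block, "_cell_angle_gamma"),
    )

    ops = []
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        ops = [parse_symop_xyz(cif.as_string(v)) for v in col]
        if ops:
            break
    if not ops:
        ops = [SymmetryOperation(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0, 0, 0))]
    sg_name = block.find_value("_space_group_name_H-M_alt") or block.find_value(
        "_symmetry_space_group_name_H-M"
    )
    sg = SpaceGroup(cif.as_string(sg_name) if sg_name else "P 1", tuple(ops))

    table = block.find(
        "_atom_site_",
        ["label", "type_symbol", "fract_x", "fract_y", "fract_z"],
    )
    loose = False
    if len(table) == 0:
        table = block.find("_atom_site_", ["label", "fract_x", "fract_y", "fract_z"])
        loose = True
    if len(table) == 0:
        raise CifParseError("missing _atom_site loop")

    occ_col = block.find_loop("_atom_site_occupancy")
    u_col = block.find_loop("_atom_site_U_iso_or_equiv")
    b_col = block.find_loop("_atom_site_B_iso_or_equiv")
    occ = [cif.as_number(v) for v in occ_col] if occ_col else None
    u_iso = [cif.as_number(v) for v in u_col] if u_col else None
    b_iso = [cif.as_number(v) for v in b_col] if b_col else None

    sites = []
    for i, row in enumerate(table):
        if loose:
            label, fx, fy, fz = (row[j] for j in range(4))
            element = _element_from_label(cif.as_string(label))
        else:
            label, element, fx, fy, fz = (row[j] for j in range(5))
            element = cif.as_string(element)
        u = None
        if u_iso is not None:
            u = u_iso[i]
        elif b_iso is not None:
            u = b_iso[i] * B_TO_U
        sites.append(
            AtomSite(
                label=cif.as_string(label),
                element=element.capitalize(),
                frac=np.array([cif.as_number(v) for v in (fx, fy, fz)]),
                occupancy=occ[i] if occ is not None else 1.0,
                u_iso=u,
            )
        )

    aniso = block.find(
        "_atom_site_aniso_",
        ["label", "U_11", "U_22", "U_33", "U_12", "U_13", "U_23"],
    )
    by_label = {s.label.upper(): s for s in sites}
    for row in aniso:
        label = cif.as_string(row[0])
        site = by_label.get(label.upper())
        if site is None:
            raise CifParseError(f"aniso loop label {label!r} matches no atom site")
        site.u_aniso = np.array([cif.as_number(row[j]) for j in range(1, 7)])

    return CrystalStructure(cell, sg, sites)


def _element_from_label(label: str) -> str:
    m = re.match(r"([A-Za-z]{1,2})", label)
    if not m:
        raise CifParseError(f"cannot deduce element from label {label!r}")
    sym = m.group(1)
    # two-letter guesses like "CA1" for a carbon are resolved to one letter
    # unless the second letter is lowercase (proper symbol, e.g. Cl)
    return sym.capitalize() if sym[1:].islower() and len(sym) == 2 else sym[0].upper()


def write_cif(structure: CrystalStructure, data_name: str = "xtalbench") -> str:
    """Write the CIF subset understood by :func:`read_cif`.

    Coordinates are printed to 6 decimals, U values to 5.
    """
    for s in structure.sites:
        if not s.label.strip():
            raise ValueError("empty atom label")
    c = structure.cell
    lines = [
        f"data_{data_name}",
        f"_space_group_name_H-M_alt '{structure.spacegroup.name}'",
        f"_cell_length_a {c.a:.6f}",
        f"_cell_length_b {c.b:.6f}",
        f"_cell_length_c {c.c:.6f}",
        f"_cell_angle_alpha {c.alpha:.6f}",
        f"_cell_angle_beta {c.beta:.6f}",
        f"_cell_angle_gamma {c.gamma:.6f}",
        "loop_",
        "_space_group_symop_operation_xyz",
    ]
    lines += [f"'{op}'" for op in structure.spacegroup.operations]
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
        "_atom_site_U_iso_or_equiv",
    ]
    for s in structure.sites:
        u = s.u_iso if s.u_iso is not None else 0.0
        lines.append(
            f"{s.label} {s.element} {s.frac[0]:.6f} {s.frac[1]:.6f} {s.frac[2]:.6f} "
            f"{s.occupancy:.4f} {u:.5f}"
        )
    aniso_sites = [s for s in structure.sites if s.u_aniso is not None]
    if aniso_sites:
        lines += [
            "loop_",
            "_atom_site_aniso_label",
            "_atom_site_aniso_U_11",
            "_atom_site_aniso_U_22",
            "_atom_site_aniso_U_33",
            "_atom_site_aniso_U_12",
            "_atom_site_aniso_U_13",
            "_atom_site_aniso_U_23",
        ]
        for s in aniso_sites:
            u = s.u_aniso
            lines.append(
                f"{s.label} " + " ".join(f"{x:.5f}" for x in u)
            )
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# SHELX HKLF-4

def read_shelx_hkl(text: str, sigma_floor_factor: float = 0.01) -> ReflectionSet:
    """Parse a fixed-width HKLF-4 file (3I4, 2F8: h k l Fo² σ).

    Parsing stops at the ``0 0 0`` terminator. Non-positive sigmas are
    replaced by ``sigma_floor_factor × median(positive σ)`` with a warning.
    """
    raw = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if len(line) < 28:
            raise ValueError(f"HKL line {lineno} too short: {line!r}")
        try:
            h = int(line[0:4])
            k = int(line[4:8])
            l = int(line[8:12])
            f_sq = float(line[12:20])
            sig = float(line[20:28])
        except ValueError as exc:
            raise ValueError(f"HKL line {lineno} unparseable: {line!r}") from exc
        if (h, k, l) == (0, 0, 0):
            break
        raw.append(((h, k, l), f_sq, sig))
    if not raw:
        raise ValueError("no reflections before terminator")
    pos = [s for _, _, s in raw if s > 0]
    floor = sigma_floor_factor * float(np.median(pos)) if pos else 1e-6
    refl = []
    n_floored = 0
    for hkl, f_sq, sig in raw:
        if sig <= 0:
            sig = floor
            n_floored += 1
        refl.append(Reflection(hkl, f_sq, sig))
    if n_floored:
        logger.warning("replaced %d non-positive sigma(s) by floor %.4g", n_floored, floor)
    return ReflectionSet(refl)


def write_shelx_hkl(refl_set: ReflectionSet) -> str:
    lines = [
        f"{h:4d}{k:4d}{l:4d}{r.f_sq:8.2f}{r.sigma:8.2f}"
        for r in refl_set.reflections
        for (h, k, l) in (r.hkl,)
    ]
    lines.append(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# restraint files (DFIX/DANG dialect, used via the "+file.rests" mechanism)

def write_restraint_file(restraints, structure: CrystalStructure | None = None) -> str:
    """Format a RestraintSet as DFIX (1–2) and DANG (1–3) instructions.

    If a companion structure is given, every restrained label must resolve.
    """
    lines = [f"REM structure-specific restraints ({restraints.source_tag})"]
    for r in restraints.restraints:
        if structure is not None:
            for lab in r.atoms:
                structure.site(lab)  # raises KeyError if absent
        card = "DFIX" if r.kind == "bond_12" else "DANG"
        lines.append(f"{card} {r.target:.4f} {r.su:g} {r.atoms[0]} {r.atoms[1]}")
    return "\n".join(lines) + "\n"


def read_restraint_file(text: str):
    """Parse DFIX/DANG lines back into a RestraintSet."""
    from .restraints import Restraint, RestraintSet

    out = []
    for line in text.splitlines():
        toks = line.split()
        if not toks or toks[0].upper() not in ("DFIX", "DANG"):
            continue
        kind = "bond_12" if toks[0].upper() == "DFIX" else "angle_13"
        out.append(Restraint(kind, (toks[3], toks[4]), float(toks[1]), float(toks[2])))
    return RestraintSet(out, source_tag="file")


# --------------------------------------------------------------------------
# XYZ

def read_xyz(text: str):
    """Read an XYZ file → (elements, Cartesian coordinates in Å)."""
    lines = text.splitlines()
    n = int(lines[0].split()[0])
    elements, coords = [], []
    for line in lines[2 : 2 + n]:
        toks = line.split()
        elements.append(toks[0])
        coords.append([float(x) for x in toks[1:4]])
    if len(elements) != n:
        raise ValueError("XYZ atom count mismatch")
    return elements, np.array(coords)


def write_xyz(elements, coords, comment: str = "") -> str:
    coords = np.asarray(coords, dtype=float)
    lines = [str(len(elements)), comment]
    for el, xyz in zip(elements, coords):
        lines.append(f"{el:<2s} {xyz[0]:14.8f} {xyz[1]:14.8f} {xyz[2]:14.8f}")
    return "\n".join(lines) + "\n"
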