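# Methods

This note records the models, conventions and numerical choices behind
`xtalbench`, and what the synthetic test bed does and does not establish
about real data.

## The benchmarking protocol

Given an experimental structure (cell, space group, asymmetric-unit sites
with ADPs), measured intensities Fo² with σ(Fo²), and a set of optimized
coordinates from any external theory:

1. **Unrestrained refinement (UR).** Positional least squares of the
   non-hydrogen atoms against Fo². This is the experimental reference.
2. **Restraint generation.** The optimized geometry is aligned onto the
   experimental atom sequence; every bonded pair becomes a distance
   restraint with s.u. 0.0005 Å, and every angle not involving hydrogen
   becomes a 1–3 distance restraint with s.u. 0.002 Å (the `tight`
   profile; a `practical` profile with 0.02/0.03 Å is shipped for
   real-life stabilization use). If a 1–3 pair is itself bonded
   (three-membered ring) only the bond restraint is kept.
3. **Restrained refinement (RR)** with identical settings apart from the
   restraints (and, if needed, damping).
4. **Scoring.** ΔR1 = R1(RR) − R1(UR), and the RMSCD between the UR
   coordinates and the optimized ones.

Tight restraints act as a diagnostic, not a modelling improvement: a
*correct* target set can be enforced at no cost (ΔR1 ≈ 0), a wrong one
drags the model away from the data and ΔR1 grows monotonically with the
error. As the restraint s.u. → ∞ the restrained solution reverts to UR;
both behaviours are verified by the test suite. For batches, the median of
ΔR1 or RMSCD is the figure to quote — single outliers dominate the mean.

## Structure factors and refinement

* **IAM structure factors.** F(h) = Σ_ops Σ_atoms occ·f(s)·DW·exp[2πi
  h·(R·r + t)], with four-Gaussian neutral-atom form factors (International
  Tables/Cromer–Mann coefficients as shipped by gemmi) and optional
  per-element anomalous terms f′ + i f″. Anisotropic Debye–Waller factors
  use the CIF U_ij convention through the dimensionless β tensor
  (β = 2π² N U N, N = diag(a*, b*, c*)); the image generated by (R, t)
  uses DW(Rᵀh), exact for the integer rotation parts. Site multiplicity
  for special positions is the user's responsibility through the occupancy
  (SHELX convention); the symmetry sum over all operations is validated
  against an explicit P1 expansion of the cell to 1e-8 relative error.
* **Least squares.** Gauss–Newton on the fractional coordinates of the
  non-hydrogen atoms with the analytic ∂F/∂x, refining against Fo²
  (amplitude-based R1 is reported). The overall scale
  k = Σ Fo²Fc²/Σ Fc⁴ is eliminated analytically every cycle. Weights are
  the σ-based scheme w = 1/[σ² + (aP)² + bP], P = (max(Fo²,0) + 2kFc²)/3,
  defaults a = 0.1, b = 0 (per-dataset weight optimization is out of
  scope; users supply a and b).
* **Restraint weighting.** The data term and the restraint term live on
  different scales (intensities² vs Å²). We use w_r = c·S/su² with
  S = mean(w_h·Fo⁴) and `restraint_weight_scale` c (default 1), which
  makes a given s.u. mean the same tightness regardless of the arbitrary
  intensity scale. This is the knob that makes "tight" tight.
* **Floating origin.** In polar space groups (all axes in P1, the screw
  axis in P2₁) the data do not fix the origin and the normal matrix is
  singular. The polar subspace is found as the common +1-eigenvector space
  of the rotation parts, and one centroid restraint per polar direction
  pins the mean coordinate, weighted at 10× the rms Jacobian column norm.
* **Riding hydrogens.** H atoms are never refined: they receive the
  positional shift of their bonded parent (their ∂F/∂x is folded into the
  parent's Jacobian columns) and Uiso = 2.4 × Ueq(parent) (3.0 for
  hydroxyl/methyl-type H via `h_u_multiplier`). This adds a small R-factor
  penalty but keeps refinements robust, and ΔR1 comparisons are unaffected
  because UR and RR share the convention.
* **ADPs are held fixed** during UR/RR comparisons: ΔR1 probes coordinate
  agreement, and letting Uij float would let thermal parameters absorb
  coordinate error. (Full Uij refinement is intentionally not part of the
  comparison protocol.)
* **Convergence and damping.** Stop at max |shift|/esd < 0.01 (esd from
  the inverse normal matrix and the goodness of fit) or when every
  Cartesian shift is below 1e-8 Å; hard cap 50 cycles. Steps that would
  increase the objective are halved up to 8 times, so the objective is
  non-increasing over accepted cycles; an optional damping factor
  multiplies every step for pathologically restraint-sensitive cases.

## Geometry comparison

RMSCD wraps each per-atom fractional difference to the nearest image
component-wise and converts with the orthogonalization matrix (a ∥ x, b in
the x–y plane — all reported quantities are invariant to this choice).
Hydrogens are omitted by default. Both structures must share the unit cell
(relative tolerance 1e-4); comparing across different cells is refused
rather than silently approximated. An optional mode removes the mean
(rigid) shift before the RMS — useful because cluster optimization permits
a small rigid drift of the molecule within the fixed cell — and its use is
recorded in the report. No symmetry-operation search is performed by
default; the atom matcher is expected to have established equivalent
positions.

Atom matching combines extended-connectivity invariants (Morgan-style
iterative refinement seeded with element and degree), Cartesian proximity,
atomic mass and, when present, partial charges into one cost
(weights 100/10/1/1, configurable — the ranking, not the exact weights,
carries the information), assigned greedily with distance then label-order
tie-breaks; hydrogens are mapped afterwards through their parents.

## Clusters

`build_cluster` surrounds the asymmetric unit with every whole symmetry
copy that has at least one atom (hydrogens included by default) within the
contact threshold, default 3.75 Å, of any ASU atom. Copies are enumerated
over all operations × lattice translations within
ceil((threshold + ASU diameter)/perpendicular cell thickness) + 1 per axis,
which cannot miss a candidate even for very oblique cells; the builder is
tested against brute-force supercell enumeration. Multi-molecule ASUs are
treated as one content block. Overlaps with the ASU closer than 0.2 Å
(special positions) are dropped with a warning. The XYZ export puts free
atoms first and emits their 1-based indices — the fixed-atom contract for
external optimizers.

## Thermal motion

A rigid body's ADPs obey U(r) = T + A L Aᵀ + A S + Sᵀ Aᵀ with A the skew
matrix of (r − origin) and trace(S) = 0; the 20 parameters are fitted
linearly (unit weights — Uij s.u.'s are rarely deposited) to the Cartesian
Uij of the non-hydrogen atoms, origin at their centroid. Molecules need
more than six such atoms, otherwise the fit is refused. Libration shortens
apparent distances; the first-order corrected positions are
r + ½(tr L·I − L)(r − origin), which for isotropic L = λI scales every
distance by exactly (1 + λ) — the analytic case used to validate the
implementation. The fitted corrections can be transferred onto restraint
targets: bond targets shift by the mean correction δ, and 1–3 targets by
the law-of-cosines propagation ΔD = [(d₁ − d₂cosθ) + (d₂ − d₁cosθ)]·δ/D,
accurate to < 1e-6 Å for |δ| ≤ 0.002 Å. The Busing–Levy riding correction
d + (⟨u²⊥⟩_rider − ⟨u²⊥⟩_parent)/(2d) is provided for rider-parent pairs.
TMA conventions differ between programs (origin choice, weighting, which
bonds enter averages), so reproductions of published mean corrections are
matched to ±0.0002 Å, not bit-exactly.

## Synthetic test bed

The generator produces a connected organic molecule (C/N/O palette, bond
lengths 1.2–1.6 Å constrained under the perception cutoff, no non-bonded
heavy contact < 2.0 Å), placed at a general position in P1, P−1, P2₁ or
P2₁/c with ~6 Å of padding; a two-fragment mode emulates multi-component
asymmetric units. ADPs come from a small rigid-body motion (T ≈ 0.01 Å²,
L ≈ 0.5 mrad² — the regime of ~20 K data, giving libration corrections of
a few 10⁻⁴ Å); hydrogens get the riding Uiso = 2.4 × Ueq(parent) so the
data are exactly representable by the refinement model. Intensities are
|F|² over all Laue-unique reflections to d_min (default 0.8 Å) with
optional fractional Gaussian noise and σ = noise·Fc² + floor. All
randomness flows from one integer seed.

What passing on this bed shows: the algebra (symmetry, structure factors,
derivatives, TLS, clusters) is correct and the diagnostics are calibrated
(ΔR1 ≈ 0 for perfect targets, monotone in target error). What it does not
show: behaviour under real-data pathologies — aspherical scattering,
extinction, absorption errors, disorder, twinning — none of which are
modelled; the engine is deliberately IAM-only, so hydrogen positions
inherit the usual IAM bias and are excluded from restraint-based scoring
(bond restraints to H exist but angle restraints involving H are off by
default).

## Known limitations

* IAM only: no aspherical (multipole/deformation-density) scattering, no
  extinction or absorption corrections, no twin or absolute-structure
  refinement.
* Positional refinement only during benchmarking; Uij and occupancies are
  fixed.
* Symmetry operations are taken verbatim from the input file; no
  space-group lookup or origin-choice normalization is attempted.
* The quantum-chemical optimization itself is out of scope; optimized
  coordinates are an input contract (CIF or XYZ).
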