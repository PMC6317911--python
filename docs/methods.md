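# Methods

## Model

The system is a curved membrane inclusion — the Piezo channel plus the lipids
between its arms — idealized as a spherical cap ("dome") of fixed membrane
area `A` and radius of curvature `R`, embedded in an otherwise planar lipid
bilayer.  The mid-bilayer surface outside the dome (the membrane footprint)
takes the shape minimizing the Helfrich energy

    GM = (Kb/2) ∫ (c1 + c2)² dA + γ ΔA,

with bending modulus `Kb`, tension `γ`, principal curvatures `c1, c2`, and
`ΔA` the decrease of in-plane area relative to the flat state.  Gaussian
curvature is omitted (for fixed topology and boundaries it is a
conformation-dependent constant, absorbed into the protein term) and the
spontaneous curvature is taken as zero.  Thermal undulations, lipid/protein
sorting, inclusion flexing, and non-axisymmetric shapes are outside the
model.

Total energy per conformation: `G = GDP + GDb + GDγ + GM`, with
`GDb = 2 Kb A / R²` (all dome area treated as membrane bent to curvature
2/R) and `GDγ = γ (A − π r0²)`, where `r0 = R sin α` is the contact-line
radius and `α` the cap half-angle.  Gating is a two-state equilibrium:
`Po = 1/(1 + e^{ΔG})` with energies in kBT.

### Units and parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `Kb` | bending modulus | 20 kBT | typical phosphatidylcholine bilayer |
| `γ` | membrane tension | — | kBT/nm²; 1 kBT/nm² = 4.114 mN/m at 298 K; lysis ≈ 3.5 |
| `A` | dome area | 390 nm² | held exactly constant across conformations |
| `Rc` | closed-state radius | 10.2 nm | α ≈ 66°, r0 ≈ 9.33 nm |
| `Ro` | open-state radius | ∞ (flat) | `FLAT` sentinel; all membrane terms ≡ 0 |
| `T` | temperature | 298 K | unit conversion only; kB = 1.380649e-23 J/K |

All internal energies are in kBT, lengths in nm, tensions in kBT/nm²; SI
constants appear only in the mN/m conversion.

Caps are restricted to at most a hemisphere (`A ≤ 2πR²`): the closed state is
sub-hemispherical and the contact-line geometry stays single-valued;
super-hemispherical domes are rejected with the admissible radius named in
the error.  The dome area is treated as exactly conserved between
conformations and exposed as a parameter.

## Small-gradient (Monge) solution

Linearizing for small slopes gives `Kb ∇⁴h − γ ∇²h = 0` on `r ≥ r0`.  Of the
four axisymmetric modes (1, ln r, I0, K0 of r/λ, λ = sqrt(Kb/γ)), far-field
flatness excludes the constant and I0 modes and the ln mode carries a net
vertical force (excluded for a force-free floating inclusion), leaving
`h(r) = C K0(r/λ)`.  Slope matching at the rim uses the cap's true geometric
slope `|h'(r0)| = tan α` by default (`sin α` available as an option; the
choice is a modeling convention in the linearized theory — both agree to the
order at which the theory is valid).  `C = λ tan α / K1(r0/λ)`.  A warning is
raised when `tan α > 0.3`, where the expansion is unreliable: for the closed
dome (tan α ≈ 2.27) the Monge energy overestimates the arclength result by
several-fold, while at `R = 100 nm` the two agree to under 1%.

Energy: adaptive quadrature of
`∫ [(Kb/2)(∇²h)² + (γ/2) h'²] 2πr dr` on `[r0, r0 + 20λ]` at 1e-8 relative
tolerance, with an analytic `e^{−2r/λ}` tail bound.  The closed form in terms
of Bessel-K antiderivatives serves as an independent oracle in the test suite
(agreement to 1e-6 relative).

At `γ = 0` the linear operator is degenerate (logarithmic far field); the
solver raises and directs callers to the catenoid reference.

## Nonlinear arclength solution (infinite membrane)

State: `y = (r, h, ψ, H, H')` versus arclength `s` from the rim, with
`r' = cos ψ`, `h' = −sin ψ`, `ψ' = 2H − sin ψ / r`, and the shape equation
`H'' + (cos ψ / r) H' = (γ/Kb) H − 2H(H² − K)`, `K = ψ' sin ψ / r` (zero
pressure, zero spontaneous curvature).  Boundary conditions: smooth
attachment `ψ(0) = α`, `r(0) = r0`; far field `ψ = H = h = 0` at
`s_max = max(10λ, 5 r0)` (doubling the cutoff changes GM by < 0.1%; the
fields decay as e^{−s/λ}).

The system is solved in λ-scaled variables (making the ODE parameter-free up
to `r0/λ` and α) with `scipy.integrate.solve_bvp`, collocation tolerance
1e-8, on a mesh graded geometrically near the rim.  Low tensions are reached
by continuation: a geometric ladder of tensions from `γ_start = Kb/r0²`
(where λ ≈ r0 and an exponential-decay ansatz converges) down to the target,
each converged iterate rescaled and resampled as the next initial guess.
Requested tension sweeps reuse the same ladder, so a full activation curve
costs little more than its lowest-tension point.

Sign conventions: the dome bulges toward positive h; ψ ∈ [0, π/2) decreases
outward (hence `h' = −sin ψ`); heights are measured from the far-field plane.
The rim height is an output of the solve, never an input.

Energy by Simpson integration of the converged profile:
`bending = ∫ (Kb/2)(2H)² 2πr ds`, `ΔA_M = ∫ 2πr (1 − cos ψ) ds`,
`GM = bending + γ ΔA_M`.  Two identities validate the minimizer: the
envelope identity `dGM/dγ = ΔA_M` holds to ~0.02% (tested at 1%), and with
lengths scaled ×k and γ ×1/k², GM is invariant to machine precision.

### Zero-tension limit

As `γ → 0` the minimizer approaches the catenoid (`c1 + c2 = 0`,
`r sin ψ = r0 sin α ≈ 8.54 nm` for the closed dome) and GM → 0.
`catenoid_reference` integrates the exact minimal surface (heights gauged to
the rim, since a catenoid approaches no planar far field).  The acceptance
script extrapolates GM linearly to γ = 0 from the two finest tensions of the
ladder {1e-2, 3e-3, 1e-3, 3e-4, 1e-4} kBT/nm²: GM(γ) carries a γ·ln(1/γ)
correction, so extrapolation from the finest levels (rather than a
least-squares line through all five) is the consistent way to take the
limit; it yields ≈ 0.02 kBT, i.e. 0.0 at one-decimal precision.

## Finite compartments

A membrane corral (e.g. a cytoskeleton-bounded compartment) is modeled as a
finite domain of unconstrained arc length `L` beyond the rim, clamped to
planarity at its edge: `ψ(0) = α`, `ψ(L) = 0`, rim height at the compartment
plane, dome height free.  The profile is found by direct minimization of the
Helfrich functional over tangent-angle profiles `ψ(s) = α(1 − s/L) + Σ aₖ
sin(kπs/L)` (hard endpoint constraints by construction; 24 modes, Simpson
quadrature on 1601 points, BFGS with seeded randomized restarts; all
candidates logged and the lowest-energy one returned).  Because the energy is
a functional of ψ and r alone, pinning the rim height is pure gauge: the
clamped and slope-only boundary variants coincide in this formulation, so no
separate variant is exposed.  Cross-validation: at `L = 10λ` the compartment
energy matches the infinite-membrane BVP to 0.06%.

Admissibility arguments give the expected orderings, which the tests verify:
`GM(L=5) ≥ GM(L=10) ≥ GM(∞)` (a clamped profile extended by plane is
admissible for the larger domain), with compartment effects largest at low
tension, where the unconstrained footprint would be widest.

The compartment diameter quoted for a given L uses the in-plane radial
approximation `S = 2(r0 + L)`; the true arc along the deformed membrane
differs at O(slope²), below the ~10 nm precision at which corral sizes are
meaningful.

## Gating

`gating_energy` applies the G-decomposition to each conformation and takes
open-minus-closed differences; for a flat open state all its membrane terms
are identically zero.  At γ = 0 (infinite membrane) both ΔGDγ and ΔGM vanish
— the footprint is then of no energetic consequence — so ΔG reduces to
ΔGDP + ΔGDb.  Po is evaluated in the log domain (exact saturation far beyond
the float overflow threshold).  Sensitivities default to the envelope
identity (footprint part = ΔA_M difference; dome part = the constant excess
area difference, −116.3 nm² for closed → flat), with central finite
differences as a verification mode.  Since ΔGDP is unknown, the absolute
gating tension is not a prediction; `calibrate_delta_gdp` solves
ΔG(γ_half) = 0 exactly (ΔG is affine in ΔGDP).  With the footprint included,
the calibrated offset for the closed → flat scenario at a 0.05 kBT/nm²
midpoint is ≈ 174 kBT — the closed state must be strongly protein-stabilized
because every membrane term favors the open state under tension.

## Numerical choices and degenerate inputs

- Collocation tolerance 1e-8 (scaled variables); profile stored on ~2000
  graded points; energies by Simpson on that grid.
- A vanishing cap (A → 0) short-circuits to the exact planar solution.
- Neck pinch-off (r → 0) and solver non-convergence raise `SolverError` with
  diagnostics (tension, residual norms, node counts), distinguished from
  usage errors.
- `solve_footprint_sweep` requires positive tensions; zero tension on an
  infinite membrane is a distinct condition routed to the catenoid.
- Multiple minima in the compartment solver: randomized restarts (seed
  recorded in the profile diagnostics and output headers); the lowest-energy
  candidate is returned and all are logged.
- Recovering ΔG from Po in float64 is limited to |ΔG| ≲ 30 by the
  representation of min(Po, 1−Po); the inversion identity is tested in that
  range with an eps·e^|ΔG| floor, and saturation is tested separately.

## What the tests do and do not show

The test suite verifies closed-form geometry against independent quadrature
oracles, the Monge solution against Bessel closed forms, the nonlinear
solver against its own collocation residual, finite-difference residuals,
the Monge solver in the shared small-slope regime, the catenoid first
integral, and the thermodynamic identities above.  Curve-level behavior is
covered as orderings and monotonicity properties (activation-curve
shift/steepening,
compartment orderings, diverging low-tension sensitivity).  All of this
concerns the idealized model — a perfectly spherical, rigid, axisymmetric
dome in a homogeneous membrane at zero temperature — and says nothing about
deviations of a real channel from that idealization.

## Problem sizes

Default runs use ~10³ collocation nodes per tension, tension ladders of at
most 12 steps, 24 compartment modes, and activation grids of 10–25 tensions;
the full test suite and the acceptance script each complete in well under
five minutes on a single core.
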