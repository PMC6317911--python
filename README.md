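# piezomech

Membrane mechanics of the dome-shaped Piezo channel: the shape and energy of
the lipid "membrane footprint" that a curved, cap-shaped inclusion imposes on
the surrounding bilayer, and the consequences for tension-dependent gating.

## The problem

Piezo1/2 are mechanosensitive ion channels whose transmembrane arms curve the
local membrane into a spherical dome (projecting into the cell).  Because a
bilayer resists bending, the dome cannot end abruptly: the surrounding
membrane bends smoothly outward over a characteristic distance, forming a
deformation footprint much larger than the protein itself.  `piezomech`
computes the minimum-energy footprint from the Helfrich functional

    GM = (Kb/2) ∫ (c1 + c2)² dA  +  γ ΔA

where `Kb` is the bending modulus (kBT), `γ` the membrane tension (kBT/nm²),
`c1, c2` the principal curvatures of the mid-bilayer surface, and `ΔA` the
in-plane area absorbed by the deformation.  Deformations relax on the decay
length `λ = sqrt(Kb/γ)` (14 nm for Kb = 20 kBT, γ = 0.1 kBT/nm²).  The dome
is an up-to-hemispherical spherical cap of fixed membrane area (390 nm²) and
radius of curvature `R` (10.2 nm in the closed conformation).

Two solvers are provided:

- **Monge (analytic)** — small-gradient limit; the footprint is the decaying
  Bessel mode `h(r) = C·K0(r/λ)`.  Fast, but overestimates the energy for a
  strongly curved dome.
- **Arclength (numerical)** — the full nonlinear axisymmetric shape equation
  in the tangent-angle parametrization, valid at arbitrary slope; solved by
  collocation with continuation in tension, down to the near-catenoid
  zero-tension regime (where `c1 + c2 → 0` and GM → 0).  Finite membrane
  compartments (cytoskeletal corrals clamped planar at their rim) are solved
  by direct energy minimization over constrained tangent-angle profiles.

Gating is modeled as a two-state equilibrium between a curved closed dome
(`Rc`) and a flatter open dome (`Ro`, possibly exactly flat), with total
energy `G = GDP + GDb + GDγ + GM` per conformation and open probability
`Po/(1−Po) = exp(−ΔG/kBT)`.  The footprint term makes the tension
sensitivity `dΔG/dγ` diverge as `γ → 0` and both left-shifts and steepens
the activation curve relative to the dome-only model.

## Worked example

```python
from piezomech import (
    FLAT, GatingScenario, MembraneSpec, calibrate_delta_gdp, cap_from_radius,
    footprint_energy, solve_footprint, tension_sensitivity,
)

cap = cap_from_radius(10.2, 390.0)          # closed dome
mem = MembraneSpec(bending_modulus=20.0, tension=0.1)
print(f"contact angle alpha = {cap.alpha:.4f} rad, rim radius r0 = {cap.contact_radius:.3f} nm")
print(f"dome excess area    = {cap.excess_area:.1f} nm^2")
print(f"decay length lambda = {mem.decay_length:.1f} nm")

prof = solve_footprint(cap, mem)
e = footprint_energy(prof)
print(f"GM = {e.footprint:.2f} kBT (bending {e.footprint_bending:.2f} + tension {e.footprint_tension:.2f})")
print(f"footprint excess area dA_M = {e.footprint_excess_area:.1f} nm^2")

sc = GatingScenario(closed=cap, open=FLAT, membrane=mem)
dgdp = calibrate_delta_gdp(sc, 0.05)        # midpoint at 0.05 kBT/nm^2
print(f"calibrated deltaGDP = {dgdp:.1f} kBT")
print(f"dG/dgamma at the midpoint = {tension_sensitivity(sc, 0.05)['dG_dgamma']:.1f} nm^2")
```

prints

```
contact angle alpha = 1.1556 rad, rim radius r0 = 9.333 nm
dome excess area    = 116.3 nm^2
decay length lambda = 14.1 nm
GM = 30.19 kBT (bending 8.92 + tension 21.27)
footprint excess area dA_M = 212.7 nm^2
calibrated deltaGDP = 174.1 kBT
dG/dgamma at the midpoint = -386.3 nm^2
```

Reading this: at a modest tension of 0.1 kBT/nm² the footprint alone costs
30 kBT — comparable to the dome's own tension term (γ·ΔA ≈ 11.6 kBT) — and
flattening the dome releases 212.7 nm² of in-plane area from the footprint on
top of the dome's 116.3 nm².  The tension sensitivity of −386 nm² (versus
−116 nm² for the dome alone) is why the footprint makes the channel an
exquisite low-tension sensor.  The closed state must be protein-stabilized by
~174 kBT for gating to occur near 0.05 kBT/nm².

## Command line

```bash
piezomech geometry  --R 10.2 --A 390 --out geometry.csv
piezomech footprint --R 10.2 --gamma 0.01 --gamma 0.1 --gamma 1 --out footprint/
piezomech gating    --Rc 10.2 --Ro inf --calibrate 0.05 --out gating.csv
piezomech compare   --R 10.2 --gamma 0.1 --out compare.csv
piezomech fixtures  --seed 0 --out fixtures/
```

All outputs are CSV with full provenance in `# key = value` headers.
Exit codes: 0 success, 2 usage error, 3 solver failure.

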