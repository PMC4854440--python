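# Methods

`dpdmem` simulates coarse-grained phospholipid membranes with dissipative
particle dynamics (DPD) under a four-to-one mapping: one bead stands for
roughly four heavy atoms (or four water molecules, `Nm = 4`).  All
internal arithmetic uses reduced units, `r0 = m0 = kBT = 1`, with the
physical calibration `r0 ≈ 0.71 nm` and `τ ≈ 143 ps`; conversion happens
only at I/O boundaries (`dpdmem.units`).

## Force field

Beads within `r < r0` interact through three pairwise central forces:

- conservative soft repulsion `F_C = a_ij (1 − r) r̂`,
- random force `F_R = sqrt(2 γ_ij kBT) (1 − r) ζ_ij r̂ / sqrt(dt)`,
- dissipative force `F_D = −γ_ij (1 − r)² (r̂·v_ij) r̂`.

`ζ_ij` is uniform on `[−√3, √3]` (zero mean, unit variance), symmetric in
`i↔j`, and drawn fresh at every force evaluation.  The `1/sqrt(dt)` factor
is the standard discretization that makes the random/dissipative pair a
fluctuation–dissipation-consistent thermostat; momentum is conserved
exactly because all three forces are pairwise antisymmetric.

Five bead types are parameterized — water `W`, choline `Q0`, phosphate
`Qa`, glycerol `Na`, hydrocarbon `C` — with the repulsion table shipped in
`dpdmem/data/forcefield.yaml`.  Like-bead repulsion is `100 kBT/r0`,
chosen so that density-3 water reproduces the dimensionless water
compressibility `k⁻¹ ≈ 16` per molecule at `Nm = 4` through the equation
of state `P = ρT + α a ρ²` (`α ≈ 0.101`).  Like-charged beads (`Q0–Q0`,
`Qa–Qa`) are more repulsive (110) as an implicit stand-in for head-group
electrostatics; there is no explicit charge or polarizability in the
model.  Friction coefficients follow the repulsion tier: `γ = 4.5` for
`a ≤ 102`, `9` for `102 < a ≤ 110`, `20` above.  The tier boundaries are
a package convention chosen so that every distinct value in the default
table falls in exactly one tier; they are configurable.

Lipids are h-shaped polymers: choline–phosphate–glycerol backbone with
two hydrocarbon tails (3 C beads for DMPC, 4 for DPPC/DOPC).  Bonds are
harmonic, `E2 = ½ K2 (r − L0)²` with `K2 = 512 kBT/r0²`; angles are
cosine-harmonic, `E3 = K3 [1 − cos(θ − θ0)]` with `K3 = 6 kBT`, `θ0 =
180°` along the tails and `120°` at the glycerol branch.  DOPC bends its
terminal tail angle to `120°` to mimic the unsaturated chain.  Bonded
bead pairs also feel the nonbonded repulsion (no exclusions), which is
why `L0 = 0.59 r0` sits below the fitted equilibrium bond length of
`0.66 r0`.  The Gaussian-fit inversion that produced these constants
(`K = 4 kBT/w²` from the distribution width `w`) is implemented in
`analysis.fit_gaussian` and applicable to any simulated bond/angle
histogram.

## Integration and ensembles

The equations of motion are integrated with the Groot–Warren modified
velocity Verlet at `dt = 0.02 τ`, prediction parameter `λ_vv = 0.5`
(configurable): positions advance ballistically, forces are re-evaluated
at the predicted velocity, and velocities get the mean of old and new
forces.  The residual discretization artifact raises the kinetic
temperature by about 0.5 % at `dt = 0.02` with the default force field
(measured in the test suite; the tolerance band is 2 %).

Nonbonded pairs come from a binned Verlet list (cutoff 1, skin 0.4,
rebuilt when any bead has moved more than half the skin).  Candidate
pairs are accumulated in canonical ascending `(i, j)` order with exact
minimum-image arithmetic, so the forces are bitwise identical to an
all-pairs double loop — a property the test suite asserts.  Per-pair
random numbers come from a counter-based hash (splitmix64 finalizer) of
`(seed, evaluation counter, i, j)`, making every trajectory exactly
reproducible from `(config, seed)` and independent of the enumeration
order.

The zero-tension ensemble (`N γ_s P⊥ T`) uses a semi-isotropic Langevin
piston: one strain coordinate for the membrane normal (z) and one shared
by `x = y`, each obeying `W ε̈ = (P − P0) V − W γ_p ε̇ + noise` with
piston inertia `W = 2·10⁶` and damping `γ_p = 0.5 τ⁻¹` (defaults chosen
for overdamped box relaxation within ~10⁴ steps at the system sizes used
here; both configurable).  Driving normal and tangential pressure to the
same target forces `⟨γ_s⟩ = 0` by the definition
`γ_s = ⟨Lz (P_z − (P_x + P_y)/2)⟩`.  The virial uses conservative and
bonded terms only; random/dissipative contributions average to zero in
the diagonal stress and are excluded, as is standard.

## Flory–Huggins calibration

The mapping from excess repulsion `Δa = a_AB − a_AA` to the
Flory–Huggins `χ` uses the coexistence relation
`χ = ln[(1 − φ)/φ]/(1 − 2φ)` for the minority fraction φ of a demixed
binary fluid.  The experiment starts from a pre-separated A/B slab at
density 3, runs NVT to equilibrium, accumulates A/B density profiles
along z, locates the interfaces at the `φ = 0.5` crossings, and averages
the minority fraction over bins farther than `d_excl = 2 r0` from every
interface (the "homogeneous slab interior"; `d_excl` configurable).  The
slope λ of `χ = λ Δa` is a zero-intercept least-squares fit over
`Δa ∈ {10, 13, 16}` — mismatches small enough to stay in the linear
regime but strong enough (`χ > 2.7`) for clean plateaus; weaker
mismatches (χ near the critical value 2) do not develop homogeneous
interiors and are excluded by construction.

## Umbrella sampling and WHAM

Lipid flip-flop free energies use stiff harmonic biases
(`k = 200 kBT/r0²`) on the phosphate bead's signed z-offset from the
instantaneous bilayer midplane (circular-mean z of all lipid beads,
making the profile drift-invariant).  The production ladder is 61
windows spaced `0.15 r0` from the bilayer centre outward; starting
structures are pulled sequentially with a soft `10 kBT/r0²` spring over
10⁴ steps, then each window runs 5·10⁴ equilibration plus 5·10⁴
production steps.  The bias reaction force is spread uniformly over all
lipid beads so momentum stays conserved.

The WHAM solver iterates the standard coupled equations on binned
histograms (bin width `0.05 r0`, no Jacobian corrections for the 1-D
Cartesian coordinate) until the largest change in any window free energy
falls below `10⁻⁶ kBT`, then reports the PMF shifted to zero at its
minimum, with per-window overlap diagnostics; adjacent windows with no
histogram overlap are a hard error.  On synthetic samples drawn exactly
from a known quadratic surface the solver recovers the input PMF within
0.2 kBT RMS and is stable to bin-width halving within 0.1 kBT (both
asserted in tests).

## Observables

- Surface tension: `γ_s = ⟨Lz (P_z − (P_x+P_y)/2)⟩` over frames.
- Membrane thickness `l_mem`: distance between the leaflet-mean choline
  z-positions; leaflets are assigned per lipid by whether the head lies
  above or below its tail midpoint.
- Area per lipid: `a0 = Lx·Ly/(n_lipids/2)`.
- Chain order: `S_chain = ½⟨3cos²θ − 1⟩` of the first-to-last tail-bead
  vector against z (a per-bond variant is available behind a flag).
- Area compressibility: linear fit `Σ = K_A (a_prj − a0)/a0` restricted
  to the near-tensionless window `|Σ| ≤ 3 kBT/r0²`.
- Bending rigidity: `κ = K_A l_mem²/48`, the fluctuation-spectrum-derived
  shortcut; applied to the reference DMPC numbers (`K_A = 23 kBT/r0²`,
  `l_mem = 3.56 nm`) it gives ≈12 kBT, slightly above the ≈11 kBT quoted
  alongside those numbers in the source literature — the formula is
  implemented literally and the ~8 % discrepancy is inherited, not a
  package error.
- Rupture: a frame has a pore when a connected chain of water beads
  (neighbour distance < 1 r0, found by a periodic KD-tree plus connected
  components) spans from 2 r0 above the midplane to 2 r0 below; pores in
  more than half the frames classify the trajectory as ruptured.  The
  margins are conventions and configurable.

Unit conversions use `kBT` at 298 K.  Note that one published conversion
for the rupture tension (`5 kBT/r0² ≈ 4 mN/m`) is inconsistent with the
same source's area-modulus conversion (`23 kBT/r0² ≈ 188 dyn/cm`); this
package uses the latter, dimensionally consistent scale
(`1 kBT/r0² ≈ 8.17 mN/m`).

## Synthetic data and scaled-down problem sizes

The packaged generators (`dpdmem.fixtures`) produce deterministic
miniature systems (a 64-bead box, a 375+375 slab, a 32-lipid bilayer)
and closed-form synthetic datasets: a tanh-interface demixed profile at
a prescribed χ, and umbrella windows sampled exactly from a quadratic
free-energy surface.  The synthetic sets are oracles — they state their
distribution, so analysis code can be checked against ground truth —
but they do not emulate finite sampling correlation, interface
fluctuations, or barostat coupling; passing those tests validates the
estimators, not the simulator, which is validated separately by the
simulation-based checks.

Default calibration pipelines run laterally scaled versions of the
reference experiments, a deliberate design choice to keep a full
calibration within minutes on one core:

- χ slabs: `5×5×20 r0` (750+750 beads) instead of `10×10×20`
  (3000+3000); the slab height and therefore the interface geometry are
  preserved.  3·10⁴ equilibration + 5·10⁴ production steps.
- Equation of state: ~1000–3000 beads, 2·10⁴ steps per repulsion value.
- Bilayer structure: a 128-lipid DMPC patch (~6000 beads) for 10⁵ steps
  in the zero-tension ensemble, rather than 1152 lipids.

Scaling down raises sampling noise (λ carries a per-seed spread of about
±0.01 at the quarter cross-section, bilayer structure ~5 %) and the
quarter-width slab depresses λ slightly: at `a_ii = 25` the scaled-box
equilibrium estimate settles at 0.285–0.289, in line with the widely
used literature slope of 0.286 for those conditions, while published
remeasurements of the same quantity range up to 0.298 — a spread wider
than the scaled estimator's own systematic.  The full sizes are
available by passing the reference dimensions to the same functions.  Long-run observables — the multi-point tension scan for
`K_A ≈ 23 kBT/r0²`, rupture near 40 % area strain, DPPC gel order
(`S ≈ 0.88`), the 61-window flip-flop PMFs (≈16 kBT for DMPC, ≈34 kBT
for gel DPPC), and vesicle self-assembly from a free patch — are
supported by the same machinery (`examples/` shows the drivers) but are
multi-hour runs and are not part of the default test battery.

## Numerical choices and edge cases

- Collinear angles: the angle-force prefactor `sin(θ − θ0)/sin θ` is
  guarded by clamping `sin θ ≥ 10⁻⁸`; for the 180° tail angles the
  prefactor is analytically finite and the guard is inert.
- Coincident beads (`r² ≤ 10⁻²⁴`) exert no pair force (the soft
  potential's force is finite anyway; this guards the 1/r direction).
- Pair-list capacity grows geometrically on overflow; candidate search
  uses a `10⁻⁹` cutoff slack so the exact acceptance test downstream is
  the only arbiter of which pairs interact.
- The χ estimator uses mean densities over all production frames before
  forming fractions (ratio-of-means), avoiding small-count ratio bias.
- Degenerate inputs fail loudly: non-finite coordinates, box collapse
  below two cutoffs, non-demixed profiles, non-overlapping umbrella
  windows, and unknown species all raise typed errors.

## Known limitations

- No explicit electrostatics or polarizable water; head-group charge
  effects enter only through the boosted `Q–Q` repulsion, so phenomena
  driven by dipole interactions (e.g. water-pore formation during
  flip-flop) are absent by construction.
- The barostat scales coordinates affinely and leaves velocities
  unscaled; piston parameters are stability defaults, not physical
  constants.
- `κ` comes from the `K_A l²/48` relation, not from a fluctuation
  spectrum; it inherits that relation's assumptions.
- The temperature shown by the thermostat carries the usual
  Groot–Warren `O(dt)` offset (~0.5 % at `dt = 0.02`).
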