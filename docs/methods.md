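# Methods

This note records the models, conventions and numerical choices behind
poreflux, and what the synthetic-data validation does and does not
demonstrate about real trajectories.

## Unit system

Lengths nm, times ns, charges e, currents pA, potentials V (biases reported
in mV), fields V/nm, diffusion constants nm²/ns, temperatures K,
conductivities S/m. All conversions live in `poreflux.units`; the single
current conversion is 1 e/ns = 160.2176634 pA. The z axis is the membrane
normal and field axis throughout. Frames store wrapped coordinates;
consumers unwrap on demand through minimum-image displacements and never
store the unwrapped result.

## The Brownian-dynamics generator

The generator emulates the statistical structure of coarse-grained MD
electrolyte trajectories without simulating solvent: charged point
particles with per-species diffusion constants follow overdamped
(position-Langevin) dynamics,

    Δz = μ q E Δt + √(2DΔt)·ξ,   μ = D/(k_B T),   ξ ~ N(0,1),

with x, y purely diffusive. Defaults are the emulated protocol's
conditions: T = 320 K, D₊ = 2.54 and D₋ = 2.45 nm²/ns (measured
coarse-grained values), 500 ps sampling for bulk conductivity runs and
100 ps for pore runs. Velocities are recorded as the unwrapped displacement
over the sampling interval divided by that interval, the same information a
sampled MD velocity carries at these time scales; inertia is irrelevant
here, which is why overdamped dynamics (rather than velocity-Verlet)
suffice.

Three deliberate simplifications:

* **No ion–ion interactions.** The electrolyte is ideal, so the
  Nernst–Einstein conductivity κ_NE = Σ Nq²e²D/(k_BTV) is *exact*, not an
  approximation — the pipeline test κ/κ_NE ≈ 1 is then a pure estimator
  check. The price is the loss of screening (see the I–V discussion below).
* **Exact bulk integration.** Without geometry, the sum of Euler–Maruyama
  steps over a sampling interval is Gaussian with the same law as the
  per-step chain, so bulk runs draw one increment per interval. Pore runs
  step explicitly because reflections depend on position.
* **Hard-wired Einstein relation.** μ = D/(k_BT) by construction, so drift
  and diffusion cannot be inconsistent with each other.

A stability guard refuses configurations whose per-step drift exceeds a
quarter of the smallest resolved length (the z bin width L_z/100, and the
slab half-thickness and pore radius when a membrane is present).

**Membrane and pore.** The membrane is a reflecting slab normal to z
pierced by a cylindrical pore. A proposed move ending inside the slab but
outside the cylinder is reflected specularly in z about the face on the
side the particle came from (iterated up to 8 times); a particle already
inside the pore that would exit the cylinder laterally has its x, y move
rejected instead. Any never-resolving proposal falls back to rejecting the
whole move, so particle number is conserved unconditionally. Specular-z
reflection is the simplest rule that preserves the equilibrium density;
detailed balance is verified by the equal left/right crossing counts at
E = 0 in the test suite.

**Analytic fixtures.** For the electrostatics module the generator also
provides densities with known potentials: a parallel-plate capacitor (two
opposite uniform slabs; potential drop σd/ε₀) and a Gaussian dipole (erf
closed form). Slab discontinuities are sampled at half height so the
trapezoid integral of the sampled density is exact on aligned grids.
Each fixture's closed form is verified against its density by a
finite-difference Poisson check at construction.

## Conductivity pipeline

⟨I⟩ is the OLS slope of the cumulative current versus time. The cumulative
sum uses left-Riemann weights over the actual inter-frame intervals (for
regular sampling this is a plain cumulative sum; the weighting only matters
for irregular frame times). Per-field conductivities are retained and their
arithmetic mean reported when several fields are run, which makes
departures from linearity visible instead of hidden. When a trajectory
carries no velocities, forward finite differences of minimum-image
displacements are used; the choice between stored and finite-difference
velocities is explicit in the API (`velocities=` argument) and defaults to
stored ones when present.

## Electrostatics

Binning is particle-based (point charges into slices; no charge
spreading), by fractional z coordinate so NPT-style varying boxes
contribute to matching slices, each frame normalized by its own bin
volume. Symmetrization averages each species profile with its mirror image
about the bilayer center (exact bin reversal on symmetric grids, linear
interpolation otherwise); it is idempotent and annihilates odd components.

The double integration imposes ψ(z₀) = 0 and dψ/dz(z₀) = 0 at the lower
grid edge by default (configurable). This is the common MD post-processing
convention and leaves the potential flat in bulk solution; the reference is
configurable because the convention is not unique — only potential
*differences* are physical. Only the vacuum permittivity enters: a relative
dielectric constant used to screen forces at simulation time is a property
of the dynamics, not of this post-processing, and dividing by it here would
double-count the screening. Composite trapezoid quadrature gives the
O(Δz²) convergence verified on the Gaussian-dipole fixture. The operation
is linear in the density, so per-species components and the −E(z−z₀)
external ramp sum exactly to the total.

## Crossing detection and the window estimator

Between consecutive frames a particle's z displacement is read under the
minimum-image convention; the traveled segment (which may extend past the
periodic boundary) generates one signed event when it straddles the
detection plane or one of its periodic images. This is the unique rule
consistent with minimum-image displacements: a wrap far from the plane
yields no event, and a genuine crossing carried through the boundary is
still counted. Events are stamped at the later frame; no sub-frame
interpolation is attempted at the 100 ps resolution the protocol
prescribes. Equality of a segment endpoint with the plane is resolved
half-open (arrivals count, departures do not), so repeated touching never
double-counts. The detector is property-tested against an independent
brute-force counter on randomized wrapping paths.

Sampling matters: at 500 ps sampling with drift, a fraction of per-frame
displacements can exceed L_z/2, and minimum-imaging then flips those
(rare) crossings. Crossing analyses therefore run on 100 ps-sampled
trajectories, where the effect is absent at the simulated drift speeds.

Q(t) = N_c − N_a is kept in integer arithmetic — exact for any event list.
The window estimator works on −Q for net-negative transport and restores
the sign on output. σ is deliberately the *mean absolute deviation* of the
single-charge increment times from Ī·Δtᵢ (not a variance), and
δI = 2σ/Δt, with σ converted from e to pA·ns before the division. For a
perfectly periodic event stream σ = 0 exactly; for a Poisson stream the
windowed rate recovers the true rate within ~3λ/√ΔQ. Zero-bias runs, where
the 45-charge window is typically unreachable, report the whole-run OLS
slope of Q(t) instead, and the `iv` command falls back to it automatically.

The ohmic reference I_ref = ΔV/R_ref with R_ref = 1 GΩ is the typical
measured resistance of these channels; the negative branch is multiplied
by 0.7 to mirror the experimentally observed ~30 % rectification, and the
comparison line drawn next to simulated points is I_ref/10.

System-neutralization bookkeeping: to cancel an embedded charge q starting
from equal nominal pairs, ceil(|q|/2) ions are removed from one side and
floor(|q|/2) added to the other (2054 pairs with +7 e → 2050 cations,
2057 anions), changing the total count by at most one.

## Stationarity

Stem occupancy counts ions with z in [plane, plane + 4 nm). The plateau
time is this package's own estimator (no standard one exists): the
earliest t* whose rolling mean over [t*, t*+window] stays within a
tolerance of the final rolling mean for the remainder of the series
(window 50 ns, tolerance 10 % by default; the tolerance floor is one
count so plateaus near zero remain meaningful). Because windows adjacent
to the series end always track the final mean, a plateau is only credited
when held for at least two windows — otherwise the series is reported as
still drifting. τ = L²/D_eff uses the harmonic-mean diffusion constant;
with the default D± and L = 18.5 nm of solvent it evaluates to ~137 ns.
L is an explicit argument because "the length occupied by solvent" admits
both the full box height and box-minus-membrane readings; the full box
reproduces the ~140 ns estimate.

## Validation problem sizes and study conditions

Chosen once for desk-scale turnaround and recorded here:

* **Bulk recovery** — 500 ions/species plus 100 neutral tracers in a
  ~11.1 nm cube (~0.6 M), E = 0.02 V/nm, 2500 frames at 500 ps. Recovers
  κ/κ_NE and tracer D within a few tenths of a percent, drift within
  sampling error.
* **Pore system** — 8 × 8 × 16 nm box, slab half-thickness 2 nm centered
  at z = 8, pore radius 1.3 nm (an α-hemolysin-like lumen), 300
  ions/species (~0.5 M), 100 ps sampling, detection plane at the trans
  face z = 6.
* **Linear-response I–V** — biases 32–80 mV (E = 0.002–0.005 V/nm), run
  lengths 330–600 ns scaled inversely with the field so each bias yields
  ≥ ~25 windows of 40 crossings. The windowed-current slope Ī/ΔV is then
  constant to a few percent.
* **Saturation probe** — E = 0.04, 0.08, 0.12 V/nm (0.64–1.9 V), 20–40 ns
  each with proportionally smaller timesteps: currents rise monotonically
  while the secant slope Ī/ΔV falls monotonically (to ~0.8 of its value at
  0.64 V) — the sub-linear approach to a limiting current expected of a
  finite pore under drift-dominated transport.

## What passing the synthetic validation does and does not show

The generator reproduces the *statistical* structure the analyses assume —
drift-diffusion kinematics, reflecting geometry, periodic wrapping, event
streams — so green tests certify the estimators: unit chains, regression
and window statistics, crossing bookkeeping, quadrature. They do not
certify electrolyte physics the generator omits: no screening, no
ion–ion or ion–water correlations, no pore charge, no protein dynamics.
Two visible consequences: the ideal gas accumulates ions against the
blocked membrane face in proportion to the drift speed, which bends the
I–V curve upward above roughly 100 mV (a real electrolyte screens this,
which is why measured channels stay linear to ~350 mV); and absolute
currents are generator-specific, so only ratios, shapes and closed-form
comparisons carry meaning. Box-size effects are likewise not emulated
(the box is constant per run; readers accept varying boxes).

## Known limitations

* The frame-table format stores one row per particle per frame — simple
  and diffable, but large for long runs; use the XTC/TRR adapter for bulky
  inputs.
* `symmetrize_profile` re-grids by linear interpolation when the grid is
  not symmetric about the requested center; exactness holds only in the
  symmetric case.
* The plateau estimator's "not reached" verdict depends on the window
  length; series that settle only within the last two windows are
  conservatively reported as drifting.
* GRO reading supports orthorhombic boxes (the first three box-vector
  components); triclinic boxes are not supported anywhere in the package.
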