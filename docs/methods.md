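# Methods

`pistack` estimates the π–π stacking binding energy of aromatic (PAH)
H-type dimers by steered molecular dynamics driven purely by a CHARMM-style
nonbonded force field, and validates the estimate against the direct
potential-energy difference of the same force field.

## Model

**Energetics.** Monomers interact only through nonbonded terms: a 12-6
Lennard-Jones potential `E = ε[(Rmin/r)¹² − 2(Rmin/r)⁶]` with CHARMM36
parameters (aromatic carbon CA: ε = 0.070 kcal/mol, Rmin/2 = 1.9924 Å;
aromatic hydrogen HA: ε = 0.022, Rmin/2 = 1.3200), combined with the CHARMM
rules (geometric-mean ε, additive Rmin/2), plus Coulomb interactions
`332.0636·qᵢqⱼ/r` between the aromatic partial charges (C −0.115 e, H
+0.115 e, ring-fusion carbons 0 e; every monomer neutral). Both terms are
damped by the CHARMM energy-switching function between 10 and 12 Å, so
energies and forces are continuous; forces are the exact negative gradient
of the switched energy (verified to 1e−6 kcal/(mol·Å) by central
differences). Electrostatics uses plain switched Coulomb rather than a
lattice-sum method: the systems are small, neutral and non-periodic, where
mesh Ewald would add nothing but a periodic artifact. This is a deliberate
deviation from solvated periodic practice and is documented here.

**Rigid monomers.** Bonded terms dominate the total potential energy of a
molecular mechanics model but contribute nothing to the *inter*-molecular
stacking energy, so each monomer is propagated as a rigid body: idealized
planar geometry (C–C 1.39 Å, C–H 1.08 Å, 120° angles), fixed internal
coordinates, 6 degrees of freedom. This is the package's main
simplification. Its cost is physical: a rigid monomer has no internal modes
to absorb the energy released when a stacking contact slips, which matters
for the force-curve analysis (see *Known limitations*).

**Integrator.** Velocity Verlet on the centre of mass plus a rigid-rotor
update: angular momentum is the propagated variable, kicked by the torque
about the COM; the free rotation over a step uses the symmetric
principal-axis factorization (half-step about axis 3, half about 2, full
about 1, and back), which is time-reversible and conserves the lab-frame
angular momentum of every molecule to round-off. Coordinates are rebuilt
from the body frame each step, so rigid geometry cannot drift. Measured
behaviour with a 1 fs step: total-energy fluctuation of a bound dimer well
below 1% of the well depth over 50 ps, error scaling ~dt². Default
timestep 0.001 ps (1 fs).

**Thermostats.** The free-diffusion (dimerization) phase uses a Langevin
thermostat implemented as an Ornstein–Uhlenbeck kick on COM velocity and on
angular momentum in the principal frame (default friction 1 ps⁻¹, 300 K).
During steered pulls the thermostat is *forbidden*, not merely off by
default — the protocol's noise-reduction requirement — and requesting one
raises a protocol error.

## Steered pulling

A dummy point starts at the pulled molecule's COM and moves at constant
velocity v (default 0.01 Å/ps) along the pulling direction n̂ (default: the
line from the fixed monomer's COM to the pulled monomer's COM at t = 0, the
natural dissociation coordinate). The applied force is the harmonic
restoring force of a spring of stiffness k (default 4 kcal/(mol·Å²) =
277.9 pN/Å, printed as 278) acting on the *projected* extension:
F = k[(x_dummy − x_COM)·n̂]n̂, the constant-velocity SMD convention of
GPU MD engines. Transverse motion is free, which is what allows a stacked
dimer to slide apart ring by ring (multi-step dissociation) instead of
popping off in one event. The force is distributed over the pulled
molecule's atoms in proportion to mass, so it exerts no torque. The
recorded scalar is the projected spring force in pN.

Replicas share the starting geometry and differ only in the seed used to
draw Maxwell–Boltzmann initial velocities (at 300 K) for the pulled
molecule; a replica seeded `None` starts at rest, giving a bitwise
deterministic pull.

## Force-curve analysis

The spring force trace is smoothed by a 10 ps centred moving average
(window exposed as a parameter) and segmented into **transitions**: ramps
from a running start force F₀ to a peak F₀+dF that end when the force falls
by more than max(25% of dF, 10 pN) below the peak. The 10 pN floor exists
because an undamped rigid dimer "rings" after each slip (period ~2 ps);
smoothing attenuates the ringing to roughly the 10–20 pN level and the
floor keeps pure ringing residue from registering as unbinding steps.
Each transition contributes the spring-energy release

    ΔE = (F₀ + dF/2)·dF / k   [pN·Å; 69.477 pN·Å = 1 kcal/mol]

which is algebraically the spring potential-energy difference
((F₀+dF)² − F₀²)/2k. Transitions whose peak occurs at a COM separation of
10 Å or more are discarded: the van der Waals interaction is short-ranged
and force features beyond that distance cannot be attributed to stacking.
Per replica the retained transition energies are summed; across replicas
the package reports mean ± sample SD (n−1; a single replica reports SD 0
with a warning).

**F₀ convention.** The spring-energy derivation requires F₀ to be the force
at the start of the ramp (equivalently, the force remaining after the
preceding drop); the phrase "force at the end of the transition" found in
descriptions of this estimator is consistent with that reading when the
transition is taken to be the drop itself. Both readings give the same
energy; the implementation uses the ramp start.

## Direct PES oracle

The binding energy of a rigid dimer in the energy-difference convention
E(monomer 1) + E(monomer 2) − E(dimer) reduces, for rigid monomers, to
minus the intermolecular energy. A full grid scan over separation
(3.0–4.75 Å, 0.25 Å), lateral offset along the long in-plane axis
(0–2.75 Å, 0.25 Å) and optionally twist (15° steps), followed by
Nelder–Mead refinement, locates the optimal stacking geometry. For benzene
the refined optimum is parallel-displaced (offset ≈ 2.9 Å) with binding
≈ 2.0 kcal/mol, inside the 2–3 kcal/mol gas-phase literature band, and the
sandwich geometry is strictly less favourable — the expected staggered
preference. For anthracene the direct value is ≈ 7.4 kcal/mol,
essentially the gas-phase quantum-chemical value for this dimer.

## Free-diffusion phase and plateau detection

Two monomers start 15 Å apart and diffuse under the Langevin thermostat
inside a reflecting sphere of radius 25 Å. The sphere stands in for the
finite solvated box of a conventional periodic simulation: in open vacuum
the relative diffusion of two monomers is transient (the pair escapes with
probability ≈ 60% from 15 Å) and spontaneous dimerization would be a coin
flip rather than a property. Inside the droplet, capture (COM < 6 Å)
occurs on the few-hundred-ps to few-ns scale.

Stable dimers appear as COM-distance plateaus: maximal intervals where the
rolling mean is below 6 Å and the rolling variance below 1.5 Ų, lasting at
least a dwell time (50 ps at desk scale). The variance tolerance was
calibrated once to the model's own bound state — a bound rigid anthracene
dimer at 300 K in vacuum fluctuates with COM variance ≈ 0.7 Ų, and the
detector must not classify the bound state itself as unstable. On synthetic
traces with injected bound intervals (σ = 0.2 Å) the detector recovers
> 95% of intervals with no false positives.

The reproduction pipeline picks the four longest plateaus' midpoint frames
as pulling starts (sampling extra in-plateau frames when fewer than four
plateaus exist); if no plateau is ever found — expected for benzene, whose
binding is too weak for stable dimerization — it falls back to the
constructed optimal stacked dimer with a warning.

## Problem sizes

Desk-scale defaults, chosen so a study runs in minutes on one CPU: 2 ns of
free-diffusion MD; pulls of ~1 ns per replica (duration set so the COM
separation passes ~11.5 Å); four replicas per system; 1 fs timestep
throughout; force curves recorded every 0.1 ps. The inner loops (pair sums
and rigid-body updates) are numba-compiled; fastmath is disabled so equal
seeds give bitwise-equal trajectories.

## What the synthetic conditions do and do not show

The generator emulates the published study's *protocol* — CHARMM36
nonbonded parameters, k = 4 kcal/(mol·Å²), v = 0.01 Å/ps, thermostat off,
one monomer fixed, four replicas, the 10 Å relevance cutoff — at desk
scale, in vacuum, with rigid monomers. It does not emulate explicit
solvent, monomer flexibility, or 100 ns sampling. Passing tests therefore
demonstrate the machinery (energetics, integration, pulling, analysis) and
its internal consistency, not solution-phase energetics.

## Known limitations

- **Vacuum + rigidity depress the force-curve estimate.** In this model a
  stacked dimer partially *yields gradually* while pulled: part of the
  binding energy is paid reversibly between slips, producing no force drop
  and hence never entering the spring-release sum; and with no solvent or
  internal modes to damp it, post-slip ringing fragments the remaining
  ramps. Measured on the anthracene dimer at v = 0.01 Å/ps: thermally
  seeded replicas average ≈ 15–30% below the direct PES value, and a fully
  cold (start-at-rest) pull loses closer to half of it; both sit a further
  ~2 kcal/mol below solvated reference values (solvated estimates
  include solvent-cage stabilization; the published gas/solvent
  quantum-chemistry gap for these dimers is ≈ 2 kcal/mol). The package
  reports what the desk-scale vacuum model actually yields (anthracene
  ≈ 6–7 kcal/mol) rather than tuning the analysis toward solvated values.
- **Frozen solvent cannot be pulled through.** The static-scenery water
  shell is faithful to "stationary water" only for configurational
  snapshots; fully immovable waters are impenetrable to a pulled molecule
  (real stationary water still yields locally), and pulls through a frozen
  shell wind the spring without bound. The scenery mode is therefore a
  background for short runs, not a pulling environment.
- T-shaped dimers and charged dyes are out of scope; so are lattice-sum
  electrostatics and pressure coupling.
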