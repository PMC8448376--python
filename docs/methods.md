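# Methods

## Model

Four scalar fields are tracked on a 2D vessel domain: resting platelets
[RP], activated platelets [AP], ADP and platelet polyphosphate (PolyP), all
in model nM (platelet "nM" is a bookkeeping convention — 10 nM total
circulating platelets with 5% activated — not an Avogadro conversion of the
count 2.5·10¹¹ /l). Each species satisfies

    ∂A/∂t + u·∇A − D ∇²A = R(A)

with diffusivities D_RP = D_AP = D_PolyP = 10⁻⁷ cm²/s and
D_ADP = 25.7·10⁻⁷ cm²/s (Brownian plus shear-enhanced estimates). The
reaction terms couple the species through a single activation flux

    S = k_AP·f_ADP([ADP])·[AP]·[RP]  +  k_SR·f_SR(SRcum)·[RP]  +  k_IIa·[RP]

    R_RP = −S,  R_AP = +S,  R_ADP = ADP_rel·S,  R_PolyP = PolyP_rel·S

with k_AP = 0.3 nM⁻¹s⁻¹ (3·10⁸ M⁻¹s⁻¹ converted once at parameter load),
k_SR = 0.6 s⁻¹ and k_IIa = 0 (thrombin-mediated activation is out of scope:
the model addresses initiation before thrombin generation). Both gates are
ramps: f_SR rises linearly from 0 at SRcum = 250 to 1 at 500; f_ADP rises
from 0 at 0.2 µM to 1 at 1 µM. The ADP gate multiplies only the
autocatalytic k_AP term; the mechanical term stays ungated, otherwise shear
activation could never bootstrap agonist release in agonist-free blood.

The release ratios come from dense-granule stoichiometry: content (3 mol
ADP, 0.74 mol PolyP per 10¹⁷ platelets) × release fraction (0.75) ×
platelet count (2.5·10¹¹ /l), expressed in nM and divided by the 10 nM
reference platelet concentration: ADP_rel = 562.5, PolyP_rel = 138.75
(dimensionless). The printed ratios are reproduced exactly with PolyP
content 0.74; the alternative literature value 0.743 is available as an
override and gives 139.3125.

Equations of the form L[ADP] = ADP_rel·L[AP] are interpreted as
reaction-term proportionality (R_ADP = ADP_rel·R_AP): taken operator-wise
the identity cannot hold because the two species have different
diffusivities, while the stoichiometric derivation above supports exactly
the reaction-coupling reading.

### PolyP criticality units

The factor-XII activation threshold for PolyP is a mass concentration,
2 µg/ml. Converting mass to molar requires a molecular weight:
`polyp_mass_to_molar(2, 101.98)` = 19 611.7 nM in monomer (NaPO₃ residue)
units. Under the model's own stoichiometry that level is provably
unreachable: W = [PolyP] + PolyP_rel·[RP] satisfies the homogeneous
transport equation (R_PolyP = −PolyP_rel·R_RP, identical D and u), its
inflow and initial value are 138.75·10 = 1387.5 nM, and the maximum
principle then bounds [PolyP] ≤ 1387.5 nM for all time. Platelet-released
polyP, however, circulates as chains of roughly 60–100 residues, and the
release inventory never states monomer units; reading the transported PolyP
as per-chain makes the criticality threshold 2 µg/ml ÷ (75 × 101.98 g/mol)
≈ 261.5 nM, which activated regions do exceed. The default
`CriticalThresholds` therefore uses chain length 75 (configurable;
`polyp_chain_length=1` restores the strict monomer reading, under which the
PolyP-critical volume fraction is identically zero by the bound above).

## Synthetic flow fields

Both generators derive the velocity from a stream function, so the continuum
field is exactly divergence-free and walls are streamlines (no-slip is also
satisfied because the profile derivative vanishes at the walls).

* **Control channel** — pulsatile Poiseuille flow
  u_x = U(t)(1 − (y/h)²), U(t) = U₀(1 + a sin 2πt/T), defaults U₀ = 20 cm/s,
  a = 0.5, h = 0.15 cm, L = 2 cm, T = 0.8 s. The default U₀ gives a wall
  shear rate of 267 s⁻¹ (TAWSS ≈ 10.7 dyne/cm²), in the range of a normal
  human coronary; see "wall-layer ignition" below for why a low-shear
  control is not a faithful normal vessel in this model.
* **Aneurysm** — a variable-width throughflow ψ_t = C·s(y/h(x)) through a
  cosine-profile bulge (h from 0.15 to 0.4 cm over 1.5 cm), plus a
  bulge-localized vortex ψ_v = A·b(x)·(1 − η²)². The throughflow pulses with
  amplitude 0.2 and the vortex with amplitude 0.6 at a π/2 phase lag
  (defaults: throughflow 4 cm/s, vortex strength 3). The phase lag is what
  makes instantaneous streamlines reshape over the cycle: a uniformly
  modulated stream function has time-invariant streamline shapes, so inlet
  particles would sweep past the vortex and never accumulate shear history.
  With the lag, inlet tracers are entrained into the bulge, orbit for many
  cycles, and build SRcum beyond the 250–500 activation ramp, while the
  vortex core region retains agonists (Eulerian stagnation). A numerical
  check at construction verifies the stagnation contract (some interior
  bulge point with cycle-averaged speed below 1% of the throughflow).

What the generators emulate: pulsatile inflow over a cardiac cycle, a
monotone-throughflow normal vessel, and an aneurysmal recirculation with
flow stagnation. What they do not emulate: 3D secondary/helical flow,
patient anatomy, wall motion (the transport consumes velocity fields, it
does not solve Navier–Stokes), flow-rate waveform shape beyond a single
harmonic. Passing tests therefore demonstrate the mechanisms — washout vs
accumulation, mechanical vs biochemical dominance — not patient-level
magnitudes.

Fields are stored as K = 20 nodal frames per period with periodic linear
interpolation in time and barycentric (P1) interpolation in space — the
same representation used when external VTU series are supplied. The cycle
phase is rounded to 12 decimals before interpolation so that samples at t
and t + T are bit-identical (the quantization, 10⁻¹² of a period, is far
below any time scale of the problem).

## Lagrangian tracking

Massless tracers (platelet Stokes number ≪ 1) are released at every
interior inlet node (wall-corner nodes are excluded — they sit at the
no-slip zeros — and seeds are nudged 10⁻⁶ of the domain diameter inward),
in four cohorts at t = 0, T/4, T/2, 3T/4. Integration is classical RK4 with
fixed dt = T/1000; a fixed step keeps the SRcum Riemann sum well defined
and runs reproducible (pathlines are bit-identical given seed, dt and
field). SR is sampled at each accepted position from the element-constant
gradient of the P1 interpolant; SRcum uses the left-endpoint sum Σ SR·Δt,
which makes it exactly non-decreasing. Termination: reaching the outlet
(the crossing is bisected along the step and the exit time interpolated),
stagnation (trailing-period path length below 10⁻³ of the domain diameter),
or 30 cycles. A wall overshoot (interpolation artifact) projects the
particle back to just inside the crossing point and continues, counting
projections; more than 100 aborts with "tracking unstable, reduce dt".

The average SRcum field is the sample-weighted per-element mean over all
samples, pathlines and cohorts (elements never visited are reported
missing); residence time is the per-element mean, over visiting pathlines,
of time spent in the element. Sample weighting makes slow regions — where a
platelet spends many steps — dominate their elements' averages, which is
the intended dose interpretation.

Because the discrete SR is the element-wise constant derivative of the P1
interpolant, it equals the analytic Poiseuille shear rate exactly at the
mid-height of each structured mesh row and differs by O(Δy) elsewhere; the
closed-form checks are evaluated at row midspans for this reason.

## Transport solver

Linear triangles with SUPG streamline stabilization;
τ = ((2/dt)² + (2|ū|/h_e)² + (4D/h_e²)²)^(−1/2) per element with ū the
element-mean velocity and h_e the equilateral-equivalent size. Time
stepping is a θ-scheme with θ = 1 (backward Euler) by default; reactions
are applied by first-order operator splitting as a vectorized RK4 substep
of the local kinetics after each implicit transport solve. dt defaults to
T/200. Systems are factorized (sparse LU) once per distinct cycle phase and
diffusivity and reused across cycles.

The advection operator uses the advective form u·∇A. The continuum fields
are divergence-free, but the P1-interpolated velocity has an O(h) discrete
divergence, and in the conservative form ∇·(uA) that error acts as a local
exponential source/sink: on the aneurysm case it compounded over 2000 steps
into concentrations two orders of magnitude above the analytic bound. The
conservative form remains available (`RADConfig(conservative=True)`) for
discretely divergence-free inputs. An optional lumped mass matrix exists
but is off by default: probing uniform advection showed the consistent-mass
SUPG scheme keeps over/undershoots below 0.01% where lumping introduced
1–2%.

Boundary conditions: Dirichlet at the inlet (circulating values), natural
no-flux walls, free (zero diffusive flux) outflow — standard for
advection-dominated outlets; the macroscale Péclet number is ~10⁷, so
upstream influence of the outlet is negligible (at the platelet microscale,
U ~ 10⁻³ cm/s and L ~ 2 µm give Pe ~ 2, which is why near-wall diffusion
physics is listed under limitations). Negative concentrations (stabilized
advection is not monotone) are clipped to zero after each step and the
clipped mass is logged per run.

One-way coupling: the SRcum field is reconstructed once from the tracking
stage, averaged to nodes, and frozen during the transport solve, mirroring
a post-processing pipeline on pre-computed flow.

## Study conditions and problem sizes

Cardiac period T = 0.8 s; meshes at 0.05 cm resolution (control 287 nodes,
aneurysm 1207 nodes); 10 cycles of transport (sufficient for the
concentration fields to reach their cyclic pattern), 30-cycle cap and
dt = T/1000 for tracking. These sizes keep a full two-case run in the
minutes range on one CPU while resolving the bulge vortex with ~8 elements
across its core.

## Known limitations

* **Wall-layer self-ignition.** Because baseline ADP (250 nM) exceeds the
  200 nM gate, stationary blood self-activates: the 0D kinetics reach full
  activation from circulating values in ≈ 3.5 s with no shear at all. Any
  no-slip wall therefore carries a thin layer whose residence time exceeds
  that fuse; at low wall shear (e.g. 133 s⁻¹) the layer ignites within a
  2 cm channel and produces steady agonist-critical wall fractions of
  several percent even in a straight vessel, which is why the control uses
  a normal-coronary wall shear (267 s⁻¹) — there, transit outruns ignition
  at every tested resolution. This sensitivity is a property of the model's
  constants, not of the discretization.
* **Trapped-core overshoot.** In the closed vortex core, stabilization
  over/undershoots created at the steep activation front are swept inward
  and cannot leave; over thousands of steps the platelet sum there can
  exceed its analytic bound (10.5 nM) severalfold. Threshold-based volume
  fractions are insensitive to this (the affected region is far above every
  threshold), and the clipped-mass log quantifies the related mass error,
  but pointwise concentrations inside the core should not be read
  quantitatively.
* **Release-phase sensitivity of the SRcum field.** In this 2D
  time-periodic flow the chaotically trapped orbits dominate the L2 norm of
  the reconstructed SRcum field, and which orbits a cohort populates
  depends on its release phase: going from 4 to 10 cohorts changes the
  field by ~30% in relative L2, and the change does not shrink with seed
  density (31% at 15 seeds/cohort, 31% at 150), i.e. it is systematic, not
  sampling noise. Volume-integrated activation metrics are far less
  affected. In 3D vessel flows, transit pathlines dominate the
  reconstruction and stagnant particles terminate instead of orbiting, so
  this sensitivity is expected to be specific to the 2D idealization.
* The SUPG scheme is not monotone in shear flows near no-slip walls;
  maximum-principle behavior at the 1% level holds for resolved transport
  in smooth flow.
* No thrombin, coagulation-factor network, clot growth, platelet
  margination (negligible at these scales and shear rates), FSI, or
  adaptive meshing.
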