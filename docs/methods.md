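# Methods

This note documents the models implemented in `stimcoil`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
measurement rig does and does not emulate.

## Scope and conventions

All problems are posed as linear magnetostatics: the drive is DC (switching
transients are handled separately by a lumped circuit model), there are no
eddy currents, and materials are linear.  Configuration files use
millimetres and amperes — the convention of winding drawings — while all
internal computation is SI (m, T, A); conversion happens once, at the I/O
boundary.  Coordinates are right-handed with the coil axis along z and the
origin at the device's geometric centre (for the rod, the rod midpoint; for
the pot core, the mid-height of the cup, open face toward +z).  Positive
current flows counter-clockwise viewed from +z and produces a +z field at a
loop's centre.

## Winding geometry and design rules

Wire sizes follow the AWG closed form d = 0.127 mm · 92^((36−g)/39) with DC
resistance from annealed-copper resistivity (1.7241·10⁻⁸ Ω·m at 20 °C); no
temperature coefficient is applied, since heating is modelled separately.
The effective wound pitch of insulated wire defaults to 1.11× the bare
diameter rounded to 0.01 mm — for 20 AWG this gives exactly 0.90 mm, which
square-packs the air-core channel (20 × 11.5 mm) to its nominal 264 turns.
The pitch is overridable per gauge in configs.

The three-coil stack's total height is h = 0.821116·d applied to the inner
side length, interpreted as the **top-coil-centre to bottom-coil-centre
distance** (coil centres at 0 and ±h/2).  This is the standard convention
for three-coil square systems; the physical envelope is taller by one coil
height.  The interpretation is stated prominently because winding tables
sometimes quote envelope heights instead, which are not the same quantity.
The stack supports centre-to-outer ampere-turn ratios of 1.0 (equal turns,
planar uniformity, the as-built choice) and 20:39 (volume uniformity).

Predicted winding resistance is turns × centroid-perimeter × Ω/m.  Leads,
contact resistance, and temperature rise are not modelled, so bench values
are expected to sit 10–30% above the prediction.

## Filament (Biot–Savart) model

Wound cross-sections are discretized into a radial × axial grid of filament
loops at cell centroids, each carrying I·N/(n_r·n_z) so the total
ampere-turns are conserved exactly at any resolution.  The default 12 × 12
subdivision changes the air-core centre field by < 0.5% versus 2× finer.
Circular loops use the complete-elliptic-integral solution (scipy's
`ellipk`/`ellipe`); square loops sum four finite straight-segment
contributions.  Evaluation within 1 nm of a filament is singular: single
evaluations raise an error, gridded maps mask the affected cells instead of
aborting.  Field maps are cell-centred grids on named planes (XY/XZ/YZ)
with the step stated in mm in the scan format (0.5 mm is the measurement
default).

## Axisymmetric finite-element solver

Rotationally symmetric devices (rod, pot core, circular coils) are solved
on the (r, z) half-plane for the scaled azimuthal potential u = r·A_φ:

    ∇·( (1/(μ₀ μ_r r)) ∇u ) = −J_φ ,   u = 0 on the axis and far boundary,

with B_r = −(1/r)∂u/∂z and B_z = (1/r)∂u/∂r.  Working with u (which decays
as r² at the axis) avoids the 1/r singularity of A_φ.  First-order
triangles are used with the 1/(μ₀μ_r r) coefficient evaluated at element
centroids; the assembled system is symmetric positive definite and solved
directly.  The coil current density is N·I divided by the *meshed* coil
area, so ampere-turns are conserved exactly under stair-step labelling.

**Meshing.**  Points are generated by a 2:1-balanced quadtree driven by a
Lipschitz size field — target edge near the device, target/8 at the rod
tips, growing at slope ≈ 0.5 away — then Delaunay-triangulated.  This keeps
triangle aspect ratios bounded (≤ 10 enforced in tests) where a graded
tensor grid could not.  A refined corridor along the axis (r ≤ 3 mm over
the scan range) supports on-axis field recovery.  Material labels are
assigned at triangle centroids; interfaces are therefore stair-stepped at
the local mesh scale, which the conserved source term and the fine near-
device resolution keep benign.  A structured `rectangle_mesh` exists for
manufactured-solution verification (u = r² is reproduced at second order).

**On-axis evaluation.**  B_z(0, z) is recovered from the near-axis
expansion u = (B/2)r² + c r⁴ by least squares over a band of probe radii
(0.7–3 × r_probe; r_probe 0.8 mm for the rod, 0.6 mm for the pot core).
On-axis scans are reported from 1 mm beyond the device surface, because
apex values at a machined tip are geometry- and mesh-sensitive.

**Domain.**  The far Dirichlet boundary sits at ≥ 5× the device extent
(rectangular domain); doubling the factor to 10 moves the 10 mm on-axis
value by < 1%, which is enforced as a test.

**Validation.**  Three independent oracles: (i) cross-solver equivalence
with the filament model at μ_r = 1, within 2% on axis ≥ 2 mm from windings;
(ii) the exact permeable-sphere-in-uniform-field solution at μ_r = 10³
(interior amplification 3μ/(μ+2), exterior dipole), matched to a few
percent at moderate resolution; (iii) manufactured-solution convergence at
O(h²).

**Material model.**  Strictly linear; mu-metal (μ_r = 10⁵) and ferrite
(μ_r = 10⁴) saturate near 0.5 T in reality, so a warning is logged whenever
the computed core field exceeds that — the rod tip region does exceed it at
the 15 A design current, meaning real tip-adjacent fields will be somewhat
lower than the linear prediction.  Remanent magnetization of the rod is a
documented caveat, not a model feature.

## Device geometry defaults

* **Rod**: the tips of a rod machined "to a point" are modelled as straight
  cones from the full 5.235 mm radius to a 0.2 mm tip radius over the last
  15 mm of each end; the coil is centred at mid-rod.  Both are
  configurable.  The on-axis field ~10 mm from the tip is sensitive to this
  unmeasured profile: shorter/blunter tapers concentrate more flux near the
  end face and can raise the 10 mm value by 25–75% relative to the default
  cone.  This is the dominant geometric uncertainty of the rod model.
* **Pot core**: the cup envelope (30 mm × 9.45 mm, channel 6.5 × 6.05 mm)
  does not determine the centre-post radius or shield thickness; they are
  inferred by matching post and shield flux areas (π p² = π(R² − (p+w)²)),
  giving p ≈ 7.14 mm and a 1.81 mm shield, and recorded in the mesh
  metadata.  The coil rests on the channel floor.  The ferrite's wide
  permeability tolerance (±30%) moves the 10 mm field by well under 5% —
  at μ_r ~ 10⁴ the flux is geometry-limited, not material-limited.

## Sham (bifilar) model

The double wrap is modelled as two complete windings of N/2 turns each,
displaced axially by the strand offset (default: one wire pitch), driven
++ in active mode and +− in sham.  Active double-wrap and single-wrap
fields agree to < 1% beyond 5 mm; the sham residual scales linearly with
strand offset for offsets much smaller than the coil, vanishes as the
offset → 0, and at one 20 AWG pitch sits roughly 40–80× below the active
field at the 10 mm report location — comfortably beyond the 10× criterion
used for a valid negative control.  The ≥ 10× figure is a validation
criterion, not an enforced constraint; results below it only produce a
warning in reports.  The strand offsets of physically wound coils are not
measured, so attenuation is characterized as a function of offset rather
than matched to a single number.

## Transients and heating

For a series RL winding, the 10–90% rise and fall times are equal,
t_r = (L/R)·ln 9.  The transient E-field at the target is estimated by
Faraday's law over that transition with ΔB = 0.8·B_steady:
E = g·0.8·B/t_r.  The geometry factor g defaults to 1 m, which reproduces
the platform's reporting convention of quoting dB/dt directly in V/m; note
that a physical loop of radius a would contribute g = a/2, so the default
is a convention, not a target-anatomy estimate — g is exposed precisely so
users can substitute a physical value.

Coil heating uses a first-order lumped model,
T(t) = T_amb + I²R·R_th·(1 − e^(−t/(R_th·C_th))), chosen because it is the
simplest model that produces the observed exponential shape of maximum
operating time versus current.  R_th and C_th are per-device fixture
parameters (defaults in tests: 3 K/W, 600 J/K), not measured constants.
The time to the 75 °C safety limit has the closed form
t* = −R_th·C_th·ln(1 − ΔT_lim/(I²R·R_th)) when the steady-state rise
exceeds the limit, and is unbounded otherwise.  Operating-time curves are
fitted as t = a·e^(−bI) by least squares in log space with unit weights.

## Scan comparison

Alignment of two |B| maps maximizes zero-normalized cross-correlation over
integer cell shifts within ±¼ of the grid size; ties break toward the
smallest displacement.  Sub-cell registration is out of scope.  Within a
measurement session the scanner offset is estimated once, from the active
scan, and applied to sham and control scans — residual/noise images carry
no usable alignment signal.  Uniformity percentages are centre-relative,
100·(|B|(±o) − |B|(0))/|B|(0), averaged over the two symmetric offsets
(this "average of the pair" reading is documented because percent-
uniformity conventions vary).  Default report locations are 10 mm on-axis
for the air/rod/pot devices and the plane centre for the three-coil stack.

## Synthetic measurement rig

The rig emulates a three-axis Hall probe on an XYZ scanner: per grid point
it averages five independent vector reads with per-axis Gaussian noise
(default σ = 0.13 mT — the noise class of consumer three-axis Hall sensors;
a fixture choice, configurable) plus a constant offset field (|offset| =
0.05 mT, standing in for ambient/Earth field and probe bias).  Scanner
misalignment is an integer-cell shift of the sampled content with edge
replication.  Everything is deterministic given (configuration, seed);
seeds are explicit arguments recorded in output metadata, and condition
sets derive independent sub-seeds per condition.

What the rig does **not** emulate: scanner kinematics and settling, sensor
nonlinearity and temperature drift, probe-axis cross-talk, and sub-cell
misalignment.  Passing end-to-end tests therefore demonstrates that the
comparison pipeline recovers known truth under idealized Gaussian
measurement statistics — not that any physical rig meets those statistics.

## Problem sizes used in tests

The test and acceptance runs use the as-simulated device geometries with
12 × 12 filament discretization for headline numbers (6–8 subdivisions in
statistical replicate loops), FEM meshes of roughly 25–90k triangles
(target edges 0.8–1.2 mm, tip refinement to ~0.15 mm), 20-seed end-to-end
replicates, and 50-replicate thermal fits.  These sizes were chosen so each
quantity is converged well inside its stated tolerance (refinement studies
are part of the test suite).

## Known limitations

* Linear materials: no saturation, hysteresis, or remanence; rod-tip fields
  above ~0.5 T are upper bounds.
* The rod taper profile is the dominant unmeasured geometric parameter (see
  above); reported tip-adjacent fields carry that uncertainty.
* Alignment is integer-cell only.
* The thermal model is lumped; spatial gradients across a winding, holders,
  and sample dishes are out of scope.
* Whether a physically double-wrapped winding's quoted turn count refers to
  strand turns or turn-pairs is ambiguous for as-built coils; resistance
  predictions inherit that ambiguity.
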