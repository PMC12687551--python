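# Methods

`kneesim` simulates an implanted tibiofemoral joint (a bicondylar,
PCL-retaining, fixed-bearing total knee replacement) under passive flexion,
and studies how malpositioning an implant component within its bone changes
joint contact forces, kinematics and individual ligament tensions.  Its core
method represents a malposition without moving any implant surface: the
ligament insertion points fixed to the malpositioned bone are mapped through
the *inverse* of the implant-in-bone transform, and the ligament reference
strains are recomputed.  This note records the model, its assumptions, the
defaults, and the design choices that were genuinely open.

## Joint model and coordinates

Right knee, right-handed frames: +X anterior, +Y proximal (the tibial
longitudinal axis), +Z lateral.  Two body-fixed implant frames are used: the
femoral component frame K_f (origin on the flexion axis midway between the
condyles) and the tibial insert frame K_t (origin on the insert dwell-point
midline).  The solver's pose variable is the placement of K_f in K_t with
six coordinates: flexion (prescribed), varus-valgus and internal-external
rotation, and AP/SI/ML translation.  Rotations compose joint-coordinate
style: flexion about the femoral Z axis, then varus-valgus about the flexed
X axis, then IE about the resulting Y axis.  Sign conventions: positive ML
is lateral; positive IE twist of the tibial insert is internal rotation.

The femur and tibia are rigid; flexion is swept 0°–80° in 1° steps
(a seated passive motion, no ground contact, gravity neglected).  At each
step the five free coordinates are equilibrated quasi-statically: the load
case is slow and inertia-free, so equilibria are stationary points of the
total potential energy, and the solver minimises

    E(pose) = Σ ligament strain energy
            + contact penalty potential
            + quadriceps tension × cable length
            + external axial preload × SI translation.

The gradient of E is assembled analytically as the negative generalized
force (sum of forces for the translations, moments about the free rotation
axes for the rotations), which makes the converged gradient itself the
equilibrium residual.  L-BFGS-B performs the minimisation; a damped Newton
polish on the gradient (finite-difference 5×5 Hessian) then drives the
residual to ~1e-8 N, far inside the contract tolerances of 0.1 N and
1 N·mm.  Sweeps warm-start each step from the previous pose and flag any
continuation jump above 2 mm / 2° per 1° step.  Seeded perturbed restarts
guard against poor starts; with none of the shipped models are they needed.
Degenerate landscapes (no contact, all fibers slack) are reported as a
warning state instead of a spurious convergence failure.

## Ligaments

Each of the 16 elastic bundles is a straight-line, tension-only fiber
between one femoral and one tibial insertion (no wrapping — deliberately
matching the virtual-ligament idealisation of physical joint simulators).
The force law is piecewise in engineering strain ε = (l − l0)/l0:

    F(ε) = 0                      ε ≤ 0      (slack: zero force AND stiffness)
         = K/(4 ε1) · ε²          0 < ε ≤ 2 ε1   (quadratic toe region)
         = K · (ε − ε1)           ε > 2 ε1       (linear region)

with K in newtons per unit strain and the transition parameter ε1 = 0.03
for every bundle (a 6 % transition strain).  The law is C1 at both section
boundaries; its strain integral times l0 is the fiber's potential.  The
packaged stiffness/reference-strain table covers two PCL bundles, three
MCL and three LCL bundles, one oblique posterior MCL, two deep MCL, two
oblique popliteal, one arcuate popliteal, and medial/lateral posterior
capsule bundles; the patellar ligament is an inextensible coupling (below).
The table ships as a CSV data file and is read, never duplicated in code.

The zero-strain length l0 is a fixed property of each fiber.  It is not
tabulated directly; instead each bundle carries its strain ε_ref in the
*reference configuration*, the 0°-flexion equilibrium, and
l0 = l_ref / (1 + ε_ref) with l_ref the chord length there.  Note the two
PCL reference strains are strongly negative: the PCL is slack near
extension and engages only once its chord has lengthened substantially in
flexion.  The synthetic insertion layout places the femoral PCL insertions
distal-anterior in the intercondylar region, far from the flexion axis, so
that the chord lengthens enough for the posterior bundle to carry load in
deep flexion — which is what produces femoral rollback in this model.

## Reference configuration and preload

The reference configuration is found by solving the 0° equilibrium with
each fiber's force magnitude pinned at its tabulated reference strain
(directions follow the chords), while an external axial force on the femur
is calibrated until the axial contact force equals the configured preload
(default 1000 N, the order of magnitude the tabulated pretension itself
produces).  Assigning l0 from the chord lengths at the converged pose makes
that pose an exact fixed point of the full elastic model.  The calibrated
external force is then frozen: malposition variants re-equilibrate under
identical external loading, so force changes between variants reflect the
malposition alone.  (A physical simulator would re-adjust its initial
contact force when a variant changes the load level substantially; a pure
simulation has no actuator compliance to compensate, so the load is
deliberately held constant.)

## Contact

Each compartment is an analytic interference query: the condyle is the
envelope of spheres of the frontal radius (22 mm) whose centers run along a
sagittal guide curve of two tangent arcs — a 36 mm distal arc contacting
near extension and a 24 mm posterior arc contacting in deep flexion (the
decreasing sagittal radius is what makes an AP implant shift change joint
separation as flexion progresses).  The tibial dish is a spherical cup
(55 mm radius, conforming but non-congruent).  Penetration has a closed
form: depth = max over guide points of |g − c| + r_frontal − R_dish, with
the maximiser available per arc analytically; interference only counts on
the concave side of the cup.  The normal force is a Hertz-type penalty
F = k_c·depth^{3/2} with potential (2/5)k_c·depth^{5/2}; the default
k_c = 3000 N/mm^{3/2} puts physiological loads (~1 kN) at ~0.5 mm
penetration.  Contact is frictionless (lubricated articulation).  The
contact force enters the energy gradient at the deepest-sphere center; the
envelope theorem makes that exact even though the contact point migrates.

## Quadriceps and patella

The six-DOF patella is collapsed into an idealised pulley: a constant-
tension cable (default 40 N, the usual passive-flexion stabilising load)
runs from a femur-fixed proximal anchor, wraps the anterior side of a
femur-fixed trochlear circle (radius 45 mm, lumping the trochlea and
patellar thickness), and ends at the tibial tuberosity; the distal segment
stands in for the inextensible patellar ligament.  The cable is planar in
the sagittal plane.  Its potential is tension × path length, with the
classic tangent-arc-tangent belt construction; the resulting pull on the
tuberosity is slightly anterior-superior at mid-flexion, i.e. the
mechanism pushes the femur posteriorly — the qualitative role the
patellofemoral joint plays under quadriceps load.  The patella option
defaults on; every directional trend also holds with it off.  Quadriceps
and PL attachments are machine-fixed (expressed in the implant frames) and
are *not* moved by a malposition, mirroring the physical limitation of a
joint simulator whose straps cannot be repositioned; a flag transforms
them too, to quantify that limitation.

## Malposition: insertion shift versus geometry shift

A malposition is a rigid transform T of a component relative to its bone
(the shipped study matrix: femoral AP ±3 mm; femoral ML ±3, ±6 mm; tibial
insert twist ±3°, ±6° about the tibial longitudinal axis through the
dwell-point midline, with a configurable pivot; insert thickness change as
SI translation ±1, ±2 mm — 14 variants plus the reference).  Two routes
are implemented:

* **insertion shift** — the implant stays put; the insertion cluster on the
  malpositioned bone is mapped through T⁻¹, and each bundle's reference
  strain is recomputed as ε_ref = (l_ref − l0)/l0 from the new chord
  lengths at the variant's own 0° equilibrium.  l0 never changes: the
  recomputation is exactly the bookkeeping that keeps the physical fiber
  unchanged when the reference geometry moves.
* **geometry shift** — the in-body ground truth: the implant surfaces carry
  T as a mount transform while the insertions stay put.  Ligament chords
  and contact are then evaluated through the bone frames by conjugating the
  implant-relative pose with the mounts.

Flexion is always prescribed between the implant frames (machine
semantics, and the frames kinematics are reported in); with that
convention the two routes describe the same physical system through
different arithmetic, and the full study agrees between them to ~1e-10 mm
and ~1e-8 N — the package's central consistency check.

Kinematic outcomes are reported between the *bone* frames (the solver pose
composed with the inverse mount): this is the frame in which the familiar
directional findings appear, e.g. the tibia following a mediolateral
femoral shift in the same direction, or rotating opposite to an insert
twist.

## Synthetic anatomy — what it is and is not

Insertion coordinates, implant surface parameters and the quadriceps
geometry are synthetic: anatomically plausible placements (collaterals at
the epicondyles, PCL in the intercondylar region, popliteal/capsular
structures posterior, small seeded asymmetries) chosen once, not fitted to
any subject.  Absolute force and displacement magnitudes therefore depend
on this parametrisation and on the unprinted contact/preload calibration —
they are not comparable to any specific cadaver or hardware experiment.
What the tests assert is correspondingly property-based: exactness of the
force law and strain bookkeeping, the insertion-shift/geometry-shift
equivalence, symmetry preservation on an exactly mirror-symmetric model
(asymmetric DOFs stay below 1e-6 through a full sweep), the solver
contract, and the *directions* of the malposition effects.  Passing them
shows the method and its implementation are sound, not that the synthetic
knee reproduces a particular specimen's magnitudes.

## Numerical choices

* Rotational free coordinates are scaled by 50 mm/rad so translational and
  rotational gradients are comparably conditioned.
* Minimiser tolerances: L-BFGS-B ftol 1e-15 / gtol 1e-10, then Newton
  polish to a 1e-8 gradient; residual contract 0.1 N / 1 N·mm.
* Slack fibers contribute zero force and zero stiffness; chord-coincident
  insertion points (strain −1) are handled without division by zero.
* Contact with zero penetration carries exactly zero force; the penalty
  exponent 3/2 keeps force and stiffness continuous at first touch.
* The cable wrap is C1 across the wrap/no-wrap transition (tangent lengths
  and arc degenerate together).
* Determinism: no unseeded randomness anywhere; repeated runs are
  bit-identical, and the only stochastic element (perturbed solver
  restarts) draws from the settings seed.
* Default problem size: 81 flexion steps × (14 variants + reference) ×
  two routes completes in a few minutes on one core.

## Known limitations

* No ligament wrapping, no anterior cruciate (the modeled design retains
  only the PCL), no post/cam and no patellofemoral surface contact.
* Penalty contact replaces polygonal mesh contact; absolute penetrations
  and hence force levels depend on k_c.
* The patella has no degrees of freedom of its own; patellar kinematics
  and retinacular loads are out of scope.
* Insert thickness variation is a pure SI translation of the articulating
  surfaces, not a reshaped insert.
* Quasi-static only: no inertia, damping, or cyclic loading effects.
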