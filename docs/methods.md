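# Methods

This note documents the models, the numerical choices and the synthetic
study conditions the package implements, and what its passing tests do and
do not demonstrate about real subjects.

## Multibody model and inverse dynamics

The leg is a kinematic tree (free pelvis; spherical hip; revolute knee and
ankle at the musculoskeletal stage).  Equilibrium is written segment-wise:
six Newton–Euler rows per segment, forces in body-fixed coordinates and
moments about the segment mass centre, with the load vector
`d_j = g_j^(app) − diag(m_j I, J′_j)·v̇_j − [0; ω̃′_j J′_j ω′_j]`.  The
coefficient matrix follows the d'Alembert convention that pairs with this
load vector: muscle columns are +∂L/∂q (tendon-excursion derivatives of the
origin-to-insertion polyline length), reaction columns are joint-constraint
Jacobian rows.  With this pairing the solved unknowns are the physical
muscle tensions and reaction forces; the convention is verified in the
tests by comparing assembled columns with central-difference path-length
derivatives through a virtual-work identity.

Segment angular velocities and accelerations are computed numerically from
the pose trajectory (`ω̃ = RᵀṘ` with second-order central differences).
The synthetic gait generator uses the *same* discrete operators when it
derives the ground reaction wrench, which is why the generated trials are
dynamically consistent to machine precision rather than to filtering error.

## Muscle recruitment

The cubic volume-normalised criterion is minimised subject to equilibrium
and non-negative muscle forces.  Muscles are ideal force generators with no
upper bound — the criterion as stated carries no `f ≤ N` constraint, and
the strength enters only through the cost normalisation.  Numerically the
problem is solved in nondimensional form: muscle unknowns as activations
`x = f/N`, free unknowns scaled by the load norm, rows equilibrated, and
redundant equality rows projected out by SVD.  Without this rescaling the
cost gradient (≈10⁻⁹ in SI units) is invisible next to the O(1)
equilibrium block and the flat directions of the optimum never resolve.  An
SLSQP pass locates the active set; an active-set KKT Newton polish then
drives the optimality system to ~10⁻¹³, which is what makes the
muscle-subdivision invariance hold to 10⁻¹⁵ relative in the tests.  The
test-side oracle is an independent log-barrier interior-point solver
(null-space Newton, LP-seeded strictly feasible start) sharing no code with
the package solver.

Length–mass–fat strength scaling is implemented as
`N ∝ (m/m₀)^(2/3) · (h/h₀) · ((1−fat)/(1−fat₀))` with configurable
exponents, and volumes scale with the lean-mass ratio; the exponents are a
documented default, not a literature-extracted fact.

## Force-dependent kinematics

At each candidate secondary pose the knee assembly's residual generalised
forces (contact + ligament + external along the five tibiofemoral
directions and, with a patella, five closure-consistent patellofemoral
directions) are driven below 0.3 N / 0.3 N·m by a damped Newton with a
finite-difference Jacobian, steps clamped to 2 mm / 2°.  The patellar
tendon is rigid: PF flexion is eliminated by root-finding the
attachment-to-tuberosity distance, the residual directions are evaluated
*through* that closure (so the tendon force does no work along them and
drops out), and the tendon tension is recovered afterwards from the
eliminated direction — its equilibrium residual is reported as the 11th
component.

Elastic-foundation contact measures the penetration of each slave
(tibial-side) face centroid by nearest-point projection onto the master
mesh, with the inside/outside decision taken from the master's outward
normal at the nearest point; pressure is linear in penetration with the
9.3 GN·m⁻³ modulus and acts along the slave face normal.  Nearest-point
queries are computed in-package (vectorised point-to-triangle-soup), so no
spatial-index dependency is needed at the fixture's mesh sizes.

The toy knee has spherical femoral condyles on shallowly dished plateau
meshes (dish radius twice the condyle radius).  The dish matters: on flat
plates the medial-lateral position is a near-neutral direction inside the
0.3 N tolerance band, and the converged state is not unique to the 0.05 mm
the restart-robustness check expects.  The toy patella articulates against
a trochlear facet held at the reference femur pose; femoral secondary
motions are millimetres, so treating the facet as fixed changes the
patellar equilibrium negligibly at desk scale.

## Load export

The equivalent femoral (and patellar) wrench sums muscle attachment forces,
the hip reaction, gravity and inertia on the free body, omits the
tibiofemoral/patellofemoral reactions, reduces about the femoral reference
point and rotates into the tibia FEA basis.  The anatomical (FEA)
coordinate systems are built once at the reference configuration — x from
lateral to medial epicondyle, y orthogonalised towards the hip centre,
z = x × y, origin midway between the epicondyles — and then move rigidly
with their bones; rebuilding the tibia frame from the instantaneous hip
position would silently zero the flexion angle.  Stance is detected on the
vertical ground reaction with a 20 N threshold and 5 N hysteresis; trials
within ±10 % of the reference stance time are retained and the
representative trial minimises the summed RMS distance of its load curves
to the retained-set mean.

## FRPVE material

Total stress is `σ = σ^f + σ^nf − p·I`.  Each fibril is a rheological
network: a strain-stiffening elastic branch with tangent `E₀ + E_ε ε`
(stress `E₀ε + ½E_ε ε²`) in parallel with a Maxwell branch (linear spring
`E_ε` in series with damper `η`, integrated by backward Euler with an
analytic consistent tangent).  Fibrils carry tension only, and the Maxwell
state relaxes fully whenever the fibril goes slack.  The published
parameter tables name `E₀` and `E_ε` without the functional form of the
nonlinearity; the form above is isolated in one function
(`_parallel_branch_stress`) so an alternative law is a one-line swap.  All
stated limit behaviours hold: relaxation to the parallel branch, both
springs in parallel for a locked damper, the elastic branch alone for a
free damper, and non-negative dissipation over closed strain cycles.

Primary fibrils follow a Benninghoff arcade from the split-line tangent at
normalised depth z = 0 to the surface normal at z = 1 (circumferential in
the meniscus); two primary senses and 13 shared secondary directions per
point, each primary weighted D = 12.16 times a secondary.  The secondary
set is a seeded random draw polished by projected gradient descent until
its second-moment tensor is within 0.5 % of I/3 — a raw 13-direction draw
misses the 2 % isotropy target.  Fluid fraction is `0.8 − 0.15z` for
cartilage and 0.72 for the meniscus; permeability follows
`k = k₀((1+e)/(1+e₀))^M`.

## Biphasic finite elements

Equal-order trilinear u-p hexahedra, 2×2×2 Gauss quadrature, geometrically
linear kinematics, backward Euler.  The matrix stress is evaluated through
the Neo-Hookean law at `F = I + ∇u`; its 6×6 Gauss tangent comes from
complex-step differentiation (machine precision, so the assembled tangent
passes the finite-difference consistency check at 10⁻¹⁰), the fibril
tangent is analytic, and the strain-dependent permeability is lagged one
step — a standard staggered treatment that keeps the within-step tangent
exact.  Drainage is p = 0 on prescribed faces and sealed elsewhere.

Two numerical points deserve emphasis.  First, millimetre-scale tissue in
SI units produces a stiffness matrix whose Darcy block (~10⁻¹⁶) sits
seventeen orders below the elastic block; the linear systems are row- and
column-equilibrated before each solve, and convergence is judged on the
equilibrated residual, which has the character of a Newton-correction size
(metres / pascals), with an absolute floor of 10⁻⁸.  Second, penalty
contact uses a quadratic pressure-overclosure blend over the first 20 µm to
keep the tangent continuous at the contact edge; the penalty
(5·10¹⁰ Pa/m by default) is chosen ~100× the slab's foundation stiffness,
giving sub-percent overclosure error without the active-set chatter of a
near-rigid penalty.

The force-driven rigid femoral indenter carries its 6 DOFs as extra
unknowns.  Its rotations are prescribed during the staged protocol: the
rotational equilibrium of a frictionless sphere pair on soft slabs is
nearly indeterminate and is not a quantity the desk-scale fixture is meant
to resolve; applied moments are reacted by the prescription.  Weak
rotational (50 N·m/rad) and translational (200 N/m) restraints stand in for
the capsule and keep the rigid-body rows regular when contact momentarily
opens — at millimetre motions they contribute well under 1 % of the applied
load, and the global-equilibrium test accounts for them explicitly.

The staged protocol mirrors the standard sequence: (1) approach to light
contact with ligament pre-strains ramped on, (2) the loads at the start of
stance, (3) the stance sweep of the equivalent-load series (0.65 s in a
configurable number of steps).

## Synthetic study conditions

The gait fixture models the recorded subject's conditions: 61.2 kg body
mass, 0.65 s stance sampled at 100 Hz, vertical ground-reaction peaks near
20 % and 80 % of stance.  Joint-angle waveforms are smooth parametric
curves shaped so the stance shows a loading-response knee-flexion wave and
a pronounced push-off near 90 % of stance; the pelvis vertical trajectory
is integrated from the two-peak target acceleration so the derived reaction
shows both peaks and its impulse matches body weight × stance time within
5 %.  The geometry is planar in the sagittal plane — a single-leg model has
no contralateral support, so in-plane consistency requires the hip under
the pelvis mass centre — while the formulation stays fully 3-D.  The muscle
set deliberately includes uniarticular/biarticular redundancy
(vasti/rectus, soleus/gastrocnemius, gluteus/hamstrings): the
strength-sweep mechanism — weakened knee-crossing muscles shed load to
uniarticular alternatives and lower the peak tibiofemoral force — exists
only with such alternatives.

The ground reaction wrench is solved per frame from the left null space of
the equilibrium matrix, which is what makes recruitment exactly feasible
with no residual actuators.  The simplified-knee FE fixture is two
5×5×2-element cartilage slabs (3 mm thick) under rigid spherical condyles,
with the printed ligament stiffnesses and pre-strains as linear springs;
its applied loads are a body-weight-scaled fraction of the exported series
because its contact patch is a fraction of a whole joint surface.

What passing tests show: the algorithms are implemented correctly — exact
equilibrium, verified optimality, converged FDK residuals, benchmark-grade
poroelasticity, and the qualitative strength-sweep and valgus-shift trends.
What they do not show: fidelity to any real subject's geometry, marker
artefacts, true muscle paths with wrapping, or subject-specific cartilage
stresses; the headline magnitudes of the original study depend on
MRI-segmented geometry and motion-capture data that are not part of this
package.

## Problem sizes and tolerances

Default analysis sizes: 66-frame stance trial; toy knee with ~200 contact
faces per compartment; consolidation column of 12–18 elements (graded 1.25
towards the drained face for the transient benchmark); simplified knee of
100 porous elements with a 4-step stance sweep.  Key tolerances:
recruitment KKT ~10⁻¹³ (scaled), FDK residuals < 0.3 N (N·m), FE Newton
relative 10⁻⁶ with a 10⁻⁸ equilibrated-residual floor, drained-modulus
agreement within 1 %, transient consolidation within 2 % L2.

## Known limitations

- Muscle paths are straight polylines; no wrapping surfaces or via-point
  activation dynamics (muscles are ideal force generators).
- The FE stage is geometrically linear; the 15 % strains of the stance
  fixture are at the edge of that regime, and finite-strain kinematics
  would shift stresses by a few percent.
- Deformable–deformable contact is reduced to deformable-versus-rigid at
  desk scale; menisci are supported as a material preset but not meshed
  into the simplified fixture.
- C3D input is not implemented (the documented wide-CSV dialect is the
  canonical format); HDF5 export is likewise replaced by CSV/JSON.
- The FDK patellar trochlea is held at the reference femur pose (see
  above).
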