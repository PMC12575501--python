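# Methods

This note documents the models, parameter choices and numerical
decisions behind `fevarsim`, in the spirit of a model-description
appendix.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinate frame and units

Right-handed patient frame: x = left–right (patient left positive),
y = antero-posterior, z = cranio-caudal (superior positive).  All
lengths in millimetres, forces in newtons, moduli in N/mm² (MPa), so
bending rigidities E·I come out in N·mm².  Aorta centerlines are stored
cranial → caudal (blood-flow direction); a branching angle below 90°
therefore denotes a caudally directed branch.

## Synthetic vasculature

The generator replaces CT segmentation.  An aorta centerline runs along
the cranio-caudal axis (default 200 mm long, 10 mm radius) with a seeded
two-harmonic lateral perturbation (default amplitude 2 mm) for
tortuosity; the perturbation is smoothly suppressed in a ±10 mm window
around each renal ostium so that branch roots sit exactly on the aorta
tube surface.  Renal branches (default 35–50 mm long, lumen radius
2.5–3.5 mm, branching angle 60–100°) leave the surface as planar
circular arcs with optional seeded sinusoidal perturbation.

Two generator defaults deserve comment because the design space was
genuinely open:

* **Branch curvature** defaults to an arc curvature of 0.015–0.03 /mm
  (radius 33–67 mm).  A near-straight branch leaves an inextensible rod
  no geometric slack: any prescribed distal displacement must then be
  carried as axial tension, the artery behaves as a taut string, and the
  distribution of bending stiffness (i.e. the stent) becomes
  mechanically irrelevant.  Renal arteries are clinically tortuous and
  accommodate breathing by bending, so the default places the model in
  the bending-dominated regime.

* **Breathing displacement** defaults to (lr, ap, cc) = (0.3, 0.6, 3.0)
  mm with ±10 % per-branch jitter, cranio-caudal dominant.  Published
  respiratory kidney excursions are of order 5–15 mm, but in a full
  FE model part of that motion is absorbed by aortic-wall compliance
  near the ostium; this rod clamps the ostium rigidly, so the
  *effective* displacement applied at the distal branch end is smaller.
  The 3 mm default was chosen so that the synthetic cohort reproduces
  pre-EVAR inspiration→expiration branching-angle changes of roughly
  9–15° (cohort mean ≈ 11.5°), the order of magnitude reported for
  fEVAR patients.  Both magnitudes are configuration parameters, not
  measurements.

All randomness flows from one master seed through fixed stream keys
(counter-based), so generation is bitwise reproducible and independent
of the order in which stages are invoked.

## Stent-graft model

The catalog holds the twelve commercially sized devices (two patients ×
two arteries × shorter/nominal/longer; lengths 18–28 mm, diameters
5–7 mm).  Deployment is purely geometric: the device occupies
[−p, L−p] in ostium-anchored arc length, where p is the aortic
protrusion (drawn per deployment from the clinical nominal band,
default 3.6–4.2 mm) and the proximal end is flared to the fenestration
diameter.  Balloon mechanics, crimping and contact are not modelled.

The stented segment's bending rigidity is the sum of artery wall
(default 100 N·mm², a configuration knob — renal wall properties are
not reliably known), Co-Cr struts (n per ring, default 6, each
contributing E(I_strut + A r²/2) with the r²/2 factor the mean squared
neutral-axis offset of points on a circle), and the ePTFE graft as a
thin-walled tube (E₁ π r³ t).  Only the *ratio* to the bare artery
enters the rod model; with the defaults it is O(10³).  In the breathing
simulation the ratio is capped at 200: beyond that the stented segment
is rigid for all practical purposes, while larger values only degrade
the conditioning of the stiffness matrix (see Numerics).

The three-point-bending harness implements the linear-elastic
closed form F = 48 EI δ / L³ and refuses deflections above 3 mm — the
bound below which the physical test protocol avoids plastic deformation
of Co-Cr.  Plasticity is not modelled.

## Elastic-rod equilibrium

Discretization at h = 1 mm (matching the 1 mm metric sampling; the last
interval may be shorter).  Energy: stretching k_s/(2h)(|e|−h)² per
segment plus bending k_b/h (1 − cos(θ − θ̄)) per interior node, with θ
the unsigned turning angle and θ̄ its rest value.  Boundary conditions:
the two proximal nodes are fixed (clamped position + tangent at the
ostium, consistent with treating the aorta as rigid there), the distal
node is displaced by the breathing vector with free orientation — a
clamped–pinned configuration.  The rod rest state is stress-free; the
stress-relaxation steps of an FE deployment workflow have no rod analog.

Numerical choices:

* **Kink regularization.** The unsigned turning angle makes the bending
  energy non-differentiable at θ = 0 — exactly where a breathing load
  drives a straightened node.  Since sin²θ = 1 − cos²θ, the energy is a
  function of c = cosθ alone, and sinθ is replaced by
  √(1 − c² + ε²) − ε with ε = 1e−4.  This changes the energy by less
  than ε per node and makes it C^∞.

* **Stretch stiffness** defaults to 10² × (artery rigidity)/h = 1e4 N.
  Under the ~1 N transverse loads of the study this gives axial strains
  of order 1e−4 — inextensible for all practical purposes.  Larger
  values buy nothing physically but raise the largest Hessian entries,
  and the achievable gradient accuracy in double precision is roughly
  (largest Hessian entry) × (position ulp); the default keeps that floor
  well below the 1e−8 N convergence tolerance.

* **Solver.** Deterministic, no randomness: the displacement is applied
  in increments of ≤ 2.5 mm (continuation), each solved by trust-region
  Newton with the analytic gradient and analytic Hessian, warm-started
  from the previous increment; a final damped-Newton polish drives the
  free-node gradient ∞-norm below 1e−8 N.  The polish judges progress on
  the gradient norm, not the energy: near the minimum, energy
  differences fall below the floating-point resolution of E long before
  the gradient reaches 1e−8.  Equilibria are additionally solved in
  branch-local coordinates (the energy is translation invariant) to
  lower the rounding floor.  Zero displacement returns the rest shape
  exactly.

* The distal end's orientation is left free — whether the real distal
  renal end is rotationally constrained is unknown; this is the softer
  assumption.

## Morphometrics

Curvature is the Menger estimate — the reciprocal circumradius of each
consecutive point triple on the 1 mm-resampled centerline — exact on
circles and parameter-free; endpoints carry no estimate; the profile
maximum is reported.  The branching angle is measured between the aorta
tangent at the point nearest the ostium and the least-squares line
through a window of the proximal branch; the end-stent angle between
least-squares directions of the last stented and first unstented window
at the distal stent end (unavailable if less than one window of artery
remains).  Deltas between respiratory states are reported as absolute
values.

The direction-estimation window is a declared knob.  The per-metric
default is 5 mm, robust to 1 mm sampling.  The **study pipeline calls
the branching angle with a 20 mm window** (about half a typical branch):
the clinical measurement compares whole centerlines, not local tangents,
and with a 5 mm window lying entirely inside every catalog device the
metric would degenerate to near-zero deltas dominated by discretization
noise.  With the 20 mm window the device-length trends emerge for the
transparent geometric reason that a longer stiff segment immobilizes a
larger fraction of the measured direction.

## Registration and validation

Rigid registration is centroid alignment followed by point-to-nearest-
point ICP (Kabsch/SVD inner solve with the determinant branch corrected,
so a reflection is never returned; max 100 iterations, RMS-improvement
tolerance 1e−6 mm).  ICP is a local method: it recovers moderate
misalignments (the 10° test case) exactly, but is not expected to escape
large-rotation local minima.  Corresponding-point distances are measured
between equal-count (default 100) arc-length-proportional resamplings,
with automatic orientation reversal decided by endpoint pairing.  The
placement-accuracy score is the percentage of points *strictly* below
the 3 mm tolerance (2 mm imaging + 1 mm segmentation error); a tie at
exactly 3.000 mm counts as a failure, so score = 100 exactly when the
maximum distance is below the threshold.  The protrusion criterion
checks each deployed device's aortic protrusion against the clinical
3.4–4.3 mm band (reference 3.88 mm) and reports the mean.

Because no post-operative imaging exists for synthetic patients, the
pipeline's distance validation compares each simulated post-EVAR
centerline against a **synthetic imaging surrogate**: the same
centerline under a smooth seeded deformation (default amplitude 2 mm,
the scale of the imaging-error budget) plus a rigid offset that the ICP
step removes.  The surrogate does not emulate voxelization, topology
errors or partial segmentations, so a perfect score here validates the
pipeline's bookkeeping, not segmentation robustness.

## What the synthetic cohort does and does not show

The generator reproduces the *structure* the analysis assumes — branch
calibers, branching-angle range, cranio-caudally dominated breathing,
curved branch courses, device-length effects with the directional
pattern seen in patients (branching-angle change: pre-EVAR > shorter ≥
nominal ≥ longer; end-stent-angle change: shorter ≤ nominal ≤ longer).
It does not reproduce any individual patient's geometry; patient-
specific published values (per-artery distances, exact degree values)
depend on CT geometry that is not public and are out of reach by
construction.  Passing tests therefore demonstrate correctness of the
metrics, registration, and mechanics, and directional fidelity of the
stent-length effects — not patient-level prediction.

## Problem sizes

Default study: patients with ~40 mm branches (≈ 40 rod nodes), four
configurations per artery (pre-EVAR + three devices), two arteries per
patient; a five-patient cohort is 40 equilibrium solves and runs in a
few minutes on one CPU.  The brute-force oracle for the rod uses a
5-node rod with a 0.05 mm grid over the free in-plane coordinates.
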