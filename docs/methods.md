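# Methods

This note records the models, numerical choices and calibrations behind
`vortexflow`, and what the phantom-based validation does and does not show
about real phase-contrast MRI data.

## Data model and conventions

A dataset is a time series of three scalar lattices (vx, vy, vz) on a
voxel-centred right-handed grid, `world = origin + index · spacing`, with
lengths in mm and velocities in mm/s; vorticity therefore carries s⁻¹ and
λ₂ s⁻² with no extra unit factors. Cardiac phases are fractions of the
cycle in [0, 1). An optional boolean lumen mask restricts every
computation; positive through-plane vorticity means counter-clockwise
rotation looking against the plane normal.

## Vorticity schemes

Three discretisations of `ω = ∇ × v`, all supporting anisotropic spacing:

* `central2` — `(f(x+h) − f(x−h)) / 2h` per partial. Customarily called a
  "first-order central difference" in the 4D-flow literature although the
  stencil is second-order accurate; the API keeps the customary name and
  this note records the discrepancy. Default for numerically exact
  (phantom) data.
* `circ8` — per vorticity component, the trapezoidal circulation integral
  around the closed 3×3 in-plane contour divided by the enclosed area
  `4 h_a h_b`. For isotropic spacing this is the classic /(8h) eight-point
  stencil. It averages over 12 independent samples, which reduces the
  white-noise variance to 24/64 = 0.375 of the central-difference value
  (verified by a seeded Monte-Carlo test) — the recommended default for
  in-vivo data. The exact historical weighting of the eight-point scheme
  varies between authors; the standard trapezoidal contour above is used.
* `central4` — five-point, fourth-order stencil, exact for cubics. On
  coarse MR grids the distant samples tend to hurt more than help; it is
  provided for completeness and comparison.

Boundary policy: no one-sided differences. A voxel is valid only when its
full stencil lies inside the mask (face-neighbour erosion for `central2`,
the three in-plane 3×3 neighbourhoods for `circ8`, ±2 axis neighbours for
`central4`); invalid voxels hold NaN, never a silent zero. This forfeits a
one-voxel rim but avoids fabricating wall vorticity from the no-slip
velocity jump.

## λ₂ criterion

`S = (J + Jᵀ)/2`, `Ω = (J − Jᵀ)/2`, `M = S² + Ω²`; M is symmetrised
explicitly before eigen-solving and its eigenvalues are returned sorted.
The solver is the closed-form trigonometric solution for symmetric 3×3
matrices, vectorised over whole lattices (millions of voxels per second)
and cross-checked against LAPACK in the tests; eigenvalue ties are benign
because only the sorted middle value is exported.

Two consequences of the algebra worth noting: any unidirectional flow
(e.g. Poiseuille) gives `M = 0` identically, so axial shear never fakes a
vortex; and a rigid rotation at rate Ω gives λ₂ = −Ω². Both are enforced
as tests, as are Galilean invariance (velocity offsets cancel in the
differences) and frame-rotation equivariance on quadratic fields (where
stencil and interpolant are exact, isolating the algebra).

## Interpolation

Spatial interpolation is "cubic of dynamic degree": tensor-product cubic
Lagrange on the 4³ neighbourhood when it is fully valid, degrading to
trilinear on the inner 2³ cell, then to the nearest valid voxel, with the
degree used reported per point. This is the only cascade that degrades
gracefully against the vessel wall while staying exact for tricubic
polynomials in the interior. Sub-voxel vorticity and λ₂ (used by the
tracker) are obtained by differentiating this interpolant analytically
rather than re-interpolating lattice values — the corrector then sees
genuine sub-voxel structure consistent with the velocity field.

Temporal refinement (e.g. 25 → 250 frames, factor 10) is a per-voxel
periodic cubic spline over the cardiac cycle: retrospectively gated data
is cyclic, so periodic closure is the physically correct boundary
condition. Original frames are preserved bit-exactly.

## Lumen segmentation

Score per voxel = temporal mean speed, optionally multiplied by a
magnitude-image value; threshold, then keep the largest 26-connected
component. Published descriptions of magnitude-weighted velocity
thresholds leave the exact product formula open; the documented score
above is the package's choice and is deliberately simple. It is exact for
the phantom (zero outside the tube) but only a starting point for in-vivo
data, where phase noise outside vessels may need a higher threshold.

## 2D ROI quantification

Planes are user-supplied geometry (id, centre, normal, radius or polygon,
pitch); the anatomical placement of the customary six aortic planes
follows imaging guidelines and is documented, not auto-detected — there is
no anatomy model in scope. The heatmap samples `ω · n̂` at a pitch
defaulting to half the smallest voxel spacing (avoids aliasing); a sample
counts only when its nearest voxel is in the lumen mask. Opposing-rotation
fractions are percentages of heatmap samples (not lumen area — identical
in the fine-pitch limit) beyond ±10 s⁻¹, a threshold chosen to suppress
noise. Orienting the normal along bulk systolic flow makes the
physiological right-handed aortic helix negative (clockwise), and flipping
the normal provably negates the map and swaps the CW/CCW fractions.

Cohort aggregation resamples each subject's curves with a periodic cubic
spline onto a common percent-of-cycle grid (200 points), then reports
pointwise mean and sample SD plus each metric's extremum and its timing.

## 3D core tracking

Seeds are 26-neighbourhood local minima of the λ₂ lattice below 10% of the
most negative in-mask value, greedily thinned so no two seeds lie within 5
voxels; seeds stand in for the pressure minima of the original
predictor-corrector formulation, λ₂ being far cheaper and more robust to
compute from velocity data. Only the strongest core is quantified per
phase (one dominant aortic vortex is the use case); other seeds remain
available.

March: RK4 prediction of step 0.5·(min spacing) along the unit vorticity
direction (sign-aligned across substeps so the integration cannot flip),
then compass-search correction in the plane perpendicular to the local
vorticity: four in-plane directions, mesh starting at 0.5 voxel, halved on
failure down to 0.01 voxel, confined to a 2-voxel disc so the corrector
cannot hop to a neighbouring vortex. Pattern search needs no derivatives
and converges fast on the shallow λ₂ valleys found in measured data; its
direction order is fixed, making the whole tracker bit-deterministic.

Stopping: the published formulations leave the stopping rule abstract, so
it is a documented calibration here — interpolated |ω| < ω_stop with
ω_stop = 50 s⁻¹ by default, a value jointly consistent with the phantom's
exact core-minimum vorticity (50.0 s⁻¹) and exact length (76.9 mm =
2 (l/π) arccos(2·50/397.9 − 1) with l = 50 mm). Guards: λ₂ ≥ 0, leaving
mask/bounds, turns sharper than 60°, and 2000 steps per direction.
Along-core min/max/mean vorticity are statistics of interpolated |ω| at
the polyline points.

Cross sections: at every retained point, 8 rays at 45° spacing in the
perpendicular plane, marched at 0.1-voxel steps on the interpolated
vorticity-magnitude until it falls below 150 s⁻¹ (the crossing is refined
by linear interpolation); radius = mean ray length, area = π r². Rays cut
by mask/bounds are truncated and flagged.

## The phantom and its calibration

The validation dataset is analytic: Poiseuille profile
`v_z(r) = vm (1 − r²/R²)` in a tube of radius R, plus a counter-clockwise
Lamb-Oseen swirl `v_θ(r) = Γ/(2πr)(1 − e^(−r²/rc²))` tapered axially by
`0.5(cos(πz/l) + 1)` on |z| ≤ l. The Lamb-Oseen diffusion time is folded
into rc, the Poiseuille pressure/viscosity factors into vm. Closed forms
exist for everything the pipeline measures, including the
discretisation-error law `ω₀ (rc²/h²)(1 − e^(−h²/rc²))` for the on-node
central-difference peak.

The canonical parameters are reconstructed calibrations (the validation
table fixes the observables, not the parameters): rc ≈ 1.6066 mm is the
root that makes the 1 mm discrete peak exactly 330.0 s⁻¹ given
ω₀ = 397.9 s⁻¹; Γ = ω₀ π rc² follows; l = 50 mm with ω_stop = 50 s⁻¹
jointly reproduce length 76.9 mm and core-minimum 50.0 s⁻¹; R = 10 mm and
vm = 100 mm/s keep the axial shear vorticity ≤ 20 s⁻¹, negligible against
every threshold. Fine-resolution (0.1 mm) evaluations run on a transverse
crop |x|,|y| ≤ 3 mm with full z extent — the core and all its closed forms
live entirely inside that window — keeping the lattice at ~4.5 M voxels
and the full pipeline under a minute.

What the phantom does *not* emulate: velocity noise at realistic VNR
(available only as an optional additive Gaussian flag), phase-offset and
eddy-current artefacts, velocity aliasing, curved vessel geometry, or a
moving/deforming lumen. Passing the validation therefore demonstrates
correctness of the numerics and the geometry handling, not robustness to
every in-vivo artefact; the single-voxel-perturbation and white-noise
variance tests probe robustness only locally.

## Numerical details and limitations

* Interpolation snaps query points within 1e-9 index units to lattice
  nodes so voxel centres reproduce stored values bit-exactly.
* Invalid voxels are zero-filled inside the sampler (they only ever
  receive zero weight; NaN would poison the tensor contraction).
* The closed-form 3×3 eigen-solver is accurate to ~1e-7 relative on
  pathological matrices, ample for s⁻² scale λ₂ values; the LAPACK
  cross-check test bounds the error.
* Bit-exact Galilean invariance is guaranteed (and tested) for
  integer-representable offsets; arbitrary float offsets agree to
  rounding, which is the best floating-point subtraction allows.
* `circ8` yields only curl components, not a full Jacobian, so λ₂ is
  restricted to the difference schemes.
* Degenerate inputs: zero-vorticity seeds give single-point cores of
  length 0; phases without a qualifying λ₂ minimum report zero metrics;
  planes that miss the lumen raise immediately.
* The tracker's step, mesh and radii scale with voxel size, so behaviour
  is resolution-independent down to the interpolant's fidelity; at 1 mm
  the remaining length bias is ≈ 1%, dominated by the stop-threshold
  crossing between samples.
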