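# Methods

This note records the models, numerical choices, and design decisions
behind `morphhead`, and what the synthetic fixtures do and do not show
about real data.

## Field conventions

A displacement field u on a voxel grid can mean two different maps, and
mixing them up is the classic mesh-morphing bug. Both are first-class and
tagged on the `VectorField` type:

- *resampling* (pull-back): `out(x) = in(x + u(x))` — used to warp
  images; this is what registration returns, with fixed = subject and
  moving = baseline/template.
- *forward* (push-forward): `x' = x + u(x)` — used to move mesh nodes.

The mesh is morphed with the numerical inverse of the total resampling
field, so the warped template image and the morphed mesh are the same map
by construction; their consistency is what the DICE-vs-node-error tests
check. Inversion is the standard fixed-point iteration
v ← −u(x + v(x)), converging for diffeomorphic fields; the default
tolerance is 0.01 voxel with 30 iterations. All world units are mm; voxel
centers sit at integer indices (NIfTI convention).

Out-of-domain sampling is a hard error beyond 0.5 voxel and a clamp
within: silent zero-fill would corrupt mesh morphing. Two consequences are
documented rather than hidden: the fixed-point inversion clamps at the
grid boundary, so the inverse is accurate only where the preimage stays
inside the grid (tests compare interior voxels); and the pipeline composes
its two registration fields with a looser 3-voxel clamp, because boundary
voxels of a demons field routinely land fractionally outside while the
displacement in air is essentially zero.

`compose_fields` offers true composition u₁(x) + u₂(x + u₁(x)) (default)
and a literal voxelwise `sum` mode. The two agree for constant fields and
differ in second order otherwise; composition is the mathematically
correct way to chain pull-backs and is what `personalize()` uses.

## Registration

**Rigid.** Centroid matching plus principal-axes alignment of the binary
masks (second-moment eigenvectors), testing the four proper axis-sign
assignments and scoring each by mask overlap. Eigenvector signs are
canonicalized (largest-magnitude component nonnegative), and overlap ties
within 0.005 resolve to the smallest rotation angle: an ellipsoid-like
mask cannot distinguish a 180° flip by overlap, and the least rotation is
the physically sensible reading. For a perfect sphere the rotation is
unconstrained by the data (the translation is still exact); this is
documented behavior, not an error.

**Deformable.** A classical diffeomorphic demons: per iteration the force
d = −(m∘φ − f)·∇f / (|∇f|² + (m∘φ − f)²), capped at `max_step` voxels,
smoothed with `sigma_update` (fluid-like), accumulated into a stationary
velocity smoothed with `sigma_field` (diffusion-like), and exponentiated
by scaling-and-squaring with N ≥ `squaring_min` squarings, N chosen so
max|v|/2ᴺ < 0.5 voxel. The exponential of a smooth velocity keeps
det(∇(id+u)) > 0, which the test suite checks on every returned field.
Defaults: pyramid (4, 2, 1) with (100, 50, 20) iterations,
sigma_update 1.0 vox, sigma_field 1.5 vox, max_step 2.0 vox,
squaring_min 4 — chosen to pass the warp-recovery property on the default
phantom and fully config-exposed. Within a level the lowest-SSD field is
kept and iteration stops after `stall_patience` non-improving steps, so
the similarity never degrades across a level; a final field worse than
the identity raises instead of returning.

**Pipeline.** `personalize()` runs: rigid mask alignment → stage-1 demons
on cranial masks (captures overall cranial shape even for large size
differences) → warp the aligned template T1 → skull strip both images →
stage-2 demons on the skull-stripped intensity images (aligns interior
structures; an externally computed dense field can be substituted here,
since the contract only needs *a* stage-2 resampling field) → compose →
invert → morph mesh → quality gate → DICE table. A failed quality gate is
reported in the result, not raised — the caller decides whether a
marginal mesh is usable.

## Mesh quality

"Jacobian" is read as the corner-based **scaled Jacobian**: at each of a
hexahedron's 8 corners the three emanating edges form a triad,
J_c = det[e₁e₂e₃]/(|e₁||e₂||e₃|), and the element value is the minimum
over corners. It lives in [−1, 1], equals 1 for any rectangular box, is
invariant to rigid motion and uniform scaling, and goes negative exactly
when a corner inverts — consistent with quality thresholds quoted as 0.2
/ 0.45 / 0.5, which a unit-bearing determinant could not be. The gate
passes when ≥ 95% of elements have a value of at least 0.5 **and** the
minimum is at or above the floor (default 0.2); thresholds are counted
with ≥, and fractions are exact integer counts. Element corner ordering
follows the VTK hexahedron convention in files and memory.

Element→region labeling takes the label of the voxel nearest the element
centroid; half-voxel ties resolve to the lowest linear index
(deterministic across platforms).

## DTI and tractography

FA uses the standard closed form √(3/2)·‖λ − λ̄‖/‖λ‖ (0 isotropic, 1
rank-one, scale-invariant); all-zero tensors define FA = 0 with a
warning, and negative eigenvalues are clipped at zero and counted. The
element fiber map takes the nearest voxel's (FA, v₁) at each centroid —
no resampling or tensor reorientation; lookup is in world coordinates, so
mixed resolutions are handled by proximity alone.

Streamlines are integrated with Euler steps (default 0.5 mm) along ±v₁
with sign continuity (choose the sign with positive dot product against
the previous step), terminating on FA < 0.2, turning angle > 45°, domain
exit, or the per-direction point budget. Euler rather than RK4 keeps the
circle-oracle error bound (radius error < one step over a quarter arc)
testable and matches classical streamline tracking. Tensors are
interpolated componentwise (trilinear) before eigen-decomposition;
eigenvector sign is irrelevant downstream because the axonal-strain
projection is a quadratic form — asserted by test, not assumed.

## Strain

The deformation gradient is evaluated at the element centroid from the
trilinear shape-function gradients of the reference configuration:
F = I + (Σᵢ uᵢ ⊗ ∂Nᵢ/∂ξ)(Σᵢ Xᵢ ⊗ ∂Nᵢ/∂ξ)⁻¹, and E = ½(FᵀF − I).
Single-point centroid evaluation matches common solver element output;
Gauss-point averaging is out of scope. E is exact for affine motions and
identically zero for rigid ones (objectivity) — both are acceptance
oracles. Components are stored as (Exx, Eyy, Ezz, Exy, Eyz, Ezx) with
*tensor* shear (Exy = γ/2); CSV import converts engineering shear when
the JSON header declares it, because solver dialects differ.

MPS is the peak (over elements and time) first principal strain per
region; MAS the same for ε_axon = v₁ᵀEv₁, evaluated only in regions with
meaningful fiber anisotropy (cerebral white matter, corpus callosum,
brain stem — deep gray matter is excluded). Percentile peaks use the
nearest-rank rule on the per-element peak distribution: deterministic, no
interpolation ambiguity. Whether "the peak" is the max of per-element
peaks or the peak of the per-time regional envelope gives the same value
with possibly different (element, time) bookkeeping; both localizations
are reported. When every element carries the same strain (affine test
motions), the nearest-rank pick among exact ties lands on the last
element in stable ascending order; the closed-form oracle applies the
same documented rule.

## Rating

DICE is 2|A∩B|/(|A|+|B|) on a shared grid; two empty masks define 1 with
a warning. CORA uses the cross-correlation sub-method only (the corridor
method is deliberately absent): both curves are linearly resampled onto a
uniform grid over their overlapping interval (dt = the smaller native
median step unless configured), the normalized cross-correlation K(δ) is
scanned over shifts |δ| ≤ d_max·T — integer grid multiples plus the exact
±d_max·T boundary, so an over-shifted candidate pins δ* to the boundary
and P = 0 exactly — and at the argmax δ*:

- V = max(K, 0)^k_v (shape),
- P = 1 below d_min·T, 0 at/above d_max·T, linear falloff^k_p between
  (phase),
- G = (min(Q_ref, Q_cand)/max(Q_ref, Q_cand))^k_g with Q = ∫curve²dt on
  the common support after shifting (size).

Positive δ* means the candidate lags the reference. Defaults d_min 0.01,
d_max 0.12, k_v = k_g = k_p = 1, all config-exposed; the combined score
is the equal-weight mean (V + G + P)/3. Aggregation is two-level — all
evaluated channels of one impact case average into the case score, cases
summarize as mean ± sample SD (n − 1 denominator; the n denominator does
not reproduce the published summary rows and is rejected). Published
rating tables are reproduced to 3 decimals, with the caveat that
recombining components that were themselves printed at 3 decimals can
differ by one unit in the last place.

## Synthetic fixtures

Phantoms are nested ellipsoids, not brain-shaped, on purpose: volumes,
overlaps, warp ground truths and strain peaks all stay closed-form. The
default phantom is a 64³ grid at 3 mm spacing with cranium semi-axes
72×88×68 mm, a brain ellipsoid inside it, and seven labeled subregions
(white matter, corpus callosum, brain stem, thalamus, hippocampus,
cerebellum, ventricles) nested in the cortex; T1-like intensities are
piecewise constant per label, smoothed at σ = 1 voxel, with seeded
Gaussian noise (sd 0.02). A single `scale` factor multiplies all radii,
which is how size series are built — a 1.37× linear step spans an
intracranial-volume ratio of ≈ 2.57, the reported smallest-to-largest
subject range. Masks and labels carry the exact pre-noise geometry; all
generators are pure functions of (spec, seed).

Analytic warps come with symbolically checked Jacobian bounds: the
sinusoidal shear has det = 1 + (2πa/L)³·(cosine product), bounded by
enforcing (2πa/L)³ ≤ 0.8; the Gaussian radial bulge a·e^{−r²/2σ²}(x−c)
has min radial eigenvalue 1 − 0.4463a (attained at r² = 3σ²) for a > 0
and det ≥ (1−|a|)³ for a < 0. Affine warps require det ≥ 0.2 directly.
Each warp carries its exact functional form, so registration tests
compare against ground truth rather than against another registration.

Impact histories are affine spatial modes (uniaxial stretch, simple
shear, rotation, rotation∘stretch) under a raised-cosine envelope peaking
at 36 ms over a 72 ms window. The rotation mode interpolates the *angle*,
so every intermediate frame is exactly rigid and the objectivity oracle
(MPS ≡ 0 at all times) holds frame by frame. The returned peak table is
computed from the closed-form E(t) = ½(F(t)ᵀF(t) − I) without touching
the shape-function strain path, making it an independent oracle for the
FE pipeline.

What passing these tests shows — and does not. The phantoms exercise the
full contract (large size differences, interior structure for stage-2
registration, diffeomorphism and quality gates) under piecewise-constant
intensities, ellipsoidal geometry, additive Gaussian noise, and smooth
ground-truth warps. Real T1 images have bias fields, partial-volume
mixtures, gyral/sulcal geometry at the mesh scale, and inter-subject
differences that are not diffeomorphic images of each other; registration
accuracy measured here is therefore an upper bound on, not an estimate
of, real-data accuracy. The strain fixtures validate the strain *path*
exactly, but affine modes cannot probe spatial strain gradients within
elements.

## Problem sizes

Default experiment sizes are chosen so the whole suite runs in about a
minute on one CPU: 64³ registration grids (48³ in the faster pipeline
unit tests), lattices of ~10³ elements, 10⁴ random tensor draws for the
projection-bound property, 41-frame impact histories. All are
configuration, not constants.

## Known limitations

- Stage 2 is intensity demons, not an attribute-matching method; an
  external field can be imported in its place, which is the supported way
  to reproduce a different second-stage engine.
- B-spline/higher-order interpolation, tensor reorientation, probabilistic
  tractography, corridor-method ratings, and any FE solving or
  constitutive modeling are out of scope.
- The demons parameters are registration hyperparameters; they were fixed
  once against the synthetic warp-recovery property and are not tuned per
  subject.
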