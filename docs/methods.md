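# Methods

## The cochlear model

The package models the cochlear lateral wall as a coiling spiral centered
at the coordinate origin, in mm, right-handed, coiling about the z axis.
Walking counter-clockwise (seen from the apex), the wall passes at distance
`A_a` from the center on the +x axis (unwound angle 0°), `B_a` on +y (90°),
`A_b` on −x (180°) and `B_b` on −y (270°). The radius at unwound angle θ
(degrees) is

    r(θ) = q(θ mod 360°) · d^(θ/360°)

where `q` is a periodic cubic spline through the four quadrant anchors
(each divided by the decay already accrued at its first-turn angle, so the
anchors are hit exactly) and `d = 0.6` is the per-turn radial decay. The
height grows linearly from 0 at the basal start to `height` (default 4 mm,
matching the ~4 mm axial extent of a cochlea) at the apex. This
construction satisfies every geometric constraint the pipeline relies on —
exact quadrant anchoring, strictly inward coiling between successive turns,
monotone height — while remaining replaceable by a more detailed spiral
formulation behind the same `CochlearParams`/`Centerline` interface. Scala
cross-sections, duct-length and volume formulas are out of scope.

The number of turns, when not fixed explicitly, is computed as

    turns = base + ln((A_a + A_b) / (B_a + B_b))

a shape-only (scale-invariant) law clamped to (1.5, 3.5), with `base`
calibrated so the mean cochlea (`A_a=5.97, A_b=3.26, B_a=3.95, B_b=2.85`)
gets 2.70 turns. The calibration point is forced by the 90° placement
scheme: twelve landmarks with the twelfth at the end of the last turn less
than 90° past the eleventh requires turns in [2.625, 2.75); 2.70 sits
safely inside. An explicit `turns` value (e.g. estimated graphically from a
patient scan) always overrides the computed one.

## Landmark placement

A scheme with spacing Δ ∈ {45°, 90°, 180°} places landmarks at every
multiple of Δ along the unwound spiral plus a terminal landmark at the
total angle 360·turns. When the terminal gap is shorter than Δ/2, the
terminal landmark replaces the final multiple rather than crowding next to
it (when the total angle is an exact multiple, the final multiple simply is
the terminal landmark). This single rule reproduces all the constellation
sizes the workflow uses: 12 on the mean cochlea at 90°, and 11/6/20 on a
2.4-turn cochlea at 90°/180°/45°. The minimal scheme places five landmarks:
0°, 90°, 180°, 270° on the basal turn plus the apex. Landmark order is the
correspondence; every operation preserves it, and paired deletion removes
the same indices from both sides before renumbering.

## Quadrant-parameter estimation

Two perpendicular chords are picked across the basal turn (endpoints P1,
P2 and Q1, Q2). The spiral center M is computed in closed form as the point
minimizing the summed squared distances to the two chord lines — solving
`Σᵢ (I − dᵢdᵢᵀ) M = Σᵢ (I − dᵢdᵢᵀ) aᵢ` — which reduces exactly to the chord
intersection when the chords are coplanar and remains well defined for the
slightly skew chords of real 3D picks (the matrix is singular only for
parallel chords, which are rejected). The extents are then plain Euclidean
distances from the endpoints to M.

## Registration

The model-to-patient map is the composition reflection ∘ (rotation +
translation) ∘ scale ∘ shear, i.e. the homogeneous matrix `F·[R|t]·C·S`
with `R = Rz(γ)·Ry(β)·Rx(α)` (a fixed convention; any full-rank choice
spans the same transform family), `C = diag(c_x, c_y, c_z)` with strictly
positive scales, `S` unit upper-triangular with entries `s_xy, s_xz, s_yz`,
and `F = diag(±1)`. Together these span all invertible linear maps, which
yields the package's primary correctness oracle: the parametric optimum
must match the closed-form unrestricted affine least-squares fit
(`affine_least_squares`, never used by the optimizer itself).

The 12 continuous parameters are fitted by BFGS with an analytic gradient,
starting from the identity parameter values, and stopping when the SSD
change between accepted iterations falls below `tol` (default 1e-6 mm²,
the conventional optimizer tolerance) or after `max_iterations` (default
100). The SSD history over accepted iterations is recorded and is
non-increasing; the gradient norm is not a stopping criterion. Reflection
cannot be reached by continuous descent (the determinant sign cannot
change), so it is discrete: by default the three sign flags are fixed at
+1, and `reflection_search=True` optimizes all 8 assignments and keeps the
lowest SSD — the relevant mode when model and scan may be opposite-sided
ears.

Three numerical choices matter:

- **Log-scale parameterization.** Internally the scale factors are
  optimized as logarithms so a line search can never cross zero scale; the
  reported `p*` holds the plain factors. This also keeps a non-mirrored fit
  from silently absorbing a reflection into a negative scale.
- **Centroid centering.** The descent runs on centroid-centered copies of
  both point sets and the optimal translation is mapped back afterwards.
  Residuals — and therefore every reported SSD — are unchanged, but the
  translation search is conditioned: without centering, poses with
  translations near ±20 mm need well over 100 iterations.
- **Proper-rotation multistart.** The SSD landscape over Euler angles is
  multimodal for large rotations; descent from the identity alone converges
  to a spurious optimum for roughly a third of uniformly random poses. By
  default the solver therefore also starts from the three half-turn
  rotations (π about each axis) — the proper-rotation counterpart of the
  reflection search — and keeps the best result. The reported iteration
  count and SSD history are those of the winning descent. `x0` supports
  warm-starting (used optionally by pruning), which skips the multistart.

Degenerate inputs are rejected: fewer than 4 pairs (underdetermined),
length mismatch, and coplanar/collinear model landmarks (rank < 3). With
exactly 4 affinely independent pairs the fit interpolates exactly (12
equations, 12 unknowns).

**Known limitation:** when the pose's middle Euler angle is within ~0.002
rad of ±π/2 (gimbal lock) the parameterization loses rank and the SSD
change can fall below 1e-6 mm² while the residual SSD is still ~1e-5 mm²
(fitted MAE ~1e-3 mm instead of ~1e-5). This affects ~2‰–2% of uniformly
random poses depending on the threshold of concern, and is a property of
the Euler parameterization combined with the SSD-change stopping rule, not
of the landmark data.

## Pruning

`prune` runs register → rank-by-error (descending, ties broken by lower
label) → delete the top batch from both sides → re-register, following a
plan of batch sizes, never dropping below `min_landmarks` (≥ 4). Protected
labels are skipped in ranking order, so when the apex tops the error
ranking the next-worst deletable landmark is removed instead — the
protected-apex mechanism replaces visual goodness-of-fit assessment: the
human decides from the per-step report (original labels, MAE, iterations,
SSD) rather than from a rendering. Re-registration restarts from the
identity by default; `warm_start=True` seeds it with the previous optimum.
Percent reductions are computed from full-precision MAEs as
`100·(1 − MAE_new/MAE_old)` and displayed at 2 decimals. Deleting
landmarks and re-optimizing can only improve the SSD restricted to the
survivors (the previous optimum stays feasible), which the tests assert on
every phantom run.

## Phantoms

The generator poses the canonical model landmarks with a random affine
transform drawn uniformly from: rotations over the full circle,
translations ±20 mm, scales [0.8, 1.2], shears [−0.2, 0.2] — affine but
anatomically plausible (scales far from 1 or large shears would be
untypical deformations for a cochlea). The default degradation quantizes
every target coordinate to the 0.3 mm voxel grid of conventional CT,
emulating the dominant real-world error source: landmarks can only be
picked on voxel centers, so each coordinate moves by at most half a voxel
(per-landmark displacement ≤ 0.15·√3 mm). An isotropic Gaussian mode
exists for robustness sweeps. Everything is deterministic given the seed.

What phantom tests do and do not show: they verify that the optimizer
recovers a known affine pose exactly (noiseless) and degrades gracefully
under grid quantization (mean recovered MAE ≈ 0.11 mm ≪ 0.3 mm
resolution). They do not emulate the harder parts of real data — manual
picking variability beyond quantization, the non-spiral appearance of a
segmented cochlea at 0.3 mm, anisotropy of real scanners, or true
anatomical deviation from the parametric model (the real cochlea's
cross-section is not circular and its shape is not exactly an affine image
of the mean model). Real-data MAEs in the 0.1–0.25 mm range therefore
cannot be reproduced by phantoms; the phantom-level claim is the noise
floor, not the clinical error.

`rasterize_mask` voxelizes the centerline as a tube (constant or
angle-dependent radius) on an isotropic grid; masks are written as NIfTI
with the spacing in the header and the origin in mm.

## Problem sizes and defaults

Tests and the acceptance checks use the constellation sizes of the
workflow itself (5–23 landmarks), 20-seed phantom batches, and 0.3 mm
grids; registration of one constellation takes milliseconds, so the whole
suite runs in well under a minute of compute. Defaults: `tol=1e-6` mm²,
`max_iterations=100`, voxel 0.3 mm, decay 0.6 per turn, height 4 mm,
reflection search off.
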