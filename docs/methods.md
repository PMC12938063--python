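# Methods

`aaastress` implements an image-to-stress pipeline for abdominal aortic
aneurysms (AAAs): per-slice segmentation of the outer aortic wall in
CT-angiography-like image stacks, NURBS smoothing and programmatic editing
of the segmented contours, lofting of the contour stack into a triangulated
surface, and inverse membrane equilibrium analysis that recovers the wall
stress carried by the imaged, pressurized configuration without any
constitutive model.  This note records the models, the numerical choices,
and the limits of what the synthetic validation shows.

## Inverse membrane equilibrium (the stress model)

A thin-walled pressure vessel is nearly statically determinate: the stress
resultants follow from equilibrium and the applied load alone.  The imaged
CTA geometry is the *deformed* configuration under mean arterial pressure,
so on the triangulated outer-wall surface with uniform thickness `h` and
internal pressure `p` we impose pointwise membrane equilibrium

    (1/√g) (√g h σ^{αβ} g_α),_β + p n = 0 ,   α, β ∈ {1, 2}

where `g_α` is the covariant tangent basis of a surface element, `g` the
determinant of the metric `g_αβ = g_α·g_β`, `σ^{αβ}` the contravariant
in-plane Cauchy stress components and `n` the outward unit normal.  No
material parameters enter.

**Discretization.**  Linear shape functions on each triangle; the covariant
basis is the pair of edge vectors from vertex 0, so `g = (2A)²` with `A`
the element area.  Stress unknowns are *nodal* — three components per
vertex.  Contravariant components are element-basis-dependent, so nodal
values are stored in a per-vertex orthonormal tangent frame (normal =
area-weighted average of incident element normals) and rotated into each
element's basis during assembly; this keeps nodal interpolation well
defined and the system linear.  Galerkin weighting with the same shape
functions gives three force-balance equations per free vertex: the
element-internal nodal force

    f_a = h √g Σ_b (1/6) [ ∂N_a/∂ξ₁ (g₁ σ¹¹_b + g₂ σ¹²_b)
                         + ∂N_a/∂ξ₂ (g₁ σ¹²_b + g₂ σ²²_b) ]

balances the consistent pressure load `p A/3 n` per element vertex.
Proximal and distal boundary rings are "fixed": they carry no balance
equations, and their residuals are the support reactions (their sum
balances the total pressure load to machine precision; this is asserted in
the tests).

**Solution.**  The system has 3V unknowns and 3·(free vertices) equations —
underdetermined, reflecting genuine static indeterminacy (e.g. the uniform
axial stress of an open tube is not fixed by interior equilibrium).  We
take the minimum-Frobenius-norm least-squares solution via Tikhonov-damped
normal equations solved with a sparse LU factorization.  Two details
matter:

* the nodal shear unknown is stored scaled by √2, so the Euclidean norm of
  the unknown vector equals the Frobenius norm of the nodal stress tensors;
  without this the minimum-norm solution depends on the (arbitrary)
  tangent-frame seeds and rigid rotations of the mesh change the answer by
  percents rather than nanounits;
* the damping weight defaults to `1e-6 · ‖A‖²_F / dof`.  Smaller values
  (e.g. 1e-10) leave the normal equations conditioned ~1e10 and roundoff
  in the weakly determined boundary band breaks frame invariance at the
  1e-5 level; at 1e-6 frame invariance holds to ~1e-9 while the cylinder
  and sphere oracles move by < 0.01%.

The minimum-norm choice resolves the indeterminate axial mode of an open
tube to zero — the membrane solution with free ends — which is why the
recovered first principal stress on a cylinder is the hoop stress `pR/h`.
A damped-Newton wrapper is retained so formulations with geometric
nonlinearity can plug in; for the fixed imaged configuration the problem
is linear and the loop converges in one step.

Element centroid stresses are the average of the three nodal values mapped
into the element basis; principal stresses are eigenvalues of the physical
2×2 tensor in an orthonormal tangent frame.  Units: vertices in cm,
pressure converted as 1 mmHg = 133.322 Pa = 1.33322e-2 N/cm², stresses in
N/cm².  The default load case is mean arterial pressure 93.3 mmHg (the
(SBP + 2·DBP)/3 rule applied to 120/80 mmHg) on a wall of uniform 1.5 mm
thickness.

**Validated against**: closed-form Laplace solutions (cylinder `pR/h`,
sphere `pR/2h`, both within 5% and in practice < 0.5% at ~5k elements),
exact linearity in `p` and `1/h`, monotone mesh convergence, frame
invariance, and global force balance.

## NURBS contour refinement

Mask boundaries are extracted by marching squares (largest connected
component only; a single outer wall per slice is assumed).  The binary
indicator is Gaussian-smoothed (σ = 1 px) before contouring: the symmetric
kernel leaves the 0.5 level set of a straight edge in place, so the
boundary is unbiased to first order while the pixel staircase is
suppressed.  This anti-aliasing matters downstream — the inverse
equilibrium solve amplifies boundary curvature noise at azimuthal harmonic
`m` roughly like `m²`, and raw staircase contours inflate recovered
stresses severalfold.

The boundary is replaced by a closed rational B-spline

    c(t) = Σ N_{i,p}(t) w_i P_i / Σ N_{i,p}(t) w_i ,   t ∈ [0, 1]

with Cox–de Boor basis functions, periodic-uniform knots and wrapped
control points (clamped-uniform knots in the open-curve mode).  Three fits
are provided for a fixed control-point count `n` and degree `p` (defaults
24 and 3):

* `control` — arc-length-resampled boundary points *are* the control
  polygon (unit weights);
* `interpolate` — control points solved so the curve passes through the
  resampled points;
* `approximate` — least-squares fit to an 8× denser resampling.

`control` is the default for curve construction; mask refinement and the
pipeline's contour-to-mesh path use `approximate`, because the
control-polygon fit of a convex section shrinks it by the B-spline circle
factor `(2 + cos 2π/n)/3` per pass (repeated refinement would drift),
while the least-squares fit is unbiased and idempotent in practice.  The
pipeline also drops to 12 control points for meshing: aortic cross
sections are near-circular, and fewer control points low-pass the residual
pixel noise that the stress solve would amplify.

Editing is programmatic — `move_control_point` and `set_weight` return new
curves; the B-spline local-support property guarantees samples outside the
moved basis's support are bit-identical.  Rasterization samples the curve
as a dense polyline (10 samples per control point) and fills it with an
even-odd polygon rule.  Contours with holes are unsupported.

## Geometry

Contour stacks (one closed contour per slice, proximal → distal) are
lofted: every contour is resampled to the same number of arc-length-spaced
points (default 48) with counter-clockwise winding, consecutive rings are
aligned by the cyclic shift minimizing the sum of squared distances (twist
minimization), and rings are joined by alternating-diagonal triangle
strips — 2m triangles per band, an open tube with exactly two boundary
loops.  Physical scaling: `(x·pixel_size, y·pixel_size, slice·spacing)` in
mm, stored in cm.  Outward orientation is enforced by capping the tube and
testing the signed volume.

Per-slice size is summarized by the hydraulic diameter `D_h = 4A/P`
(shoelace area over perimeter), which equals the geometric diameter for a
circle; the maximum over slices and its slice index locate the aneurysm
bulge.  The slice-plane convention is used throughout (no centerline
reconstruction).

## Segmentation model

A 2-D U-Net variant whose encoder stages use *dilated* 3×3 convolutions
with per-stage rates 1 → 2 → 3 → 1; the effective receptive field of a
dilated convolution is `RF = (k−1)·d + 1`, so dilation widens context
without extra parameters or pooling.  The decoder mirrors the encoder
(dilation 1) with nearest-neighbour upsampling and skip concatenation; a
1×1 convolution plus sigmoid yields per-pixel foreground probability.
Large slices are split into square patches (64 px default, final offsets
flush with the image edge, reflect padding when the image is smaller than
a patch) and re-assembled by averaging overlapping probabilities.

Training minimizes an equal-weight sum of soft Dice loss (additive
smoothing ε = 1, so two empty masks score Dice 1) and mean binary
cross-entropy, under Adam (initial learning rate 1e-4, batch 16) with
reduce-on-plateau halving of the learning rate (patience 5, floor 1e-6)
and early stopping (patience 5), both monitored on validation Dice.
Augmentation applies seeded flips, ±15° rotation and 0.9–1.1 zoom
identically to image and mask, plus image-only 0.9–1.1 intensity scaling.

The network, backpropagation and optimizer are implemented directly on
numpy arrays (im2col convolutions; the input gradient is the correlation
with the channel-transposed, spatially flipped kernel at the same
dilation).  Gradients are verified against finite differences in the
tests.  Everything is deterministic given the configuration seed.

**Toy scale.**  The architecture defaults (4 stages, base 16 channels) are
sensible for real data but CPU training in the test suite uses a reduced
configuration (`TOY_CONFIG`: 3 stages with rates 1→2→1, base 8 channels,
learning rate 1e-3, batch 2, no augmentation) that overfits ten 64×64
phantom slices to Dice > 0.99 in under 200 epochs within a couple of
minutes.  This demonstrates that the architecture, loss, scheduler and
patching machinery function — it says nothing about segmentation accuracy
on clinical CTA, which requires training at full scale on real data.

## Evaluation metrics

Segmentation agreement: confusion counts and the derived accuracy,
sensitivity, precision, specificity, Dice (DSC), IoU, and Matthews
correlation; the identity `IoU = DSC/(2−DSC)` is asserted property-style.
Degenerate denominators follow the common convention (1 if both masks
empty, 0 if exactly one is).  The 95th-percentile Hausdorff distance is
computed on inner-boundary pixels as the pooled 95th percentile of both
directed nearest-neighbour distance sets (the pooled variant, not the
maximum of two directed percentiles), scaled per-axis to mm.  Stacks are
scored per slice and aggregated as mean ± SD.

Stress summaries over element-centroid first principal stresses: the 99th
percentile (linear interpolation between closest ranks), the arithmetic
mean, and the spatially averaged wall stress (SAWS, area-weighted mean).
Group comparison helpers: R² (squared Pearson correlation by default; the
1 − SS_res/SS_tot-about-identity variant is available) and the Friedman
rank test (scipy backend, mid-rank ties; identical groups return FS 0,
p 1).

## Synthetic phantoms

The fusiform phantom is a tube of baseline outer radius `r0` with a
Gaussian bulge, `r(z) = r0 + (rmax−r0)·exp(−((z−z0)Δz)²/w²)`; defaults
r0 = 1 cm, rmax = 2 cm, w = 3 cm, 40 slices of 2 mm on a 128² grid of
0.8 mm pixels — a modest AAA (4 cm bulge diameter) at CTA-like sampling.
Slices are rendered with three intensity levels ordered lumen > wall >
background (300/120/20, arbitrary synthetic values that mimic
contrast-CTA ordering only) plus seeded Gaussian noise (SD 10), with
per-slice ground-truth outer-wall masks and the exact analytic circle
contours.  Analytic cylinder and icosphere meshes provide the Laplace-law
stress oracles.  All outputs are bit-reproducible from (spec, seed).

What the phantoms do *not* emulate: CT physics (partial volume, beam
hardening, calcification), intraluminal thrombus, non-circular and
branching anatomy, wall-thickness variation, and inter-patient variability.
Passing the synthetic suite therefore validates the numerics and the
plumbing, not clinical performance.

## Problem sizes and scope

Default validation sizes: ~4.6k-element cylinder, 1.3k-element icosphere,
25-slice phantom pipelines, 10-slice toy training runs — chosen so the
whole suite exercises every stage at desk scale.  Out of scope by design:
forward FEA and constitutive models, bending stiffness and
through-thickness stress gradients, thrombus load sharing, non-uniform
thickness, multi-phase (ECG-gated) loading, volumetric meshing, and any
claim about clinical segmentation accuracy or inference speed.
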