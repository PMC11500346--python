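# Methods

This note documents the models, numerical choices and limitations behind
`meshcomp`: a pipeline that fits a low-rank parametric 3D body mesh to a
single orthographic (DXA-style) coronal silhouette augmented with height,
waist and hip circumferences, and predicts ten total/regional
body-composition metrics from the fitted shape coefficients.

## The body model

The mesh generator follows the SMPL recipe. A template mesh `T` (V vertices,
canonical supine frame: body axis = +y, depth off the scanbed = +z) is
deformed by a linear shape basis,

    V_shaped = T + sum_b S[:, :, b] * beta_b ,

joints are obtained from the shaped vertices by a linear regressor `J` whose
rows are convex weights over nearby vertices, and the mesh is posed by
linear blend skinning over an acyclic kinematic tree of axis-angle joint
rotations (Rodrigues' formula, with a second-order Taylor branch below
|theta|^2 = 1e-8 so the gradient is exact at the zero pose). Pose-corrective
blendshapes are omitted: the fitting losses depend only on (theta, beta) and
the downstream regression uses beta alone.

LBS is computed in displacement form,

    v' = v + sum_j w_vj [ (G_R,j - I)(v - j_rest,j) + (G_t,j - j_rest,j) ] ,

which makes the zero-pose identity bit-exact and is algebraically the usual
rigid-blend formula. Everything is differentiable end-to-end through the
package's reverse-mode tape (`meshcomp.autodiff`), a small engine written on
NumPy with a custom-op hook for the rasterizer kernels.

Joint regressor supports are selected by in-plane (x, y) distance and closed
under z-mirror symmetry. This puts regressed joints on the medial axis and
makes their depth exactly invariant under sagittal-only shape changes — a
property the scanbed depth prior relies on (otherwise spurious depth
gradients leak into under-determined shape directions).

### The synthetic humanoid

A licensed registered body model cannot be redistributed, so the package
ships a generator for a synthetic humanoid: a union of closed
elliptical-cross-section tubes (torso, head, two arms, two legs; ~1.8k
vertices, 17 joints) that overlap at shoulders/neck/hips so the coronal
silhouette is one connected region. Each component is a closed 2-manifold;
the union is edge-manifold, so the signed-tetrahedron volume equals the sum
of component volumes (small embedded overlaps at the joints are counted
twice; the default template's volume, 64.9 L, is in the realistic range for
a 1.68 m adult).

The ten shape directions are constructed, not learned: stature, torso depth
(sagittal only — by construction invisible in the coronal silhouette, which
encodes the single-view depth ambiguity the anthropometry loss exists to
resolve), waist girth, hip girth, limb thickness, shoulder width, leg
length, and three seeded smooth residual fields. One unit of each
coefficient is one prior SD. Waist/hip/calf/arm landmark rings are vertex
index lists on the template (waist = narrowest torso band, hip = widest
pelvic band); height uses two fixed extrema vertex ids (head-top and heel
cap centroids) so its gradient is well defined (no argmax switching).

## Measurements

Circumferences: the ring vertices are projected onto the transverse plane
(the body-axis coordinate is dropped), an ellipse is fitted by least squares
on the conic `a x^2 + b xy + c y^2 + d x + e y + f = 0` under the
normalization `a + c = 1` (valid for any real ellipse), which reduces the
fit to a linear solve differentiated exactly via the implicit form of the
normal equations. Geometric parameters follow from the closed-form 2x2
eigendecomposition. The perimeter uses Ramanujan's second approximation,

    P = pi (a+b) [ 1 + 3h / (10 + sqrt(4 - 3h)) ],  h = ((a-b)/(a+b))^2 ,

whose relative error against Gauss–Legendre quadrature of the exact
arc-length integral is < 1e-5 up to aspect ratio 4 (measured: ~2.5e-7).
Volume is the signed tetrahedron sum over faces, reported in liters, with a
warning (not an error) for non-closed meshes.

In the fitting loop, height and circumferences are measured on the shaped
*unposed* mesh (the T-pose convention): anthropometric tape measurements
describe the body, not the scan pose, and this keeps the anthropometry terms
independent of pose estimation error.

## Silhouette rendering

The weak-perspective camera maps `p2d = s (x, y) + (t_x, t_y)`; depth is
dropped; image convention is x right, y down, origin top-left, pixel centers
at integer coordinates. The soft rasterizer aggregates per pixel

    occ(p) = 1 - prod_f (1 - w_f * sigmoid(k d_f(p))) ,

where `d_f` is the signed 2D distance of the pixel center into projected
face f (positive inside; distance to the nearest edge with the envelope
derivative) and `k` is the sharpness in 1/px. As k grows the render tends to
the hard rasterization (IoU vs a scanline polygon-fill oracle: 0.999+ at
k = 60). Forward and hand-derived backward passes are Numba kernels; each
face only touches a bounding box padded by 8/k + 1 px (sigmoid tails beyond
are < 3e-4 and truncated — finite-difference checks should therefore ignore
directional derivatives below ~1e-6).

`w_f` is a face fade: for a closed mesh every silhouette pixel is covered by
a front-facing face, so back-facing faces are culled — smoothly, by a
smoothstep of the projected orientation over a 1 px^2 band, with the
orientation derivative propagated in backward. The smooth fade matters
twice: binary culling would make the loss discontinuous when a face turns
edge-on, and the tube end-caps of the synthetic template are *exactly*
edge-on in the canonical view, which would otherwise put gradient kinks at
the unperturbed configuration. A `backface_cull=False` flag restores the
plain product over all faces.

Silhouette extraction from DXA-style grayscale images thresholds, keeps the
largest connected component, and fills interior holes (both cleanup steps
toggleable). The threshold is a required parameter with no claimed default.

## The fitting objective

Three loss groups, each with manually tuned non-negative weights
(`LossWeights`, all defaults are this package's tuning):

* anthropometry (`l1=50, l2=50, l3=100`, meters^2):
  `l1 (C_W_hat - C_W)^2 + l2 (C_H_hat - C_H)^2 + l3 (H_hat - H)^2`;
* silhouette (`l4=30`) — mean per-pixel squared difference between the soft
  render and the target mask (the mean, rather than the printed sum, makes
  the weight resolution-independent; `silhouette_reduction="sum"` restores
  the raw sum) — plus a 2D joint regulariser (`l5=1e-4`) toward the
  projected joints of the initial estimate;
* scanbed alignment: `l6=2` on the x/y (out-of-bed-plane) components of
  spine/hip/knee/ankle rotations, `l7=0.5` anchoring arm/wrist rotations to
  their initial values, and `l8=2` pulling elbow/wrist joint depths to the
  pelvis depth plane. The joint subsets are model metadata
  (`joint_groups`), not constants.

Optimization is Adam over (beta, theta, camera) with per-group learning
rates (0.03 / 0.02 / 0.3), a fixed 400-iteration budget, joint camera
optimization from the start (freezable by flag), and best-loss iterate
selection; there are no stochastic terms, so fits are deterministic. Adam's
epsilon is set to 1e-2 rather than the usual 1e-8: Adam normalizes steps per
parameter, so a shape direction whose gradient is at numerical-noise level
(the silhouette-invisible torso-depth direction when the circumference terms
are disabled) would otherwise random-walk at full learning-rate speed along
a loss-flat valley. The larger epsilon suppresses steps where the gradient
is ~1e-5 or below while leaving well-determined directions (gradients
1e-2–1) untouched.

Measured behaviour on the default synthetic conditions (20 subjects, shape
shrunk 60% toward the prior mean with noise, perturbed supine pose, 256x256
canvas): silhouette IoU >= 0.97 for every subject, waist/hip circumference
agreement with the fit targets ~0.1–0.3%, torso-depth coefficient error
~0.2 SD; ablating the waist/hip terms leaves the silhouette fit intact but
at least doubles (typically 3–7x) the depth error — the depth information
enters through the circumferences, not the silhouette.

## The composition regressor

A single feed-forward network maps the feature vector (shape coefficients,
height, weight, BMI — always computed, never supplied — and sex coded
female=0/male=1) to all ten metrics. Architecture: input linear layer to
width 80, two residual hidden layers (identity skips), linear head; ~15k
trainable parameters, inside the intended 14k–18k band. Training: Adam,
lr 0.01, 100 epochs, batch 256, inverted dropout 0.1 on hidden activations
(training only), features and targets standardized on the training split,
best-validation-epoch weights returned, fully seeded. The multi-task loss is
weighted by learned homoscedastic uncertainties,

    L(W, sigma) = sum_i MSE_i / (2 sigma_i^2) + sum_i log sigma_i ,

parameterized by log sigma_i; since targets are standardized, sigma_i lives
on the standardized scale and its stationary point is the per-metric
residual RMSE (asserted analytically in the tests). The linear baseline is
per-metric OLS behind the same predict interface, with a named-column error
on rank deficiency.

The noiseless linear-map recovery experiment (R^2 > 0.999 per metric) is
run with dropout disabled: that study's task has no noise to regularize
against, and the dropout gradient noise otherwise leaves a ~1% residual
floor at a fixed 100-epoch budget. Default training keeps dropout 0.1.

Comparison-study feature sets: A = height+weight; B = +waist; C =
+waist+hip; D = shape+height+weight+BMI+sex through the linear baseline;
E = the same features through the network.

## Multiview fusion

Per-view diagonal Gaussians over shape are fused as a product of Gaussians:
precisions add, means are precision-weighted. Whether the product is
renormalized does not affect the returned mean/variance. Full-covariance
fusion is a straightforward extension that is deliberately left out.

## Synthetic cohorts

`generate_cohort` draws beta ~ N(0, diag(prior_sd^2)), measures true
anthropometry on the shaped mesh (weight = mesh volume x 1070 kg/m^3, a
soft-tissue-scale density chosen so the default template weighs ~69 kg),
adds tape noise (1 cm SD on waist/hip, 0.3 cm on height, 0.2 kg on weight),
renders the supine silhouette with the hard rasterizer under a standard
camera (0.82 x canvas / 1.8 m scale), and generates composition from a known
map: linear terms in weight, waist, hip and sex; shape terms (torso depth →
visceral fat, echoing the correlation of visceral fat with sagittal
abdominal diameter; limb thickness → peripheral fat and lean); and one
quadratic waist term in visceral fat so the network/linear comparison is
non-trivial. Magnitudes are loosely anchored to adult-cohort scales (total
fat ~24 +/- 6 kg, PBF ~33%, lean ~43 kg) — inspiration, not claims. The
exact identities pbf = 100·fat/weight, almi = alm/height^2 and
android = visceral + abdominal SCAT hold in every record because the
derived metrics are computed from the noised base metrics. Sex enters the
composition map only; the mesh geometry is sex-free (a documented
simplification). A `composition_effects` level ("full" / "anthro" /
"basic") restricts the map for study designs that need a degenerate
generator.

Per-subject randomness is keyed by (seed, subject index, stream), so
cohorts are bit-reproducible and the longitudinal generator can re-realize
a subject with a drifted shape while reusing the same noise draws: zero
drift reproduces phase 1 exactly, and within-subject deltas are driven by
the drift alone. Drift defaults concentrate on the depth/waist/hip
directions (SD 0.6) with near-static stature/limb directions (SD 0.05),
emulating cohorts whose lean mass changes little; because lean is the small
difference weight − fat − const, its deltas are intrinsically harder to
predict, which reproduces the fat-vs-lean ordering of change correlations.

Initializer degradation emulates a probabilistic single-view estimator
biased toward the prior mean: init shape = (1 − 0.6)·truth + N(0, 0.1^2),
pose = supine + N(0, 0.03^2) per component + a 0.15 rad forward torso lean
split over spine/chest, camera = truth, 2D joint targets projected from the
degraded state.

## Agreement statistics

Bias = mean(pred − truth); limits of agreement = bias ± 1.96·SD of the
differences (sample SD, n−1), with no LoA confidence-interval correction;
RMSE; two-sided paired t-test for bias = 0 (scipy, cross-checked against a
second implementation in the tests). R^2 is reported as squared Pearson
correlation; `r2_definition="explained"` switches to 1 − SSE/SST (the two
differ for biased predictors). Bland–Altman payloads put the *reference*
value on the x-axis, not the pair mean. Reports round biases/LoA/r to two
decimals for display; machine output keeps full precision.

## Problem sizes and runtimes

Test-suite and acceptance-script study sizes are chosen as the package's
default desk-scale conditions: 20 fitted subjects (plus the ablation) for
recovery, cohorts of 1000–3000 for the regression studies, 5000 rows for
the linear-map recovery, 1000 subjects for fusion calibration. A single
256x256 fit takes ~10 s on one CPU core (~25 ms per iteration, dominated by
the rasterizer kernels).

## Known limitations

* The synthetic humanoid is a geometric stand-in: its shape space is
  constructed rather than learned from scans, its parts join by overlap
  rather than blended geometry, and its silhouettes lack DXA texture,
  attenuation and soft-tissue supine deformation. Passing tests demonstrate
  the correctness and calibration of the pipeline's machinery on known
  ground truth, not clinical accuracy on real DXA cohorts.
* The composition generator is a stylized linear(+one quadratic) map;
  real-data relationships are richer, so absolute R^2/RMSE values here are
  not comparable with published cohort numbers — only the qualitative
  orderings (shape inputs beat anthropometry-only; network beats linear
  under nonlinearity; fat changes beat lean changes) are meaningful.
* Circumference uses a single-ellipse cross-section approximation, not a
  geodesic tape path; for strongly non-elliptical sections both this
  implementation and a tape measure diverge in different ways.
* The probabilistic image-based initializer is represented only by its
  output contract (a Gaussian over shape + a pose estimate), emulated by
  the degradation model above.
* Loss weights and optimizer settings are this package's tuning; they were
  chosen for the synthetic study conditions and will need re-tuning for
  other body models or image resolutions.
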