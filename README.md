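# meshcomp

Body composition from parametric 3D body shape.

Whole-body DXA quantifies total and regional fat and lean mass, but
scanners are confined to clinics. A person's outer 3D shape, however,
carries most of that signal — and a usable estimate of 3D shape can be
recovered from a single orthographic coronal silhouette (a DXA scout-style
image, or a phone photo pipeline) *if* the missing depth dimension is
supplied some other way. `meshcomp` implements that idea end to end:

1. **Mesh fitting.** A low-rank parametric body mesh — template `T`, linear
   shape basis (coefficients β), linear joint regressor, linear blend
   skinning over axis-angle joint rotations θ — is fitted to a binary
   silhouette `S_gt` under a weak-perspective camera `c = [s, t_x, t_y]` by
   minimizing

       L(β, θ, c) = λ1‖Ĉ_W − C_W‖² + λ2‖Ĉ_H − C_H‖² + λ3‖Ĥ − H‖²
                  + λ4‖R(M(θ, β), c) − S_gt‖² + λ5‖Ĵ_2D − J_2D‖²
                  + λ6‖θ⁽¹⁾|_{x,y}‖² + λ7‖θ⁽²⁾ − θ⁽²⁾_init‖² + λ8‖z_arms − z_pelvis‖²

   where Ĉ_W, Ĉ_H, Ĥ are waist/hip circumference and height measured
   differentiably on the mesh (ring projection → least-squares ellipse →
   Ramanujan perimeter), R is a soft differentiable silhouette rasterizer,
   and the last row encodes supine scanbed priors. The waist/hip terms are
   the point: a coronal silhouette is blind to sagittal depth, and the
   circumferences inject it.
2. **Composition regression.** The fitted β plus height, weight, BMI and
   sex feed a small (~15k-parameter) residual feed-forward network with ten
   outputs (total fat, PBF, android/gynoid/visceral/abdominal-SCAT/
   peripheral fat, total lean, appendicular lean mass, ALMI), trained with
   a homoscedastic multi-task loss Σᵢ MSEᵢ/(2σᵢ²) + Σᵢ log σᵢ whose
   per-metric uncertainties σᵢ are learned. An OLS baseline shares the
   predict interface.
3. **Multiview fusion.** For the photo pathway, per-view Gaussian shape
   estimates are fused by a product of Gaussians (precisions add).
4. **Evaluation.** Bland–Altman bias and 95% limits of agreement
   (bias ± 1.96 SD), RMSE, Pearson r / R², paired t-tests, and a
   longitudinal change analysis on within-subject deltas.

Real DXA cohorts are access-restricted, so the package ships a fully
synthetic pathway: a watertight humanoid body model with interpretable
shape directions (stature, torso depth, waist/hip girth, ...), and a cohort
generator producing silhouettes, tape-noised anthropometry, composition
metrics with known generative structure, longitudinal pairs and degraded
initial estimates. Every stage of the pipeline is testable against known
ground truth. No PyTorch is required: the package carries its own
reverse-mode autodiff tape on NumPy with Numba rasterizer kernels.

## Worked example

```python
import numpy as np
from meshcomp import (
    build_synthetic_model, GeneratorConfig, generate_cohort,
    SilhouetteFitModel, FitConfig, cohort_frame, CompositionModel,
)

model = build_synthetic_model(seed=0)

# one synthetic subject: silhouette + noised tape measurements + degraded init
subject = generate_cohort(model, GeneratorConfig(n=1, seed=3))[0]
fit = SilhouetteFitModel(
    model, subject.silhouette, subject.observed_anthro, subject.init
).fit(FitConfig())
print(fit.summary())

# composition model on a synthetic cohort (true shapes)
df = cohort_frame(generate_cohort(
    model, GeneratorConfig(n=2000, seed=5, with_silhouettes=False, with_inits=False)))
res = CompositionModel(df.iloc[:1600], spec="E").fit(seed=0)
print(res.evaluate(df.iloc[1600:]).round(3).head(4))
```

Output:

```
Silhouette fit
  iterations: 400 (best at 393)
  final loss: 0.182484
  final IoU : 0.9897
  measured anthropometry (m):
      height: 1.7197
       waist: 0.6721
         hip: 0.8190
```

The fit reproduces the silhouette (intersection-over-union 0.99 against the
target mask) and matches the supplied waist/hip circumference and height
targets to a few millimeters; the torso-depth shape coefficient — invisible
in the coronal view — is recovered through the circumference terms.

```
                 r  r_squared   rmse   bias
metric
total_fat    0.977      0.955  1.303 -0.035
pbf          0.957      0.915  1.860 -0.026
android_fat  0.974      0.949  0.270 -0.004
gynoid_fat   0.930      0.864  0.363  0.019
```

Held-out agreement of the Model-E network on the synthetic cohort: the
R² ≈ 0.95 for total fat reflects the generator's noise floor, and the
learned σᵢ rank the metrics by residual noise.

## Command line

```sh
meshcomp build-model --out model.npz
meshcomp simulate --model model.npz --n 20 --seed 0 --out cohort/
meshcomp fit --model model.npz --silhouette cohort/S0_00000.png \
             --anthro anthro.csv --out fit.json --mesh-out fitted.obj
meshcomp train --cohort cohort/cohort.csv --spec E --out regressor.npz
meshcomp evaluate --pred pred.csv --truth truth.csv --out report.json --plots plots/
meshcomp experiment comparison --seed 0 --out study/
```

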