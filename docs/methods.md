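# Methods

`printfid` models one complete print-quality workflow for extrusion
bioprinting of a shear-thinning ink: predict the deposited strand from
rheology, score printed scaffolds against their CAD target, classify prints
High/Low with a CNN, and optimize printing parameters with a full-factorial
design. This note records the models, the defaults and why they were
chosen, and what the synthetic-data studies do and do not demonstrate.

## Extrusion model

The ink is treated as an Ostwald–de Waele (power-law) fluid,
`eta(gamma_dot) = K * gamma_dot^(n-1)`, in fully developed laminar flow
through a cylindrical nozzle of bore `W_n` (radius `R = W_n/2`) and channel
length `L`. The model is one-dimensional and isothermal; entrance effects,
viscoelastic relaxation, and crosslinking kinetics on the bed are outside
its scope.

Relations implemented:

- `Q = V_ext * pi * R^2` — the flow rate is extrusion velocity times the
  nozzle cross-sectional area. (The area reading is the only one that is
  dimensionally a volume flux.)
- `V_max = V_ext * (3n+1)/n` — the centreline/mean velocity ratio used by
  this model family. The textbook power-law pipe profile gives
  `(3n+1)/(n+1)`; that variant is available as `profile="textbook"` so the
  two can be compared, but the default reproduces the ratio form.
- `V_ext = n/(3n+1) * R^2/K * dP/L` and its exact algebraic inverse
  `K = n/(3n+1) * R^2/V_ext * dP/L` (generalized Hagen–Poiseuille).
- `dP = 8 * eta * V_ext * L / R^2` — the Newtonian pressure drop, used with
  an effective viscosity.
- `D_f = 4 * W_n * V_ext / (n * V_max)` — strand diameter. `W_n` must be a
  length for the expression to carry units of length, so the inner
  *diameter* is used. With `V_max` from the ratio relation this collapses
  to `D_f = 4 W_n/(3n+1)`: a Newtonian ink gives exactly the bore, and
  shear-thinning inks (n < 1) swell beyond it (die swell).

Units: the public API uses printer-native units (mm, mm/s, kPa); the
pressure-drop arithmetic runs in SI with all conversions centralized in
`printfid._units`. The power-law fit is ordinary least squares in log–log
space over a configurable shear-rate window (default: the whole curve,
since rheometer fitting ranges are rarely reported). Nozzle gauges map to
bores 25G = 0.250 mm and 27G = 0.210 mm; the table is user-overridable.
The channel length of a dispensing tip is rarely published, so it defaults
to 12.7 mm (a standard half-inch tip) and every CLI report flags when the
default was used.

The CLI's pressure-drop figure evaluates the effective viscosity at the
characteristic shear rate `V_ext / R`; this is a deliberate, simple
surrogate for the full wall-shear calculation and is labelled as such in
the report.

## Fidelity scoring

Images are converted to grayscale, Gaussian-smoothed (sigma 1 px),
binarized with Otsu's threshold, and resized to 128 x 128 for the
classifier. Re-binarization after the resize keeps the top-k interpolated
intensities where k preserves the pre-resize foreground fraction; a fixed
0.5 threshold systematically thickens strands that are only a few pixels
wide.

- **SSIM** is the mean over 7 x 7 uniform sliding windows (reflect
  padding) of the standard luminance/contrast/structure product with
  `C1 = (0.01 D)^2`, `C2 = (0.03 D)^2`, `D` the dynamic range. The variant
  with `mu_x^2 + mu_y^2` in place of the variance sum in the second
  denominator factor is available via `as_printed=True`; it is not the
  default because it breaks the self-similarity identity
  `ssim(x, x) = 1` on non-binary images.
- **Dimensional similarity** `SD = 100 - (|L - L_o| + |W - W_o|) /
  max(L_o, W_o) * 100`. Absolute values are applied to both deviations so
  undershoot cannot raise the score above 100.
- **Aggregate similarity** `SA = (SSIM% + SD)/2`, with SSIM rescaled to
  percent before averaging.
- **Manual similarity** `100 - E_D`, where `E_D` is the mean of the three
  absolute percentage errors of length, width, and strand diameter. (A
  literal `sum/3 * 100` reading double-scales percent inputs; it is kept
  behind a `literal=True` flag.)
- All similarity outputs are clamped to [0, 100].

Physical measurement from an image (`measure_mesh`) uses the tight
foreground bounding box for length/width and estimates the strand diameter
as `2 * median(EDT on the skeleton) - 1 px`, correcting for the half-pixel
boundary offset of the Euclidean distance transform. Accuracy is limited
to about one pixel; strands whose rasterized width is an even number of
pixels can be under-read by up to one pixel, which is why dimensional
measurements are taken at the image's native resolution rather than on
the 128 x 128 classifier input.

## Classifier

Architecture: input (128, 128, 1); four blocks of 3 x 3 convolution with
channel depths 32/64/128/256, each followed by batch normalization, ReLU
and 2 x 2 max pooling; flatten; one 256-unit ReLU dense layer with L2
penalty 1e-4; dropout 0.5; a single sigmoid output (High = 1 when the
aggregate similarity SA reaches the label threshold, default 70%). The
network is implemented in `printfid.nn`, a compact NumPy engine whose
convolutions run as nine shifted GEMMs; a `width` knob scales all depths
proportionally for quick studies.

Training: stratified 80/20 split; incremental stages over growing subsets
of the training pool (250, then +100 per stage, final stage = the full
pool); binary cross-entropy with class weights `n/(2 n_c)`; Adam at 1e-3;
early stopping on validation loss (patience 10 of at most 100 epochs by
default); minority-class balancing by flips and 90-degree rotations, the
only augmentations that preserve the mesh's symmetry. One seed drives the
split, initialization, shuffling and augmentation; two runs with the same
seed and configuration reproduce the validation loss exactly on a fixed
BLAS.

Metrics: recall, F1 and accuracy at threshold 0.5, overall ROC-AUC and
PR-AUC. In a binary problem the one-vs-rest ROC-AUC is the same number for
both classes, so the per-class pair reported is the per-class *average
precision* (PR-AUC), which genuinely differs; the three quantities are
never conflated.

Best-print selection: among images predicted High, the one with maximal SA
wins; ties break by manual similarity, then lowest run_id; the winner's
row of the factorial experiment matrix supplies its printing parameters.
If nothing is predicted High the result is empty with a warning.

## Factorial design and regression

The design crosses nozzle gauge {27, 25} G, pressure {160..200} kPa and
velocity {5..25} mm/s (50 cells). Regression uses natural-unit *centered*
factors (A-26, B-180, C-15) — not ±1 orthogonal coding — so coefficients
are directly comparable with the shipped reference surfaces `eq19`
(strand diameter, mm, R² 0.85 at scale) and `eq20` (SSIM similarity, %,
R² 0.97), which are stored as literal coefficient sets independent of any
fitting.

Fitting is OLS on all terms up to ABC with per-term t-test p-values;
pruning removes, in a single pass, every non-intercept term with p >= 0.01
and refits the survivors, returning the full trace. No hierarchy
protection is applied: the reference `eq20` surface itself keeps main
effects that its own significance screen would drop, so the shipped
surfaces are deliberately decoupled from the pruning rule. Under the
centered linear coding the unreplicated 50-run design still leaves 42
residual degrees of freedom, so all eight terms (including ABC) get
p-values whenever the residual degrees of freedom are positive; a constant
response is reported as intercept-only with R² defined as 0.

Comparison statistics: MAE, MSE and the product-moment correlation, with
the correlation undefined (an error) for constant vectors.

## Synthetic data generator

`render_mesh` rasterizes a square grid scaffold — default 10 mm x 10 mm,
5 x 5 strands of 0.25 mm (the 25G bore) at 0.05 mm/px on a 256 x 256
canvas, outer strand centrelines inset by half a strand so the
edge-to-edge extent equals the CAD dimension. Controls: `defect_rate`
removes whole strand segments between crossings (seeded Bernoulli),
`dimension_bias` stretches the overall length/width, `noise_sigma` adds
clipped Gaussian intensity noise. Ground truth is returned from the spec,
not re-measured.

DoE responses are drawn from the reference surfaces plus Gaussian noise.
The default noise levels, sigma = 0.330 mm (diameter) and 1.078 %
(similarity), follow from `sigma^2 = V * (1 - R^2)/R^2` with V the surface
variance over the balanced design (0.6189 mm², 37.60 %²), so that the
all-terms fit at 17 replicates per cell (850 runs) lands at R² ≈ 0.85 and
0.97 respectively.

The labelled image sets mix a good component (defect 0–4%, bias
sd 0.08 mm, light noise) and a poor component (defect 30–60%, bias
1.2–2.4 mm, heavier noise), scored by the fidelity module and labelled at
SA ≥ 70%. The two components are well separated by construction, which is
what makes the classifier sanity studies *sanity checks*: passing them
shows the architecture, training loop and plumbing work, not that the
network would reach any particular accuracy on micrographs of real
prints. A `plant_optimum` switch renders one image exactly at the CAD
spec so the end-to-end selection test has a known right answer.

## Problem sizes

Training studies in the test suite use the narrow network (width 4–8) on
60–120 images, with the full-width 32/64/128/256 architecture exercised
once on a 400-image separable set (two epochs per stage). The acceptance
script repeats that 400-image run plus an 80-image planted-optimum
pipeline, a 1000-point algebra grid, 100 rheology noise seeds, and
factorial fits up to 850 runs. These sizes were chosen so a complete run
takes minutes on a single CPU while still exercising every component at
meaningful scale.

## Limitations

- Published wet-lab and instrument-bound values — caliper means of real
  printed meshes, FEM/CFD flow fields, rheometer extremes, and the
  original microscope-image classifier scores — depend on raw data and
  commercial software that are not distributed with their source; they
  cannot be recomputed here and are not claimed. The synthetic studies
  validate the machinery, with known ground truth, in their place.
- The mesh renderer is schematic: binary strands with additive noise, no
  hydrogel texture, illumination gradients, or die-swell geometry beyond
  the analytic prediction. Classifier results on it do not transfer to
  real micrographs.
- Strand-diameter measurement from images is pixel-quantized (about one
  pixel of systematic uncertainty, parity-dependent).
- The velocity-ratio relation `(3n+1)/n` is implemented as the model
  family defines it, without asserting physical correctness against the
  textbook profile ratio; both are available.
- Bit-level training reproducibility assumes a fixed BLAS; across
  different BLAS builds results match only to numerical precision.
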