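# Methods

This note documents the models, the preprocessing conventions, the synthetic
cohort generator, and the numerical choices behind `adaptdose`. It is the
package's own account of its science; every number quoted here is computed by
the test suite or the bundled scripts.

## Problem setting

In online adaptive radiotherapy (ART) for head-and-neck cancer, a plan is
re-optimized at every treatment session against that day's anatomy. A dose
predictor that proposes a realistic 3D dose distribution for the adaptive
session shortens planning. Most population dose predictors see only the
session's anatomy (contours + CT); they are blind to the *per-patient*
trade-offs the physician encoded in the approved pre-treatment plan. The
dual-head model implemented here conditions the prediction on that
pre-treatment plan, so patient-specific organ-sparing intent carries forward
across sessions without per-patient retraining.

## Inputs and preprocessing

A *plan session* holds a CT (HU), binary masks for structures drawn from a
canonical 44-entry organ-at-risk (OAR) roster, a merged PTV prescription map
(Gy per voxel), and — for approved plans — the planned dose (Gy). All volumes
are resampled to a 5 mm isotropic working grid (trilinear for CT/dose,
nearest-neighbour for masks and the prescription map, whose levels are
categorical). The output shape of resampling is `ceil(n * s_in / s_out)` per
axis.

The networks consume fixed-layout channel stacks:

* **primary head (90 channels)** — 44 OAR masks in roster order, the 44
  matching distance maps, the merged PTV map, and the CT of the *adaptive*
  session;
* **secondary head (91 channels)** — the same layout for the *pre-treatment*
  session plus its approved dose.

Structures absent from a session contribute all-zero mask and distance
channels, so the channel manifest is identical for every patient. One roster
entry (`posterior_neck`, the posterior-neck planning region) completes the
roster to 44 alongside the 43 individually enumerated clinical structures.

**Distance maps.** Each OAR contributes a normalized map in [0, 1]:
`exp(-d / tau)` with `d` the Euclidean distance (mm) to the nearest
in-structure voxel, hence exactly 1.0 inside the structure, decaying to 0
far away. Default `tau` = 50 mm (a gentle gradient across a head-and-neck
field; configurable). An alternative *isocenter* mode measures distance to
the structure's centre of mass with inside voxels clamped to 1.0; it is kept
as an option because the two conventions coexist in the field, but the
surface mode is the default since one map is produced per OAR.

**Intensity normalization.** CT: `(HU + 1000) / 2000` clipped to [0, 1].
Dose and prescription channels: divided by the cohort's maximum prescription
(default 72 Gy). Predictions are made in normalized units and rescaled to Gy.

## Architectures

Both networks are 3D encoder–decoders built from the same blocks:

* encoder block: two (3x3x3 conv, stride 1 → group norm (32 groups) → ReLU →
  block dropout) stages at the level width;
* downsampling: *concatenated* 2x2x2 max pooling and 2x2x2 average pooling —
  spatial dims halve, channels double;
* upsampling: concatenation of nearest-neighbour interpolation, trilinear
  interpolation, and a 2x2x2 stride-2 transposed convolution;
* output: a 1x1x1 convolution to one channel, followed by ReLU (dose is
  non-negative; configurable).

Level widths are 64, 128, 256, 512 over four resolution levels at the full
configuration. Block dropout grows with depth:
`rate(f) = 0.05 * (f / 512)^0.25` for a block with `f` filters, so deeper
(wider) blocks are regularized more strongly.

The **baseline U-Net** runs a single encoder over the 90-channel adaptive
stack. The **dual-head network** adds a mirrored secondary encoder over the
91-channel pre-treatment stack. Each head applies its own dual pooling; the
pooled secondary features are concatenated onto the pooled primary features
before the next primary block, whose convolutions project the widened input
back to the nominal level width. After the third downsampling the
concatenated streams feed one shared bottleneck (512 channels at 12x12x8 for
a 96x96x64 input), and a single decoder with skip connections from the
*primary* encoder reconstructs the dose. For a 96x96x64 patch the audit
landmarks are [1, 64, 96, 96, 64] after the first block, [1, 128, 48, 48, 32]
after the first pooling, [1, 512, 12, 12, 8] at the bottleneck, and
[1, 1, 96, 96, 64] at the output.

Design points the published structure leaves open, resolved here: channel
bookkeeping at fusion points (convolutions after each concatenation project
back to the level width, which is what makes the printed bottleneck width
hold); the transposed-convolution branch uses kernel 2, stride 2, no output
padding; decoder blocks are group-normalized like encoder blocks (flag to
disable); dropout follows every conv+norm+ReLU stack and is disabled at
inference; weights use He fan-in initialization from a seeded generator. A
skip-free parallel upsampling stream merged before the output head is
available behind the `bypass_stream` flag (off by default) for the
description of a feature map that bypasses the skip connections; it is not
part of the audited configuration. At small test widths, group normalization
uses the largest divisor of the channel count not exceeding 32.

### Numerical core

The networks run on a small reverse-mode autodiff engine written on numpy
(`adaptdose.nn`): im2col-based 3D convolution with the input gradient
computed as a flipped-kernel correlation (both GEMM-bound), exact-argmax max
pooling, separable half-pixel trilinear upsampling and its adjoint, group
normalization with the standard closed-form backward pass, and Adam. All ops
are checked against central finite differences in the test suite. Volumes
are channel-first float32 with an implicit batch of one (the training
protocol uses batch size 1). Input-layer convolutions skip the input
gradient and prune identically-zero channels from the contraction — exact
optimizations that matter because most of the 90 roster channels are zero
for any one patient.

## Training protocol

Adam with a constant learning rate (default 1e-4), batch size 1, MSE loss on
prescription-normalized dose (sum of squared voxel differences over the voxel
count). Training samples are random patches (default 96x96x64): the centre
is drawn from a Gaussian at the PTV centre of mass (per-axis sigma, default
5 voxels — patches almost always contain the target) and clamped so the
patch fits; volumes smaller than the patch are zero-padded. Augmentation is
purely geometric and in-plane (the axial plane of the patch): with
probability 0.5 one flip along x or y, and independently with probability
0.5 one rotation from {90°, 180°, 270°} (a switch selects the alternative
uniform-over-four-angles reading). The identical transform is applied to the
input stack(s) and the target.

One epoch visits every training sample a configurable number of times in
shuffled order with a fresh random patch per visit. Validation loss is
computed on whole volumes in inference mode — deterministic, so
best-checkpoint selection is reproducible — stitched from patch-sized tiles
with overlap averaging, so that group-normalization statistics at validation
time match the training patches. A `validate_every` knob thins validation to
every k-th epoch where wall-clock budgets demand it (the best checkpoint is
then selected among validated epochs). For deployment-style prediction,
grids compatible with the pooling hierarchy can also be predicted in one
fully-convolutional pass; because group normalization pools statistics over
the whole window, tiled and single-pass predictions agree only
approximately, and on trained models the difference is a small fraction of
the dose scale (asserted in the suite).

The dual-head model can additionally train on each pre-treatment plan fed to
both heads with its own dose as target (self-conditioning), mirroring a
cohort whose pre-treatment plans are part of the training pool; a flag
excludes these samples, and matched-exposure comparisons (below) exclude
them.

## Dosimetric evaluation

Cumulative DVHs are computed by counting masked voxels at or above each
level of a uniform 1000-point dose grid. `Dx%` (minimum dose to the hottest
x% of a structure) is the `(1 - x/100)` quantile of the voxel doses with
linear interpolation between order statistics; reading `Dx%` off a DVH curve
uses definition-based step inversion, which agrees with the quantile to grid
resolution when voxels sample the dose range densely. `Dmax` is the maximum
voxel dose (no volume qualifier). Homogeneity is `(D2% - D98%) / D50%`.
Prediction errors are absolute differences as a percentage of the patient's
highest prescription. Model comparisons use the two-tailed Wilcoxon
signed-rank test at alpha 0.05 on paired per-patient error differences
(zero differences dropped, ties mid-ranked, exact null for small samples);
identical predictions are reported as degenerate with p = 1.

## Synthetic phantom cohort

The clinical cohort behind the method is not publicly available, so the
package ships a generator that emulates its *statistical* structure — not
beam physics. Each synthetic patient has:

* an anatomy: a body ellipsoid, 1–2 ellipsoidal PTVs (prescriptions uniform
  in 42.5–72 Gy) near the grid centre, and eight roster OARs (cord-like tube
  plus gland/cavity ellipsoids) placed in anatomically-inspired directions
  2–10 mm from the target surface;
* a latent *sparing profile*: one strength `sigma_o` ~ U(0, 0.6) per OAR,
  constant across the patient's sessions — the stand-in for physician intent;
* a dose: the prescription inside the PTV; outside, the nearest PTV's level
  decaying as `exp(-d_PTV / lambda)` with `lambda` = 30 mm, multiplied by
  `1 - sigma_o * exp(-d_o / lambda)` per spared OAR (attenuation applies
  outside the PTV only, preserving target coverage as clinical plans do),
  plus smooth zero-mean noise (0.2 Gy) clipped at zero;
* a between-session deformation: the PTV shrinks in place (volume factor
  0.9–1.0), OARs shift (Gaussian, sigma 2 mm), glands additionally lose
  volume (0.85–1.0). Masks are re-rasterized from the deformed analytic
  shapes, so ground truth stays exact rather than interpolated.

The adaptive ground-truth dose uses the *same* sparing profile on the new
anatomy. The generator's scales were fixed by a model-free design rule: the
MSE floor of "copy the pre-treatment dose" must lie below the floor of the
best sparing-blind anatomy-only predictor (both computable analytically from
the generator). At the defaults the floors are ~6e-5 and ~1.1e-4 on
normalized dose, i.e. the pre-treatment plan genuinely carries information
about the adaptive dose beyond anatomy — the property the dual-head
architecture is designed to exploit, and a precondition for any comparison
between the two models to be meaningful.

What the phantom does **not** model: realistic CT texture and bone anatomy,
beam geometry and penumbra shapes, deformable (non-affine) anatomical
change, contour uncertainty, or inter-planner variability. Passing the
mechanism tests therefore shows that the implementation can detect and
exploit pre-plan conditioning when it is present, not that it reproduces
clinical error magnitudes.

## Scaled-down study sizes

Tests and the bundled analyses run on one CPU, so the mechanism-recovery
experiment uses a reduced configuration chosen as this package's desk-scale
standard: 24 training + 4 validation patients on a 48x48x32 grid (5 mm),
networks at base width 8 with 3 levels, 32^3 patches, 288 training steps
(12 passes over 24 plans), learning rate 1e-3, validation every second
epoch, three seed replicates, and matched adaptive-sample exposure for the
two models (self-conditioning samples excluded). The learning rate is
higher than the full-scale default because at width 8 and ~300 steps both
models would otherwise remain far from convergence; the comparison is made
at the best-validation checkpoint per run and summarized by the median over
replicates.

## Known limitations

* At the desk-scale training length (~300 steps at width 8) both models are
  still optimization-limited, far from the task's information floors. The
  model-comparison test finds the dual-head model ahead on the median across
  seed replicates, driven by markedly more stable best-checkpoint selection;
  per-replicate margins are modest at this scale. Full exploitation of the
  conditioning pathway — whose secondary features reach the decoder only
  through pooled fusion, a long credit-assignment chain — requires training
  budgets closer to the full-scale protocol, which runs roughly three orders
  of magnitude more steps. The data-side preconditions (the pre-plan
  carrying recoverable, anatomy-independent sparing intent) are established
  independently by the phantom property tests and the generator's floor
  diagnostic.
* The autodiff engine is CPU-only and single-volume; the full-scale
  3000-epoch configuration is supported but slow (it exists for fidelity,
  not for routine use here).
* Group normalization ties predictions to the inference window (see above).
* The Wilcoxon exact null is used up to n = 25; beyond that the normal
  approximation with tie correction applies.
* The phantom's analytic dose model makes spared-OAR gradients smooth and
  axis-free; real dose falloff is beam-direction dependent.
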