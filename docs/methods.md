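# Methods

## The model

`cardio4d` learns a conditional generative model of 4D cardiac anatomy.
An anatomy sequence is a label map x_t over t = 0 … T−1 (labels:
0 background, 1 LV blood pool, 2 myocardium, 3 RV blood pool) on a fixed
voxel grid; the clinical conditions c are age group, sex, weight, height
and systolic blood pressure. The model factorises as a conditional β-VAE
over the end-diastolic frame plus a recurrent latent dynamics module for
the rest of the cycle:

* **Condition embedding.** c is encoded as a 12-vector — one-hot over 7
  decade age groups ([10, 80) years), one-hot over sex, and min–max
  scaled weight/height/SBP (scaling constants are the cohort sampling
  ranges: 33–131 kg, 142–195 cm, 79–183 mmHg). An MLP (two hidden layers
  of width 64) maps it to the condition latent z_c ∈ R^32. Out-of-range
  continuous values are clamped with a logged warning rather than
  rejected, so inference on unseen demographics degrades gracefully.
* **Encoder.** q_φ(z_0 | x_0, z_c): four stride-2, kernel-4 3D
  convolutions (ReLU) over the one-hot ED frame; the flattened feature
  map is concatenated with z_c at the bottleneck and two linear heads
  emit the posterior mean and log-variance of z_0 ∈ R^32. z_c enters at
  the bottleneck (not as extra input channels); this keeps the condition
  pathway low-dimensional and is the variant that lets the same z_c
  vector drive encoder, temporal module and decoder.
* **Temporal module.** A single LSTM cell with shared weights, hidden
  and cell state initialised to zero, consumes the joint latent
  z^c_0 = [z_0, z_c] ∈ R^64 and rolls out one-to-many:
  z^c_t = LSTM(z^c_{t−1}). Element 0 of the rollout is the raw
  concatenation itself; because the cell is shared, the trainable
  parameter count is independent of T and a length-T rollout is a prefix
  of any longer one.
* **Decoder.** p_θ(x_t | z^c_t): a linear map to the coarsest grid
  (grid/16 per axis), then four stride-2, kernel-4 transposed
  convolutions producing 4-class logits; per-voxel probabilities by
  softmax, label maps by argmax.
* **Loss.** L = Σ_t CE(x_t, x̂_t) + β·KL[q(z_0|x_0,z_c) ‖ N(0, I)], with
  CE the voxel-mean cross-entropy per frame, summed over frames, and the
  KL term appearing once per sequence (only the t = 0 posterior is
  variational). β defaults to 0.001: the KL term is a gentle regulariser,
  not a disentanglement pressure. Training is end-to-end with Adam
  (lr 5·10⁻⁴, batch 8 whole sequences), up to 500 epochs at full scale
  with early stopping on the validation loss.

**Inference tasks.** *Completion*: given x_0 and c, z_0 is taken as the
posterior mean (deterministic; a sampling mode exists behind a flag),
concatenated with z_c, rolled out and decoded — frame 0 of the output is
the model's reconstruction of x_0, not a pass-through. *Generation*:
z_0 ~ N(0, I), otherwise identical. *Condition sweep*: z_0 is held fixed
while one factor varies, so output differences isolate that factor.

### Numerical backend

The network runs on a small reverse-mode autodiff engine written on
numpy (float32 throughout), with the strided 3D convolution and its
transpose evaluated as one slice-matmul per kernel offset accumulated on
the zero-padded grid. Every layer's gradient is validated against
central finite differences in the test suite, and the transposed
convolution is additionally checked to be the exact adjoint of the
convolution. All parameter initialisation and data order flow from
explicit integer seeds; two runs with the same seed on the same platform
are float-identical.

One optimisation detail matters for CPU-scale runs: the final decoder
bias is initialised to the log class frequencies of the training set, so
the untrained decoder starts at the label marginal instead of uniform.
This removes an early plateau in which the optimiser merely rediscovers
the ~90/10 background/foreground balance and roughly halves the epochs
needed to reach a given Dice.

## The phantom cohort

Real cine-CMR segmentation cohorts are not redistributable, so the
package ships a synthetic stand-in with exact ground truth:

* LV blood pool: an ellipsoid with semi-axes (a, b, c), baseline
  (25, 25, 30) mm.
* Myocardium: a shell of constant thickness w (baseline 9 mm) around it.
* RV blood pool: the region between the myocardial outer surface and a
  concentric copy enlarged by rv_scale = 1.25, clipped to the x ≥ centre
  half-space — a half-shell hugging the septum. The concentric
  construction is deliberate: its volume has the closed form
  ½·(rv_scale³ − 1)·V_outer, so every phenotype (LVM via a 1.05 g/mL
  myocardial density; LVEDV/LVESV/RVEDV/RVESV as ellipsoid volumes) is
  analytic and serves as an oracle for the voxel-counting extractor. An
  offset-ellipsoid crescent would look marginally more anatomical but
  has no closed-form volume.

**Conditions → geometry.** Sampling is uniform over the cohort ranges
(ages 18–73 y, weight 33–131 kg, height 142–195 cm, SBP 79–183 mmHg),
with sex female with probability 775/1383; continuous age is binned into
the 7 decade groups for conditioning. Effect sizes (per unit, applied
multiplicatively to the baseline):

| effect | default | direction |
|---|---|---|
| age → wall thickness | +5 % per age group | mass rises with age |
| age → LV semi-axes | −2 % per age group | LVEDV falls with age |
| sex (male) → semi-axes | +8 % | male hearts larger |
| body size → all lengths | (BSA/1.75)^(1/3) | isometric BSA scaling (Du Bois) |
| per-subject jitter | σ = 4 % on lengths | unexplained variation |

The age slopes are free parameters of the phantom, chosen to give
unambiguous, physiologically plausible trends at cohort scale (≈ +4 g
LVM and −6 mL LVEDV per decade group); they are not estimates of any
real cohort. Extreme body sizes are shrunk isotropically so the whole
heart stays inside the fixed 160 × 160 × 128 mm field of view (the
analogue of template cropping in real pipelines); voxel spacing is
FOV/grid, giving 1.25 × 1.25 × 2 mm at the full 128 × 128 × 64 grid.

**Motion.** A volumetric scale s(t) follows a raised-cosine systole and
diastole: s = 1 at t = 0 (end-diastole by convention), minimum
1 − ejection_amplitude at phase es_phase = 0.45 of the cycle (frame 9 of
20), returning towards 1 at the cycle end. The cube root of s scales the
cavity semi-axes isotropically; wall thickness is preserved (the wall
thickens in absolute terms at systole, as real myocardium approximately
conserves volume). Ejection amplitude defaults to 0.5 ± jitter, clipped
to [0.3, 0.7] — an ejection fraction range spanning normal hearts; the
value is a package default, configurable per cohort.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: papillary muscles, trabeculation, an RV free
wall and outflow tract, through-plane motion, orientation variability,
segmentation errors, pathology, and longitudinal within-subject ageing
(the age effect is purely cross-sectional). The phantom's anatomy
manifold is far smoother than real hearts', so absolute Dice/HD values
on it are optimistic relative to clinical data.

## Evaluation suite

* **Overlap/surface**: Dice per structure (defined 1.0 when both masks
  are empty); Hausdorff distance as the full maximum (not HD95) and
  average symmetric surface distance, both on surface voxels
  (6-connectivity, voxel centres in mm) with exact KD-tree nearest
  neighbours. Frames where a structure is empty in either mask are
  excluded from surface-distance averages with a logged count.
* **Phenotypes**: per-frame volumes by voxel counting; EDV/ESV as the
  per-chamber max/min over frames (robust to phase shifts in generated
  sequences; ties resolve to the earliest frame); LVM as myocardial
  volume at the LV EDV frame × 1.05 g/mL.
* **Distribution fidelity**: per phenotype, a joint (age, value)
  histogram KL divergence (7 age bins × 20 value bins on the shared
  union range, additive smoothing 10⁻¹⁰, renormalised) and the 1-D
  empirical Wasserstein-1 distance on pooled values (computed via
  scipy's CDF formulation; the test suite cross-checks it against a
  brute-force optimal-transport linear program).
* **Protocols**: completion is scored against ground truth over frames
  1 … T−1 (frame 0 is reconstruction, not completion); generation draws
  20 latent samples per condition set and reports the mean and the best
  value of each metric, plus mean/minimum absolute phenotype
  differences.

## Desk-scale benchmark

The full-scale configuration (128 × 128 × 64, T = 20, 500 epochs) is a
GPU-class workload; the package's reference experiment is a reduced
profile chosen to keep a complete train-and-evaluate cycle within
minutes on one CPU core: 32 × 32 × 16 grid (5 × 5 × 8 mm voxels),
T = 10, encoder channels (8, 16, 32, 64), 60 training / 6 validation /
10 held-out subjects, at most 60 epochs with early-stopping patience 10.
The generation task uses 5 held-out condition sets × 20 samples; the
ageing analysis uses 200 seeded sweeps comparing the youngest and oldest
age groups under fixed anatomy latents. A generated cycle counts as
"contracting" when its minimum LV volume falls below 0.9 × the frame-0
volume — the 10 % margin makes the check meaningful (any noisy sequence
has min < max, but only a genuinely contracting one loses a tenth of its
cavity).

## Design choices where the design was open

* Channels-last activation layout and slice-matmul convolutions: chosen
  purely for numpy efficiency; validated against finite differences.
* Early stopping monitors the validation sequence loss (the training
  objective) rather than validation Dice; the loss is smoother at small
  validation sizes.
* The condition MLP's internals (2 × 64 hidden), encoder channel widths
  ((16, 32, 64, 128) full scale, halved at test scale) and the decoder's
  latent-to-grid linear layer are package defaults, configurable in
  `ModelConfig`.
* Cross-entropy is unweighted across classes; the voxel-mean per frame,
  frame-sum per sequence convention fixes the scale of β.
* Checkpoints store parameters plus the full configuration; configs
  round-trip through YAML with strict unknown-key rejection.

### Condition-manipulation at desk scale: a known failure mode

The age-sweep analysis exposes a real limitation of the method at the
benchmark's scale, reproduced and dissected during development. The
phantom cohort builds in "older = thicker wall, smaller cavity, roughly
constant outer size", and the 60-subject training split carries that
signal cleanly (partial LV volume slope ≈ −5 mL per age group given
weight, height and sex, at every cohort seed tested). The trained
model's sweeps nevertheless recover only the myocardial-mass sign
reliably; the generated LV cavity volume responds to age near the noise
floor, and on some cohort seeds with the wrong sign.

The cause is resolution- and data-limited identifiability, not a
defect of the evaluation chain: at 5 × 5 × 8 mm voxels one age group
shifts the cavity boundary by well under half a voxel, and the
cross-entropy objective can realise "older subjects have more
myocardium" more cheaply by growing the wall *outward* into diffuse
background probability than by moving it *inward* against confidently
labelled cavity voxels — so the learned age direction tends toward
"slightly larger overall" instead of "thicker wall at fixed outer
size". Interventions that do not change this outcome (each tested
directly): raising the KL weight 10–50×, shrinking the latent to 8 or
4 dimensions, replacing the condition MLP with a linear embedding, and
training to 200 epochs. At the full-scale configuration the per-group
boundary shifts span several voxels and the cohort is an order of
magnitude larger, which is the regime the method is designed for; the
desk-scale benchmark therefore reports the sweep statistics as
measured, and the matching acceptance check on the cavity-volume trend
is expected to fail at this scale.

## Known limitations

* The numpy backend is single-core; the full-scale configuration is
  supported but impractical without days of CPU time.
* The phantom's analytic oracle covers volumes and mass, not surface
  distances; HD/ASSD are validated on hand-constructed geometry only.
* KL/WD estimates at benchmark scale (10 real subjects) are high-variance;
  they are reported as measured quantities, not calibrated statistics.
* Batch semantics are whole sequences per batch item; frame-level
  batching is not supported.
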