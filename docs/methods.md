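# Methods

`neurodg` implements a disease-informed domain-generalization framework for
3D volumetric classification, together with the synthetic study conditions
used to validate it. This note records the model, the procedures, the
defaults and the reasoning behind the genuinely open design choices.

## The classification model

The classifier maps a skull-stripped, intensity-scaled volume
`x ∈ [0,1]^{D×H×W}` to probabilities over K = 3 diagnostic classes
(NC = normal cognition, MCI = mild cognitive impairment, AD = dementia due
to Alzheimer's disease):

1. **Encoder.** A stack of `(conv 3×3×3 → ReLU → average-pool /2)` stages
   produces features `F ∈ R^{C×d×h×w}` at `1/downsample_factor` of the input
   resolution (`downsample_factor = 2^{n_stages}`). Inputs are centered at
   0.5 before the first convolution so first-layer activations are
   zero-mean; with all-positive raw intensities the early gradient
   directions are strongly correlated and optimization stalls. The encoder
   is deliberately small and weight-free (no pretrained checkpoints): the
   framework's claims concern the attention/prior mechanism, not encoder
   capacity.
2. **Class-wise attention.** Two parallel 3×3×3 convolutions read the
   features: one yields K per-class feature channels `F'`, the other —
   squashed through a sigmoid — yields the K attention gates
   `M ∈ [0,1]^{K×d×h×w}`. The module output is the elementwise product
   `F' ⊙ M`. The sigmoid parameterization is the simplest gate consistent
   with elementwise multiplication; normalizing M across the class axis
   (e.g. a softmax over K) is a plausible alternative that was not adopted,
   because it would force the gates of different classes to compete even
   where several classes legitimately attend to the same tissue.
3. **Classifier.** Global average pooling over the spatial axes turns each
   class channel into one logit; a softmax yields probabilities. Pooling
   spatially (instead of flattening) is what keeps channel k interpretable
   as "evidence for class k at each location".

Attention lives at feature resolution `d×h×w`; saliency priors computed at
input resolution are resampled (trilinear, align-corners) onto that grid for
the similarity loss. The alternative — decoding M back to input resolution —
was rejected as it adds a decoder the method does not otherwise need.

All parameters are float64 and derive from a single seed; forward passes,
training and attribution are bitwise deterministic given the seed. Gradients
come from a small in-package reverse-mode engine (`neurodg.autodiff`)
validated against finite differences.

## Two-stage training

**Stage 1** fits a baseline on weighted cross-entropy

    L_WCE = −(1/N) Σ_i w_{y_i} log ŷ_{i,y_i},   w_k = 1 / count_k,

where inverse-count weights counter the NC > MCI > AD imbalance of dementia
cohorts. (The underlying objective is a plain sum over the minibatch; we
mean-reduce so that the similarity weight λ keeps its meaning across batch
sizes — a deliberate, documented normalization.)

**Priors.** The baseline is explained per class with *expected gradients*, a
Monte-Carlo Shapley-style attribution for differentiable models: each draw
pairs a background volume `b` (a seeded subset of training NC volumes — the
reference condition) with `α ~ U(0,1)` and accumulates
`(x − b) ⊙ ∇f_k(b + α(x − b))`, where `f_k` is the pre-softmax logit (the
softmax saturates and starves gradients). Averaging attribution grids over
the baseline's *correct* predictions of class k (argmax equals label, ties
toward the lower index) gives the class prior `SHAP_k`; a class with no
correct predictions yields an explicit absent-prior marker rather than a
zero grid. For testing, `exact_shapley` enumerates all 2^G coalitions of
≤ 16 feature groups and is exact; the expected-gradients estimator
converges to the path-integral (Aumann–Shapley) attribution, which equals
discrete Shapley for additive scorers and tracks it closely at low
curvature — both satisfy efficiency/completeness, the axiom the alignment
procedure relies on.

**Stage 2** trains a *fresh* model on

    L = L_WCE + λ · L_sim,
    L_sim = (1/N) Σ_i Σ_k ‖M_{i,k} − SHAP_k‖₂,

with the L2 norm over flattened voxels per (sample, class) map. Every class
channel is aligned to its own class prior for every sample
(`sim_scope="all_classes"`); aligning only the channel of the true label is
available as `sim_scope="true_class_only"`. A `normalize_by_voxels` switch
divides the squared distance by the voxel count for resolution-independent
magnitudes. Gradient accumulation (micro-batch 2 × 8 steps = effective
batch 16 by default) reproduces the single-large-batch update to float
rounding; λ = 0 reduces stage 2 exactly (bitwise) to stage-1 training.

**Prior scale in the loss.** Raw expected-gradients priors have voxel
magnitudes of order 1e-3 — incommensurate with the sigmoid gate's [0,1]
range. The loss consumes raw priors by default; a `prior_scale="unit"`
switch aligns against the [-1,1]-scaled prior instead (scaling divides by
the maximum absolute value, preserving sign and rank order — the same
transform used for visualization). At desk scale the unit-scaled target is
the meaningful one: any λ strong enough to move the loss against raw priors
collapses the gate, because the attention head's shared convolution bias is
the cheapest direction toward an almost-everywhere-zero target, and the
sigmoid then saturates irrecoverably. With unit priors the planted disease
regions carry targets near 0.5 and background near 0, so gentle pressure
reshapes attention instead of deleting it.

**Choosing λ.** λ is the framework's tunable trade-off and is selected by
hyper-parameter search on validation behavior, as the method prescribes. At
full MRI resolution (182×218×182, unnormalized L2) the reference value is
λ = 5×10⁻⁵, which is also the package default. The desk-scale sweep (one
validation fold, decades from 1e-5 to 3e-3) reproduced the same qualitative
regimes: λ ≤ 1e-5 leaves attention unchanged, λ ≥ 3e-4 collapses the gate
and degrades accuracy, and λ = 5e-5 sits in the gentle-regularizer window
where the similarity loss falls on held-out data and AD-channel attention
mass concentrates on planted disease voxels without hurting classification.
The alignment study conditions therefore also use λ = 5e-5.

**Optimizer.** Adam with a fixed step size (default 3e-3 at desk scale) —
the optimizer and schedule are otherwise unconstrained by the method, so a
single explicit, seeded choice is used. The best checkpoint is the highest
validation macro F1. Divergence (non-finite loss) aborts with diagnostics.

**Augmentation and Mixup.** The augmentation set is random gamma contrast,
a random smooth multiplicative bias field (±15%), random spatial cropping
(80% extent) followed by trilinear upsampling back to the input shape, and
a final intensity scaling to [0,1] (a no-op for in-range volumes, so the
all-flags-off transform is the identity). Mixup — convex combinations of
example pairs and their one-hot labels with `λ_m ~ Beta(α, α)`, α = 0.2 —
is provided as the standard data-level domain-generalization comparator.

## Evaluation

The confusion matrix is fixed as rows = true, columns = predicted. Macro F1
averages per-class F1 (the printed form of the defining equation omits the
1/K factor that the accompanying text requires; the text's average is
implemented, since a bare sum would exceed 1). Precision divides the
diagonal by predicted counts and recall by true counts — the convention of
the reference library whose multiclass MCC formula is also implemented:

    MCC = (c·s − Σ p_k t_k) / sqrt((s² − Σ p_k²)(s² − Σ t_k²)),

defined as 0 when a factor under the root vanishes, and symmetric under
transposing the matrix. Both metrics are tested to 1e-12 against
independently coded loops and against scikit-learn.

Cross-validation is stratified k-fold (k = 5) with a rolling validation
fold: fold f tests on stratum f, validates on stratum f+1 (mod k) and
trains on the rest — a 3:1:1 split whose per-class proportions match the
cohort within one sample.

## Region scores and pathology correlation

The AD-channel attention map is resampled to the parcellation grid
(trilinear, align-corners), summed per region and divided by the region's
voxel count ("aggregated, normalized by regional volume" — aggregation must
be a sum for volume normalization to make sense). Background (label 0) is
excluded throughout. Region scores are correlated across subjects with
per-region ordinal severity grades (0 none – 3 severe) for three stains —
amyloid-beta deposits, neurofibrillary tangles (NFT), neuritic plaques
(NP) — using Spearman's rank correlation with average ranks for ties and a
two-sided t-approximation p-value on n−2 degrees of freedom. p-values are
deliberately not adjusted for multiple comparisons; cells with fewer than 3
shared subjects or degenerate variance are reported as explicitly missing,
never silently dropped. An exact permutation p-value (n ≤ 10) is available
as a small-sample cross-check, and a permuted-grade null utility verifies
that the t-approximation rejects at ≈ the nominal level for autopsy-sized
samples (n = 23).

## The synthetic cohort generator

The generator emulates the *structure* of a processed structural-MRI
dementia study, not its biology:

- **Parcellation**: contiguous axis-aligned blocks tiling the interior of
  the grid (jittered-even cut points, so region volumes are comparable, as
  in real atlases), inside a one-voxel background shell mirroring a
  skull-stripped mask.
- **Subjects**: per-subject smooth base fields (Gaussian-filtered noise
  rescaled to [0.4, 0.9] inside the brain mask), so inter-subject anatomy
  varies everywhere while class signal lives only in designated regions.
- **Disease signal**: per-region ordinal grades g ∈ {0..3} drawn from
  class-ordered categoricals (NC concentrated at 0; AD at 2–3; MCI
  intermediate, with its mass at 0 doubling as partial region coverage);
  intensities inside disease region r are attenuated by `effect_size · g_r`
  *before* noise and clipping, keeping the grade→signal map exactly linear
  (the [0.4, 0.9] base range leaves clipping disengaged whenever
  `3 · effect_size ≤ 0.4`).
- **Stains**: amyloid-beta grades are the planted severities; NFT and NP
  add a ±1 ordinal jitter (15%/70%/15%), giving three noisy reads of one
  latent pathology.

What the generator does **not** emulate: scanner physics, site effects,
registration error, anatomy-correlated atrophy patterns, or any
quantitative atrophy magnitude — the effect sizes are conventions chosen to
give a learnable desk-scale problem, not estimates of real disease effect.
Passing tests on this cohort demonstrate that the machinery recovers
planted signal under its own generative assumptions; they say nothing about
performance on real MRI.

## Study conditions (presets)

Fixed in `neurodg.presets` and used by the validation suite and
`scripts/acceptance.py`:

- **Prior recovery**: 60 subjects/class, 32³ volumes, 27 regions of which 3
  are diseased (~10% of voxels), effect 0.12/grade, noise sd 0.02; stage-1
  for 8 epochs. Checks that the AD prior's top-decile |attribution| voxels
  overlap planted disease voxels at ≥ 3× chance (observed ≈ 10×).
- **Alignment benefit**: 30 subjects/class, 24³ volumes, 8 regions (2
  diseased), effect 0.15, noise 0.02; both stages 12 epochs, λ = 5e-5
  against unit-scaled priors, compared over ≥ 3 seeds on one stratified
  fold. Checks that stage-2 validation similarity loss falls below the
  stage-1 post-hoc value and that the AD channel's attention mass fraction
  inside disease voxels increases on average.
- **Autopsy cohort**: 23 subjects (8 NC / 8 MCI / 7 AD) spanning the grade
  range, matching the size of a real multi-stain neuropathology validation
  set. The correlation procedure is exercised with the generative
  attenuation field as the saliency surrogate, which ties region scores to
  grades by construction and isolates the statistics under test.

Problem sizes throughout (volume side lengths 16–32, 2-stage encoders with
≤ 16 channels, ≤ 180 subjects) are the package's desk-scale operating
point: large enough for the phenomena to appear, small enough that the full
validation suite runs on one CPU in minutes.

## Numerical conventions and edge cases

- Trilinear resampling uses the align-corners convention (target index i
  maps to source `i·(S−1)/(T−1)`), so constants stay constant and linear
  ramps stay linear — properties the tests pin down.
- `sqrt` in the similarity loss uses subgradient 0 at 0, so a perfectly
  aligned channel contributes zero gradient rather than NaN.
- Predicted probabilities are clamped at 1e-12 inside the cross-entropy.
- Unit scaling of an all-zero prior grid returns it unchanged with a
  warning flag.
- Degenerate metric cases: per-class F1 is 0 when precision+recall is 0;
  MCC is 0 when a root factor vanishes; Spearman on constant input returns
  an explicit undefined marker with the reason.

## Known limitations

- The encoder is intentionally small; nothing here speaks to pretrained or
  transformer feature extractors.
- Expected gradients inherits the baseline-set dependence of all reference-
  based attributions; priors are only as good as the stage-1 model.
- The similarity loss can collapse the attention gate when its weight is
  large relative to the prior scale (see above); the packaged λ sits in the
  safe regime for the packaged resolutions, but new resolutions warrant a
  fresh sweep.
- Real-data affines are passed through untouched; no registration or atlas
  warping is performed.
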