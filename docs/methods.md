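# Methods

## Problem and model

`fmriatt` decodes the cognitive state expressed in a 4D fMRI recording — a
time series of 3D brain volumes — and exposes *where* the decoder attends
while doing so.  The architecture is:

1. **Decomposed 4D convolution front end.**  A 4D kernel
   `K ∈ R^{kl×kh×kw×kd×c_in×c_out}` applied to an input
   `x ∈ R^{l×h×w×d×c}` is realized as a loop of native 3D convolutions over
   temporal taps: output frame `j` is `Σ_{i<kl} Conv3D(K_i, x_{j·st+i})`,
   with `l_out = ⌊(l−kl)/st⌋ + 1`.  The inner 3D convolution uses spatial
   stride 2 and "same" padding (odd kernels).  Convolution means
   cross-correlation (no kernel flip), the deep-learning convention.  The
   double temporal sum admits two readings (accumulate both indices, or
   enumerate output frames with one and accumulate taps with the other);
   only the enumerate-then-accumulate reading is consistent with a
   subsequent temporal squeeze-and-flatten producing multiple frames, so
   that is what is implemented, with `⌊(l−kl)/st⌋+1` as the standard strided
   frame count.  After the front end the temporal axis is flattened into
   channels (time-major: channel block `t` holds frame `t`'s channels), so
   everything downstream is 3D.

2. **Four 3D mixed residual-attention stages.**  Each stage splits into a
   main branch `M(x)` (one pre-activation ResNet block:
   BN–ReLU–Conv3–BN–ReLU–Conv3 plus an identity or strided 1×1×1 projection
   shortcut) and a U-shaped attention branch: `depth_steps` stacks of
   (2×2×2 max-pool + ResBlock) down, mirrored (trilinear upsample +
   ResBlock) up, a 1×1×1 convolution to `M`'s channel width, and a sigmoid,
   giving a mask `A(x) ∈ (0,1)`.  Attention residual learning combines the
   branches as `out = M(x)·(1 + A(x))`: the `A→0` limit is the identity on
   `M`, output magnitude is bounded by `[|M|, 2|M|]`, and the sign of `M`
   is never flipped — the mask re-weights features without destroying them.
   When the main branch strides, the attention branch reaches `M`'s grid by
   leaving its first down-step uncompensated (one fewer up-step), keeping
   the branch depths symmetric.  The per-stage mask is returned alongside
   the output for visualization.

3. **Head.**  Global average pooling (chosen for input-size robustness)
   feeds a fully-connected layer: one score per class (classification) or
   a single real (trait regression).

Variants: `conv4d_plain` keeps the identical channel plan but uses only
each stage's main branch (so the attention variant is a strict superset in
parameters), and `conv3d_attention` degenerates the front end to `kl=1,
st=1` — mathematically a shared per-frame 3D convolution whose frame
outputs are flattened to channels, the classic frames-as-channels 3D
baseline.

### Stage geometry

Stage strides default to (1, 2, 1, 1) after the stride-2 front end.  On the
16³ benchmark grid this yields feature grids 8³ → 8³ → 4³ → 4³ → 4³.  A
strict halve-every-stage plan would collapse the final stage of a 16³ input
to 1³, which destroys the spatial content of exactly the masks the final
stage is supposed to explain; keeping the last stages at 4³ preserves a
meaningful final-stage mask while still downsampling aggressively early.
U-branch depths default to (2, 2, 1, 1) and are clamped so no pooled grid
drops below one voxel.  All of this is per-stage configurable.

## Compute core

The layer stack (Conv3d, Conv4d, BatchNorm, ReLU, sigmoid, 2×2×2 max-pool,
trilinear resize, linear, pooling) is implemented directly on numpy arrays
(channels-last) with explicit hand-derived backward passes, plus Adam and a
reduce-on-plateau schedule.  Correctness is enforced empirically rather
than by construction: central finite-difference gradient checks cover every
layer family and the full attention module (relative error < 1e-6 for
layers in float64; the module-level acceptance bound is 1e-3), and the 4D
convolution is checked elementwise against a brute-force oracle that loops
over every output position without any convolution primitive.  Trilinear
resizing uses half-pixel-centre sampling (align-corners-false convention)
in both the attention U and mask upsampling, so mask affines and resampled
values agree.  The learning rate after `r` plateau reductions is recomputed
as `lr0/factor^r` (not repeated division), making the schedule exactly
reproducible.

## Training and inference protocol

Subject-level fivefold cross-validation: subjects are shuffled once and cut
into five disjoint test blocks (each subject is tested in exactly one
fold); within a fold the remainder splits 70/10 train/validation (exact
counts when `n` is divisible by 10).  No subject's instances ever straddle
partitions.  Optimization uses Adam (β₁=0.9, β₂=0.999), batch 16, initial
learning rate 1e-4, decayed ×1/5 when the validation loss fails to improve
by a relative 1e-4 for 15 consecutive epochs ("plateau after 15 epochs" is
read as patience 15); the best-validation snapshot is restored at the end.
Each epoch draws a fresh random contiguous `k`-frame segment per instance
(temporal augmentation); validation uses the deterministic center window.
Segments are standardized to zero mean / unit variance before entering the
network — the percent-signal-change-style normalization that removes the
arbitrary BOLD baseline scale.

Instance-level inference enumerates **all** stride-1 `k`-windows, sums
their class-probability vectors, and takes the argmax (soft majority vote).
"Sum the predictions, take the majority" is ambiguous between soft and hard
voting; soft voting is the default and hard per-window voting is available
behind a flag.  Exact ties resolve to the lowest class index.  Divergence
(non-finite loss) raises with the epoch and learning rate.

## Transfer learning

`swap_head` builds a new model whose backbone is bit-identical to the
source checkpoint and whose fully-connected head is freshly initialized;
freeze policies (`none`, `freeze_conv4d`, `freeze_through_stage_s`) and a
backbone learning-rate multiplier `lr_scale ∈ (0,1]` control adaptation.
The default policy is full fine-tuning (the backbone is *adapted*, not
frozen).  For trait regression the loss switches to MSE; targets are
z-scored on the training partition only and predictions are mapped back to
the original scale.  Subject partitions are inherited from the source plan
(`consistent_partition`), and a leakage guard rejects any plan that places
a source-training subject in a transfer test or validation partition.
Inter-dataset transfer uses leave-one-subject-out cross-validation with one
fine-tuning run per held-out subject.  Spearman correlation (average ranks
for ties, large-sample p-value) is evaluated at the subject level
(instance predictions averaged per subject) on test-partition subjects.

## Synthetic data generator

The generator emulates the statistical structure the decoder assumes:

- **Design.**  Block mode: one boxcar of `block_frames` frames from frame 0
  (a scaled-down task block; real blocks run tens of frames).  Event mode:
  a single-frame stimulus after a 2-frame lead-in, optionally jittered —
  the event-related analogue of a picture-viewing trial windowed with
  padding frames.
- **Hemodynamics.**  The boxcar is convolved with the canonical
  double-gamma HRF (response delay 6 s, undershoot delay 16 s, dispersions
  1, undershoot ratio 1/6, unit peak), truncated to the series length.
- **Space.**  The brain is a centered ellipsoid (semi-axes 0.45 of each
  extent); class ROIs are small ellipsoids placed deterministically on a
  ring in the central axial plane, validated non-empty, inside the brain,
  and pairwise disjoint.  Voxels outside the brain are exactly zero.
- **Amplitude.**  `series = 100 + (amplitude + trait_slope·trait)·regressor`
  on the class ROI, plus i.i.d. Gaussian noise everywhere inside the brain.
  Traits are one standard-normal draw per subject, shared by all of a
  subject's instances.

Defaults (the package's standard study conditions): 16³ grid, 12 frames at
TR 1 s, 3 classes, 12 subjects, 2 instances per subject and class,
amplitude 2, noise SD 2, trait slope 0.5, 8-frame blocks — a moderate-SNR
regime where decoding is learnable but not trivial.  What the generator
deliberately omits: physiological drift, motion, spatial and temporal noise
autocorrelation, subject-specific anatomy, and within-block condition
mixtures.  Results on it therefore demonstrate that the mechanisms work —
not that field-scale accuracy would be reached on real data.

## Benchmarks and their scale

The decoding benchmark trains the attention and plain variants on one
subject-level fold of the default dataset (segment length 8) and scores
majority-vote accuracy on held-out subjects.  The regression-transfer
benchmark re-heads the pretrained classifier and fine-tunes it on a
*trans-set*: same subjects, traits, and geometry, but trait slope 2, noise
SD 1, and 4 instances per subject and class.  The stronger trait effect is
deliberate: under the source conditions the trait signal is weak enough
that even a ridge probe on oracle features cannot fit the training
subjects, so the transfer mechanism would be untestable; the trans-set is
defined so the quantity the workflow is supposed to recover is actually
present at recoverable strength.  Fine-tuning uses lr0 1e-3 with backbone
`lr_scale` 0.1 (the fresh head needs larger steps than the adapted
backbone) for 20 epochs, against a from-scratch control at identical
epochs.  Benchmark replicates derive *every* random element (dataset,
splits, weights, batching) from the replicate seed.  Epoch counts
(40 decoding / 20 transfer) are scaled down from the 60-epoch reference
protocol to desk scale; they sit well past the point where the validation
loss of these synthetic problems bottoms out.

## Interpretability statistic

Masks are collected per stage and condition by averaging over every
stride-1 window of every instance of that condition (flat averaging; the
bundle records sample counts), plus an unweighted across-condition
average.  Contrasts are condition minus average, so they sum to zero
across conditions by construction.  The headline statistic upsamples the
final-stage channel-mean contrast of class `c` to the input grid and
computes

    S(c) = mean(contrast inside ROI_c) − mean(contrast inside other ROIs).

`S(c) > 0` for every class means each class's attention contrast
concentrates on that class's true activation site — the testable,
synthetic-ground-truth form of "high-level masks cover task-specific
areas".  For display, channels are ranked by the variance of their
condition contrast (an objective stand-in for hand-picking channels), and
figures use a diverging colormap centered at 0.5 for raw masks and 0 for
contrasts.

## Known limitations

- The compute core is CPU/numpy; it is sized for desk-scale experiments,
  not for field-scale volumes at [80, 96, 88].
- Gaussian white noise flatters any decoder; real fMRI noise structure
  (drift, motion, autocorrelation) is out of scope of the generator.
- The interpretability statistic is a point estimate without a
  significance test; the statistical reliability of attention masks is an
  open question and deliberately not claimed.
- Mask resampling assumes the anatomical target shares the input's world
  space; no registration is performed.
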