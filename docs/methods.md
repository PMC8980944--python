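# Methods

## Problem and model

Chronic stroke lesions appear hypointense on T1-weighted MRI, vary in
volume over four orders of magnitude, and occupy a vanishing fraction of
the voxels in a typical scan: most axial slices contain no lesion at
all.  `strokeseg` segments such lesions slice by slice with a 2D
encoder-decoder network and restacks the slice predictions into a 3D
volume for per-patient evaluation.

The network is a U-Net variant with three modifications:

1. **Cross-spatial attention (CSAM) on every skip path.**  For an
   encoder feature `Fe` and the spatially aligned decoder feature `Fd`
   (both `C x H x W`), each side produces a spatial attention map from
   channel-wise average and max pooling, a 3x3 convolution and a
   sigmoid:

       M(F) = sigmoid(conv3x3([avgpool_c(F); maxpool_c(F)]))

   The maps *cross* over: the encoder's map gates the decoder feature
   and vice versa, each with a residual addition, and the two branches
   are concatenated:

       Ss(Fe, Fd) = [ M(Fe) * Fd + Fd ; M(Fd) * Fe + Fe ]    (2C x H x W)

   Each CSAM instance owns two independent 3x3 attention convolutions,
   one per branch; encoder and decoder feature statistics differ, so
   weight sharing would couple two different estimation problems.

2. **Channel attention (CAM) applied serially after CSAM.**  Global
   average and max pooling of the mixed feature give two length-2C
   descriptors; a shared two-layer perceptron (bottleneck `2C/r`,
   reduction `r = 16` by the usual CBAM convention, hidden width
   floored at 4) maps both, and the sigmoid of the sum rescales each
   channel.

3. **Deep supervision with a mixed loss.**  Every decoder stage feeds a
   side head (1x1 convolution, sigmoid, bilinear upsampling to input
   resolution).  Numbering the heads step 1 (finest, the prediction) to
   step 4 (coarsest), the training loss is

       L = (L_Dice1 + L_BCE1) + alpha (L_Dice2 + L_BCE2)
             + beta (L_Dice3 + L_Dice4)

   Dice handles the foreground/background imbalance on every head; BCE
   adds pixel-level sharpness only on the two finest heads, whose
   outputs are expected to resolve local detail.  BCE is the standard
   nonnegative mean negative log-likelihood.  The soft Dice smoothing
   term `epsilon` (default 1.0) keeps lesion-free slices differentiable
   and makes the empty-vs-empty loss exactly zero.

### Architecture details

The encoder is a ResNet-34-style stack: a 7x7 stride-2 stem and four
stages of (3, 4, 6, 3) basic residual blocks, producing features at
strides 2/4/8/16/32 with channel widths `(b, b, 2b, 4b, 8b)`; `b = 64`
reproduces ResNet-34, and `b` is configurable because the wiring — not
the width — is what the attention modules modify.  The first
convolution takes one channel (T1 is grayscale); training is from
scratch.  The decoder runs four stages from the stride-32 feature: x2
bilinear upsampling, a 1x1 convolution aligning the decoder channel
count to the encoder feature (the cross-attention formula requires
equal shapes; 1x1 alignment is the cheapest choice that preserves
spatial layout), CSAM then CAM, and two Conv-BN-ReLU layers reducing
`2C` to the next stage's width.  Upsampling everywhere is
bilinear-then-convolve; there are no transposed convolutions.  Four
fusion stages match the four skip levels; the stride-2 stem feature is
the finest fusion input, and the step-1 head upsamples its output x2 to
input resolution.  Side-head biases initialize at -2 so the initial
foreground probability (~0.12) reflects the class prior rather than a
50% coin flip, which removes several epochs of burn-in on imbalanced
data.

Ablation switches reproduce the four study configurations: `baseline`
(plain concatenation skip, single-head Dice+BCE), `csam`, `csam_cam`
(attention but single-head loss), and `full` (attention plus deep
supervision with the mixed loss).

### Numerical engine

No deep-learning framework is part of the dependency stack; the package
ships a compact reverse-mode autodiff engine on float32 numpy arrays
(`strokeseg.autograd`) with the primitives a 2D segmentation network
needs — im2col convolution, max pooling, batch norm composed from
arithmetic primitives, and separable bilinear resampling expressed as
two constant interpolation matrices (so its gradient is exactly the
transposed resampling).  Every primitive is verified against central
finite differences in the test suite.  Sigmoid outputs are clamped 1e-7
inside (0, 1) so attention maps and probability heads keep their
open-interval contract under float32 saturation; BCE additionally
clamps probabilities at 1e-7 before the logarithms.  Max-reduction ties
split the gradient equally, which keeps backward passes deterministic.
Training is bit-reproducible on a fixed device for fixed seeds: weight
init draws from a generator seeded by the model config, shuffling from
the training config.

## Training protocol

Adam (beta1 0.9, beta2 0.999, no weight decay) with the poly schedule
`lr = init_lr * (1 - epoch/n_epoch)^power`, stepped per epoch (the
schedule is defined in epochs), defaults `init_lr = 1e-3`, `power =
0.9`, `n_epoch = 100`, batch size 24.  All slices — lesion-bearing and
empty — enter training (a `lesion_only` flag exists but defaults off);
the Dice terms exist precisely because of the resulting imbalance.
Model selection keeps the epoch with the best validation mean 3D DSC,
computed by the same evaluation module used at test time.  Inference
uses only the step-1 head.  Loss weight defaults `alpha = 0.5`,
`beta = 0.25` down-weight the auxiliary heads by depth; no reference
values exist for these, so they are an explicit, documented default and
both are exposed in configuration rather than buried constants.

## Preprocessing

Per-volume min-max normalization to [0, 1] first (the choice is
configurable; normalization before cropping means the crop cannot
change a volume's reference range), then for full-scale 233 x 197
slices a fixed crop with diagonal coordinates (10, 40)–(190, 220).
These coordinates only fit the slice when read as (x, y) — rows 40–220
of the 233, columns 10–190 of the 197 — yielding a 180 x 180 region;
the (row, col) reading would run past the 197-pixel width.  The crop is
followed by bilinear resizing to 192 x 192.  Masks travel through the
same geometry with nearest-neighbor resampling and re-binarization
(> 0.5), so no fractional labels exist anywhere downstream.  Volumes
whose slices do not contain the crop box (e.g. compact synthetic data)
skip the crop and resize directly to the configured target; the network
accepts any spatial size divisible by 32.  Subject-level splits are a
seeded permutation partition (full-scale sizes 137/36/56 of 229).

## Evaluation

Predictions are thresholded at 0.5 (ties count as lesion).  Each test
subject's full 3D volume reduces to one TP/FP/FN triple; the report
carries per-patient DSC = 2TP/(2TP+FP+FN), Recall = TP/(TP+FN),
Precision = TP/(TP+FP), their unweighted means across patients, and a
pooled "global" DSC computed from counts summed over all test voxels —
the only reading of a global Dice that differs from the mean.
Degenerate cases (possible only with synthetic data): empty truth and
empty prediction scores DSC 1.0; empty truth with a nonempty prediction
0.0; recall defaults to 1.0 when the truth is empty; precision to 0.0
when nothing is predicted, with the row flagged.  Metrics are computed
in preprocessed space, matching how training targets were defined.

## Synthetic cohorts

The generator emulates the *layout and statistics* of MNI-normalized
T1 stroke data, not its anatomy: an elliptical brain (semi-axes 0.42 of
each volume axis) of smoothly textured intensity on a dark background;
zero or more darker ellipsoidal lesions (default contrast -0.3, the
hypointense direction) placed so that each provably fits inside the
brain; additive Gaussian noise (default sd 0.05) with clipping to
[0, 1].  Lesion radii parameterize the in-plane semi-axes; the
through-plane semi-axis scales with the brain's own depth-to-width
ratio, so thin stacks carry anisotropic blobs the way thick-slice
acquisitions do, and most slices remain lesion-free.  Configs whose
radius upper bound exceeds half the smallest in-plane brain axis are
rejected.  One master seed derives per-subject seeds as `seed + index`;
generation is bit-reproducible.

What the generator does **not** emulate — cortical anatomy, lesion
location statistics (the real data skews ~48/44/8% across
left/right/other), multi-site scanner effects, partial-volume
boundaries — bounds what passing tests show: they demonstrate that the
pipeline is wired correctly and that the network can learn a
low-contrast, imbalanced segmentation task end-to-end, not that it
reaches any particular accuracy on clinical data.

## The scaled-down benchmark

`strokeseg.benchmark.run_benchmark` fixes the study conditions: 12
subjects of 16 x 96 x 96 voxels, 1–2 lesions of in-plane radius 5–10,
contrast -0.3, noise 0.05, cohort seed 7, split 8/2/2, batch size 8,
25 epochs, network width `b = 8`.  The width is the one scale knob
turned relative to the full-size model: at `b = 8` a complete training
runs in under two minutes on one CPU core while preserving every
architectural element.  Ablation comparisons train the full and
baseline configurations with identical seeds on the identical cohort,
and compare three-seed medians to absorb training stochasticity; at
the benchmark's reference seeds the full model's median held-out mean
3D DSC clears 0.80 with margin.  Twenty-five epochs do not fully
converge a freshly initialized network, so results at other seeds vary
more than fully trained models would.

## Known limitations

- 2D slice-wise only; no 3D or 2.5D context (deliberately out of
  scope).
- The numpy engine is single-threaded and eager; full-width (b = 64)
  training at 192 x 192 is supported but slow — it exists for users
  who bring real cohorts and patience, and the CLI will run it.
- Batch norm with very small batches (the tail of an epoch) uses the
  batch statistics as-is; batches of one slice are legal but noisy.
- No data augmentation, early stopping, or multi-device support.
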