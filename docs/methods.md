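# Methods

## Segmentation by translation

`translung` treats binary segmentation of grayscale biomedical images as an
image-to-image translation problem. The input image x (a lung-window CT
slice, or a phantom emulating one) is regarded as a "blurred" rendition of
its own segmentation; the target y is the reference mask rendered as an
image (foreground 1.0, background 0.0). A conditional GAN learns the
mapping:

    G* = arg min_G max_D  Γ_cGAN(G, D) + λ · Γ_L1(G)

where

    Γ_cGAN(G, D) = E_{x,y}[log D(x, y)] + E_{x,z}[log(1 − D(x, G(x, z)))]
    Γ_L1(G)      = E_{x,y,z}[ ‖y − G(x, z)‖₁ ]

The critic D sees the (condition, candidate) pair jointly, so it penalises
masks that are plausible in isolation but inconsistent with the input. The
L1 term anchors the translation to the reference. The noise input z is
realised as dropout in the generator (active during training, optionally at
inference), the standard interpretation in translation networks. Inference
is *translate-then-binarize*: the generator output in [0, 1] is thresholded
at 0.5 ("≥ threshold is foreground" everywhere in the package).

### Architecture and optimisation

The generator is a stride-2 encoder–decoder with skip connections, depth
log2(input size) so the bottleneck is 1×1, channels doubling from
`base_channels` and capped at 8×, instance normalisation (equivalent to
batch normalisation at batch size 1, but deterministic at inference),
leaky-ReLU encoder / ReLU decoder activations, dropout (rate 0.5) in the
three innermost decoder stages, and a final tanh mapped affinely to [0, 1].
The discriminator is a patch critic: `patch_depth` (default 3) stride-2
stages, one stride-1 stage, then a 1-channel projection and sigmoid,
yielding a grid of per-patch real-probabilities (a 70×70 receptive field at
the defaults).

Training follows the canonical recipe: Adam with learning rate 2e-4 and
β₁ = 0.5, batch size 1, λ = 100, no learning-rate decay. The critic ascends
Γ_cGAN implemented as binary cross-entropy toward 1 on (x, y) and toward 0
on (x, G(x)), averaged and halved (the halving slows the critic relative to
the generator; exposed as `halve_d_loss`). The generator descends the
non-saturating adversarial loss −E[log D(x, G(x))] plus λ·L1; this moves
the same saddle point as the literal second term of Γ_cGAN but keeps
gradients alive early in training. Probabilities are clamped to
[1e-7, 1 − 1e-7] inside logarithms, so all logged losses are finite even at
a saturated critic. The logged per-epoch `g_total` is computed as
`g_adv + λ·g_l1` from the epoch means, so the identity holds exactly.

All networks are implemented on a compact numpy layer library
(`translung.nn`) with hand-written backpropagation — im2col convolutions,
transposed convolutions defined as the exact adjoint of the strided
convolution, instance norm, max pooling, dropout — and the Adam optimiser.
Every layer's gradients are verified against central-difference numeric
differentiation in the test suite.

### Baselines

* **U-Net** (`translung.unet`): the standard encoder–decoder segmenter —
  double 3×3 convolution blocks, 2×2 max pooling, transposed-convolution
  upsampling, skip concatenation, sigmoid head — trained with plain
  pixelwise binary cross-entropy, no Dice term, no augmentation, and the
  same optimiser, epochs, shuffling and seed semantics as the translator so
  the comparison isolates the objective.
* **Otsu** (`translung.classical`): 256-bin global threshold maximising
  between-class variance, ties broken toward the smallest threshold,
  dark class as foreground by default (lungs are dark). Applied naively —
  no body masking — so it also captures the dark background; this is
  deliberate, matching the naive protocol whose poor scores the comparison
  is designed to reproduce.
* **Canny** (`translung.classical`): Gaussian smoothing, 3×3 Sobel
  gradients, non-maximum suppression with the gradient direction quantized
  to four sectors (plateau ties keep the pixel whose forward neighbour is
  strictly smaller, so an ideal step yields a one-pixel line), and
  double-threshold hysteresis (thresholds are fractions of the maximum
  gradient magnitude; weak edges survive only if 8-connected to a strong
  edge). The edge pixels themselves are the predicted mask — again the
  naive protocol; no boundary filling is applied.

### Evaluation

Per image, every pixel is a binary classification decision:
accuracy = (TP+TN)/total, overlap rate = Jaccard index of the foregrounds,
precision, recall, and F-measure = 2PR/(P+R). Degenerate denominators
follow fixed conventions: two empty masks are a perfect match; an empty
prediction against a nonempty reference scores 0 on the affected ratios;
F = 0 when P+R = 0. Cohort summaries report min/max/mean/standard
deviation, with the population (divide-by-n) standard deviation. These
conventions matter only on pathological inputs; on the study cohorts every
denominator is nonzero.

## The phantom generator

The package is developed and tested against synthetic thoracic-slice
phantoms with exact ground truth rather than patient data. Each phantom is:
a dark background (intensity 0.05), a bright elliptical torso (intensity
drawn per image from [0.55, 0.85], semi-axes 0.46/0.40 of the image side
with ±4% jitter), and two darker lung fields (intensity from [0.08, 0.32],
strictly below the torso range, matching the dark-lung/bright-tissue
ordering of lung-window CT). Each lung is an ellipse with height/width
ratio 2.2, independently jittered in both axes by a factor drawn from
[0.88, 1.12] and rotated by up to ±8°. Optional intralung clutter — up to 3
bright nodule disks (radius 2–6 px) and Poisson-distributed vessel-like
line segments — is drawn inside the lungs at torso-range intensities. The
scene is Gaussian-blurred (σ = 0.7 px) and corrupted with i.i.d. Gaussian
noise (σ = 0.02), clipped to [0, 1]. The mask is the pre-noise lung
geometry.

**Calibration.** The base lung semi-axes are solved analytically so that
the two un-jittered ellipses cover exactly `lung_area_fraction_target` of
the image (default 0.2543, the mean lung-area fraction of the emulated
dataset). The axis-jitter factors are independent with unit mean, so the
*expected* per-image fraction equals the target while individual draws vary
(sd ≈ 2 percentage points); the emulated statistic is a dataset average,
not a per-image constraint, and the target dataset's own spread is
unreported, so the jitter width is a free choice fixed once.

**Annotation-error modes.** `corrupt_labels` emulates expert mistakes
observed in real manual segmentations: `half_lung` zeroes one lateral half
of the foreground (split at the foreground column centroid, side chosen at
random); `residual_background` adds a band of spurious foreground hugging
the outer torso boundary (the torso located by Otsu thresholding of the
image itself, so the mode works on loaded data too); `dilate_erode`
perturbs the boundary morphologically. Only masks are touched, never
images, and the clean mask is retained on every corrupted pair so
experiments always can evaluate against truth.

**What the phantoms do not emulate:** real anatomy (mediastinum, airways,
lobar structure), HU physics and correlated CT noise, pathology beyond
bright disks, inter-patient variability structure, and annotation styles
beyond the three corruption modes. Passing the phantom studies shows the
mechanism works — translation training converges, the adversarial+L1
objective segments dark fields accurately, label noise at 20% is absorbed —
not that the reported real-data figures transfer to any particular scanner
or cohort.

## Study problem sizes

The replication studies run on 64×64 phantoms with 16-channel networks
(the package's desk-scale default; every architectural mechanism — depth
log2(size), patch critic, skips, dropout-as-z — is preserved, only width
and resolution shrink):

* **Training study**: 67 training phantoms, 30 held-out, 20 epochs; the
  trained translator reaches mean held-out F ≈ 0.97 (the full-scale
  real-data analog of this design reports mean F 0.8705).
* **Method comparison**: translator and U-Net at the identical budget
  against Otsu and Canny; both learned methods exceed both classical
  baselines by ≥ 0.3 absolute on mean overlap and F.
* **Label noise**: 20% of training masks corrupted in `half_lung` mode;
  held-out F against clean truth stays ≥ 0.75.
* **Sample size**: 237-phantom training versus its 67-phantom subset at a
  shared 2-epoch budget, averaged over 3 seeds; more data never scores
  worse.

## Numerical and design choices

* float32 parameters and activations; float64 for metric and objective
  *values*.
* Normal(0, 0.02) weight initialisation; norm gains Normal(1, 0.02).
* Instance norm is skipped at 1×1 spatial extent (it would zero the
  activation); the innermost encoder stage therefore has no norm.
* Binarization tie-break: "≥ threshold is foreground", used identically in
  mask loading (128/255), translation output (0.5), and the sigmoid head.
* Masks on disk are {0, 255} 8-bit PNG; images `round(v·255)`; loading
  re-binarizes at 128/255 so antialiased third-party masks stay binary.
* Image resizing is bilinear; mask resizing nearest-neighbour (then
  re-binarized), so masks never acquire fractional values. Sizes are
  restricted to powers of two ≥ 32, the generator-depth requirement.
* All randomness flows from integer seeds through `numpy` generators;
  per-pair, init, shuffle and dropout streams are split via
  `SeedSequence`. Same seed + params ⇒ bit-identical outputs everywhere.
* Checkpoints are single `.npz` archives holding specs, config, history and
  parameter tensors, with a format version; loading reconstructs
  bit-identical deterministic inference.

## Known limitations

* CPU-only and single-threaded BLAS-bound: full 256×256, 64-channel
  training is possible but slow (hours), as expected for a from-scratch
  numpy implementation; the scaled studies are the supported regime.
* Single-channel, single-class, 2-D only.
* The phantom studies quantify mechanism, not clinical performance (see
  above). Real-data use must document its own resampling to a power-of-two
  resolution.
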