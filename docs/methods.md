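# Methods

`gemmascope` implements a classifier-based protocol for detecting and
validating cryptic morphological differences between two classes of plant
images — the motivating case is male versus female gemmalings of the
liverwort *Marchantia polymorpha* photographed on agar plates during their
first week of growth — together with a genome-window derivation caller for
recombinant inbred lines (RILs). Because the protocol's value lies in its
*inferential logic* (which image channel carries the class information, and
does the classifier attend to the plant or to nuisance background?), the
package ships a synthetic image generator whose class differences can be
planted channel by channel, so every stage of the pipeline is testable
without any external image download.

## The classification protocol

Images are center-cropped to a square (crop side 0.75 of the long side, the
ratio of a 1,200 px crop on a 1,200 × 1,600 frame), the scale bar is erased
with a local background median, training images are expanded to their
8-element dihedral orbit (right-angle rotations × horizontal flip), resized,
scaled to [0, 1] and channel-standardized with the ImageNet constants
(mean [0.485, 0.456, 0.406], sd [0.229, 0.224, 0.225]). Evaluation images
receive the same treatment without flips or rotations and are
bit-deterministic.

A frozen convolutional backbone maps each image to a globally
average-pooled feature vector; only a 2-logit affine head is trained, by
minibatch softmax cross-entropy with Adam (learning rate 0.001, batch size
32, 500 epochs), keeping the checkpoint with maximum validation accuracy
(earliest epoch on ties). Data are split 64:16:20 into
training/validation/test, stratified by class; all augmented variants of a
source image stay in that image's partition. Head features are standardized
with training-set statistics before the affine map, with a variance floor
(0.1 × the median feature sd, added in quadrature) so rarely-firing
features cannot be inflated into spuriously dominant inputs; the
standardization is folded back into the stored affine head, which therefore
acts on raw pooled features. Every reported accuracy is the mean over five
independent trials that re-randomize both the split and the head
initialization. The negative control permutes class labels before
splitting and must land in the central 95% binomial band around 0.5.

## The backbone

The reference design for this protocol is an ImageNet-pretrained ResNet50
used as a frozen 2,048-d feature extractor. `gemmascope` abstracts the
backbone behind a three-method adapter (`pooled_dim`, `forward` returning
last-layer activations plus pooled features, and `input_gradient`), and
ships `TinyConvBackbone`, a compact fixed-weight CNN implemented directly
on NumPy with explicit forward and backward passes (convolutions are 3×3,
stride 1, reflect-padded; reflect padding avoids spurious border edges on
dark plates). Its first layer combines:

* a four-channel **surface front end** — ON/OFF luminance channels split at
  intensity 0.30 (between dark agar and bright tissue) and R−G / G−R
  color-opponent channels (brown plate versus green tissue), specified in
  raw intensity units and folded through the normalization constants. These
  channels form an isolated pathway: identity taps carry them to the last
  convolutional layer (so spatially broad surface cues remain visible to
  Grad-CAM), and all other downstream filters are blinded to them;
* seeded He-initialized random filters whose per-channel spatial mean is
  shrunk to 10%, attenuating responses to spatially uniform plate tint
  while leaving edge/texture responses untouched.

The channel plan is 3 → 20 → 32 → 32 pooled dimensions. The network's
final stage is one extra 2×2 average pool, so the activations
entering global pooling live on a coarse (input/8) grid, as in deep
reference backbones; global average pooling is identical over either grid.
The backbone is reproducible from its seed alone and is never trained in
the classification protocol; `fit_backbone` provides full end-to-end
training (verified against numerical gradients) for pretext-task
pretraining when a task-tuned backbone is wanted.

## The synthetic generator

Each image holds one star-convex plantlet, r(θ) = r₀(1 + Σₖ aₖ cos(kθ+φₖ))
with k ≤ 8 and a dominant bilobed/lobed term (k = 2 early, more lobes
later), rendered on a dark agar background with pixel noise and faint
bright scratch segments, plus a fixed-position scale bar and the exact
ground-truth silhouette mask. Expected radius grows with day
(fractions {0: .08, 1: .10, 2: .12, 3: .15, 4: .18, 7: .24} of the image
side over the day 0–7 schedule).

Class differences are standardized mean differences injected into four
independent channels (male at −d/2, female at +d/2 latent units):

* **area** — log projected area, within-class sd 0.25 (a ~25% CV);
* **color** — tissue hue along a green ↔ brown (chlorotic) axis, latent sd
  0.08, so either class pole is a positive surface color rather than the
  absence of green; tissue brightness carries an independent sd-0.08 noise;
* **contour** — the split of a tightly controlled total high-harmonic
  amplitude (0.24 ± 0.015) between a coarse scallop harmonic (k = 5) and a
  fine crenellation harmonic (k = 8); the spectral-centroid latent has sd
  0.15. Coding the difference as a centroid shift at constant energy keeps
  expected area and radial variance identical across classes, so severe
  blurring — which erases the crenellation-vs-scallop distinction — leaves
  almost no residual class signal;
* **background** — plate tint (sd 0.02) plus scratch density, a deliberate
  confound mimicking nuisance cues such as scratches on the medium.

The radius is renormalized by the harmonic area inflation (1 + ½Σa²), which
keeps the channels statistically independent. All-zero effects make the two
classes draws from one distribution. A single integer seed is expanded into
per-image counter-based streams; foreground and background draw from
separate child streams, so changing only background parameters leaves
foreground pixels bit-identical. What the generator does **not** emulate:
photorealistic thallus texture, gemma-cup/rhizoid anatomy, lens changes
across days, uneven illumination, or any real biological covariance between
channels — so green-light results here demonstrate that the *pipeline's
logic* recovers planted structure, not that real gemmalings behave this
way.

## Feature ablations and attribution

Three ablations are applied to raw images before preprocessing: background
masked to black (I), binarization into white silhouette on black (II), and
binarization followed by severe Gaussian blur (III; bandwidth 60 px at the
1,200-px reference scale, scaled proportionally, output left
grayscale-valued). On the four single-channel synthetic datasets the
expected information ordering is: the background dataset collapses to
chance after (I); the color dataset additionally after (II); the contour
dataset additionally after (III); the area dataset survives all three.

Grad-CAM is implemented from its definition: channel weights are the
spatially averaged gradients of the target logit with respect to the
last-layer activations (for an affine head over global average pooling this
gradient is the head weight divided by the cell count — verified against a
hand-derived chain rule on a linear toy backbone), the weighted sum is
rectified after summation, bilinearly upsampled and min-max normalized
(identically-zero maps stay zero). Integrated gradients follow the
straight-path midpoint rule; completeness holds within 5% at 256 steps.
The XRAI-style map averages integrated gradients over black and white
baselines, oversegments the image with Felzenszwalb graph segmentation at
three scales, and greedily ranks regions by mean attribution gain over the
not-yet-covered area.

Validation binarizes normalized heatmaps at 0.5 and compares them to the
geometry-matched plant silhouette with IoU, summarized per day/sex/method
by median and IQR over correctly predicted test images only; the
heatmap-area fraction separates "looked elsewhere" from "looked nowhere".
Representative images per group are those with the highest unnormalized
predicted-class logit. The localization null model replaces the heatmap
with random same-area disks; the permutation p-value is the fraction of
null medians at least as large as the observed median IoU.

## Desk-scale validation conditions

The canned validation experiments (`gemmascope.experiment`) use 80 images
per class per dataset, 128-px generation, 96-px model input, day 2, five
trials, 500 epochs. Single-channel effect sizes are area d = 3, color
d = 4, contour d = 6 and background d = 3: the area value is a moderate,
realistic morphometric difference, while the color and especially contour
differences are set high because hue and fine-contour information sit close
to the desk-scale resolution limit and the dissection logic requires each
channel to be individually well-detectable before its ablation. The
transfer experiment plants pair A with area d = 5 plus color d = 4 and pair
B with only color d = 2 (half of A's), evaluating on the target's 20% test
split. Chance bands are central 95% binomial intervals at the relevant
test-set size.

## Genome-window derivation calls

Variants of Tak-2, Rit-1 and Rit-2 against the Tak-1 reference are counted
in fixed windows (100 kb or 1,000 kb; the window size is always an explicit
argument). Window index is `pos // window_size` on 1-based positions — a
variant at exactly the window size falls in the second window — and
truncated terminal windows scale the significance threshold in proportion
to their width. A window is "significant" for a line when it holds strictly
more than 100 polymorphisms per 100 kb. Derivation per autosomal window:
Tak-2 not significant → SHARED; Tak-2 significant and (Rit-1 or Rit-2)
significant → TAK2; otherwise TAK1. Sex-chromosome (U/V) windows are
excluded. Fractions are length-weighted. The synthetic genome generator
plants a derivation class per window and samples counts uniformly away from
the threshold (below 0.3× or above 2× it), so recovery must be exact;
reproducing the real Tak/Rit split requires the deposited sequencing data
and is out of scope.

## Numerical and design notes

* Otsu segmentation blurs with σ = 10 px at the 1,200-px reference scale
  (scaled to the image), auto-detects foreground polarity as the threshold
  side touching the image border least (ties → higher saturation), dilates
  with a disk of radius 5 px at 256-px scale, fills holes and keeps the
  largest component. A constant image raises "degenerate intensity
  histogram".
* Hedges' g uses the pooled (n−1) variance and J = 1 − 3/(4(n₁+n₂) − 9);
  equal samples return 0, zero pooled variance with unequal means raises.
* MCC with a zero denominator is defined as 0; IoU of two empty masks is
  defined as 0 (with a warning) rather than NaN.
* t-SNE uses perplexity 30, 1,000 iterations and seed 1,000,000 by default
  and refuses fewer than 3 × perplexity rows.
* All computation is float32 in the backbone (deterministic, twice the GEMM
  speed) and float64 elsewhere.

## Known limitations

The backbone is a fixed compact CNN, not a large pretrained network: its
features are weaker than ResNet50's, which is why planted desk-scale effect
sizes are larger than what the original imaging setting plausibly exhibits,
and why fine-contour detection sits near its floor. Grad-CAM maps from
random-feature channels are spikier than those of semantically coherent
deep channels, making the 0.5-threshold heatmap area sensitive to the
channel mix. The RIL module deliberately starts from variant tables:
read mapping, calling and filtering belong to established external
toolchains.
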