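# Methods

## Problem and pipeline

The impurity rate of machine-harvested wheat is defined on masses: the
percentage of a sample's mass contributed by non-grain material (straw,
awn, husk). A camera watching the grain stream sees areas, not masses, so
the pipeline has two stages: (1) per-pixel semantic segmentation of each
RGB frame into background (0), grain (1) and impurity (2); (2) conversion
of the two foreground pixel counts into a mass rate through a calibration
constant.

## Segmentation network

DeepLabV3+ encoder–decoder, implemented on a small reverse-mode autodiff
engine over numpy (`wheatvision.nn`). The engine provides exactly the
operators the architecture needs — strided/dilated/grouped convolution via
im2col with a bincount-based scatter in the backward pass, batch
normalisation, ReLU/ReLU6, channel concatenation, global average pooling,
half-pixel-centre bilinear resizing, and a softmax cross-entropy head —
each verified against finite differences in the test suite.

Backbones: `resnet50`/`resnet101` (bottleneck stacks 3-4-6-3 / 3-4-23-3),
`mobilenetv2` (inverted residuals, ReLU6), `xception65` (entry/middle/exit
separable-convolution flows with 16 middle blocks), and `tiny` (a
four-stage basic-residual net used for desk-scale training). All widths
scale by `width_multiplier`; at output stride 16 the final stage trades
stride for dilation 2 (at stride 8, the last two stages dilate). Two
implementation substitutions relative to the canonical designs, both forced
by the convolution-only engine and immaterial at the scales trained here:
the ResNet stem's max-pool is a 3×3 stride-2 convolution ("ResNet-C"), and
Xception's per-block max-pools are stride-2 separable convolutions.

Head: ASPP with rates (6, 12, 18) — the canonical choice at output stride
16 — plus 1×1 and image-pooling branches, projected to `256·wm` channels;
decoder upsamples ×4, concatenates a `48·wm`-channel projection of the
stride-4 backbone feature, applies two 3×3 convolutions and a 1×1
classifier, and upsamples ×4 to full resolution.

Training minimises unweighted per-pixel cross-entropy over the three
classes (background included) with Adam, batch shuffling and step-decayed
learning rate; defaults live in `TrainConfig` (epochs 30, batch 8, lr 1e-3
decayed ×0.1 every 15 epochs, decoupled weight decay 1e-4 on conv weights).
The optimiser, schedule and loss are design choices of this package — the
device study did not publish its hyperparameters — so they are exposed
entirely through `TrainConfig`, never hard-coded. The retained checkpoint
is the best-on-validation-MIOU epoch (final epoch when no validation set is
given). A fixed seed makes initialisation, shuffling and hence the loss
trajectory bit-reproducible on CPU. Pretrained initialisation is supported
only as an explicit user-supplied checkpoint path; nothing is downloaded.

## Quantification

With grain pixels `T_w`, impurity pixels `T_z` and the mass-ratio constant
∂ (grain grams per 1000 px ÷ impurity grams per 1000 px):

    P_z = T_z / (T_z + ∂ T_w) × 100.

`P_z` is strictly increasing in `T_z`, decreasing in `T_w` and ∂, bounded
in [0, 100], and equals the manual mass rate `P_cz = w_z/w × 100` exactly
when ∂ equals the true per-kilopixel density ratio (a property test holds
this to 1e-12 relative on noiseless synthetic scenes). A frame with neither
grain nor impurity pixels yields the *undefined* marker, not 0 or 100: an
empty frame is a sampling failure of the device, not an extreme rate.

Calibration estimates ∂ from weighed samples as a **ratio of means** of
the per-sample grain- and impurity-mass-per-kilopixel values; this is more
stable than the mean of per-sample ratios when individual samples contain
few impurity pixels (small `T_z` makes a per-sample ratio wild). The
mean-of-ratios variant is available via `method=`, and the coefficient of
variation of the per-sample ratios is reported as a dispersion diagnostic.
The shipped default ∂ = 11.8906 is a laboratory calibration for wheat; it
must be re-estimated when the crop, camera distance or illumination
geometry changes, and the CLI's `detect` deliberately refuses to apply any
default implicitly.

## Evaluation metrics

Per class c ∈ {grain, impurity}: TP/FP/FN pixel counts pooled (micro)
across the image set, then P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R),
F_IOU = TP/(TP+FP+FN); F_MIOU is the mean of the two foreground IOUs —
background is excluded, which is the convention that makes the published
two-class means internally consistent. Pooling across images (rather than
macro-averaging per-image metrics) is the common semantic-segmentation
convention; duplicating every image leaves pooled metrics unchanged, which
the suite asserts. `metrics_from_pr` uses the identity
F_IOU = PR/(P+R−PR) to audit printed tables when raw masks are
unavailable. Zero-denominator metrics return a NaN "undefined" marker with
a warning and are excluded from averages — never silently reported as 0.

Trial statistics compare a device detection series with a manual sampling
series per batch/trip: absolute error of the means (percentage points),
relative error (% of the manual mean), and the coefficient of variation of
each series. The CV uses the sample standard deviation (divisor N−1) with
the square root applied — the quantity is a coefficient of variation even
where the source typography drops the radical.

## Synthetic scenes

`SceneSpec` renders a dark-background pile of ellipse "grains" and
elongated impurities (70% piecewise-linear bent strips ≈ straw, 30% thin
partial annuli ≈ husks). Every object is a polygon burned into the mask in
draw order (later object wins, matching LabelMe semantics; impurities are
drawn last since straw rides on top of a real pile), so the stored
LabelMe JSON re-rasterizes to the stored mask exactly. Rasterization uses
the even-odd rule at integer pixel centres and is checked against an
independent per-pixel ray-casting oracle.

Defaults state the emulated world once: 512×512 canvas, 120 grains with
semi-axes 9–16 px, 8 impurities of length 60–140 px and width 4–9 px,
wheat-like colours (grain ≈ RGB 184/152/96, straw ≈ 206/196/150) with
per-object jitter σ=14, Gaussian blur σ=0.8 px and additive noise σ=4.
The mass model assigns 0.1565 g per 1000 grain pixels — a ~300-px grain
then weighs ≈ 46.9 mg, matching the thousand-kernel weight of the field
wheat being emulated — and fixes the impurity density so the true ∂ is
exactly 11.8906; weighing noise is multiplicative Gaussian with CV 5%
(typical for field scales at sub-gram impurity masses). Desk-scale tests
shrink the canvas to 128×128 with proportionally smaller objects.

What a green test does **not** establish: the renderer has no perspective,
occlusion ordering by depth, specular highlights, motion blur or moisture
darkening, and its two classes are more colour-separable than real straw
on wheat. Synthetic results therefore validate the *machinery* (losses,
metrics, calibration algebra, reproducibility), not field accuracy.

## Numerical choices and degenerate inputs

- All randomness flows from integer seeds through `numpy.random.default_rng`
  / `SeedSequence`; no global RNG state is touched.
- float32 throughout the network; bilinear resize uses half-pixel centres
  (`align_corners=False` convention).
- Mask resizing is nearest-neighbour (bilinear interpolation of labels
  would fabricate invalid classes); 0.6× rescaled variants are zero-padded
  as background and 1.8× variants centre-cropped so tensor shapes stay
  constant across the augmented set.
- Degenerate (zero-area) polygons are skipped with a warning; unknown
  label strings and malformed JSON are hard errors naming the offender.
- Non-finite training loss aborts with the epoch, learning rate and batch
  indices in the message.

## Known limitations

Full-width backbones are constructible and differentiable but impractical
to train on CPU; published full-scale segmentation scores are reproduced
only through their internal metric identities, not by retraining. The
inference-speed measurement is wall-clock on whatever hardware runs it and
is never compared against published timings. The scene generator's free
appearance parameters were chosen once for realism, not fitted to any
image statistics.
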