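# Methods

## The model

`segnet` implements a dual-pathway convolutional model of attentional
object segmentation in the primate ventral stream. A driving feedforward
hierarchy of model areas — V1m (20 features, 56x56), V2m (50, 28x28), V4m
(100, 14x14), then a strided projection to a 100x7x7 tensor, a
fully connected ITm (500 units) and FCm (12 units, one per object class) —
maps a grayscale stimulus onto independent per-class detection scores
(elementwise sigmoids; scenes are multi-label). Each area contains three
convolutional blocks; a block is a 3x3 convolution, batch normalization
and a rectifier wrapped by a skip connection (identity where channel
counts match, a learned 1x1 projection otherwise). Areas are joined by
2x2 stride-2 convolutions.

The feedback pathway carries an attended class back to pixels. A one-hot
attention template multiplies the class scores elementwise; the gated
vector is expanded by fully connected layers mirroring FCm/ITm and a
transposed convolution to a 100x7x7 map, concatenated with the
feedforward tensor of the same shape (200 channels) and fused back to 100
channels by a 1x1 convolution. This short head is *driving* — ordinary
layers. Everything below it is *modulatory*: every convolutional layer of
V1m/V2m/V4m has a mirrored feedback unit of identical shape, and with `a`
the local feedforward activity, `z` the feedback drive arriving from
above and `beta` a learned per-feature offset,

    b = max(0, a * (z + beta))
    c = b - a

so feedback can only scale activity that the stimulus already drives
(`b = 0` wherever `a = 0`), and the signal sent downward, `c`, is the
difference between feedback and feedforward unit activity — a
segmentation signal referenced to the driven response. Between areas `c`
is up-projected by a learned 2x2 stride-2 transposed convolution; within
an area, mirrors are chained by learned 1x1 convolutions. The final
segmentation map reads the lowest V1m mirror's `b` through a learned 1x1
convolution and a sigmoid (reading `c` instead is a config switch).

Design points that the architecture description leaves open, resolved
here as the package's own choices:

- in-area kernels are 3x3 with padding that preserves resolution;
- the rectifier sits after the skip addition, which guarantees the
  non-negative `a` the modulation equation requires;
- `beta` is one offset per feature map (a scalar-per-layer mode exists);
- the feedback spatial up-projection must *increase* resolution, so it is
  a transposed convolution mirroring the feedforward downsampling;
- batch normalization uses running statistics in every evaluation and
  simulation code path, making inference deterministic;
- the driving feedback head has no normalization layers;
- the 1x1 read-out is initialized as the positive channel mean, so that
  high V1m feedback-unit activity `b` itself means "attended pixels" —
  the convention the region-trace analyses assume (a random-sign read-out
  can satisfy the same loss with `b` anti-correlated to the map).

### Feedback initialization

The modulation cascade multiplies activity by the unnormalized `a` at
every mirrored layer, so with ordinary fan-in-scaled random weights the
feedback drive grows by orders of magnitude per area and the read-out
starts deep in sigmoid saturation. Before phase 2 the feedback pathway is
therefore calibrated layer-sequentially on a batch of training stimuli:
each feedback layer receives a fixed input divisor (`in_scale`) chosen so
the drive `z` it produces has unit standard deviation, and the read-out
logits a small one. The divisors are plain constants, not parameters —
scaling the weights themselves would make the L2 term dominate Adam's
normalized update and erase the (initially faint) task gradient. All
operations between the calibrated layers are positively homogeneous, so
the correction is exact up to the few calibration iterations used.

## Stimuli

Scenes are 56x56 grayscale images with one to three non-overlapping
objects from 12 classes on an oriented background texture: a
texture-defined square (class 0), a texture-defined rectangle (class 1)
and digits 0-9 (classes 2-11). Textures are short anti-aliased bars
(length 5 px, 8 elements per 100 px^2, placement jitter 1.5 px, unit
contrast) on a jittered grid; a texture figure is a rotated rectangle
whose interior carries a texture rotated 45-135 degrees away from the
background, so figures are orientation-defined, not luminance-defined
(figure/ground mean-intensity difference below 0.05). Figure sides are
14-28 px (rectangles keep an aspect ratio of at least 1.3 so the two
shape classes remain distinct); rotations are uniform in [0, 180).
Digits are glyph strokes pasted over the texture; the stroke pixels (the
rescaled bitmap above an intensity threshold of 0.3) define the
ground-truth mask. Digit scale is uniform in [0.75, 1.5], with
nearest-neighbour resampling so stroke statistics scale cleanly.

Digits default to procedural glyphs — hand-designed stroke skeletons with
seeded slant/scale/thickness jitter — so the package needs no downloads;
a directory of standard IDX ubyte files substitutes real MNIST bitmaps
(`--mnist-dir`). Skeleton strokes are dilated to a few pixels' width:
handwritten strokes are thick blobs, and without the dilation the glyphs
degenerate into thin lines that are locally indistinguishable from the
texture bars at V1m's 2x2-pixel receptive-field scale, which makes
pixel-accurate digit segmentation ill-posed. Whether a digit's ground truth should be its strokes or
a filled region is a genuine ambiguity; strokes are used because the
segmentation target needs a pixel-accurate definition.

Region analyses partition the canvas around one object: `figure` is the
mask eroded by 2 px, `edge` the 2 px band on each side of the contour
(square connectivity), `ground` the rest, and pixels of other objects are
`excluded`. The 2 px edge half-width matches the 2x2-pixel V1m receptive
fields, so the edge band spans about one RF.

## Training

Phase 1 trains the feedforward pathway alone for multi-label
classification (sigmoid + binary cross-entropy on the 12 logits; Adam,
learning rate 0.001, weight decay 0.0005; reference schedule 2,500 epochs
at batch 1024). Phase 2 freezes every feedforward parameter (enforced by
checksum) and trains the feedback pathway for attention-conditioned
segmentation (same optimizer; reference schedule 2,500 epochs at batch
256): per example an attended class is sampled uniformly from the classes
present, the target map is 1 on that class's pixels and 0 elsewhere, and
pure-texture background pixels are excluded from the pixelwise
cross-entropy. Keeping non-attended object pixels in the loss as
0-targets is what teaches the network to suppress unattended objects; a
config flag switches to the stricter reading that ignores everything
outside the attended object.

Evaluation uses three measures: the per-image classification absolute
error (sum of |score - label| over the 12 classes, range 0-12), the
pixel-wise absolute error (mean |map - 1| over attended-object pixels,
range 0-1, background not counted), and the background false-labeling
rate (fraction of true background pixels above threshold 0.5).

## Numerical engine

No deep-learning framework is used: `segnet.nn` is a self-contained
float32 numpy engine (im2col and direct-loop convolutions, transposed
convolutions, batch normalization, Adam) with hand-written backward
passes. Convolution has three execution paths — a plain GEMM for 1x1
kernels, numba direct loops for stride-1 kernels, and channels-last
im2col + GEMM otherwise — which are cross-checked against each other in
the test suite and against finite differences during development.
Training is deterministic for a fixed seed (single-threaded BLAS,
seeded `numpy.random.Generator` everywhere).

## Time-stepped propagation

To study response dynamics the trained network runs under wavefront
semantics: activity crosses exactly one connection per discrete step.
Each processing stage recomputes its output every step from its
predecessors' previous-step values. The default granularity is per-area
(input -> V1m -> V2m -> V4m -> ITm -> FCm -> feedback head -> V4m mirror
-> V2m mirror -> V1m mirror: a 9-connection loop); a per-layer mode
splits each area into its three blocks/mirrors (21 connections). The
total step budget defaults to twice the loop length plus 4.

The network is initialized at its full response to an i.i.d. uniform
white-noise image whose mean and standard deviation match the background
texture statistics, with the attention template already active in FCm.
The stimulus then replaces the noise and the state is stepped forward.
Because the V1m mirrors are gated by the *local* feedforward activity,
three response phases emerge with increasing latency even though there is
only a single feedback pass: a stimulus-driven transient (one connection),
figure-ground modulation (the feedback drive becomes stimulus-dependent
through the nearby mirrored areas after a few connections), and
object-based attention (the class-specific signal must cross the full
loop through FCm). This ordering is a structural prediction of the
architecture and is asserted by the temporal acceptance suite.

Traces average the channel-mean activity of the lowest V1m mirror's `b`
(configurable to `c`) over figure/edge/ground regions, with the SEM taken
across stimuli. Space-time profiles bin per-pixel traces by signed
Euclidean distance to the figure boundary (bins: far ground, ground,
edge, figure, center) and subtract the far-ground reference. Onset
statistics are computed on raw step-resolution traces; the 160-step
linear up-sampling with a 3rd-order, 7-sample Savitzky-Golay filter is
display-only.

## Scaled-down protocols

The published scores (classification absolute error 0.023, pixel error
0.0015, background false labeling < 0.1%) come from GPU-scale training on
MNIST-derived data and are not reproducible on one CPU; the repository
instead fixes two desk-scale protocols (`segnet.protocols`) that the test
suite and the acceptance script rerun from scratch. Both keep the full
depth, areas and resolutions and shrink only channel counts.

*Smoke protocol* (run for three seeds by the test suite): texture squares
and rectangles only, 2,000 training / 300 validation stimuli, 6/12/12
area channels with 24 ITm units, 8 feedforward epochs (batch 64) and 24
feedback epochs (batch 32).

*Full-task protocol* (run by the acceptance script and the worked
example): all 12 classes, 2,000 training / 200 validation stimuli,
8/16/16 channels with 24 ITm units, 10 feedforward epochs and 64 feedback
epochs. The temporal suite places one texture square and one distractor
object per scene and directs attention either to the square or to the
distractor, at the default per-area granularity.

The feedback phase of both protocols overrides two optimizer settings of
the reference schedule (learning rate 3e-3 instead of 1e-3, weight decay
0 instead of 5e-4; both logged in the run logs). At a few thousand
optimizer steps — against roughly half a million in the reference
schedule — the reference settings leave the pathway on the
attention-blind plateau of the loss (the counted-pixel target rate is
exactly 1/2 by construction, so the plateau sits at ln 2): the L2 term
dominates Adam's normalized update for any weight whose task gradient has
not yet grown, shrinking structure faster than it forms. The feedforward
phase keeps the reference settings.

At this scale the square/rectangle discrimination itself does not become
decodable (a control with fresh stimuli generated every epoch — 20,000
unique images, memorization impossible — plateaus at the same validation
accuracy as training on the fixed 2,000), so the smoke protocol's
classification and attention-routing quality is intrinsically limited;
the full-task protocol, whose digit classes are asymmetric and locally
distinctive, is the one that develops attention-selective feedback.

## Known limitations

- A single feedforward and a single feedback pass; no full recurrence,
  no lateral connections, no dorsal/thalamic routes.
- The procedural glyphs are cleaner than handwritten digits; models
  trained on them will not transfer to real MNIST without retraining.
- The generator's textures are statistically stationary bars; real
  texture-segregation stimuli vary element shape and density.
- At desk scale the square/rectangle discrimination generalizes far less
  well than the published full-scale classification, which bounds what
  the scaled-down end-to-end check can demonstrate about the full model.
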