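# Methods

## Problem and model

`nucseg3d` segments bright, roughly convex nuclei in single-channel 3D
microscopy volumes without labeled training data. The method rests on two
assumptions about such data: nuclei contrast locally with their
surroundings, and intensity is spatially coherent (neighbouring voxels of
the same structure have similar values). Both are consequences of how
fluorescence volumes are formed — stained nuclei are bright and compact,
and the optical point-spread function smooths everything it images.

The segmentation network is a pair of 3D U-Nets. The encoder produces a
per-voxel categorical distribution over K classes (K = 2 by default); the
decoder receives those probabilities and reconstructs the input volume.
Both are trained jointly by one objective:

    L = w_ncuts * SoftNCuts(p, I) + w_rec * Rec(decoder(p), I)

updated in a single backward pass.

### The Soft Normalized Cuts term

The volume is a graph: voxels are nodes, and voxels u, v closer than a
radius r (strict Euclidean inequality, so r = 2 includes the full
26-neighbourhood) are joined by an edge of weight

    w(u,v) = exp(-(I(u)-I(v))^2 / sigma_I) * exp(-||X(u)-X(v)||^2 / sigma_X)

Note both squared terms are divided by sigma, not sigma squared. The hard
normalized cut — sum over classes of (weight leaving the class) /
(total weight touching the class) — is relaxed to soft memberships:
numerator `sum p_k(u)(1-p_k(v))w(u,v)`, denominator `sum p_k(u)w(u,v)`.
Self-pairs (u = v, weight 1) are included in both sums, contributing
p(1-p) to the numerator; the loss then lies in [0, K], the uniform
assignment scores exactly K-1, and hard partitions recover the hard
normalized cut. A class whose total association falls below 1e-8
contributes 0 (degenerate empty class) rather than NaN.

The implementation aggregates per offset (26 shifted products plus the
self term) rather than building the graph; a brute-force O(N^2) double sum
is kept in the test suite as the oracle, and the analytic gradient is
checked against central finite differences.

Intensities are remapped affinely to [0, 100] before training
(`remap_intensity`); sigma_I = 1 is calibrated to that range, sigma_X = 4
and r = 2 are the defaults. With sigma_I = 1, voxels differing by more
than ~3 intensity units are effectively disconnected — the graph encodes
"locally flat" regions. This is also why spatial coherence matters: if the
background were voxel-independent noise with a spread of several units,
the graph would disconnect everywhere and the cut term would carry no
structure.

### The reconstruction term and loss balance

The decoder must reconstruct the [0, 100] volume from the K probability
maps; the error is plain MSE on that scale (or BCE, in which case the
target is rescaled to [0, 1]). Because MSE on a [0, 100] range sits in the
tens-to-thousands while the cut term is at most K, the weighted sum with
w_rec in [5e-3, 0.5] is reconstruction-dominated. That is deliberate and
necessary: with K = 2 the cut objective alone has many near-zero minima —
any partition whose boundary follows iso-intensity surfaces, including
splits of the background into broad regions of slightly different
brightness. The reconstruction term selects, among those, the partition
most informative about the image, which for sparse bright objects is
nuclei-vs-background (the best 2-level quantization of the histogram).
Defaults are w_ncuts = 0.5 and w_rec = 0.5; the cut term still matters —
it sharpens memberships toward hard assignments and penalizes spatially
incoherent label noise. When adapting to new data, w_rec (within
[5e-3, 0.5]) and the learning rate (within [2e-5, 2e-3]) are the two knobs
worth moving; the loss history records both raw terms per epoch so their
relative magnitudes can be inspected after a warm-up epoch.

### Architecture

Each U-Net has seven blocks over three resolution levels (three 2x
max-poolings down, three 2x2x2 stride-2 transpose convolutions up): three
descending blocks, a bottleneck, three ascending blocks, with the
descending outputs concatenated to the matching ascending inputs. A block
is two 3x3x3 convolutions, each followed by ReLU and group normalization.
Two choices here were genuinely open and are worth recording:

- **Normalization in the outer blocks.** Group normalization is applied in
  all seven blocks, not only the middle five. Without it, raw
  [0, 100]-scale activations reach the 1x1x1 softmax head, which saturates
  at initialization and collapses training to a constant output (verified
  by a supervised overfit check).
- **Reflect padding.** The 3x3x3 convolutions use 1-voxel reflect padding
  instead of zeros. Zero padding gives border voxels a distinctive
  signature, and a self-supervised objective happily builds a "border"
  class out of it (observed as misclassified slabs along volume faces);
  reflect padding removes the cue.

Feature widths default to 64/128/256 (bottleneck 512) and are configurable
down to 8/16/32 for CPU-scale runs; group count defaults to 8, clipped to
the channel count. Encoder head: 1x1x1 convolution + channel softmax;
decoder head: 1x1x1 convolution, linear. Using three levels instead of
four keeps the parameter count down (the test suite checks the three-level
model is strictly smaller than the four-level extension of the same
widths).

The layers, Adam, and reverse-mode autodiff are implemented in NumPy
(`_autodiff.py`), with convolutions as im2col matrix products in float32;
the engine's operators are finite-difference checked in float64. Gradients
of the cut term enter the tape through its analytic gradient.

### Training protocol

Volumes are remapped to [0, 100] (no percentile normalization in the
self-supervised path), tiled into cubic patches (64 default; the last
window per axis is shifted to end at the boundary), augmented by random
axis flips and 90-degree rotations only — transforms that preserve the
intensity histogram exactly — and batched (batch size 2). Adam with a
constant learning rate (default 2e-5; up to 2e-3 for small, high-contrast
data), 50 epochs by default. With a fixed seed, training is bit-for-bit
reproducible: all randomness flows from one `numpy` generator, and every
operator is deterministic.

Inference uses sliding windows (window 64, 25% overlap) with uniform
averaging of overlapping predictions and per-voxel renormalization;
volumes are reflect-padded to multiples of 8 and cropped back.

Self-supervision fixes no class identity, so the foreground class is
chosen post hoc as the class whose probability correlates positively with
intensity (`select_foreground_class`, overridable). The probability
threshold is estimated per training fold: for each (prediction, labels)
pair the Dice-maximizing threshold on a 0.05..0.95 grid (ties toward the
lower value; degenerate endpoints excluded), averaged across pairs.

## Instance segmentation

`voronoi_otsu_label` re-implements Voronoi-Otsu labeling on
scipy/scikit-image primitives: Gaussian smoothing at `spot_sigma` and
regional maxima (one seed per connected plateau) for seeds; Gaussian
smoothing at `outline_sigma` and Otsu's threshold (256 bins) for the mask;
seeds outside the mask dropped; mask voxels assigned to the nearest seed
by Euclidean distance transform. No seeds yields an all-zero map, not an
error. Defaults (0.65 / 0.65) suit nuclei a few voxels in radius.
Connected components and distance-transform watershed are available as
alternatives; connectivity is 26 throughout.

Post-processing operators, applied in the order threshold → label →
closing → border merge → size filter:

- `morphological_closing`: ball-structured dilation then erosion, with
  padding so border behaviour matches an unbounded background.
- `merge_labels_by_border_intensity`: for each 26-adjacent label pair, the
  mean intensity over border voxels (both sides); pairs with means inside
  [35, 100] (on the [0, 100] scale) are merged transitively via
  union-find. This fuses over-split bright objects while leaving dim
  contacts alone.
- `filter_by_volume`: removes labels whose voxel count falls outside
  [min, max] — the documented remedy for a label-free detector having no
  concept of "cell" when artifacts are present.

## Evaluation

Pairwise IoU between instances is computed from a contingency table.
Matching at threshold tau is a maximum-cardinality, then maximum-total-IoU
one-to-one assignment over pairs with IoU strictly greater than tau
(Hungarian algorithm on a shifted score; verified against exhaustive
search over all assignments). F1 = 2TP/(2TP+FP+FN) with precision and
recall, over tau = 0.1..0.9 step 0.1, plus the mean. F1 without an IoU
threshold equals the Dice score on the semantic masks; two empty masks
score Dice 1, and a matching with no predictions and no ground truth
scores F1 1 (both conventions tested).

## Synthetic data

The generator (`synth.py`) produces what the method assumes: axis-aligned
ellipsoidal nuclei (semi-axes drawn from `radius_range`, default 2–6
voxels) with Gaussian radial intensity profiles peaking at 60–100 units,
centers rejection-sampled to respect a minimum separation (capped at
10,000 attempts, then an error — never silent under-placement), on a
background of level 5, optionally with a smooth background gradient, a
brightness halo around each nucleus, and cylindrical bright streaks
mimicking clearing artifacts (placed away from nuclei by default, with
the artifact mask returned for evaluation-time exclusion). The scene is
blurred by a Gaussian PSF (sigma 1 voxel) and detector noise is added
after the blur (Gaussian, sd 0.5, or Poisson). Instance labels are the
exact pre-blur ellipsoid supports, so ground truth is exact by
construction.

What the generator does **not** emulate: anisotropic voxel size, realistic
light-sheet PSF structure (stripes, shadowing), tissue autofluorescence,
nucleus texture, or densely packed touching nuclei. Passing the bundled
tests therefore demonstrates that the implementation is correct and that
the method behaves as described under its stated assumptions — not that it
will reach the same scores on arbitrary real microscopy.

## Scaled-down study sizes

The bundled end-to-end checks train a small model (widths 8/16/32) on four
32-cube volumes of ~15 nuclei for 25 epochs with 16-voxel patches, batch
size 2, learning rate 2e-3, w_ncuts = w_rec = 0.5 — about two minutes on
one CPU core — and evaluate on a fifth, held-out volume (semantic Dice
typically 0.8–0.9). Sixteen-voxel patches are used at this scale because,
at equal compute per epoch, they give four times as many gradient steps as
32-voxel patches, which the small-data optimization needs. The instance
pipeline check uses 30 well-separated nuclei in a 64-cube volume with the
0.65/0.65 sigmas. `scripts/acceptance.py` re-runs all of this from scratch
and writes the measured numbers as JSON.

## Numerical choices and degenerate inputs

- Affinity cutoff is strict (`distance < r`), evaluated on squared
  distances; at r = 2 this includes the (1,1,1) diagonal offsets
  (sqrt(3) < 2).
- Truncated neighbourhoods at volume borders are not renormalized.
- Constant volumes: `remap_intensity` maps to all-lo; Otsu raises.
- Empty classes in the cut term contribute 0 (1e-8 guard).
- Regional-maxima plateaus produce one seed per connected plateau.
- Max-pool gradients flow to the first argmax on ties.
- Checkpoints are deterministic zip archives (fixed timestamps) holding
  weights plus the architecture and training configs, so a checkpoint is
  self-describing and identical runs produce byte-identical files; loading
  validates the stored architecture against the expected one.
- Training aborts with a diagnostic naming the epoch if the loss goes
  non-finite.
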