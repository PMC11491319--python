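# Methods

This note documents the models and procedures implemented in `lungcbo`,
the choices made where the design was open, and what the synthetic data do
and do not show.

## Synthetic phantoms

Each phantom is an 8-bit 2-D slice emulating the gross statistical
structure of a chest CT section: a bright soft-tissue background
(default level 180), two dark elliptical lung fields (level 70, semi-axes
0.32·N vertical and 0.18·N horizontal at image size N), and one circular
nodule of configurable radius centered in the left lung. The nodule is
rendered soft-tissue-dense — 30 levels above the background — making it
the brightest structure in the slice, as an intrapulmonary solid nodule is
relative to the surrounding aerated lung. Two acquisition artifacts are
layered on: additive Gaussian noise (sd 4) and a low-frequency
multiplicative bias field (a half-period sine sheet, peak excursion 20
levels) that motivates histogram equalization.

Class structure: benign nodules have a smooth disk margin and mild
intra-nodule texture (amplitude 10); malignant nodules get a spiculated
margin (radial perturbation by three random angular harmonics of orders
4–8, amplitude 2.5 px) and strong texture (amplitude 45). These two knobs
separately exercise shape- and texture-sensitive stages. For classifier
experiments whose point is that the network uses *texture*, both classes
are generated with spiculation 0 so shape statistics are identical.

Per-image seeds derive from the master seed by a counter scheme
(`SeedSequence([master, index])`), so a dataset is bit-reproducible
regardless of generation order.

What the phantoms do **not** emulate: 3-D partial-volume effects, vascular
and bronchial structure, attachment of nodules to pleura or vessels,
scanner-specific noise spectra, and the intensity statistics of any real
CT archive. Passing tests on phantoms therefore demonstrate that the
pipeline's machinery is correct and internally consistent — not that its
accuracy transfers to clinical data.

## Splits

`split_dataset` apportions N records to train/val/test fractions by the
largest-remainder method: floors first, leftover items to the largest
fractional parts, ties resolved in listed order (train, val, test). At
N = 1,135 and fractions 70/10/20 this yields 795/113/227. Note 795 + 113 +
227 = 1,135 exactly; a 114-image validation set would require N = 1,136.
K-fold assignment distributes N mod k single extra items to the first
folds, so fold sizes differ by at most one.

## Histogram equalization

Input level v maps to `round((L−1)·CDF(v))` with round-half-away-from-zero
(platform-deterministic, unlike banker's rounding). No cdf-min
renormalization variant is applied, so a constant image maps to L−1 = 255.
The mapping is monotone, conserves histogram mass, and is idempotent up to
±1 level of rounding. A median filter (edge-replicated borders, via
`scipy.ndimage`) is provided as an optional second preprocessing operator;
the pipeline config selects either or both in any order, defaulting to
equalization only — with synthetic Gaussian noise of sd 4 the equalization
step dominates, and the filter's value is mainly for impulse-like noise.

## Colliding Bodies Optimization

The canonical formulation: n bodies (n even), mass m_k ∝ 1/fit(k)
normalized to sum 1; per iteration the population is sorted ascending by
fitness, the better half is stationary with zero pre-collision velocity,
and moving body i approaches its partner p with v_i = x_p − x_i.
Post-collision velocities follow 1-D collision mechanics with restitution
coefficient ε:

    v'_moving     = (m_i − ε·m_p)·v_i / (m_i + m_p)
    v'_stationary = (m_i + ε·m_i)·v_i / (m_i + m_p)

Both bodies then step from the collision site x_p (the moving body) or
their own position (the stationary body) by rand ∘ v', with rand a fresh
uniform [−1, 1] vector per body. Open design points fixed here:

- **ε schedule**: ε(t) = 1 − t/T (elastic early for exploration, plastic
  late for contraction); overridable per config.
- **Bounds**: violations handled by clipping — simplest, and it keeps
  boundary optima exactly reachable.
- **Positive fitness**: masses require fit > 0. A raw objective with a
  declared finite lower bound b is shifted to raw − b + 1; otherwise
  positive raw values are used directly, falling back to exp-rescaled
  ranks (positive and order-preserving) when negatives appear.
- The population itself is memoryless; the best-so-far is tracked outside
  the dynamics for reporting only, so the history is non-increasing by
  construction.

Defaults (population 30, 200 iterations for benchmarks; 20 and 100 for
thresholding) are engineering choices — no canonical budget exists — and
are validated by the sphere benchmark (median best fitness reaches the
global minimum 1 to ~1e−16 over 20 seeds) and by exhaustive-scan
equivalence on bilevel Otsu.

## CBO-Otsu segmentation

The Otsu criterion is the between-class variance
σ_B² = Σ_j w_j (μ_j − μ_T)² over the k+1 classes induced on the gray-level
histogram by thresholds t_1 < … < t_k (class j = levels in (t_{j−1}, t_j]).
Bilevel thresholding also ships as an exhaustive scan over all 255
candidates (tie → smallest t, matching common reference implementations);
it is the oracle the CBO route is tested against. CBO minimizes the
positive fitness 1/(1 + σ_B²) over continuous positions in [0, 254]^k;
at evaluation a position is *repaired* — rounded, clipped, sorted,
duplicates nudged to the nearest free level — rather than penalized,
keeping the search space smooth. The best repaired threshold set over all
evaluations is returned.

Nodule extraction takes connected components (8-connectivity, 0-based
(row, col), half-open bounding boxes) of a chosen foreground class,
discards components below `min_area`, and sorts by area descending. The
pipeline uses the top (brightest) class and additionally drops components
whose bounding box touches the image edge: an intrapulmonary nodule never
reaches the slice border while the body/background component always does,
so border exclusion is the candidate filter. On default phantoms this
recovers the benign nodule exactly (area 310 px vs the rasterized disk's
310) and localizes malignant nodules to sub-pixel centroid accuracy with a
modest area underestimate, because strong intra-nodule texture pushes some
pixels below threshold.

## Local binary patterns

Bit h of a pixel's code is 1 when sampling point h on the circle of H
points, radius R, is ≥ the center (G(0) = 1: ties set the bit); the code
is Σ bit_h·2^h. Convention, fixed because codes are
convention-dependent: h = 0 due east, counterclockwise ordering,
nearest-neighbor (rounded-offset) circle sampling. Borders are excluded
rather than padded — padding would fabricate texture at image edges. No
uniform-pattern reduction is applied. Codes are invariant to any strictly
monotone intensity transform, which the property tests exercise. The
per-nodule descriptor concatenates the 2^H-bin code histogram over the
nodule mask with area, equivalent diameter, centroid, and mean intensity
(261 values at H = 8).

## Classifier

A deliberately small DenseNet-style network implemented directly on numpy
(im2col convolutions, batch normalization, manual backpropagation, Adam):
initial 3×3 convolution to 16 channels; 2 dense blocks of 2 layers, each
layer BN → ReLU → 3×3 conv producing growth-rate g = 8 maps concatenated
with all earlier maps in the block; a transition (1×1 conv compressing by
θ = 0.5, then 2×2 average pooling) between blocks; BN → ReLU → global
average pooling → 2-way softmax. Input contract: grayscale resized to
64×64, scaled to [0, 1]. This configuration trains in minutes on one CPU
core; depth, growth rate, compression and input size are configurable.

Choices worth stating: inputs are the preprocessed (equalized) full
images — segmentation masks and LBP histograms are logged as auxiliary
features, not fed to the network; a probability tie at 0.5 resolves to
malignant (the conservative call for a screening-style tool); seeded runs
are reproducible on a fixed compute backend, but bit-equality across BLAS
builds is not promised.

Training defaults are 16 epochs at learning rate 5e-4 with best-validation
-epoch weight restoration (the usual early-stopping convention). The
restoration matters here: equalization stretches the dense background
noise across the gray scale, validation accuracy oscillates between
epochs on this small dataset, and the final epoch is not reliably the
best one; checkpointing on the validation split — which exists precisely
for model selection — makes the outcome stable across seeds. On 400
texture-separated phantoms (split 280/40/80) the network then reaches
perfect held-out separation on every tested seed; since both classes
share identical shape statistics in that experiment, the signal used is
necessarily textural.

## Evaluation

Malignant is the positive class. Metrics with zero denominators are
explicit nulls, never zeros — silent zeros would corrupt model
comparisons. ROC thresholds predict malignant at score ≥ t; the curve is
computed at every distinct score (no interpolation dropping) and AUC by the
trapezoidal rule, which the tests pin to the Mann–Whitney pairwise
statistic within 1e−12 including ties. Error histograms bin
(target − predicted positive probability) into equal-width bins on [−1, 1]
per data split.

## Telemetry

The channel-update adapter mirrors the public ThingSpeak convention
(api_key plus up to eight numeric fields, form-encoded POST). Metric
values are transmitted as percentages rounded to 2 decimals. The transport
is abstract: tests use an in-process mock exclusively, and the pacing
policy (minimum interval between sends, delay or reject) is enforced
client-side. Transmission failure is recorded as a status in the run
report and never interrupts the pipeline. Only scalar metrics are
transmitted — no per-patient or identifying data.

## Problem sizes and numerical notes

Default experiment sizes — 400 phantoms for end-to-end classification,
100 random 32×32 images for threshold-oracle comparison, 20 seeds for the
sphere benchmark, 16 training epochs — are chosen so the entire suite runs
on a single desk-class CPU core while leaving comfortable statistical
margins; all are configurable upward. Network arithmetic is float32;
histogram and threshold arithmetic float64. Degenerate inputs (constant
images, single-class label sets, empty regions) raise explicit errors
rather than returning sentinel values.

## Known limitations

- Phantom realism is deliberately minimal (see above); reported phantom
  metrics say nothing about clinical performance.
- The CBO threshold search is stochastic; for k = 1 it matches the
  exhaustive optimum essentially always at the default budget, but no
  guarantee exists for large k on adversarial histograms.
- Malignant nodule area is systematically underestimated by bilevel
  thresholding when intra-nodule texture straddles the threshold.
- The classifier is desk-scale by design; it is not a DenseNet-121 and is
  not intended to reproduce large-scale benchmark accuracies.
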