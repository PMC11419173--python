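# Methods

`stainshift` studies a specific failure mode of weakly supervised
histopathology classifiers: a tile-based outcome predictor trained on
slides stained in one session (a *batch*) can lose most of its
discriminative power on slides of the very same tissue stained in
another session, and color normalization only partially repairs the
gap.  The package provides (i) a generative simulator of paired-batch
H&E cohorts, (ii) the tiling/augmentation pipeline, (iii) traditional
(sparse-NMF, structure-preserving) and generative (cycle-consistent)
stain normalization, (iv) a weakly supervised tile scorer with median
slide aggregation, and (v) an evaluation harness that quantifies
same-batch versus cross-batch generalization.

## Color model

All color handling assumes the Beer–Lambert law.  With per-channel
white level I0 (255 by default), optical density is

    OD = −ln(clip(I, 1, I0) / I0)            (natural logarithm)

and an H&E image factorizes as OD ≈ W·C with

* W ∈ R^{3×2}, non-negative unit columns: column 0 hematoxylin,
  column 1 eosin.  Hematoxylin is identified as the column with the
  larger red-to-blue OD ratio W[0]/W[2]: hematoxylin looks blue-purple
  because it absorbs red light, so its OD vector is red-heavy (the
  standard published vectors, H = (0.65, 0.70, 0.29) and
  E = (0.07, 0.99, 0.11) after column normalization, satisfy this).
* C ≥ 0, per-pixel stain concentrations.

## Synthetic paired-batch cohorts

Each virtual patient owns a tissue phenotype (nuclear density, nuclear
radius, chromatin-texture amplitude, stroma fraction, tissue coverage,
hematoxylin uptake level) and a tissue seed.  Concentration fields are
procedural: a smooth thresholded Gaussian field defines the tissue
support (background margin forced empty); eosin lives in
stroma/cytoplasm; faint cytoplasmic hematoxylin (strictly below
`CYTO_H_BASE = 0.06`) is restricted to the cellular part of the tissue
because acellular collagenous stroma takes up essentially no
hematoxylin — this also keeps the deconvolution problem
well-identified, since pure-eosin pixels exist.  Nuclei are disks from
a Poisson process (expected count = density × tissue area) with
overlap rejection and a small retry budget, painted with hematoxylin
`0.85 × uptake × (1 + amp × texture)`, where `texture` is a standardized
smooth noise field with sub-nuclear correlation length (σ = 1.5 px).
Nuclei displace the eosin beneath them (×0.12).

A *batch* is a `StainProfile`: stain matrix, per-stain intensity
scales, white level, OD noise.  Batch B defaults to batch A's matrix
rotated in the stain plane (10° by default) with intensity ratio 0.8 —
batch A is the darker, more basophilic session.  Within a batch, each
slide realizes a jittered profile (rotation sd 2°, intensity log-sd
0.06): staining varies slide to slide even inside one session, and
this within-batch variability is what a flexible classifier silently
entangles with the outcome signal.  Render-noise and jitter streams
are keyed by the *profile's optical fingerprint* rather than its A/B
slot, so swapping the two profiles swaps the rendered slides exactly,
and identical profiles render byte-identical slides.

The planted outcome signal (binary Met+/Met−, exact count
`round(n × met_fraction)`) is carried by morphology by default: Met+
patients get `chromatin_texture_amp` shifted by the effect size, so the
class difference is invisible to first-order color statistics and the
stain shift acts as a pure confounder.  A `signal_channel="color"`
switch instead scales hematoxylin uptake by (1 + effect) for negative
controls.  With effect 0 both classes follow the identical generating
law.

**What the simulator does not emulate:** real nuclear morphology
(shape, clustering, mitoses), scanner optics, focus/compression
artifacts, pen marks, tissue folds, or any biologically grounded link
between morphology and metastasis — the planted texture signal is a
stand-in for an unknown prognostic feature, not a claim about biology.
Passing tests therefore demonstrate properties of the pipeline under a
controlled stain-confounded data-generating process, not performance
on real slides.

## Tiling

Tissue masks come from Otsu's threshold on the 256-bin luma histogram
(BT.601 weights), restricted to an annotation when given; tissue is
the darker class.  Ties in the between-class variance are broken
toward the smallest threshold; a single-valued histogram returns that
value with a warning.  Tiles are 512×512 windows (40× scale) whose
center pixel is mask-foreground, sampled uniformly without replacement
(with replacement, logged, only when fewer valid centers than
requested exist), then 2×2 mean-pooled to 256×256 — mean pooling is
exactly intensity-conserving, which makes the geometry testable.
Training-time augmentation is a right-angle rotation (lossless, the
granularity is otherwise unspecified), two independent flips and a
random 224×224 crop; inference uses the center crop.  Coordinates are
0-based (row, col) with half-open windows everywhere.

## Stain normalization

*Estimation.*  Background pixels (max-channel OD < β = 0.15) are
discarded; with fewer than 100 stained pixels the tile is rejected.
W is initialized from the extreme percentile angles (1st/99th) of the
projection onto the top-2 SVD plane of the OD cloud, then refined by
alternating L1-penalized non-negative coding (cyclic coordinate
descent, exact for two stains) and a multiplicative dictionary update
with column renormalization, until the relative objective decrease
falls below 1e−6 (≤200 iterations).  Because L1 shrinkage of the codes
systematically tilts the dictionary, a short unpenalized polish
(20 alternations with λ = 0) follows in the converged basin; the
worst-case angular recovery error on noise-free synthetic tiles is
re-measured by `scripts/acceptance.py` on every run.  Defaults:
λ = 0.1, β = 0.15, all exposed in `StainConfig`.

*Traditional normalization.*  The target is the arithmetic mean of the
per-tile unit stain vectors over 100 random tiles per training slide
(columns renormalized), plus per-stain robust scales = pooled 99th
percentile concentrations under the target matrix.  A test tile is
normalized by estimating its own matrix (fallback: a caller-supplied
per-slide matrix; unchanged-with-warning when too few stained pixels),
solving non-negative least-squares concentrations, rescaling each
stain row by target-scale/source-scale, and recomposing with the
target matrix — a single positive factor per stain, so per-pixel
concentration ranks (the morphology) are exactly preserved.
Normalization is applied to *test* images only; training always sees
original colors (a flag can change this).

*Generative normalization.*  A miniature cycle-consistent translator:
two fully convolutional generators (8 base channels, instance norm,
global residual skip with a near-zero final convolution, so the map
starts near identity) and two patch discriminators, least-squares
adversarial loss, L1 cycle weight 10, Adam (lr 2e−4, β1 0.5), 64×64
crops, batch 2, a fixed budget of 2,000 steps (training until the
discriminator can no longer tell domains apart has no operational
threshold; a step budget is the reproducible substitute).  Because
the generators are fully convolutional they are applied to whole
tiles directly at inference — no seam-prone tiled application is
needed.  The protocol trains one normalizer per test slide against
the pooled training tiles; a cheaper per-batch mode exists behind a
flag.  All networks are implemented in numpy with manual
backpropagation (channels-last im2col convolutions); gradients are
verified against finite differences in the test suite's development
harness.

## Tile scorer

Every tile inherits its slide's outcome label (weak supervision; no
tile-level truth exists).  The default backbone is a compact CNN —
three stride-2 3×3 convolution+ReLU blocks (8/16/32 channels), global
average pooling, a linear head and sigmoid — trained with BCE and
Adam.  Library defaults are lr 1e−4, batch 32, 10 epochs; the
reference study uses lr 3e−3, batch 16, 10 epochs, which converges on
its 900-tile training sets in about a minute on one CPU.  A slide's
progression-risk score is the *median* of its tile scores; for
even-length lists, the mean of the two middle order statistics.

## Evaluation harness

Folds are contiguous 1-based test blocks counted down from the last
subject: with (154 subjects, block 36, 3 folds) the test blocks are
119–154, 83–118, 47–82 with 118 training subjects each; subjects 1–46
are never tested, exactly as printed in such designs — no fourth fold
is invented.  Cohort randomization interleaves the two outcome classes
proportionally (largest-remainder), so contiguous blocks are
class-balanced at the cohort prevalence, matching the balanced printed
folds.  AUC is the Mann–Whitney statistic (ties count ½) computed from
ranks; accuracy binarizes at 0.5.  Significance: a one-sided
label-permutation test against the no-signal null and a one-sided
paired subject-level bootstrap for normalized-vs-original AUC, both
with the add-one rule and 9,999 resamples by default (the named
procedures are this package's choices; the printed hypotheses are
one-sided).  Bonferroni correction is α/m.  Train/test patient
disjointness is asserted at runtime in every fold.

## Reference study conditions

The desk-scale confound study (`stainshift.study`) uses 60 patients
(met fraction 0.5), morphology effect 0.25, a strong batch shift
(20° rotation, intensity ratio 0.5, OD noise 0.03), 768² slides,
20 tiles/slide, and 2 folds of 15 test subjects.  The effect size is
calibrated so same-batch slide AUC lands in the high-signal regime
such studies report (≈0.8–1.0); the within-batch jitter plus the
between-batch shift then expose the cross-batch failure: the scorer's
learned texture readout is tuned to batch A's operating point, and at
batch B's shifted colors its invariance to staining nuisance breaks,
scrambling the slide ranking.  A color-borne signal variant was
examined and behaves differently (a monotone color feature preserves
within-test-set ranking and thus AUC); it is kept as a negative
control, not as the reference condition.  With identical batch
profiles the two renderings are byte-identical and the same/cross gap
vanishes by construction.

Problem sizes throughout (60 patients, 768² slides, 20 tiles/slide,
999 permutations in the study harness, 500 simulations for test
calibration) are the package's desk-scale choices; all are plain
parameters and scale up unchanged.

## Numerical notes and limitations

* All randomness flows from explicit integer seeds through named
  derived streams (`SeedSequence`-based); identical inputs give
  byte-identical outputs, including the GAN and CNN training loops
  (single-threaded BLAS determinism assumed).
* Networks run in float32; AUC/statistics in float64.
* Degenerate inputs are defined, not fatal: single-valued histograms
  warn; tiles without stained pixels pass through normalization
  unchanged with a warning; too-crowded nucleus placement accepts the
  last candidate after a bounded retry budget.
* The cycle-consistent normalizer at this scale corrects global color
  statistics; it does not model the morphology-altering failure mode
  that full-size generative normalizers can exhibit beyond what its
  small capacity implies.
* `resnet18`/pretrained backbones are not available in this build; the
  compact CNN is the supported scorer.
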