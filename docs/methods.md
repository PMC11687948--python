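# Methods

`taximage` classifies host phenotypes from microbiome relative-abundance
tables by first re-expressing each sample as a small single-channel image,
then training a residual convolutional network with spatial attention, and
finally projecting the network's class saliency back onto taxa, metabolites
and functional traits.  This note records the model, its assumptions, the
numerical choices, and what the bundled simulator does and does not emulate.

## Taxa-to-image transformation

**Similarity.** Each taxon gets a feature vector in one of three modes:
`metabolic` (its row of the taxa × metabolite annotation table, used exactly
as loaded), `abundance` (its standardized relative-abundance profile across
samples), or `combined` (column-z-scored concatenation of both).  Two
pairwise-distance modes are also available: `pearson`/`spearman`
(d = 1 − r of abundance profiles; zero-variance taxa get the uninformative
r = 0 so embeddings never receive missing values) and `cophenetic`
(path-length distance between leaves of a user-supplied phylogeny; edges
without branch lengths count as 1).

**Embedding.** t-SNE or UMAP maps taxa to the plane (distance matrices go
through the precomputed-metric pathway).  Both are seeded and deterministic
given that seed.  Defaults follow the embedders' conventions: perplexity 30,
`n_neighbors` 15, `min_dist` 0.1.  Accuracy is empirically insensitive to
these choices (the acceptance suite sweeps perplexity ∈ {5, 30, 50} and
`n_neighbors` ∈ {5, 15, 25} and requires the spread ≤ 0.10).

**Rasterization.** The point cloud is enclosed by its minimum-area rotated
rectangle, found by rotating calipers on the convex hull (one rectangle edge
is collinear with a hull edge, so only hull-edge angles need testing; a
0.01°-step brute force agrees to < 0.1% relative area).  Coordinates are
rotated into the rectangle frame and binned onto an H × W grid (default
32 × 32; the experiments below use 16 × 16 for cross-validation sweeps and
24 × 24 for interpretability, trading resolution for runtime).  Bins are
half-open except the last (points on the far edge clamp into the final
pixel).  Collinear or single-point embeddings pad the degenerate axis to
10⁻⁶ of the long axis.  Taxa landing in the same pixel are *summed*, so
each raw image's pixel total equals 1 exactly — compositional mass is
conserved, and the invariant is asserted in tests.  The stack is divided by
the global maximum pixel value of the *training* data; the constant is
stored and reused for held-out samples so train and test images are
comparable.  Collision counts are logged because co-located taxa are
indistinguishable downstream: at small image sizes a pixel can hold a
double-digit number of taxa, which caps interpretability resolution.

## Network

Input images pass through an optional concave rescale (default: square
root), which lifts low-abundance pixels relative to the dominant taxon
while keeping zeros at zero and empty pixels uninformative.  This view is
attached to the model and applied identically during training, prediction,
saliency and occlusion.  The square root (rather than a per-pixel z-score)
is deliberate: it preserves the sign convention that *presence is bright*,
which keeps feature detectors oriented toward elevated taxa and makes the
saliency maps read as "what is abundant here drives this class".  A
per-pixel standardization option exists but is off by default.

Architecture: a 3 × 3 stem convolution, then residual blocks given as a
plain list of (filters, kernel, stride) triples, then global average
pooling and a linear softmax head.  Each block runs, in order: convolution,
batch-norm, ReLU, convolution, batch-norm, spatial attention, shortcut
addition, ReLU.  The spatial attention gate is the CBAM construction:
channel-mean and channel-max maps are concatenated and passed through a
single 7 × 7 convolution and a logistic function, giving a per-location
gate in (0, 1) multiplied into the main branch before the shortcut join.
The shortcut is the identity, or a strided 1 × 1 convolution + batch-norm
when shape changes.  Convolutions use same padding, so spatial size shrinks
as ⌈h/stride⌉ and never collapses.

The whole network — forward, backward, Adam with decoupled weight decay —
is implemented in NumPy with im2col convolutions and analytic gradients
(verified against central finite differences in both batch-norm modes).
Defaults: two blocks (16, 3, 1)/(32, 3, 2) — experiments here use the
lighter (8, 3, 1)/(16, 3, 2) — Adam lr 10⁻³, weight decay 10⁻³ (skipping
biases and batch-norm parameters), batch 32, cross-entropy with optional
inverse-frequency class weights, a 15% stratified validation split, early
stopping on validation loss with patience 10–12, best-validation parameters
restored.  On these sparse images the loss surface shows a long initial
plateau (validation loss can sit flat for ~20 epochs before dropping), so
early stopping is armed only after `min_epochs` (default 25) — without the
floor, occasional folds stop inside the plateau and degenerate to
single-class predictions.  Everything is seeded; identical seeds give
bit-identical models.

**Cross-validation.** Stratified k-fold (default 5, optionally repeated).
The entire representation — similarity, embedding, pixel map, normalization
constant, input view — is refit on each training fold and applied frozen to
the held-out fold.  Held-out labels can never influence training (asserted
by a parameter-hash test).

## Saliency and back-projection

Grad-CAM on the class logit: gradients at a chosen residual block's output
(default: the last block, i.e. after its attention-gated branch, shortcut
and activation) are spatially averaged into channel weights; the rectified
weighted channel sum is bilinearly upsampled to image size and
max-normalized.  Per-class maps average the per-sample maps of all samples
bearing that label; maps are normalized to max 1 *before* averaging and the
mean is renormalized — a convention (each sample contributes equally), not
a claim of fidelity to any particular reference.  Each taxon inherits the
saliency of its pixel, so co-located taxa tie by construction and the
shared-pixel count is reported alongside the scores.  "Important" taxa are
those at or above a percentile (default 90th) of the nonzero scores; ties
at the threshold are kept.  An occlusion map (drop in class probability
when zeroing each pixel) provides a gradient-free cross-check; saliency and
occlusion correlate positively on held-out samples.

A caveat the simulation experiments surfaced: because relative abundances
are compositional, spiking a taxon subset necessarily *depresses* every
other taxon after renormalization.  When the spiked subset carries a large
share of community mass, that echo is itself discriminative, and a
classifier may legitimately attend to unspiked taxa; on such draws
saliency-based recovery of the spiked set degrades.  The acceptance check
therefore takes the median over five independent simulations.

## Downstream interpretation

Metabolite sums: for each group of important taxa, annotation columns are
summed over the group (binary annotations ⇒ producer counts) and metabolites
at or above a within-group percentile (default 99th) of the nonzero sums
are retained, plus the cross-group intersection.  Differential metabolites:
log₂ of pseudocounted group means (ε = 10⁻³), a two-sided rank-sum test per
metabolite between important and unimportant taxa (Welch t available),
Benjamini–Hochberg adjustment, and columns sufficient for volcano and MA
views, with "expression" proxied by mean annotation weight.  Trait
summaries count gram status, motility and oxygen tolerance per taxa set
(taxa absent from the trait table count as "unknown", conserving set sizes)
and report the median gene count over known values.

## Simulator

The generator emulates sparse compositional 16S count data.  A lognormal
rank-abundance template (σ = 2) is the expected composition; differential
abundance multiplies a chosen taxon subset by a fold change in the case
class and renormalizes.  Per sample, taxon intensities are gamma-distributed
around the template (CV 0.3 by default), a Bernoulli dropout sparsifies the
vector, and the fixed library (10,000 reads) is drawn *without replacement*
from an urn of 100 × library_size balls apportioned by largest-remainder
rounding of the normalized intensities — so column sums are exact and
sampling zeros arise naturally.  Dropout probabilities are
abundance-weighted, pᵢ = min(1, c/(1 + templateᵢ · library)), mimicking
detection-limit zeros that concentrate in rare taxa; the scalar c is
calibrated by a 200-sample pilot plus bisection so the expected overall
zero fraction hits the target sparsity (realized sparsity is monotone in
the target and within ±0.03 at the 0.78–0.89 levels of interest).  Crossed
designs add cohorts by perturbing the template with lognormal noise
(σ = 0.3) per cohort, yielding `phenotype|cohort` labels.  Annotation
tables give differentially abundant taxa an enriched "signal" metabolite
block (default: produced with probability 0.9 vs 0.2 background); trait
tables draw categorical traits and gene counts uniformly in [1500, 6000].

What the simulator does **not** emulate: taxon–taxon ecological
correlations beyond compositional closure, phylogenetic signal in
abundances, batch effects, variable library sizes, and annotation databases
with realistic coverage gaps.  Passing tests therefore demonstrate that the
pipeline recovers planted signal under controlled sparsity and effect
sizes — not performance on any real cohort.

## Experiment sizes and numerical choices

The bundled experiments use 200 taxa, 60 samples per class, 45
differentially abundant taxa, target sparsity 0.8, fold changes
{1, 1.5, 2, 4}; cross-validation sweeps run at 16 × 16 with up to 50
epochs, interpretability runs at 24 × 24 with up to 40 epochs, both with
the light two-block architecture — sizes chosen so a single-core run of the
whole battery stays comfortable while leaving the conclusions unchanged at
larger settings.  t-SNE uses 400–500 iterations with random init (required
for the precomputed-distance path and kept for feature inputs so both paths
share a convention).  Distance matrices are symmetrized and clipped to
[0, 2] against floating-point drift; all-zero saliency maps are left at
zero rather than normalized.  Chance-level bands for two balanced classes
are read as [0.4, 0.6].

## Known limitations

Taxa identifiers join by exact string match — no taxonomy harmonization.
Image layouts are dataset-wide but embedding-seed dependent; compare runs
only at a fixed seed.  Multiple taxa per pixel tie in importance by
construction.  The NumPy network targets small inputs (tens of pixels per
side, hundreds of samples); it is not a GPU substitute.  Compositional
echo (above) can divert saliency when spiked mass is large.
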