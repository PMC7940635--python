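# Methods

## Signal model and preprocessing

A sequencing read reports a Tn5 transposase insertion. The insertion site is
recovered from the read's first aligned base with the conventional
strand-specific offsets (+4 bp on the plus strand, −5 bp on the minus strand,
where the first base of a minus-strand read is its rightmost aligned base,
`end − 1` in the half-open coordinates used throughout). Each cut site is
extended symmetrically — ±100 bp for accessibility tracks, ±5 bp for
footprinting — and accumulated into a per-base coverage track; a site
contributes a window of exactly `2·ext + 1` bases, truncated at chromosome
ends rather than dropped.

Peak labels for training come from the clean track alone: each base's coverage
(rounded to the nearest integer) is scored as `−log₁₀ P(X ≥ obs)` for
`X ~ Poisson(λ)` with λ equal to the genome-wide mean of the clean track (the
uniform "equal coverage everywhere" control). Scores are capped at 350 to
avoid double underflow. Bases above the cutoff (default 3) are segment-called
with the same caller used at inference time: runs of above-threshold bases,
gaps ≤ `max_gap` (default 30 bp) merged, segments < `min_len` (default
200 bp) dropped. These two defaults are not printed by the upstream
literature for the labeling step; they are exposed in every API that uses
them, and the label-time and inference-time callers are deliberately one code
path so the two stages can never drift apart.

## Windows

Each chromosome is tiled into non-overlapping intervals (default 50 kb; the
final partial interval is kept) and every interval is expanded by a `pad`
(default 5 kb) of real flanking context so the convolutional stack can
predict every central base. Windows are fixed-length — `interval_len + 2·pad`
— with zeros beyond chromosome bounds, including the zero-extension of a
final partial interval; each example records its true central span for
stitching. Channel 0 is noisy coverage; optional channels are binary motif
indicators on the forward and reverse strands (for cross-modality prediction
of factor binding from accessibility plus motif locations).

## Network

Residual blocks contain three same-length dilated convolutions with ReLU
activations and an identity skip (a learned kernel-1 projection when channel
counts differ); a ReLU follows the addition. The regression stage (default 5
blocks, 15 filters, kernel 51, dilation 8) ends in a kernel-1, single-filter
convolution with ReLU, so predicted coverage is nonnegative and the stage's
receptive field is set entirely by the 15 dilated layers:
`1 + 15·(51−1)·8 = 6001 bp`. The classification stage (default 2 blocks)
consumes the denoised signal itself — not the hidden features — and ends in a
kernel-1 convolution with a sigmoid. There is no batch normalization.

Two choices here are this package's own, made because the classification head
must learn within a few hundred optimizer steps at desk scale:

- **log1p compression.** Raw coverage spans orders of magnitude (0 to
  hundreds); feeding it directly to the classification stage produces initial
  pre-activations in the thousands and a saturated sigmoid that gradient
  descent cannot rescue quickly. The classification stage therefore reads
  `log(1 + ŝ)`. The transform is fixed and strictly monotone, so the peak
  probability remains a function of the denoised signal.
- **Uncommitted head initialization.** The classification output layer is
  zero-initialized, and at the start of training its bias is set to
  `logit(π)` where π is the training-label prevalence (prior-probability
  initialization). Without this, the first gradient steps reduce the global
  positive rate by pushing down the largest (peak) activations, and the head
  settles into an inverted ranking it cannot escape in a short schedule; with
  it, the rate-matching gradient vanishes at step one and the first weight
  updates are purely discriminative.

All layers, backpropagation and Adam are implemented on numpy (im2col views
feeding BLAS matrix products, float32 by default). Every backward pass is
validated in the test suite by float64 finite differences — exhaustively per
layer, and end-to-end in an all-positive weight regime where the network is
locally smooth (ReLU kinks otherwise contaminate numeric derivatives).

## Loss

Per window: `MSE(ŝ, s)`, `1 − r(ŝ, s)`, and `BCE(p̂, y)`, combined with
nonnegative weights (default 1 each) and averaged over the batch. If either
vector of the Pearson term is constant (e.g. an all-zero window), `r` is
defined as 0; the denominator carries an ε of 1e−8, and BCE probabilities are
clamped at 1e−7. The loss covers the full padded window by default (pads
carry real or zero context); an option restricts it to the central interval.

## Training

Examples are split by chromosome: validation chr20 (human) or chr11 (mouse),
holdout chr10, all else training. Adam (lr 2e−4, standard betas), batches of
64, 25 epochs, examples reshuffled each epoch from a seeded generator, and
the validation set evaluated after every epoch; the returned model carries
the parameters of the epoch with the lowest total validation loss (a config
switch selects on validation AUPRC instead). A non-finite loss aborts with a
diagnostic rather than training through NaNs. Given fixed seeds the entire
run — histories, checkpoints, forwards — is bit-reproducible on one thread.

## Inference and peak calling

Genome-wide application runs each padded window and keeps only the central
interval, so every base gets exactly one prediction. With
`pad ≥ (rf_regression − 1)/2 + (rf_classification − 1)/2` the stitched result
is independent of the tiling: it equals a single window covering the whole
chromosome. Note that a *raw* whole-chromosome forward pass differs from any
padded-window pass within one receptive field of a chromosome end — stacked
same-padding convolutions implicitly zero intermediate activations at the
array edge, whereas a padded window computes them — so the conservation
property is stated, and tested, against the single-window reference; away
from chromosome ends the two references agree exactly.

Peaks are bases with probability strictly greater than 0.5 (strict, so an
exactly ambivalent sigmoid output is excluded), gap-merged and
length-filtered as above, each annotated with its maximum value and the
leftmost position attaining it (the summit).

## Evaluation

Pearson, Spearman (average ranks on ties) and MSE compare denoised to clean
tracks genome-wide and stratified inside/outside a region mask; AUPRC and
AUROC score the per-base probabilities against labels across all thresholds.
AUROC uses the tie-corrected Mann–Whitney formulation and AUPRC the step
integration over distinct thresholds (no interpolation); both are checked
against O(n²) brute-force enumerations in the tests. Constant inputs yield an
explicit undefined flag, never NaN.

## Differential accessibility (background-ensemble z-scores)

Background subsamples are denoised, normalized to a common genome-wide total
(the ensemble mean of raw totals by default), and reduced to per-base mean
and unbiased sd via Welford's streaming algorithm (one track of memory;
identical tracks give exactly zero variance). A sample normalized to the same
total is scored as `z = (x − μ)/σ` inside the regulatory mask (single-base
TSS positions expanded ±100 kb and merged); bases with σ = 0 get z = 0 and
never seed regions. Bases with |z| > 2 within 200 bp of one another merge
into regions; each region's signed top z becomes a two-sided normal p-value
(the conservative choice — both signs are kept at selection); BH correction
is applied per sample across its regions and calls with q < 0.05 are kept,
then filtered by a minimum sample coverage (default 1 normalized unit,
configurable; the filter removes regions invisible to conventional analysis).

A calibration caveat worth knowing: with `z_cut = 2` every candidate region
has `p = 2Φ(−|z|) < 0.0455` by construction, so BH at FDR 0.05 cannot reject
any candidate at these defaults — the BH step only bites for lower cutoffs or
stricter FDRs. False-positive control in practice rests on the selection
threshold itself, on the spatial smoothness of denoised tracks (which keeps
null exceedances rare and localized), and on the coverage filter. The test
suite therefore exercises the null regime with smooth, sub-σ-deviating
samples — the regime the procedure presumes — and verifies exact spiked-region
recovery there; with base-pair-independent null noise at a dense mask, any
|z| > 2 excursion becomes a permanent discovery, which is a property of the
procedure, not of this implementation.

## Synthetic data

The simulator emulates what the method assumes about real data: cut sites as
a homogeneous Poisson background (default 0.05 sites/bp) multiplied ~10× in
non-overlapping peaks (60 per chromosome, 300–1500 bp, placed by rejection
sampling with a bounded retry cap), fixed 36 bp reads with fair-coin strands,
optional uniform cell barcodes, binomial thinning of reads or read pairs
(pairs never split), and flat-top peaks with central dips for footprint
fixtures. All outputs are a pure function of (spec, seed) through one PCG64
generator. Not emulated: fragment-length structure, Tn5 sequence bias,
duplicates, doublets, barcode errors. Passing tests on this generator shows
the pipeline recovers structure under the model's own assumptions — it does
not certify performance on real chromatin, where noise is non-Poisson and
peak shapes are irregular.

## Problem sizes for the recovery experiment

The synthetic-recovery run uses a 3 Mb genome (2 Mb training chromosome plus
512 kb validation "chr20" and holdout "chr10"), thinning p = 0.1, 25 kb
tiling with 600 bp pads, and a compact network (2 regression blocks, 1
classification block, 8 filters, kernel 25, dilation 4; receptive field
577 bp) trained 10 epochs with lr 2e−3 and batch 8 — a step size scaled to
the short schedule, since Adam's per-step displacement is ≈ lr and the
reference schedule assumes thousands of steps. On this fixture the trained
model improves holdout Pearson r (≈ 0.90 → 0.94) and base-pair AUPRC
(≈ 0.96 → 0.99) over the noisy data, the directional analogue of the
method's headline behavior.

## Known limitations

- Chromosome-end bases (within one receptive field) are predicted from
  zero-extended context; at default scales that is 6 kb per chromosome end.
- The per-base Poisson labeler uses a single genome-wide λ; it has no local
  background correction, so broad enriched domains label as peaks.
- The BH step is vacuous at the default z-score parameters (see above).
- Coverage values are treated as exchangeable across chromosomes during
  normalization; no GC or mappability correction exists anywhere.
- bigWig input requires the optional pyBigWig dependency; bedGraph is the
  canonical format.
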