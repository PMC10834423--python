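# Methods

## Overview

`cnnee` identifies enhancers from multi-omics signal and annotates the
enhancer RNAs (eRNAs) they transcribe.  The pipeline has two halves:

1. **Enhancer prediction.**  A 1-D convolutional network classifies 4 kb
   genomic windows from a 4 × 400 input matrix — four assay rows (ATAC-seq,
   H3K27ac, H3K4me3, RNA coverage) by 400 columns of 10 bp bins, each bin
   the mean signal over its bases.  Windows with predicted probability
   > 0.5 are passed to Grad-CAM, which maps each window's classification
   evidence back onto the 400 bins; runs of bins at or above the window's
   mean importance become refined enhancer intervals.  Refined intervals are
   merged across overlapping windows and calls overlapping a transcription
   start site are removed.
2. **eRNA annotation.**  Each enhancer seeds a 6 kb eRNA region (± 3 kb
   around its midpoint, excluding regions that touch protein-coding exons).
   Region read counts are normalized between samples by TMM and within
   samples to RPM over the effective library.  eRNAs are then classified
   (detectable: tissue-mean RPM ≥ 1 somewhere; tissue-specific: one tissue
   strictly above 3× the mean of the other tissues' means; housekeeping:
   ≥ 1 everywhere, split into low/medium/high variability at the quartiles
   of the coefficient of variation), associated with target genes (< 1 Mb,
   Spearman |ρ| ≥ 0.3, P < 0.05) and transcription-factor regulators (same
   gate, no distance filter), tested for QTL-trait enrichment (2 Mb windows,
   two-sided Fisher exact test against shuffled-region background), and
   filtered for cross-species conservation (BLAST identity ≥ 0.5,
   E ≤ 1e-5, best hit per query).

## Classifier

### Architecture

Six catalogued architectures share one layout and differ only in layer
counts (conv, max-pool, dense): model 1 (6, 1, 1), 2 (7, 2, 1), 3 (6, 2, 1),
4 (7, 3, 1), 5 (1, 1, 1), 6 (5, 1, 1).  Every convolution (same padding,
default kernel 5 bins) is followed by a squeeze-and-excitation block: global
average pool over positions, a two-layer bottleneck (reduction 4) with a
sigmoid gate, and channel-wise rescaling.  Max-pool layers (size 4) follow
the earliest conv blocks.  Channel widths default to 16 doubling per layer
with a cap at 64 — wide enough to separate the planted signal classes,
narrow enough that training six architectures on one CPU stays in seconds to
minutes.  All of this is configurable through `ModelSpec`; the layer counts
are the only fixed facts.

The dense head sits on a **temporal global average pool**, not a flatten.
This is a deliberate design choice with two consequences.  First, the
classifier is translation-invariant over the window, which is the right
inductive bias for sliding-window scanning (an enhancer is an enhancer
wherever it sits in the 4 kb frame).  Second, it makes the Grad-CAM
formulation exact: with a GAP head the globally averaged gradient of the
score with respect to a channel's activation map equals that channel's dense
weight (over L), so the weighted activation sum *is* the class evidence map.
Under a flatten head the per-position gradients carry opposite signs at
signal and background positions and the global average destroys them; in our
experiments the resulting importance maps were uniformly non-positive and
carried no localization signal at all.

### Training

The network is trained with Adam (default learning rate 3e-3, batch 64) on
binary cross-entropy over the logit.  Inputs are transformed per assay row
as `(log1p(x) − μ)/σ` with μ, σ estimated on the training set only and
stored with the model; prediction re-applies them, so the probability
contract (output strictly inside (0, 1)) cannot be broken by feeding raw
matrices.  The implementation is pure NumPy with hand-written backward
passes for every layer; owning the backward pass is also what exposes the
final-conv-block gradients Grad-CAM needs.  Gradients are verified against
central finite differences in the test suite.  Bit-reproducibility for a
fixed seed is promised on single-threaded CPU execution; multi-threaded
BLAS reductions may reorder sums.

Five-fold cross-validation uses stratified folds (each fold holds both
classes, every example validated exactly once); the mean report averages
fold metrics arithmetically and sums confusion counts.  The classification
rule is strict — probability exactly 0.5 is negative.

### Grad-CAM refinement

For a predicted-positive window: channel weights are the global average of
∂(pre-sigmoid score)/∂(activation map) at the output of the final conv
block (after its SE gate); the importance profile is the ReLU of the
weighted activation sum, linearly interpolated from feature-map resolution
to the 400 input bins (bin-centre to bin-centre).  Bins strictly below the
profile mean are filtered; maximal surviving runs ≥ 50 bp become intervals.
The ≥-mean rule means an all-equal profile keeps the whole window — that
degenerate case is logged rather than silently dropped.  Refinement uses
overlapping windows (default stride 2000 bp, 50 % overlap) so enhancers
straddling one window boundary are recovered from the neighbour.

## Normalization details

TMM follows the edgeR procedure: reference sample = the one whose
upper-quartile count fraction is closest to the mean of those fractions;
per sample, genes positive in both it and the reference contribute
M (log2 ratio) and A (log2 mean abundance); 30 % of M and 5 % of A ranks are
trimmed from each end; the factor is 2^(precision-weighted mean of retained
M), with delta-method binomial weights; factors are rescaled to geometric
mean 1.  The implementation reproduces Bioconductor edgeR's
`calcNormFactors(method="TMM")` to ≤ 1e-6 on random matrices (cross-checked
in the suite).  RPM divides by library size × TMM factor; the library size
is the sample's total mapped read count when supplied, else the column sum.

Statistical primitives are deliberately bought, not built: Spearman ρ and
its t-approximation P-value (scipy), the two-sided Fisher exact test with
probability ordering (scipy), and Benjamini–Hochberg FDR (statsmodels).
Each is pinned by an independent oracle in the tests: rank-then-Pearson,
exact-integer hypergeometric enumeration over all tables with total ≤ 60,
and the direct step-up definition.

## Interpretation choices on the annotation side

* "Average expression in other tissues" is the **unweighted mean of the
  other tissues' per-tissue mean RPMs**, not the pooled sample mean —
  tissue sample counts are unbalanced and the definition is tissue-level.
* The coefficient of variation of a housekeeping eRNA is computed across
  tissue means (sample sd, n−1); quartile boundaries use linear
  interpolation (type 7).  When Q1 = Q3 every eRNA satisfies both the
  low (≤ Q1) and high (≥ Q3) rules; low wins (documented tie rule).
* A tissue-specific eRNA is never simultaneously housekeeping —
  specificity takes precedence.
* eRNA–gene distance is the edge-to-edge gap between the 6 kb eRNA region
  and the gene body (0 when overlapping); the < 1 Mb filter is strict and
  applied before any correlation is computed.  The significance gate is the
  raw-P rule (|ρ| ≥ 0.3 and P < 0.05); BH FDR over all tested pairs in the
  tissue is computed and reported alongside, and both thresholds are
  configurable.
* The QTL contingency table contrasts eRNA regions against a background of
  the same regions uniformly re-placed (length-preserving, seeded); a trait
  is significant at P ≤ 0.05 with relative enrichment
  (eRNA associated fraction / background associated fraction) > 1.

## The synthetic genome and what it does (not) show

`synthetic_data` plants the structure every downstream stage assumes, and
emits truth labels so each stage has a recovery target.

**Genome fixture.**  Background signal is i.i.d. Gaussian noise (mean 1,
default sd 0.1) on a 10 bp grid; enhancer coordinates snap to the grid and
multiply all four assay levels by `signal_gain` (default 5), so the expected
inside/outside ratio is the gain exactly and a direct averaging oracle can
test it.  Each enhancer is overlapped by an expressed non-coding transcript
(TPM 0.5–5, its TSS 400 bp outside the enhancer) so the positive-set
intersection rule can fire.  Promoter-like **decoys** carry the same
ATAC/H3K27ac/H3K4me3 elevation but no RNA signal and no expressed
transcript: they are what makes the transcriptome row informative.  Their
density is one decoy per five enhancers — at that ratio a classifier without
the RNA row still finds elevated elements more likely enhancer than decoy
and degrades gracefully (precision loss), whereas at 1:1 the posterior
flips below the 0.5 threshold and the ablated model collapses to
all-negative.  Protein-coding genes (with exons and strand-resolved TSSs)
are placed clear of enhancer windows.

**Expression fixture.**  Counts are negative-binomial (variance
m + 0.1 m²) around per-tissue expected RPMs, with per-sample lognormal
biological noise (sd 0.4 on the log scale) and library sizes of 1.5–3 M.
Planted levels are chosen so the truth labels are consistent with the
operational definitions *at four samples per tissue*: housekeeping at 6 RPM
(well above the ≥ 1 gate in every tissue), tissue-specific at fold × 1.5
above a ~1 RPM base, and background split 60 / 40 between silent
(~0.05 RPM) and unevenly expressed (4–8 RPM in most tissues, 0.2 in 2–4) —
the latter detectable but neither housekeeping nor 3×-specific.  Planting
background close to the gates makes truth labels flip under count noise and
turns recovery statistics into coin flips; that is a property of low counts,
not of the classifier.  Designated target genes share a per-sample Gaussian
latent factor with their eRNA at a configurable correlation (default 0.7).

**QTL fixture.**  Trait QTLs (50–500 kb) are placed either within 2 Mb of
randomly chosen eRNAs (enriched traits) or uniformly (null traits), on a
genome-scale coordinate space (tests use 10 × 120 Mb) with 30 QTLs per
trait — a realistic count for a well-studied trait category.  Two failure
modes informed this geometry: strongly clustered eRNAs violate the Fisher
test's independence assumption and inflate the null rate (~13 % at nominal
5 %), while very few QTLs per trait leave the enrichment undetectable.  With
independent eRNA positions and 30 QTLs/trait the planted enrichment is
detected in ≥ 95 % of seeds and null traits are flagged at 2–4 % (the exact
test is conservative).

**What passing these tests does not show.**  The fixtures have no sequence
composition, GC or mappability structure, no correlated assay noise, no
peak-caller artefacts, and enhancer signal that is homogeneously
multiplicative — real signal is none of these.  Recovery on the fixture
demonstrates that the implementation is correct and the statistical
machinery calibrated, not that the classifier's real-data operating point
matches any published figure; published metrics depend on the underlying
multi-omics data, which is not shipped.

## Problem sizes and numerical choices

The recovery experiments train Model 6 on 200 positives + 2000 negatives
(4 × 1.5 Mb genome) for 4 epochs per fold — the task is designed separable,
and the suite verifies out-of-fold F1 ≥ 0.90 with the full matrix and a
strict F1 decrease without the RNA row.  Window recentring uses the floor
midpoint; windows leaving the chromosome are dropped (never zero-padded)
and counted in the log.  Uncovered bases count as 0 in bin means (fixed
denominator).  Probabilities are clipped to (1e-12, 1 − 1e-12) before loss
evaluation.  narrowPeak summit columns are ignored; no blacklist masking is
applied.

## Known limitations

* bigWig reading requires the optional pyBigWig dependency; bedGraph is the
  canonical signal format and nothing is written as bigWig.
* The histone intersection rule defaults to "either" (overlap with at least
  one of H3K27ac/H3K4me3); "both" is available via configuration.
* Grad-CAM is applied to predicted-positive windows (not only training
  positives).
* Strandedness of eRNA transcription is not modelled; the 6 kb regions are
  unstranded.
* The CLI's `associate` stage reports regulator (TF) associations over all
  samples; per-tissue target-gene discovery is available through
  `cnnee.association.find_targets`.
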