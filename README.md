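# cnnee

Enhancer prediction and enhancer-RNA (eRNA) annotation from multi-omics
signal, for regulatory genomics in species where enhancers have not been
systematically mapped (the pipeline was designed with livestock genomes in
mind, but nothing in it is species-specific).

Enhancers are distal cis-regulatory elements marked by open chromatin
(ATAC-seq) and active histone modifications (H3K27ac, H3K4me3), and active
enhancers transcribe short non-coding eRNAs visible in RNA-seq coverage.
`cnnee` integrates all four signals:

1. **Prediction.**  Each 4 kb genomic window is summarized as a 4 × 400
   matrix *X*, where row *a* is assay *a*'s mean signal in 400 consecutive
   10 bp bins.  A 1-D CNN with squeeze-and-excitation blocks maps *X* to
   P(enhancer) = σ(f(X)); windows with P > 0.5 are candidates.  Six
   catalogued architectures differ in (conv, pool, dense) layer counts;
   Model 6 (5 conv, 1 pool, 1 dense) is the default.
2. **Boundary refinement.**  Grad-CAM turns the classifier's evidence into a
   per-bin importance profile
   L = ReLU(Σ_k α_k A_k),  α_k = mean_t ∂f/∂A_k(t),
   where A_k are the final conv block's activation maps.  Bins at or above
   the window-mean importance form the refined enhancer; calls overlapping a
   TSS are removed.
3. **eRNA annotation.**  Every enhancer seeds a 6 kb eRNA region (± 3 kb of
   its midpoint, minus protein-coding-exon overlaps).  Counts are normalized
   by TMM (trimmed mean of M-values) and RPM; eRNAs are classified as
   detectable (tissue-mean RPM ≥ 1 somewhere), tissue-specific (one tissue
   > 3× the mean of the others), and housekeeping (≥ 1 everywhere, sub-split
   at the CV quartiles); targets and TF regulators are found by Spearman
   co-expression (|ρ| ≥ 0.3, P < 0.05; < 1 Mb for targets); trait
   enrichment uses a Fisher exact test on 2 Mb QTL proximity; cross-species
   conservation hits are filtered at identity ≥ 0.5 and E ≤ 1e-5.

A synthetic-data module generates download-free genomes, expression
matrices and QTL maps with planted truth, used throughout the test suite.

## Worked example

```python
import numpy as np
import cnnee as C
import cnnee.signal_matrix as sm

# 1. simulate a toy genome with 30 planted enhancers
spec = C.SyntheticGenomeSpec(
    chrom_sizes={"chr1": 800_000}, n_enhancers=30, signal_gain=5.0, seed=4)
fx = C.make_genome_fixture(spec)

# 2. training set: peak intersections + 10x downsampled negatives
tx = C.transcript_peaks(fx.genes)                       # TPM > 0.1
positives = C.call_positive_regions(
    fx.peaks["ATAC"], fx.peaks["H3K27ac"], fx.peaks["H3K4me3"], tx)
negatives = C.sample_negatives(positives, fx.chrom_sizes, seed=4)
dataset = C.make_dataset(positives, negatives, fx.tracks, fx.chrom_sizes)
print(f"{len(positives)} positives, {len(negatives)} negatives")

# 3. five-fold cross-validation of Model 6
model6 = C.ModelSpec.from_catalogue(6)
reports, mean = C.cross_validate(
    model6, dataset, k=5, config=C.TrainConfig(epochs=10, seed=0), seed=0)
print(f"5-fold CV: accuracy={mean.accuracy:.4f} precision={mean.precision:.4f} "
      f"recall={mean.recall:.4f} F1={mean.f1:.4f}")

# 4. scan the genome, refine boundaries with Grad-CAM, assemble calls
model = C.build_model(model6, init_seed=0)
C.train(model, dataset, C.TrainConfig(epochs=10, seed=0))
windows = C.tile_genome(fx.chrom_sizes, stride_bp=2000)
matrices = [sm.build_matrix(fx.tracks, w, chrom_length=fx.chrom_sizes[w.chrom])
            for w in windows]
refined = [
    (iv, prob)
    for matrix, prob, is_pos in C.predict_windows(model, matrices) if is_pos
    for iv in C.refine_boundaries(C.grad_cam(model, matrix))
]
tss = [t for g in fx.genes for t in g.tss_positions]
calls = C.assemble_enhancers(refined, tss)
recovered = sum(any(c.interval.overlaps(e) for c in calls)
                for e in fx.truth_enhancers)
print(f"{len(calls)} enhancer calls, {recovered}/{len(fx.truth_enhancers)} "
      f"truth enhancers recovered, median call length "
      f"{int(np.median([len(c.interval) for c in calls]))} bp")

# 5. eRNA regions around the calls
exons = [e for g in fx.genes if g.biotype == "protein_coding" for e in g.exons]
regions = C.define_erna_regions(calls, exons, fx.chrom_sizes)
print(f"{len(regions)} eRNA regions of {len(regions[0].interval)} bp")
```

Output:

```
30 positives, 300 negatives
5-fold CV: accuracy=1.0000 precision=1.0000 recall=1.0000 F1=1.0000
30 enhancer calls, 30/30 truth enhancers recovered, median call length 1195 bp
30 eRNA regions of 6000 bp
```

The CV metrics say the planted signal is cleanly separable at gain 5; the
interesting numbers are the last two lines — every planted enhancer is
re-found by the sliding-window scan, and the Grad-CAM-refined calls (median
1195 bp) are far narrower than the 4 kb windows they came from, tracking
the planted enhancer lengths (600–1200 bp).

## Command-line pipeline

Every stage is a subcommand over a single YAML config
(`cnnee <stage> --config config.yaml [--seed N] [--outdir DIR]`):

```
simulate  trainset  train  cv  predict  call-enhancers
erna  classify  associate  qtl  conserve
```

Each stage writes its outputs plus a `manifest.json` (inputs with
checksums, all parameters, seed) under `<outdir>/<stage>/`.  Defaults
follow the published protocol constants (4 kb / 10 bp matrices, 10×
negatives, threshold 0.5, ± 3 kb regions, RPM ≥ 1, 3× specificity, 1 Mb /
|ρ| ≥ 0.3 / P < 0.05 targets, 2 Mb QTL windows, identity ≥ 0.5 with
E ≤ 1e-5, 5 CV folds).

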