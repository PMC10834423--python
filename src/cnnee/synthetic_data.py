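"""Download-free synthetic fixtures with the structure the pipeline assumes.

The genome fixture emulates the multi-omics inputs of the enhancer classifier:
a toy genome carrying

* *truth enhancers* — regions where all four assay tracks (ATAC, H3K27ac,
  H3K4me3, RNA coverage) rise multiplicatively above background, each overlapped
  by an expressed non-coding transcript (the eRNA) and by ATAC/histone peaks;
* *decoy elements* — promoter-like regions with the same ATAC/H3K27ac/H3K4me3
  elevation but **no** RNA signal and no expressed transcript.  They are the
  background feature that makes the transcriptome row informative: a classifier
  without the RNA row cannot tell them from true enhancers;
* protein-coding genes with transcripts, exons and TSSs placed clear of the
  enhancers.

Background signal is i.i.d. noise on a 10 bp grid with mean 1; the enhancer
effect is multiplicative, so the expected inside/outside signal ratio equals
``signal_gain`` exactly.  Enhancer coordinates are snapped to the grid.

The expression fixture emulates a tissue-labelled eRNA count matrix with
planted tissue-specific and housekeeping eRNAs and negative-binomial counts,
plus a gene count matrix whose designated target genes share a Gaussian latent
factor with their eRNA at a configurable correlation.

Every fixture is a pure function of (spec, seed): one global seed fans out to
per-component generators through ``numpy.random.SeedSequence`` spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    GeneModel,
    GenomicInterval,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
)
from .signal_matrix import ASSAY_ORDER

GRID_BP = 10

__all__ = [
    "SyntheticGenomeSpec",
    "SyntheticExpressionSpec",
    "GenomeFixture",
    "ExpressionFixture",
    "FixtureError",
    "make_genome_fixture",
    "make_expression_fixture",
    "make_qtl_fixture",
    "make_clustered_intervals",
    "write_genome_fixture",
]


class FixtureError(ValueError):
    """Invalid fixture specification or failed placement."""


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


# ---------------------------------------------------------------------------
# Genome fixture
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenomeSpec:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    n_enhancers: int = 60
    enhancer_length_range: tuple[int, int] = (600, 1200)
    signal_gain: float = 5.0
    noise_sd: float = 0.1
    seed: int = 0
    n_decoys: int | None = None  # promoter-like elements; default n_enhancers // 5
    n_genes: int = 20
    peak_jitter_bp: int = 50

    def __post_init__(self) -> None:
        if self.signal_gain <= 1:
            raise FixtureError("signal_gain must be > 1")
        lo, hi = self.enhancer_length_range
        if not (0 < lo <= hi):
            raise FixtureError("bad enhancer_length_range")
        if self.noise_sd < 0:
            raise FixtureError("noise_sd must be ≥ 0")


@dataclass
class GenomeFixture:
    truth_enhancers: list[GenomicInterval]
    tracks: dict[str, SignalTrack]
    peaks: dict[str, list[GenomicInterval]]
    genes: list[GeneModel]
    decoys: list[GenomicInterval]
    chrom_sizes: dict[str, int]


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_sizes: Mapping[str, int],
    lengths: Sequence[int],
    occupied: dict[str, list[tuple[int, int]]],
    margin: int,
    max_tries: int = 10_000,
) -> list[GenomicInterval]:
    """Place intervals on the grid avoiding ``occupied`` (± margin)."""
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    placed: list[GenomicInterval] = []
    for length in lengths:
        length = (length // GRID_BP) * GRID_BP or GRID_BP
        for _ in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            limit = chrom_sizes[chrom] - length - margin
            if limit <= margin:
                continue
            start = (int(rng.integers(margin, limit)) // GRID_BP) * GRID_BP
            end = start + length
            clash = any(
                start - margin < oe and os < end + margin
                for os, oe in occupied.get(chrom, [])
            )
            if not clash:
                occupied.setdefault(chrom, []).append((start, end))
                placed.append(GenomicInterval(chrom, start, end))
                break
        else:
            raise FixtureError(
                f"could not place a {length} bp element after {max_tries} tries"
            )
    return placed


def make_genome_fixture(spec: SyntheticGenomeSpec) -> GenomeFixture:
    """Generate tracks, peaks, genes and truth labels for a toy genome."""
    n_decoys = (spec.n_decoys if spec.n_decoys is not None
                else max(1, spec.n_enhancers // 5))
    occupied: dict[str, list[tuple[int, int]]] = {}
    rng_place = _rng(spec.seed, 0)

    lo, hi = spec.enhancer_length_range
    enh_lengths = rng_place.integers(lo, hi + 1, size=spec.n_enhancers)
    # margin 2.5 kb keeps planted TSSs, decoys and gene bodies clear of the
    # 4 kb windows recentred on enhancers
    enhancers = _place_nonoverlapping(
        rng_place, spec.chrom_sizes, enh_lengths, occupied, margin=2500
    )
    decoy_lengths = rng_place.integers(lo, hi + 1, size=n_decoys)
    decoys = _place_nonoverlapping(
        rng_place, spec.chrom_sizes, decoy_lengths, occupied, margin=2500
    )
    gene_lengths = rng_place.integers(2000, 5001, size=spec.n_genes)
    gene_bodies = _place_nonoverlapping(
        rng_place, spec.chrom_sizes, gene_lengths, occupied, margin=2500
    )

    # --- genes: protein-coding genes plus one expressed eRNA transcript per
    # truth enhancer (TSS 400 bp outside the enhancer)
    rng_genes = _rng(spec.seed, 1)
    genes: list[GeneModel] = []
    for i, body in enumerate(gene_bodies):
        strand = "+" if rng_genes.random() < 0.5 else "-"
        tpm = float(np.round(rng_genes.lognormal(1.0, 1.0), 3))
        gid = f"GENE{i:04d}"
        tx = GenomicInterval(body.chrom, body.start, body.end, name=f"{gid}.1",
                             strand=strand)
        n_exons = int(rng_genes.integers(2, 4))
        bounds = np.sort(
            rng_genes.choice(
                np.arange(body.start + 100, body.end - 100, 50),
                size=2 * n_exons, replace=False,
            )
        )
        exons = [
            GenomicInterval(body.chrom, int(bounds[2 * j]), int(bounds[2 * j + 1]),
                            name=f"{gid}.1", strand=strand)
            for j in range(n_exons)
        ]
        tss = body.start if strand == "+" else body.end - 1
        genes.append(
            GeneModel(
                gene_id=gid, gene_name=f"gene{i}", biotype="protein_coding",
                tss_positions=[(body.chrom, tss, strand)],
                exons=exons, transcripts=[(tx, tpm)],
            )
        )
    for i, enh in enumerate(enhancers):
        gid = f"ERNAT{i:04d}"
        tx = GenomicInterval(
            enh.chrom, max(0, enh.start - 400), enh.end + 400,
            name=f"{gid}.1", strand="+",
        )
        tpm = float(np.round(rng_genes.uniform(0.5, 5.0), 3))
        genes.append(
            GeneModel(
                gene_id=gid, gene_name=None, biotype="lncRNA",
                tss_positions=[(tx.chrom, tx.start, "+")],
                exons=[], transcripts=[(tx, tpm)],
            )
        )

    # --- signal tracks: background noise × multiplicative element effects
    rng_tracks = _rng(spec.seed, 2)
    tracks: dict[str, SignalTrack] = {}
    decoy_gain = {"ATAC": spec.signal_gain, "H3K27ac": spec.signal_gain,
                  "H3K4me3": spec.signal_gain, "RNA": 1.0}
    for assay in ASSAY_ORDER:
        records: list[tuple[str, int, int, float]] = []
        for chrom in sorted(spec.chrom_sizes):
            size = (spec.chrom_sizes[chrom] // GRID_BP) * GRID_BP
            n_cells = size // GRID_BP
            level = np.ones(n_cells)
            for enh in enhancers:
                if enh.chrom == chrom:
                    level[enh.start // GRID_BP : enh.end // GRID_BP] = spec.signal_gain
            for dec in decoys:
                if dec.chrom == chrom:
                    level[dec.start // GRID_BP : dec.end // GRID_BP] = decoy_gain[assay]
            noise = rng_tracks.normal(1.0, spec.noise_sd, size=n_cells)
            values = np.maximum(level * noise, 0.0)
            cell_starts = np.arange(n_cells, dtype=np.int64) * GRID_BP
            records.extend(
                zip([chrom] * n_cells, cell_starts, cell_starts + GRID_BP, values)
            )
        tracks[assay] = SignalTrack.from_intervals(records)

    # --- peak calls: every enhancer and decoy gets jittered ATAC/histone
    # peaks; extra ATAC-only background peaks exercise the intersection rules
    rng_peaks = _rng(spec.seed, 3)
    peaks: dict[str, list[GenomicInterval]] = {a: [] for a in
                                               ("ATAC", "H3K27ac", "H3K4me3")}
    for element in enhancers + decoys:
        for assay in peaks:
            j1 = int(rng_peaks.integers(-spec.peak_jitter_bp, spec.peak_jitter_bp + 1))
            j2 = int(rng_peaks.integers(-spec.peak_jitter_bp, spec.peak_jitter_bp + 1))
            start = max(0, element.start + j1)
            end = max(start + GRID_BP, element.end + j2)
            peaks[assay].append(GenomicInterval(element.chrom, start, end))
    n_bg = max(5, spec.n_enhancers // 4)
    bg_lengths = rng_peaks.integers(lo, hi + 1, size=n_bg)
    peaks["ATAC"].extend(
        _place_nonoverlapping(rng_peaks, spec.chrom_sizes, bg_lengths,
                              occupied, margin=500)
    )
    for assay in peaks:
        peaks[assay].sort(key=lambda iv: (iv.chrom, iv.start))

    return GenomeFixture(
        truth_enhancers=enhancers, tracks=tracks, peaks=peaks,
        genes=genes, decoys=decoys, chrom_sizes=dict(spec.chrom_sizes),
    )


# ---------------------------------------------------------------------------
# Expression fixture
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExpressionSpec:
    tissues: dict[str, int] = field(
        default_factory=lambda: {f"tissue{i:02d}": 4 for i in range(15)}
    )
    n_ernas: int = 200
    planted_specific: dict[str, set[str]] = field(default_factory=dict)
    specific_fold: float = 6.0
    planted_housekeeping: set[str] = field(default_factory=set)
    target_gene_rho: float = 0.7
    seed: int = 0
    base_rpm: float = 0.3  # median background eRNA expression
    hk_rpm: float = 6.0  # housekeeping baseline (well above the RPM ≥ 1 gate)
    library_size_range: tuple[int, int] = (1_500_000, 3_000_000)
    dispersion: float = 0.1
    sample_log_sd: float = 0.4  # per-sample biological noise on log scale

    def __post_init__(self) -> None:
        if len(self.tissues) < 2 or any(n < 3 for n in self.tissues.values()):
            raise FixtureError("need ≥ 2 tissues with ≥ 3 samples each")
        if self.specific_fold <= 3:
            raise FixtureError(
                "specific_fold must be > 3 or the planted eRNAs cannot clear "
                "the 3× tissue-specificity rule"
            )
        all_specific: set[str] = set()
        for ids in self.planted_specific.values():
            if all_specific & set(ids):
                raise FixtureError("an eRNA is planted specific in two tissues")
            all_specific |= set(ids)
        if all_specific & self.planted_housekeeping:
            raise FixtureError("planted specific and housekeeping sets overlap")
        unknown = set(self.planted_specific) - set(self.tissues)
        if unknown:
            raise FixtureError(f"planted tissues not in tissue list: {unknown}")


@dataclass
class ExpressionFixture:
    counts: pd.DataFrame  # eRNA × sample, integers
    tissue_labels: pd.Series  # sample → tissue
    gene_counts: pd.DataFrame  # gene × sample, integers
    truth: dict


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float
               ) -> np.ndarray:
    """Over-dispersed counts, var = m + dispersion·m²."""
    mean = np.maximum(mean, 1e-8)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def make_expression_fixture(spec: SyntheticExpressionSpec) -> ExpressionFixture:
    """Counts with planted tissue-specific/housekeeping eRNAs + target genes."""
    rng = _rng(spec.seed, 10)
    tissue_names = sorted(spec.tissues)
    samples: list[str] = []
    labels: list[str] = []
    for t in tissue_names:
        for j in range(spec.tissues[t]):
            samples.append(f"{t}_s{j}")
            labels.append(t)
    n_samples = len(samples)
    tissue_of = np.array(labels)

    erna_ids = [f"eRNA{i:05d}" for i in range(spec.n_ernas)]
    specific_of: dict[str, str] = {}
    for t, ids in spec.planted_specific.items():
        for e in ids:
            specific_of[e] = t
    unknown = (set(specific_of) | spec.planted_housekeeping) - set(erna_ids)
    if unknown:
        raise FixtureError(f"planted ids beyond n_ernas: {sorted(unknown)[:3]} …")

    # Expected RPM per eRNA per tissue.  Background eRNAs come in two
    # archetypes chosen to be consistent with the operational definitions:
    # silent (never detectable) and unevenly expressed (detectable in several
    # tissues but dim in others — neither housekeeping nor 3×-specific).
    n_t = len(tissue_names)
    mean_rpm = np.empty((spec.n_ernas, n_t))
    for i, e in enumerate(erna_ids):
        if e in spec.planted_housekeeping:
            mean_rpm[i] = spec.hk_rpm * rng.uniform(0.8, 1.25, n_t)
        elif e in specific_of:
            base = rng.uniform(0.8, 1.2)
            mean_rpm[i] = base
            t_idx = tissue_names.index(specific_of[e])
            mean_rpm[i, t_idx] = base * spec.specific_fold * 1.5
        elif rng.random() < 0.6:
            mean_rpm[i] = spec.base_rpm / 6.0  # silent background
        else:
            # expressed high enough that count noise cannot mimic the 3× rule
            row = rng.uniform(4.0, 8.0) * rng.uniform(0.8, 1.2, n_t)
            dim = rng.choice(n_t, size=int(rng.integers(2, 5)), replace=False)
            row[dim] = 0.2
            mean_rpm[i] = row

    lib_sizes = rng.integers(*spec.library_size_range, size=n_samples)
    tissue_idx = np.array([tissue_names.index(t) for t in tissue_of])
    # shared per-(eRNA, sample) latent deviations; reused for target genes
    latent = rng.normal(0.0, 1.0, size=(spec.n_ernas, n_samples))
    sample_rpm = mean_rpm[:, tissue_idx] * np.exp(
        spec.sample_log_sd * latent - spec.sample_log_sd**2 / 2
    )
    mean_counts = sample_rpm * lib_sizes[None, :] / 1e6
    counts = _nb_counts(rng, mean_counts, spec.dispersion)

    # one designated target gene per planted eRNA, correlated via the latent
    rho = spec.target_gene_rho
    target_ernas = sorted(specific_of) + sorted(spec.planted_housekeeping)
    gene_ids, gene_rows, targets = [], [], {}
    for k, e in enumerate(target_ernas):
        gid = f"TGT{k:04d}"
        i = erna_ids.index(e)
        z = rho * latent[i] + np.sqrt(1 - rho**2) * rng.normal(0, 1, n_samples)
        g_rpm = 20.0 * np.exp(spec.sample_log_sd * z - spec.sample_log_sd**2 / 2)
        gene_rows.append(_nb_counts(rng, g_rpm * lib_sizes / 1e6, spec.dispersion))
        gene_ids.append(gid)
        targets[e] = gid
    n_null_genes = max(10, len(target_ernas) // 2)
    for k in range(n_null_genes):
        g_rpm = 20.0 * np.exp(
            spec.sample_log_sd * rng.normal(0, 1, n_samples)
            - spec.sample_log_sd**2 / 2
        )
        gene_rows.append(_nb_counts(rng, g_rpm * lib_sizes / 1e6, spec.dispersion))
        gene_ids.append(f"NULL{k:04d}")

    truth = {
        "specific": dict(specific_of),
        "housekeeping": set(spec.planted_housekeeping),
        "targets": targets,
        "library_sizes": pd.Series(lib_sizes, index=samples),
    }
    return ExpressionFixture(
        counts=pd.DataFrame(counts, index=erna_ids, columns=samples),
        tissue_labels=pd.Series(labels, index=samples),
        gene_counts=pd.DataFrame(
            np.vstack(gene_rows) if gene_rows else np.empty((0, n_samples), int),
            index=gene_ids, columns=samples,
        ),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# QTL fixture
# ---------------------------------------------------------------------------

def make_clustered_intervals(
    chrom_sizes: Mapping[str, int],
    n_clusters: int,
    per_cluster: int,
    length_bp: int = 6000,
    cluster_span_bp: int = 1_000_000,
    seed: int = 0,
) -> list[GenomicInterval]:
    """eRNA-like regions grouped in clusters, as enhancer domains are."""
    rng = _rng(seed, 20)
    chroms = sorted(chrom_sizes)
    out: list[GenomicInterval] = []
    for c in range(n_clusters):
        chrom = chroms[int(rng.integers(len(chroms)))]
        anchor = int(rng.integers(0, chrom_sizes[chrom] - cluster_span_bp - length_bp))
        for _ in range(per_cluster):
            start = anchor + int(rng.integers(0, cluster_span_bp))
            out.append(GenomicInterval(chrom, start, start + length_bp,
                                       name=f"c{c}"))
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def make_qtl_fixture(
    ernas: Sequence[GenomicInterval],
    n_traits: int,
    enriched_trait_fraction: float,
    seed: int,
    chrom_sizes: Mapping[str, int] | None = None,
    qtls_per_trait: int = 30,
    qtl_length_range: tuple[int, int] = (50_000, 500_000),
) -> tuple[list[tuple[str, GenomicInterval]], set[str]]:
    """Trait-labelled QTL intervals; enriched traits sit near eRNAs.

    For an enriched trait each QTL is placed within 2 Mb of a randomly chosen
    eRNA; for a null trait QTLs are placed uniformly on the genome.  Returns
    the QTL list and the set of truly enriched trait names.
    """
    if not ernas:
        raise FixtureError("ernas must be non-empty")
    rng = _rng(seed, 21)
    if chrom_sizes is None:
        chrom_sizes = {}
        for iv in ernas:
            chrom_sizes[iv.chrom] = max(chrom_sizes.get(iv.chrom, 0),
                                        iv.end + 4_000_000)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], float)
    probs = sizes / sizes.sum()

    n_enriched = int(round(n_traits * enriched_trait_fraction))
    enriched = {f"trait{t:03d}" for t in range(n_enriched)}
    qtls: list[tuple[str, GenomicInterval]] = []
    for t in range(n_traits):
        trait = f"trait{t:03d}"
        for _ in range(qtls_per_trait):
            length = int(rng.integers(*qtl_length_range))
            if trait in enriched:
                anchor = ernas[int(rng.integers(len(ernas)))]
                offset = int(rng.integers(-1_500_000, 1_500_000))
                start = max(0, anchor.midpoint + offset - length // 2)
                chrom = anchor.chrom
            else:
                chrom = chroms[int(rng.choice(len(chroms), p=probs))]
                start = int(rng.integers(0, max(1, chrom_sizes[chrom] - length)))
            end = min(start + length, chrom_sizes.get(chrom, start + length))
            if end <= start:
                end = start + length
            qtls.append((trait, GenomicInterval(chrom, start, end, name=trait)))
    return qtls, enriched


# ---------------------------------------------------------------------------
# On-disk fixture (exercises the real parsers)
# ---------------------------------------------------------------------------

def write_genome_fixture(fixture: GenomeFixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture in the formats `genomic_io` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    write_chrom_sizes(fixture.chrom_sizes, outdir / "genome.chrom.sizes")
    paths["chrom_sizes"] = outdir / "genome.chrom.sizes"
    for assay, track in fixture.tracks.items():
        p = outdir / f"{assay}.bedGraph"
        write_bedgraph(track, p)
        paths[f"track_{assay}"] = p
    for assay, pk in fixture.peaks.items():
        p = outdir / f"{assay}.peaks.bed"
        write_bed(pk, p)
        paths[f"peaks_{assay}"] = p
    write_bed(fixture.truth_enhancers, outdir / "truth_enhancers.bed")
    paths["truth_enhancers"] = outdir / "truth_enhancers.bed"
    write_bed(fixture.decoys, outdir / "decoys.bed")
    paths["decoys"] = outdir / "decoys.bed"
    gtf = outdir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for gene in fixture.genes:
            spans = [tx.start for tx, _ in gene.transcripts], [
                tx.end for tx, _ in gene.transcripts
            ]
            chrom = gene.transcripts[0][0].chrom
            strand = gene.transcripts[0][0].strand or "+"
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            if gene.gene_name:
                attrs += f' gene_name "{gene.gene_name}";'
            fh.write(
                f"{chrom}\tsynthetic\tgene\t{min(spans[0]) + 1}\t{max(spans[1])}"
                f"\t.\t{strand}\t.\t{attrs}\n"
            )
            for tx, tpm in gene.transcripts:
                t_attrs = attrs + f' transcript_id "{tx.name}";'
                if tpm is not None:
                    t_attrs += f' TPM "{tpm}";'
                fh.write(
                    f"{chrom}\tsynthetic\ttranscript\t{tx.start + 1}\t{tx.end}"
                    f"\t.\t{tx.strand}\t.\t{t_attrs}\n"
                )
            for exon in gene.exons:
                e_attrs = attrs + f' transcript_id "{exon.name}";'
                fh.write(
                    f"{chrom}\tsynthetic\texon\t{exon.start + 1}\t{exon.end}"
                    f"\t.\t{exon.strand}\t.\t{e_attrs}\n"
                )
    paths["gtf"] = gtf
    return paths
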