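"""Positive/negative training examples from peak intersections.

Positives are ATAC peaks that overlap at least one expressed-transcript
interval (TPM strictly > 0.1) and at least one active-histone peak
(H3K27ac / H3K4me3; "either" by default, configurable to require both).
Negatives are background 4 kb windows downsampled to 10× the positives, never
overlapping a positive region.  Every region is then recentred to a 4 kb
window about its floor midpoint and turned into a 4 × 400 signal matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import GeneModel, GenomicFileError, GenomicInterval, SignalTrack
from .signal_matrix import WINDOW_BP, InputMatrix, build_matrix

logger = logging.getLogger("cnnee")

__all__ = [
    "TrainingExample",
    "transcript_peaks",
    "call_positive_regions",
    "sample_negatives",
    "make_dataset",
    "write_manifest",
]


@dataclass
class TrainingExample:
    matrix: InputMatrix
    label: int  # 1 positive, 0 negative
    origin: GenomicInterval

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def _overlaps_any(
    query: GenomicInterval, by_chrom: Mapping[str, np.ndarray]
) -> bool:
    """Any-overlap test against per-chromosome (start, end) arrays."""
    arr = by_chrom.get(query.chrom)
    if arr is None or arr.size == 0:
        return False
    return bool(np.any((arr[:, 0] < query.end) & (arr[:, 1] > query.start)))


def _index(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.array(v, dtype=np.int64) for c, v in out.items()}


def transcript_peaks(
    genes: Sequence[GeneModel], tpm_threshold: float = 0.1
) -> list[GenomicInterval]:
    """Intervals of transcripts expressed above the TPM threshold (strict >)."""
    any_tpm = any(
        tpm is not None for g in genes for _, tpm in g.transcripts
    )
    if not any_tpm:
        raise GenomicFileError("no transcript carries a TPM value")
    out = [
        tx
        for g in genes
        for tx, tpm in g.transcripts
        if tpm is not None and tpm > tpm_threshold
    ]
    return out


def call_positive_regions(
    atac_peaks: Sequence[GenomicInterval],
    h3k27ac_peaks: Sequence[GenomicInterval],
    h3k4me3_peaks: Sequence[GenomicInterval],
    transcript_peaks: Sequence[GenomicInterval],
    histone_mode: str = "either",
) -> list[GenomicInterval]:
    """ATAC peaks overlapping a transcript peak and active-histone peak(s).

    Overlap means ≥ 1 shared base under half-open coordinates; bookended
    intervals do not overlap.  ``histone_mode`` "either" requires overlap with
    at least one of the H3K27ac/H3K4me3 sets, "both" with each of them.
    """
    if histone_mode not in ("either", "both"):
        raise ValueError(f"histone_mode must be 'either' or 'both', got {histone_mode}")
    k27 = _index(h3k27ac_peaks)
    k4 = _index(h3k4me3_peaks)
    tx = _index(transcript_peaks)
    positives = []
    for peak in atac_peaks:
        if not _overlaps_any(peak, tx):
            continue
        has27 = _overlaps_any(peak, k27)
        has4 = _overlaps_any(peak, k4)
        ok = (has27 and has4) if histone_mode == "both" else (has27 or has4)
        if ok:
            positives.append(peak)
    return positives


def sample_negatives(
    positives: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    ratio: int = 10,
    seed: int = 0,
    window_bp: int = WINDOW_BP,
    max_tries_factor: int = 1000,
) -> list[GenomicInterval]:
    """Background windows, ``ratio`` per positive, none overlapping a positive."""
    if not positives:
        raise ValueError("positives must be non-empty")
    pos_index = _index(positives)
    rng = np.random.default_rng(seed)
    chroms = sorted(c for c, s in chrom_sizes.items() if s >= window_bp)
    if not chroms:
        raise GenomicFileError("no chromosome can hold a window")
    sizes = np.array([chrom_sizes[c] - window_bp for c in chroms], dtype=float)
    probs = (sizes + 1) / (sizes + 1).sum()
    n_needed = ratio * len(positives)
    negatives: list[GenomicInterval] = []
    tries = 0
    max_tries = max_tries_factor * n_needed
    while len(negatives) < n_needed:
        if tries >= max_tries:
            raise GenomicFileError(
                f"could not sample {n_needed} negatives in {max_tries} draws; "
                "background too constrained"
            )
        tries += 1
        ci = int(rng.choice(len(chroms), p=probs))
        start = int(rng.integers(0, chrom_sizes[chroms[ci]] - window_bp + 1))
        window = GenomicInterval(chroms[ci], start, start + window_bp)
        if not _overlaps_any(window, pos_index):
            negatives.append(window)
    return negatives


def make_dataset(
    positives: Sequence[GenomicInterval],
    negatives: Sequence[GenomicInterval],
    tracks: Mapping[str, SignalTrack],
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[TrainingExample]:
    """Recentre each region to a 4 kb window about its midpoint and label it.

    Regions whose recentred window would run off the chromosome are dropped
    (counted in the log), never zero-padded.
    """
    examples: list[TrainingExample] = []
    n_dropped = 0
    for label, regions in ((1, positives), (0, negatives)):
        for region in regions:
            mid = region.midpoint
            start = mid - WINDOW_BP // 2
            end = start + WINDOW_BP
            size = chrom_sizes.get(region.chrom) if chrom_sizes else None
            if start < 0 or (size is not None and end > size):
                n_dropped += 1
                continue
            window = GenomicInterval(region.chrom, start, end)
            matrix = build_matrix(tracks, window, chrom_length=size)
            examples.append(TrainingExample(matrix=matrix, label=label,
                                            origin=region))
    if n_dropped:
        logger.info("dropped %d region(s) whose 4 kb window left the chromosome",
                    n_dropped)
    return examples


def write_manifest(examples: Sequence[TrainingExample], path: str | Path) -> None:
    """TSV manifest: window coordinates, label, origin region."""
    with open(path, "w") as fh:
        fh.write("chrom\twindow_start\twindow_end\tlabel\t"
                 "origin_start\torigin_end\n")
        for ex in examples:
            w, o = ex.matrix.window, ex.origin
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{ex.label}\t"
                     f"{o.start}\t{o.end}\n")
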