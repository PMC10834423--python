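"""Fixed-size model input matrices from signal tracks.

A candidate region is represented over a 4 kb window as a 4 × 400 matrix:
four assay rows (ATAC, H3K27ac, H3K4me3, RNA coverage) by 400 columns of
10 bp bins, each bin holding the mean signal over its bases (uncovered bases
contribute 0, i.e. the denominator is always the bin width).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import GenomicFileError, GenomicInterval, SignalTrack

ASSAY_ORDER: tuple[str, ...] = ("ATAC", "H3K27ac", "H3K4me3", "RNA")
WINDOW_BP = 4000
BIN_BP = 10
N_BINS = WINDOW_BP // BIN_BP

__all__ = [
    "ASSAY_ORDER",
    "WINDOW_BP",
    "BIN_BP",
    "N_BINS",
    "InputMatrix",
    "NormStats",
    "bin_signal",
    "build_matrix",
    "tile_genome",
    "compute_norm_stats",
    "normalize_matrix",
    "save_matrices",
    "load_matrices",
]


@dataclass
class InputMatrix:
    """4 assay rows × 400 bins of mean signal over a 4 kb window."""

    window: GenomicInterval
    values: np.ndarray  # (4, 400) float64
    assay_order: tuple[str, ...] = ASSAY_ORDER

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_BP:
            raise GenomicFileError(
                f"window length {len(self.window)} != {WINDOW_BP}"
            )
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.assay_order), N_BINS):
            raise GenomicFileError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.assay_order)}, {N_BINS})"
            )
        if not np.all(np.isfinite(self.values)):
            raise GenomicFileError("non-finite values in input matrix")


def bin_signal(
    track: SignalTrack,
    window: GenomicInterval,
    bin_bp: int = BIN_BP,
    chrom_length: int | None = None,
) -> np.ndarray:
    """Mean signal per ``bin_bp`` bin across the window.

    Bin ``b`` covers bases ``window.start + bin_bp*b … window.start +
    bin_bp*(b+1)``; bases not covered by any track interval count as 0 in the
    mean so the denominator is always ``bin_bp``.
    """
    length = len(window)
    if length % bin_bp != 0:
        raise GenomicFileError(
            f"window length {length} not divisible by bin {bin_bp}"
        )
    if window.start < 0 or (chrom_length is not None and window.end > chrom_length):
        raise GenomicFileError(
            f"window {window.chrom}:[{window.start},{window.end}) is off the "
            "chromosome end"
        )
    starts, ends, values = track.intervals(window.chrom)
    lo = int(np.searchsorted(ends, window.start, side="right"))
    hi = int(np.searchsorted(starts, window.end, side="left"))
    # Per-base values via a difference array + cumsum; the track guarantees
    # no overlaps so plain addition is exact.
    diff = np.zeros(length + 1, dtype=np.float64)
    s = np.clip(starts[lo:hi] - window.start, 0, length)
    e = np.clip(ends[lo:hi] - window.start, 0, length)
    np.add.at(diff, s, values[lo:hi])
    np.add.at(diff, e, -values[lo:hi])
    per_base = np.cumsum(diff[:-1])
    return per_base.reshape(length // bin_bp, bin_bp).mean(axis=1)


def build_matrix(
    tracks: Mapping[str, SignalTrack],
    window: GenomicInterval,
    chrom_length: int | None = None,
) -> InputMatrix:
    """Stack the four assay signal rows in the fixed assay order."""
    missing = [a for a in ASSAY_ORDER if a not in tracks]
    if missing:
        raise GenomicFileError(f"missing assay track(s): {', '.join(missing)}")
    if len(window) != WINDOW_BP:
        raise GenomicFileError(f"window length {len(window)} != {WINDOW_BP}")
    rows = [
        bin_signal(tracks[a], window, BIN_BP, chrom_length) for a in ASSAY_ORDER
    ]
    return InputMatrix(window=window, values=np.stack(rows))


def tile_genome(
    chrom_sizes: Mapping[str, int],
    window_bp: int = WINDOW_BP,
    stride_bp: int = 2000,
) -> list[GenomicInterval]:
    """Sliding windows ``[k*stride, k*stride + window_bp)`` per chromosome.

    Windows running past the chromosome end are dropped, not padded; a
    chromosome shorter than one window yields no windows.
    """
    if stride_bp < 1:
        raise ValueError("stride must be ≥ 1")
    windows: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for start in range(0, size - window_bp + 1, stride_bp):
            windows.append(GenomicInterval(chrom, start, start + window_bp))
    return windows


@dataclass
class NormStats:
    """Per-assay mean/sd of log1p signal, estimated on the training set."""

    mean: np.ndarray  # (4,)
    sd: np.ndarray  # (4,)

    def to_json(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> "NormStats":
        return cls(np.asarray(obj["mean"], float), np.asarray(obj["sd"], float))


def compute_norm_stats(matrices: Sequence[InputMatrix]) -> NormStats:
    if not matrices:
        raise ValueError("need at least one matrix to estimate stats")
    stacked = np.stack([m.values for m in matrices])  # (N, 4, 400)
    logged = np.log1p(stacked)
    mean = logged.mean(axis=(0, 2))
    sd = logged.std(axis=(0, 2))
    sd = np.where(sd > 0, sd, 1.0)
    return NormStats(mean=mean, sd=sd)


def normalize_matrix(m: InputMatrix, stats: NormStats) -> InputMatrix:
    """Per-row ``(log1p(x) − mean) / sd`` using training-set statistics only."""
    sd = np.where(stats.sd > 0, stats.sd, 1.0)
    values = (np.log1p(m.values) - stats.mean[:, None]) / sd[:, None]
    return InputMatrix(window=m.window, values=values, assay_order=m.assay_order)


def save_matrices(matrices: Sequence[InputMatrix], path: str | Path) -> None:
    """Binary container (.npz) plus a JSON sidecar of window coordinates."""
    path = Path(path)
    np.savez_compressed(path, values=np.stack([m.values for m in matrices]))
    sidecar = {
        "assay_order": list(ASSAY_ORDER),
        "windows": [
            {"chrom": m.window.chrom, "start": m.window.start, "end": m.window.end}
            for m in matrices
        ],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_matrices(path: str | Path) -> list[InputMatrix]:
    path = Path(path)
    values = np.load(path)["values"]
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return [
        InputMatrix(
            window=GenomicInterval(w["chrom"], w["start"], w["end"]),
            values=values[i],
            assay_order=tuple(sidecar["assay_order"]),
        )
        for i, w in enumerate(sidecar["windows"])
    ]
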