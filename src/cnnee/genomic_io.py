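"""Readers and writers for the genomic file formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) internally.  The only
1-based format handled here is GTF, which is converted at the boundary:
``start - 1`` on the way in, so a GTF feature ``1000..2000`` becomes the
interval ``[999, 2000)``.

Formats: BED3/4/6 and narrowPeak (extra columns ignored), 4-column bedGraph,
bigWig (optional, behind a capability check), Ensembl-dialect GTF, BLAST
``-outfmt 6`` tabular output and two-column chrom.sizes tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("cnnee")

__all__ = [
    "GenomicInterval",
    "SignalTrack",
    "GeneModel",
    "BlastHit",
    "GenomicFileError",
    "read_bed",
    "write_bed",
    "read_signal",
    "write_bedgraph",
    "read_gtf",
    "read_blast_tabular",
    "read_chrom_sizes",
    "write_chrom_sizes",
]


class GenomicFileError(ValueError):
    """Malformed genomic file content (bad coordinates, overlaps, columns)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise GenomicFileError("chrom must be non-empty")
        if self.start < 0:
            raise GenomicFileError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise GenomicFileError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-", "."):
            raise GenomicFileError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint; deterministic for odd lengths."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1 shared base under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


class SignalTrack:
    """Piecewise-constant genomic signal.

    Per chromosome, three parallel arrays (start, end, value) sorted by start
    with no overlaps; absent positions have value 0.
    """

    def __init__(self) -> None:
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_intervals(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if start < 0 or start >= end:
                raise GenomicFileError(
                    f"bad signal interval {chrom}:[{start}, {end})"
                )
            if not np.isfinite(value):
                raise GenomicFileError(f"non-finite signal value at {chrom}:{start}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, items in by_chrom.items():
            items.sort(key=lambda t: t[0])
            starts = np.array([t[0] for t in items], dtype=np.int64)
            ends = np.array([t[1] for t in items], dtype=np.int64)
            values = np.array([t[2] for t in items], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise GenomicFileError(
                    f"overlapping signal intervals on {chrom} near position "
                    f"{int(starts[i + 1])}"
                )
            if np.any(values < 0):
                logger.warning("negative signal values on %s", chrom)
            track._data[chrom] = (starts, ends, values)
        return track

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, values) for one chromosome; empty arrays if absent."""
        if chrom not in self._data:
            empty_i = np.empty(0, dtype=np.int64)
            return empty_i, empty_i.copy(), np.empty(0, dtype=np.float64)
        return self._data[chrom]

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Signal value at every base of [start, end); uncovered bases are 0."""
        out = np.zeros(end - start, dtype=np.float64)
        starts, ends, values = self.intervals(chrom)
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            out[max(s, start) - start : min(e, end) - start] = v
        return out


@dataclass
class GeneModel:
    """A gene with its transcripts, exons and strand-resolved TSS positions.

    The TSS of a transcript on the + strand is its start coordinate; on the
    − strand it is ``end − 1`` (the last base of the half-open interval).
    """

    gene_id: str
    gene_name: str | None = None
    biotype: str = "protein_coding"
    tss_positions: list[tuple[str, int, str]] = field(default_factory=list)
    exons: list[GenomicInterval] = field(default_factory=list)
    transcripts: list[tuple[GenomicInterval, float | None]] = field(
        default_factory=list
    )


@dataclass(frozen=True)
class BlastHit:
    """One row of BLAST tabular output; identity stored as a fraction."""

    query_id: str
    subject_id: str
    identity_fraction: float
    evalue: float
    fields: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise GenomicFileError(
                f"identity fraction {self.identity_fraction} outside [0, 1]"
            )
        if not np.isfinite(self.evalue) or self.evalue < 0:
            raise GenomicFileError(f"bad e-value {self.evalue}")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, min_columns: int = 3) -> list[GenomicInterval]:
    """Read BED-family records (BED3/4/6, narrowPeak) preserving file order."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_columns or len(fields) < 3:
                raise GenomicFileError(
                    f"{path}:{lineno}: expected ≥{max(min_columns, 3)} columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise GenomicFileError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise GenomicFileError(
                        f"{path}:{lineno}: non-numeric score"
                    ) from exc
            strand = fields[5] if len(fields) > 5 else None
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, score, strand)
                )
            except GenomicFileError as exc:
                raise GenomicFileError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write BED records with as many columns as the records carry."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None:
                fields.append(format(iv.score, "g") if iv.score is not None else ".")
            if iv.strand is not None:
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Signal (bedGraph / bigWig)
# ---------------------------------------------------------------------------

def _is_bigwig(path: Path) -> bool:
    with open(path, "rb") as fh:
        magic = fh.read(4)
    return magic in (b"\x26\xfc\x8f\x88", b"\x88\x8f\xfc\x26")


def read_signal(path: str | Path) -> SignalTrack:
    """Read a bedGraph (canonical) or bigWig (if pyBigWig is available)."""
    path = Path(path)
    if _is_bigwig(path):
        try:
            import pyBigWig  # noqa: PLC0415
        except ImportError as exc:
            raise GenomicFileError(
                f"{path} looks like bigWig but pyBigWig is not installed; "
                "convert to bedGraph"
            ) from exc
        bw = pyBigWig.open(str(path))
        try:
            records = []
            for chrom in bw.chroms():
                for s, e, v in bw.intervals(chrom) or []:
                    records.append((chrom, s, e, float(v)))
        finally:
            bw.close()
        return SignalTrack.from_intervals(records)

    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise GenomicFileError(
                    f"{path}:{lineno}: bedGraph needs 4 columns, got {len(fields)}"
                )
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise GenomicFileError(f"{path}:{lineno}: bad bedGraph row") from exc
    return SignalTrack.from_intervals(records)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            starts, ends, values = track.intervals(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse gene/transcript/exon features from an Ensembl-dialect GTF.

    GTF is 1-based closed; output intervals are 0-based half-open.  Transcript
    lines may carry a ``TPM`` attribute (as StringTie writes).  Exons without a
    known parent transcript are skipped with a warning.
    """
    genes: dict[str, GeneModel] = {}
    transcript_gene: dict[str, str] = {}
    n_orphans = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GenomicFileError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, raw = fields[:9]
            if feature not in ("gene", "transcript", "exon"):
                continue
            start, end = int(start1) - 1, int(end1)
            attrs = _gtf_attributes(raw)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GenomicFileError(f"{path}:{lineno}: missing gene_id")
            if gene_id not in genes:
                genes[gene_id] = GeneModel(
                    gene_id=gene_id,
                    gene_name=attrs.get("gene_name"),
                    biotype=attrs.get("gene_biotype", "protein_coding"),
                )
            model = genes[gene_id]
            if attrs.get("gene_name") and model.gene_name is None:
                model.gene_name = attrs["gene_name"]
            if attrs.get("gene_biotype"):
                model.biotype = attrs["gene_biotype"]
            if feature == "transcript":
                tid = attrs.get("transcript_id", f"{gene_id}.t{lineno}")
                transcript_gene[tid] = gene_id
                tpm = float(attrs["TPM"]) if "TPM" in attrs else None
                iv = GenomicInterval(chrom, start, end, name=tid, strand=strand)
                model.transcripts.append((iv, tpm))
                tss = start if strand == "+" else end - 1
                model.tss_positions.append((chrom, tss, strand))
            elif feature == "exon":
                tid = attrs.get("transcript_id")
                if tid is None or tid not in transcript_gene:
                    n_orphans += 1
                    continue
                model.exons.append(
                    GenomicInterval(chrom, start, end, name=tid, strand=strand)
                )
    if n_orphans:
        logger.warning("%d exon(s) without a parent transcript skipped", n_orphans)
    return list(genes.values())


# ---------------------------------------------------------------------------
# BLAST tabular / chrom.sizes
# ---------------------------------------------------------------------------

def read_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse standard 12-column ``-outfmt 6`` output.

    Column 3 carries percent identity on the 0–100 scale; it is stored as a
    fraction in [0, 1].
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise GenomicFileError(
                    f"{path}:{lineno}: expected 12 tabular columns"
                )
            try:
                identity = float(fields[2]) / 100.0
                evalue = float(fields[10])
            except ValueError as exc:
                raise GenomicFileError(
                    f"{path}:{lineno}: non-numeric identity or e-value"
                ) from exc
            try:
                hits.append(
                    BlastHit(fields[0], fields[1], identity, evalue, tuple(fields))
                )
            except GenomicFileError as exc:
                raise GenomicFileError(f"{path}:{lineno}: {exc}") from exc
    return hits


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise GenomicFileError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def check_chroms(
    intervals: Iterable[GenomicInterval], chrom_sizes: Mapping[str, int]
) -> None:
    """Hard-fail on intervals whose chromosome is absent from the size table."""
    for iv in intervals:
        if iv.chrom not in chrom_sizes:
            raise GenomicFileError(
                f"interval on unknown chromosome {iv.chrom!r}"
            )
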