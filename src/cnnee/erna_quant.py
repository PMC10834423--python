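"""eRNA regions, expression normalization and classification.

An eRNA region is the 6 kb interval centred on an enhancer midpoint
(± 3 kb); regions overlapping a protein-coding exon or running off the
chromosome are excluded.  Per-sample read counts in these regions are
normalized between samples with TMM (trimmed mean of M-values, the edgeR
procedure restated) and within samples to reads per million over the
effective library size.

Classification, all at the tissue level (per-tissue mean RPM):

* detectable — mean RPM ≥ 1 in at least one tissue;
* tissue-specific — one tissue's mean is strictly more than 3× the unweighted
  mean of the other tissues' means;
* housekeeping — mean RPM ≥ 1 in every tissue (a tissue-specific eRNA is not
  also called housekeeping);
* housekeeping eRNAs are split at the quartiles of their coefficient of
  variation (sd/mean across tissue means, n−1) into low (≤ Q1),
  medium (between) and high (≥ Q3) variability groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .enhancer_calls import EnhancerCall
from .genomic_io import GenomicInterval

logger = logging.getLogger("cnnee")

__all__ = [
    "ErnaRegion",
    "ExpressionMatrix",
    "ErnaClassification",
    "define_erna_regions",
    "count_reads",
    "tmm_factors",
    "rpm_normalize",
    "classify_ernas",
    "cv_groups",
]

ERNA_HALF_BP = 3000
ERNA_LEN_BP = 2 * ERNA_HALF_BP


@dataclass
class ErnaRegion:
    """6 kb candidate eRNA region centred on its parent enhancer midpoint."""

    erna_id: str
    interval: GenomicInterval
    enhancer_id: str

    def __post_init__(self) -> None:
        if len(self.interval) != ERNA_LEN_BP:
            raise ValueError(
                f"eRNA region must span {ERNA_LEN_BP} bp, got {len(self.interval)}"
            )


@dataclass
class ExpressionMatrix:
    """eRNA × sample RPM values with tissue labels and effective libraries."""

    values: pd.DataFrame  # RPM, eRNA × sample
    tissue_labels: pd.Series  # sample → tissue
    effective_library_sizes: pd.Series  # sample → library × TMM factor

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("RPM values must be non-negative")
        missing = set(self.values.columns) - set(self.tissue_labels.index)
        if missing:
            raise ValueError(f"samples without tissue label: {sorted(missing)[:3]}")

    def tissue_means(self) -> pd.DataFrame:
        """Per-tissue mean RPM (eRNA × tissue)."""
        return self.values.T.groupby(self.tissue_labels).mean().T


@dataclass
class ErnaClassification:
    erna_id: str
    detectable: bool
    specific_tissue: str | None
    housekeeping: bool
    cv: float | None = None
    cv_group: str | None = None


def define_erna_regions(
    enhancers: Sequence[EnhancerCall],
    exons: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
) -> list[ErnaRegion]:
    """± 3 kb around each enhancer midpoint, minus exon overlaps and edges."""
    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ex in exons:
        exon_by_chrom.setdefault(ex.chrom, []).append((ex.start, ex.end))
    regions: list[ErnaRegion] = []
    n_bounds, n_exonic = 0, 0
    for k, call in enumerate(enhancers):
        mid = call.interval.midpoint
        start, end = mid - ERNA_HALF_BP, mid + ERNA_HALF_BP
        size = chrom_sizes.get(call.interval.chrom)
        if size is None:
            raise KeyError(
                f"enhancer on chromosome {call.interval.chrom!r} absent from "
                "the size table"
            )
        if start < 0 or end > size:
            n_bounds += 1
            continue
        if any(
            s < end and start < e
            for s, e in exon_by_chrom.get(call.interval.chrom, [])
        ):
            n_exonic += 1
            continue
        regions.append(
            ErnaRegion(
                erna_id=f"eRNA{len(regions) + 1:06d}",
                interval=GenomicInterval(call.interval.chrom, start, end),
                enhancer_id=call.enhancer_id,
            )
        )
    if n_bounds or n_exonic:
        logger.info(
            "dropped %d region(s) at chromosome edges, %d overlapping "
            "protein-coding exons", n_bounds, n_exonic,
        )
    return regions


def count_reads(
    regions: Sequence[ErnaRegion],
    reads_per_sample: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Reads overlapping each region by ≥ 1 bp, counted once per region."""
    samples = sorted(reads_per_sample)
    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in reads_per_sample[sample]:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        arrays = {
            c: (np.array([x[0] for x in v]), np.array([x[1] for x in v]))
            for c, v in by_chrom.items()
        }
        for i, region in enumerate(regions):
            iv = region.interval
            arr = arrays.get(iv.chrom)
            if arr is None:
                continue
            starts, ends = arr
            counts[i, j] = int(np.sum((starts < iv.end) & (ends > iv.start)))
    return pd.DataFrame(counts, index=[r.erna_id for r in regions],
                        columns=samples)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame | np.ndarray,
    library_sizes: Sequence[float] | None = None,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the sample mean of those fractions.  Per sample, genes
    expressed in both it and the reference contribute a log2 ratio (M) and a
    log2 mean abundance (A); the most extreme 30% of M and 5% of A are
    trimmed and the factor is the precision-weighted mean of the retained M
    values (weights from the delta-method binomial variance).
    """
    mat = np.asarray(counts, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 samples")
    if library_sizes is None:
        lib = mat.sum(axis=0)
    else:
        lib = np.asarray(library_sizes, dtype=np.float64)
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive library size")

    frac = mat / lib
    q75 = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(mat.shape[1])
    yr, nr = mat[:, ref], lib[ref]
    for s in range(mat.shape[1]):
        y, n = mat[:, s], lib[s]
        keep = (y > 0) & (yr > 0)
        if not keep.any():
            factors[s] = 1.0
            continue
        m = np.log2((y[keep] / n) / (yr[keep] / nr))
        a = 0.5 * np.log2((y[keep] / n) * (yr[keep] / nr))
        v = (n - y[keep]) / (n * y[keep]) + (nr - yr[keep]) / (nr * yr[keep])
        if np.max(np.abs(m)) < 1e-6:
            factors[s] = 1.0
            continue
        ng = m.size
        lo_l = np.floor(ng * logratio_trim) + 1
        hi_l = ng + 1 - lo_l
        lo_s = np.floor(ng * abundance_trim) + 1
        hi_s = ng + 1 - lo_s
        rm = rankdata(m)
        ra = rankdata(a)
        trimmed = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        if not trimmed.any():
            factors[s] = 1.0
            continue
        f = np.sum(m[trimmed] / v[trimmed]) / np.sum(1.0 / v[trimmed])
        factors[s] = 2.0**f
    # rescale so factors multiply to 1
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def rpm_normalize(
    counts: pd.DataFrame,
    factors: Sequence[float],
    tissue_labels: pd.Series | Mapping[str, str],
    library_sizes: Sequence[float] | None = None,
) -> ExpressionMatrix:
    """RPM over the effective (TMM-scaled) library size.

    ``RPM[i, s] = counts[i, s] / (library_size[s] * factor[s]) * 1e6``; the
    library size defaults to the sample's column sum.
    """
    factors = np.asarray(factors, dtype=np.float64)
    if np.any(factors <= 0):
        raise ValueError("normalization factors must be positive")
    lib = (counts.sum(axis=0).to_numpy(dtype=np.float64)
           if library_sizes is None else np.asarray(library_sizes, float))
    eff = lib * factors
    if np.any(eff <= 0):
        raise ValueError("zero effective library size")
    rpm = counts.to_numpy(dtype=np.float64) / eff[None, :] * 1e6
    labels = pd.Series(dict(tissue_labels)) if not isinstance(
        tissue_labels, pd.Series) else tissue_labels
    return ExpressionMatrix(
        values=pd.DataFrame(rpm, index=counts.index, columns=counts.columns),
        tissue_labels=labels.reindex(counts.columns),
        effective_library_sizes=pd.Series(eff, index=counts.columns),
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_ernas(
    expr: ExpressionMatrix,
    detect_rpm: float = 1.0,
    specific_fold: float = 3.0,
) -> list[ErnaClassification]:
    """Detectable / tissue-specific / housekeeping calls from tissue means.

    The specificity comparison is strict (``mean_t > fold × mean of the other
    tissues' means``); the detectability and housekeeping gates are inclusive
    (``≥ detect_rpm``).  Specificity takes precedence over housekeeping.
    Results are invariant to sample and tissue ordering.
    """
    means = expr.tissue_means().sort_index(axis=1)
    tissues = list(means.columns)
    if len(tissues) < 2:
        raise ValueError("classification needs at least 2 tissues")
    m = means.to_numpy()
    n_t = len(tissues)
    out: list[ErnaClassification] = []
    row_sums = m.sum(axis=1)
    for i, erna_id in enumerate(means.index):
        detectable = bool(np.any(m[i] >= detect_rpm))
        specific: str | None = None
        if detectable:
            for t in range(n_t):
                other_mean = (row_sums[i] - m[i, t]) / (n_t - 1)
                if m[i, t] > specific_fold * other_mean:
                    specific = tissues[t]
                    break
        housekeeping = bool(np.all(m[i] >= detect_rpm)) and specific is None
        cv: float | None = None
        if housekeeping:
            cv = float(np.std(m[i], ddof=1) / np.mean(m[i]))
        out.append(
            ErnaClassification(
                erna_id=str(erna_id), detectable=detectable,
                specific_tissue=specific, housekeeping=housekeeping, cv=cv,
            )
        )
    cv_groups(out)
    return out


def cv_groups(classifications: Sequence[ErnaClassification]) -> dict[str, str]:
    """Assign low/medium/high CV groups to housekeeping eRNAs, in place.

    Boundaries are the linearly interpolated sample quartiles of the CV
    distribution; low: CV ≤ Q1; high: CV ≥ Q3; medium: strictly between.
    Low wins when Q1 == Q3 (degenerate all-equal case).
    """
    hk = [c for c in classifications if c.housekeeping]
    if not hk:
        return {}
    if len(hk) < 4:
        logger.warning(
            "only %d housekeeping eRNAs; CV quartile groups not assigned",
            len(hk),
        )
        return {}
    cvs = np.array([c.cv for c in hk], dtype=np.float64)
    q1, q3 = np.quantile(cvs, [0.25, 0.75])  # linear interpolation (type 7)
    groups: dict[str, str] = {}
    for c in hk:
        if c.cv <= q1:
            c.cv_group = "low"
        elif c.cv >= q3:
            c.cv_group = "high"
        else:
            c.cv_group = "medium"
        groups[c.erna_id] = c.cv_group
    return groups
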