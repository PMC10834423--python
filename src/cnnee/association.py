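"""Target-gene / regulator co-expression, QTL enrichment, conservation hits.

Within one tissue, candidate eRNA–gene pairs closer than 1 Mb (edge-to-edge
gap; 0 when overlapping) are tested with Spearman's rank correlation; pairs
with |rho| ≥ 0.3 and raw P < 0.05 are reported as targets, with
Benjamini–Hochberg FDR computed over every tested pair for the record.
Putative regulators (transcription factors) use the same statistical contract
without the distance filter.

QTL enrichment per trait: an eRNA is trait-associated when its region falls
within 2 Mb of any QTL of the trait.  The 2×2 table contrasts associated
fractions among eRNAs and among background regions (by default
coordinate-shuffled eRNA regions), tested two-sided with Fisher's exact test;
a trait is significant when P ≤ 0.05 and the relative enrichment exceeds 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .erna_quant import ErnaRegion, ExpressionMatrix
from .genomic_io import BlastHit, GeneModel, GenomicInterval

logger = logging.getLogger("cnnee")

__all__ = [
    "AssociationRecord",
    "QtlEnrichmentResult",
    "spearman_rho",
    "bh_fdr",
    "find_targets",
    "find_regulators",
    "fisher_exact",
    "qtl_enrichment",
    "shuffle_intervals",
    "conservation_filter",
]


@dataclass
class AssociationRecord:
    erna_id: str
    partner_id: str
    partner_kind: str  # "gene" or "tf"
    rho: float
    p_value: float
    fdr: float
    distance_bp: int | None = None
    partner_name: str | None = None


@dataclass
class QtlEnrichmentResult:
    trait: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    relative_enrichment: float

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05 and self.relative_enrichment > 1.0


# ---------------------------------------------------------------------------
# Statistics primitives
# ---------------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho on average ranks; P from the t approximation (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho is undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test (probability-ordering rule) + odds ratio.

    The odds ratio is the sample ``(a·d)/(b·c)``; NaN when 0/0.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2×2 table of non-negative integers")
    _or_cond, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    num, den = a * d, b * c
    if num == 0 and den == 0:
        odds = float("nan")
    elif den == 0:
        odds = float("inf")
    else:
        odds = float(num / den)
    return float(p), odds


# ---------------------------------------------------------------------------
# Co-expression
# ---------------------------------------------------------------------------

def _gene_bodies(genes: Sequence[GeneModel]) -> dict[str, GenomicInterval]:
    out: dict[str, GenomicInterval] = {}
    for g in genes:
        if not g.transcripts:
            continue
        chrom = g.transcripts[0][0].chrom
        start = min(tx.start for tx, _ in g.transcripts)
        end = max(tx.end for tx, _ in g.transcripts)
        out[g.gene_id] = GenomicInterval(chrom, start, end, name=g.gene_name)
    return out


def _edge_gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def _correlate(
    erna_expr: pd.DataFrame,
    partner_expr: pd.DataFrame,
    pairs: Sequence[tuple[str, str, int | None]],
    partner_kind: str,
    rho_min: float,
    p_max: float,
    partner_names: Mapping[str, str] | None = None,
) -> list[AssociationRecord]:
    tested: list[tuple[str, str, int | None, float, float]] = []
    for erna_id, partner_id, dist in pairs:
        x = erna_expr.loc[erna_id].to_numpy(dtype=float)
        y = partner_expr.loc[partner_id].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning(
                "constant expression for pair (%s, %s); excluded",
                erna_id, partner_id,
            )
            continue
        rho, p = spearman_rho(x, y)
        tested.append((erna_id, partner_id, dist, rho, p))
    if not tested:
        return []
    fdr = bh_fdr([t[4] for t in tested])
    records = []
    for (erna_id, partner_id, dist, rho, p), q in zip(tested, fdr):
        if abs(rho) >= rho_min and p < p_max:
            records.append(
                AssociationRecord(
                    erna_id=erna_id, partner_id=partner_id,
                    partner_kind=partner_kind, rho=rho, p_value=p,
                    fdr=float(q), distance_bp=dist,
                    partner_name=(partner_names or {}).get(partner_id),
                )
            )
    return records


def find_targets(
    erna_expr: ExpressionMatrix,
    erna_regions: Sequence[ErnaRegion],
    gene_expr: pd.DataFrame,
    genes: Sequence[GeneModel],
    tissue: str,
    max_dist_bp: int = 1_000_000,
    rho_min: float = 0.3,
    p_max: float = 0.05,
) -> list[AssociationRecord]:
    """Within one tissue, genes < 1 Mb away and significantly co-expressed.

    The distance filter is applied first (strict ``< max_dist_bp``, gap
    between the eRNA region and the gene body); kept pairs satisfy
    ``|rho| ≥ rho_min`` and raw ``P < p_max``.  BH FDR is computed over all
    tested pairs in the tissue.
    """
    samples = [s for s in erna_expr.values.columns
               if erna_expr.tissue_labels[s] == tissue]
    if len(samples) < 4:
        raise ValueError(f"tissue {tissue!r} has {len(samples)} samples, need ≥ 4")
    bodies = _gene_bodies(genes)
    region_of = {r.erna_id: r.interval for r in erna_regions}
    pairs: list[tuple[str, str, int | None]] = []
    for erna_id, region in region_of.items():
        if erna_id not in erna_expr.values.index:
            continue
        for gene_id, body in bodies.items():
            if gene_id not in gene_expr.index:
                continue
            gap = _edge_gap(region, body)
            if gap is not None and gap < max_dist_bp:
                pairs.append((erna_id, gene_id, gap))
    names = {g.gene_id: g.gene_name for g in genes if g.gene_name}
    return _correlate(
        erna_expr.values[samples], gene_expr[samples], pairs, "gene",
        rho_min, p_max, names,
    )


def find_regulators(
    erna_expr: ExpressionMatrix,
    tf_expr: pd.DataFrame,
    tf_list: Sequence[str],
    tissue: str | None = None,
    rho_min: float = 0.3,
    p_max: float = 0.05,
) -> list[AssociationRecord]:
    """TFs co-expressed with eRNAs; same thresholds, no distance filter."""
    if not tf_list:
        raise ValueError("TF list must be non-empty")
    present = [t for t in tf_list if t in tf_expr.index]
    for t in set(tf_list) - set(present):
        logger.warning("TF %s absent from the expression matrix; skipped", t)
    if tissue is not None:
        samples = [s for s in erna_expr.values.columns
                   if erna_expr.tissue_labels[s] == tissue]
        if len(samples) < 4:
            raise ValueError(f"tissue {tissue!r} has {len(samples)} samples")
    else:
        samples = list(erna_expr.values.columns)
    pairs = [
        (erna_id, tf, None)
        for erna_id in erna_expr.values.index
        for tf in present
    ]
    return _correlate(
        erna_expr.values[samples], tf_expr[samples], pairs, "tf",
        rho_min, p_max,
    )


# ---------------------------------------------------------------------------
# QTL enrichment
# ---------------------------------------------------------------------------

def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    seed: int = 0,
) -> list[GenomicInterval]:
    """Length-preserving uniform re-placement (the default QTL background)."""
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    out = []
    for iv in intervals:
        length = len(iv)
        for _ in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            if chrom_sizes[chrom] > length:
                start = int(rng.integers(0, chrom_sizes[chrom] - length))
                out.append(GenomicInterval(chrom, start, start + length))
                break
        else:
            raise ValueError(f"cannot place a {length} bp interval anywhere")
    return out


def _associated_mask(
    regions: Sequence[GenomicInterval],
    qtls: Sequence[GenomicInterval],
    window_bp: int,
) -> np.ndarray:
    expanded: dict[str, list[tuple[int, int]]] = {}
    for q in qtls:
        expanded.setdefault(q.chrom, []).append(
            (max(0, q.start - window_bp), q.end + window_bp)
        )
    mask = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        mask[i] = any(
            s < r.end and r.start < e for s, e in expanded.get(r.chrom, [])
        )
    return mask


def qtl_enrichment(
    ernas: Sequence[ErnaRegion] | Sequence[GenomicInterval],
    qtls: Sequence[tuple[str, GenomicInterval]],
    background: Sequence[GenomicInterval],
    window_bp: int = 2_000_000,
) -> list[QtlEnrichmentResult]:
    """Per-trait Fisher test of eRNA vs background 2 Mb QTL proximity."""
    if not background:
        raise ValueError("background regions must be non-empty")
    regions = [e.interval if isinstance(e, ErnaRegion) else e for e in ernas]
    by_trait: dict[str, list[GenomicInterval]] = {}
    for trait, q in qtls:
        by_trait.setdefault(trait, []).append(q)
    results: list[QtlEnrichmentResult] = []
    for trait in sorted(by_trait):
        trait_qtls = by_trait[trait]
        if not trait_qtls:
            logger.warning("trait %s has no QTLs; skipped", trait)
            continue
        a = int(_associated_mask(regions, trait_qtls, window_bp).sum())
        b = int(_associated_mask(background, trait_qtls, window_bp).sum())
        table = ((a, len(regions) - a), (b, len(background) - b))
        p, _odds = fisher_exact(table)
        erna_frac = a / len(regions)
        bg_frac = b / len(background)
        enrich = erna_frac / bg_frac if bg_frac > 0 else float("inf")
        results.append(QtlEnrichmentResult(trait, table, p, enrich))
    return results


# ---------------------------------------------------------------------------
# Conservation hit filtering
# ---------------------------------------------------------------------------

def conservation_filter(
    hits: Sequence[BlastHit],
    identity_min: float = 0.5,
    evalue_max: float = 1e-5,
) -> dict[str, BlastHit]:
    """Keep significant hits, then one best hit per query.

    Best = lowest e-value, ties broken by highest identity, then lexicographic
    subject id.
    """
    best: dict[str, BlastHit] = {}
    for hit in hits:
        if hit.identity_fraction < identity_min or hit.evalue > evalue_max:
            continue
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
            continue
        key_new = (hit.evalue, -hit.identity_fraction, hit.subject_id)
        key_cur = (cur.evalue, -cur.identity_fraction, cur.subject_id)
        if key_new < key_cur:
            best[hit.query_id] = hit
    return best
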