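"""eRNA regions, read counting, TMM/RPM normalization and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import cnnee as C
from cnnee.enhancer_calls import EnhancerCall
from cnnee.erna_quant import (
    ErnaClassification,
    ErnaRegion,
    classify_ernas,
    count_reads,
    cv_groups,
    define_erna_regions,
    rpm_normalize,
    tmm_factors,
)
from cnnee.genomic_io import GenomicInterval


def _enh(start, end, chrom="chr1", eid="E1"):
    iv = GenomicInterval(chrom, start, end)
    return EnhancerCall(interval=iv, source_window=iv, prob=0.9,
                        enhancer_id=eid)


def _region(start, chrom="chr1", rid="r1", eid="E1"):
    return ErnaRegion(rid, GenomicInterval(chrom, start, start + 6000), eid)


SIZES = {"chr1": 1_000_000, "chr2": 1_000_000}


class TestDefineErnaRegions:
    def test_region_is_6kb_centred_on_midpoint(self):
        (region,) = define_erna_regions([_enh(10_000, 11_000)], [], SIZES)
        assert (region.interval.start, region.interval.end) == (7500, 13_500)
        assert len(region.interval) == 6000
        assert region.enhancer_id == "E1"

    def test_one_bp_exon_overlap_excluded(self):
        exon = GenomicInterval("chr1", 13_499, 13_600)
        assert define_erna_regions([_enh(10_000, 11_000)], [exon], SIZES) == []

    def test_bookended_exon_kept(self):
        exon = GenomicInterval("chr1", 13_500, 13_600)
        assert len(define_erna_regions([_enh(10_000, 11_000)], [exon],
                                       SIZES)) == 1

    def test_region_past_chromosome_start_dropped(self):
        # midpoint 2000 → region would start at −1000
        assert define_erna_regions([_enh(1500, 2500)], [], SIZES) == []

    def test_unknown_chromosome_hard_error(self):
        with pytest.raises(KeyError):
            define_erna_regions([_enh(10_000, 11_000, chrom="chrZ")], [],
                                SIZES)

    def test_exclusion_matches_brute_force_oracle(self, rng):
        enhancers = [
            _enh(int(s), int(s) + int(rng.integers(200, 1500)), eid=f"E{i}")
            for i, s in enumerate(rng.integers(10_000, 900_000, 60))
        ]
        exons = [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 3000)))
            for s in rng.integers(0, 1_000_000, 80)
        ]
        got = {r.enhancer_id for r in define_erna_regions(enhancers, exons,
                                                          SIZES)}
        expected = set()
        for e in enhancers:
            mid = (e.interval.start + e.interval.end) // 2
            s, t = mid - 3000, mid + 3000
            if s < 0 or t > SIZES["chr1"]:
                continue
            if any(x.start < t and s < x.end for x in exons):
                continue
            expected.add(e.enhancer_id)
        assert got == expected


class TestCountReads:
    def test_any_overlap_counting(self):
        region = _region(10_000)
        reads = {
            "s1": [GenomicInterval("chr1", 12_000, 12_100),  # inside
                   GenomicInterval("chr1", 15_999, 16_050),  # 1 bp overlap
                   GenomicInterval("chr1", 16_000, 16_100)],  # bookended: out
            "s2": [],
        }
        counts = count_reads([region], reads)
        assert counts.loc["r1", "s1"] == 2
        assert counts.loc["r1", "s2"] == 0

    def test_matches_all_pairs_oracle(self, rng):
        regions = [_region(int(s) // 10 * 10, rid=f"r{i}")
                   for i, s in enumerate(rng.integers(0, 900_000, 25))]
        reads = {
            f"s{j}": [
                GenomicInterval("chr1", int(s), int(s) + 80)
                for s in rng.integers(0, 990_000, 400)
            ]
            for j in range(3)
        }
        counts = count_reads(regions, reads)
        for region in regions:
            for sample, rs in reads.items():
                expected = sum(r.overlaps(region.interval) for r in rs)
                assert counts.loc[region.erna_id, sample] == expected


def _tmm_oracle(mat, lib=None):
    """Independent loop-based restatement of the trimmed-mean definition."""
    mat = np.asarray(mat, float)
    lib = mat.sum(axis=0) if lib is None else np.asarray(lib, float)
    q75 = [np.quantile(mat[:, s] / lib[s], 0.75) for s in range(mat.shape[1])]
    ref = min(range(mat.shape[1]), key=lambda s: abs(q75[s] - np.mean(q75)))
    factors = []
    for s in range(mat.shape[1]):
        m_vals, a_vals, w_vals = [], [], []
        for g in range(mat.shape[0]):
            y, yr = mat[g, s], mat[g, ref]
            if y > 0 and yr > 0:
                p, pr = y / lib[s], yr / lib[ref]
                m_vals.append(np.log2(p / pr))
                a_vals.append(0.5 * np.log2(p * pr))
                w_vals.append((lib[s] - y) / (lib[s] * y)
                              + (lib[ref] - yr) / (lib[ref] * yr))
        if not m_vals or max(abs(v) for v in m_vals) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m_vals)
        lo_l, hi_l = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_s, hi_s = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rm, ra = rankdata(m_vals), rankdata(a_vals)
        num = den = 0.0
        for i in range(n):
            if lo_l <= rm[i] <= hi_l and lo_s <= ra[i] <= hi_s:
                num += m_vals[i] / w_vals[i]
                den += 1.0 / w_vals[i]
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        mat = pd.DataFrame(np.tile([[10], [40], [5], [100]], (1, 4)))
        assert np.allclose(tmm_factors(mat), 1.0)

    def test_geometric_mean_is_one(self, rng):
        mat = pd.DataFrame(rng.negative_binomial(5, 0.02, size=(300, 5)))
        factors = tmm_factors(mat)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        a = np.array([10, 50, 3, 200, 80, 7, 15, 120])
        mat = pd.DataFrame({"A": a, "B": 2 * a})
        assert np.allclose(tmm_factors(mat), [1.0, 1.0])

    def test_all_zero_sample_rejected(self):
        mat = pd.DataFrame({"A": [1, 2], "B": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(mat)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(pd.DataFrame({"A": [1, 2]}))

    def test_matches_independent_reimplementation(self, rng):
        """Factors agree with a separate loop-based oracle to 1e-8 on 50
        random over-dispersed matrices."""
        for _ in range(50):
            n_genes = int(rng.integers(50, 300))
            n_samples = int(rng.integers(2, 7))
            mat = rng.negative_binomial(3, 0.05, size=(n_genes, n_samples))
            mat[:, 0] += 1  # keep every sample non-zero
            mat = pd.DataFrame(mat + (mat.sum(axis=0, keepdims=True) == 0))
            assert np.allclose(tmm_factors(mat), _tmm_oracle(mat), atol=1e-8)

    def test_matches_edger_reference(self, rng, tmp_path):
        """Cross-check against the Bioconductor implementation."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        mat = rng.negative_binomial(5, 0.01, size=(400, 6)).astype(int)
        mat[:50, 3] *= 4
        df = pd.DataFrame(mat)
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t", index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(edgeR)); '
             f'x <- as.matrix(read.delim("{path}")); '
             'cat(sprintf("%.10f", calcNormFactors(x, method="TMM")))'],
            capture_output=True, text=True, timeout=120,
        )
        if r.returncode != 0:
            pytest.skip(f"edgeR unavailable: {r.stderr[:100]}")
        reference = np.array([float(v) for v in r.stdout.split()])
        assert np.allclose(tmm_factors(df), reference, atol=1e-6)


class TestRpm:
    def test_arithmetic(self):
        counts = pd.DataFrame({"s1": [4]}, index=["r1"])
        expr = rpm_normalize(counts, [1.0], {"s1": "t1"},
                             library_sizes=[2_000_000])
        assert expr.values.loc["r1", "s1"] == pytest.approx(2.0)

    def test_zero_count_is_zero_rpm(self):
        counts = pd.DataFrame({"s1": [0, 5]}, index=["a", "b"])
        expr = rpm_normalize(counts, [1.0], {"s1": "t"})
        assert expr.values.loc["a", "s1"] == 0.0

    def test_column_sums_match_direct_formula(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(40, 3)),
                              columns=["a", "b", "c"])
        factors = np.array([0.8, 1.0, 1.25])
        libs = np.array([1e6, 2e6, 5e5])
        expr = rpm_normalize(counts, factors, {"a": "t", "b": "t", "c": "t"},
                             library_sizes=libs)
        expected = counts.sum(axis=0).to_numpy() / (libs * factors) * 1e6
        assert np.allclose(expr.values.sum(axis=0), expected)

    def test_nonpositive_factor_rejected(self):
        counts = pd.DataFrame({"s1": [1], "s2": [2]})
        with pytest.raises(ValueError):
            rpm_normalize(counts, [0.0, 1.0], {"s1": "t", "s2": "t"})


def _expr_from_tissue_means(means: dict[str, list[float]], n_samples=4):
    """ExpressionMatrix with exact per-tissue means (no sampling noise)."""
    tissues = sorted(means)
    n_ernas = len(next(iter(means.values())))
    cols, labels = {}, {}
    for t in tissues:
        for j in range(n_samples):
            name = f"{t}_{j}"
            cols[name] = means[t]
            labels[name] = t
    values = pd.DataFrame(cols, index=[f"e{i}" for i in range(n_ernas)])
    return C.ExpressionMatrix(
        values=values, tissue_labels=pd.Series(labels),
        effective_library_sizes=pd.Series(1e6, index=values.columns),
    )


class TestClassifyErnas:
    def test_specificity_strictly_above_threefold(self):
        expr = _expr_from_tissue_means({"A": [10.0, 9.0], "B": [3.0, 3.0],
                                        "C": [3.0, 3.0]})
        cls = {c.erna_id: c for c in classify_ernas(expr)}
        assert cls["e0"].specific_tissue == "A"  # 10 > 3×3
        assert cls["e1"].specific_tissue is None  # 9 = 3×3: strict >

    def test_housekeeping_inclusive_gate(self):
        expr = _expr_from_tissue_means({"A": [1.2, 0.9], "B": [1.5, 1.5],
                                        "C": [1.1, 1.1]})
        cls = {c.erna_id: c for c in classify_ernas(expr)}
        assert cls["e0"].housekeeping
        assert not cls["e1"].housekeeping  # one tissue below 1
        assert cls["e1"].detectable  # but ≥ 1 somewhere

    def test_specificity_takes_precedence_over_housekeeping(self):
        expr = _expr_from_tissue_means({"A": [20.0], "B": [1.5], "C": [1.5]})
        (c,) = classify_ernas(expr)
        assert c.specific_tissue == "A"
        assert not c.housekeeping

    def test_undetectable_never_specific(self):
        expr = _expr_from_tissue_means({"A": [0.9], "B": [0.1], "C": [0.1]})
        (c,) = classify_ernas(expr)
        assert not c.detectable
        assert c.specific_tissue is None

    def test_single_tissue_rejected(self):
        expr = _expr_from_tissue_means({"A": [1.0]})
        with pytest.raises(ValueError):
            classify_ernas(expr)

    def test_invariant_to_sample_and_tissue_order(self, rng):
        means = {t: list(rng.uniform(0, 5, 30)) for t in ("A", "B", "C", "D")}
        expr = _expr_from_tissue_means(means)
        shuffled = expr.values[list(rng.permutation(expr.values.columns))]
        expr2 = C.ExpressionMatrix(
            values=shuffled, tissue_labels=expr.tissue_labels,
            effective_library_sizes=expr.effective_library_sizes,
        )
        a = [(c.erna_id, c.specific_tissue, c.housekeeping)
             for c in classify_ernas(expr)]
        b = [(c.erna_id, c.specific_tissue, c.housekeeping)
             for c in classify_ernas(expr2)]
        assert a == b


class TestCvGroups:
    @staticmethod
    def _hk(cvs):
        return [
            ErnaClassification(erna_id=f"e{i}", detectable=True,
                               specific_tissue=None, housekeeping=True, cv=cv)
            for i, cv in enumerate(cvs)
        ]

    def test_quartile_boundaries_linear_interpolation(self):
        groups = cv_groups(self._hk([0.1, 0.2, 0.3, 0.4]))
        assert groups == {"e0": "low", "e1": "medium", "e2": "medium",
                          "e3": "high"}

    def test_all_equal_cvs_resolve_low(self):
        groups = cv_groups(self._hk([0.2, 0.2, 0.2, 0.2]))
        assert set(groups.values()) == {"low"}

    def test_partition_covers_all_housekeeping(self, rng):
        hk = self._hk(list(rng.uniform(0, 1, 37)))
        groups = cv_groups(hk)
        assert len(groups) == 37
        assert all(c.cv_group in ("low", "medium", "high") for c in hk)

    def test_matches_quantile_oracle(self, rng):
        cvs = list(rng.uniform(0, 2, 25))
        groups = cv_groups(self._hk(cvs))
        q1, q3 = np.quantile(cvs, [0.25, 0.75])
        for i, cv in enumerate(cvs):
            expected = ("low" if cv <= q1 else
                        "high" if cv >= q3 else "medium")
            assert groups[f"e{i}"] == expected
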