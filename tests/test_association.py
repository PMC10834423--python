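"""Co-expression statistics, QTL enrichment and conservation filtering."""

import math

import numpy as np
import pandas as pd
import pytest

import cnnee as C
from cnnee.association import (
    bh_fdr,
    conservation_filter,
    find_regulators,
    find_targets,
    fisher_exact,
    qtl_enrichment,
    shuffle_intervals,
    spearman_rho,
)
from cnnee.erna_quant import ErnaRegion, ExpressionMatrix
from cnnee.genomic_io import BlastHit, GeneModel, GenomicInterval


class TestSpearman:
    def test_monotone_and_antitone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho(x, [2, 4, 6, 8, 10])[0] == pytest.approx(1.0)
        assert spearman_rho(x, [10, 8, 6, 4, 2])[0] == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [3, 2, 1])

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        """With ties, rho equals Pearson correlation of average ranks and the
        p-value equals the t-approximation on n−2 df (independent oracle)."""
        from scipy.stats import rankdata, t as t_dist

        for _ in range(300):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 6, n).astype(float)  # many ties
            y = rng.integers(0, 6, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = spearman_rho(x, y)
            rx, ry = rankdata(x), rankdata(y)
            expected_rho = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(expected_rho, abs=1e-12)
            if abs(expected_rho) < 1:
                tt = expected_rho * math.sqrt(
                    (n - 2) / (1 - expected_rho**2))
                expected_p = 2 * t_dist.sf(abs(tt), n - 2)
                assert p == pytest.approx(expected_p, rel=1e-9)


class TestBhFdr:
    def test_matches_direct_definition_oracle(self, rng):
        """Step-up adjusted p-values equal min_{j≥i} (m·p_(j)/j) clipped at 1,
        on 1000 random p-vectors."""
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.random(m)
            got = bh_fdr(p)
            order = np.argsort(p)
            ranked = p[order]
            adj = ranked * m / np.arange(1, m + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj, 1.0)
            assert np.allclose(got, expected, atol=1e-12)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0


def _fisher_oracle(a, b, c, d):
    """Two-sided p by exact-integer probability-ordering enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    num_a = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(n, c1)
    p_num = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        num_x = math.comb(r1, x) * math.comb(r2, c1 - x)
        if num_x <= num_a:
            p_num += num_x
    return p_num / total


class TestFisherExact:
    def test_symmetric_table(self):
        p, odds = fisher_exact([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_fully_discordant_table(self):
        p, _ = fisher_exact([[0, 10], [10, 0]])
        assert p == pytest.approx(_fisher_oracle(0, 10, 10, 0))
        assert p == pytest.approx(2 / math.comb(20, 10))

    def test_odds_ratio_conventions(self):
        assert math.isnan(fisher_exact([[0, 5], [0, 5]])[1])
        assert fisher_exact([[3, 0], [1, 2]])[1] == math.inf

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])

    def test_random_tables_match_enumeration_oracle(self, rng):
        for _ in range(300):
            a, b, c, d = (int(v) for v in rng.integers(0, 16, 4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p, _ = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(_fisher_oracle(a, b, c, d), abs=1e-10)


def _expression(n_ernas, n_samples, rng, rho_pairs=None):
    """eRNA RPM matrix (+ optionally correlated gene matrix)."""
    x = rng.normal(0, 1, size=(n_ernas, n_samples))
    values = pd.DataFrame(
        np.exp(x), index=[f"e{i}" for i in range(n_ernas)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    labels = pd.Series("liver", index=values.columns)
    expr = ExpressionMatrix(values=values, tissue_labels=labels,
                            effective_library_sizes=pd.Series(
                                1e6, index=values.columns))
    return expr, x


class TestFindTargets:
    def _setup(self, rng, gene_positions, rho=0.9):
        n = 40
        expr, latent = _expression(3, n, rng)
        regions = [
            ErnaRegion(f"e{i}", GenomicInterval("chr1", 1_000_000 + i * 10_000,
                                                1_006_000 + i * 10_000), f"E{i}")
            for i in range(3)
        ]
        genes, rows = [], []
        for k, pos in enumerate(gene_positions):
            gid = f"g{k}"
            tx = GenomicInterval("chr1", pos, pos + 5000, name=f"{gid}.1",
                                 strand="+")
            genes.append(GeneModel(gene_id=gid, gene_name=f"G{k}",
                                   transcripts=[(tx, 1.0)]))
            z = rho * latent[0] + math.sqrt(1 - rho**2) * rng.normal(0, 1, n)
            rows.append(np.exp(z))
        gene_expr = pd.DataFrame(rows, index=[f"g{k}" for k in
                                              range(len(gene_positions))],
                                 columns=expr.values.columns)
        return expr, regions, gene_expr, genes

    def test_distance_filter_applied_first(self, rng):
        # gene 1.5 Mb away from every region: excluded regardless of rho
        expr, regions, gene_expr, genes = self._setup(rng, [2_600_000])
        out = find_targets(expr, regions, gene_expr, genes, "liver")
        assert out == []

    def test_nearby_correlated_gene_found(self, rng):
        expr, regions, gene_expr, genes = self._setup(rng, [1_050_000])
        out = find_targets(expr, regions, gene_expr, genes, "liver")
        assert any(r.erna_id == "e0" and r.partner_id == "g0" for r in out)
        rec = next(r for r in out if r.erna_id == "e0")
        assert rec.partner_name == "G0"
        assert rec.distance_bp is not None and rec.distance_bp < 1_000_000

    def test_overlapping_gene_distance_zero(self, rng):
        expr, regions, gene_expr, genes = self._setup(rng, [1_002_000])
        out = find_targets(expr, regions, gene_expr, genes, "liver")
        rec = next(r for r in out if r.erna_id == "e0" and r.partner_id == "g0")
        assert rec.distance_bp == 0

    def test_too_few_samples_rejected(self, rng):
        expr, regions, gene_expr, genes = self._setup(rng, [1_050_000])
        with pytest.raises(ValueError, match="samples"):
            find_targets(expr, regions, gene_expr, genes, "kidney")

    def test_invariant_to_sample_permutation(self, rng):
        expr, regions, gene_expr, genes = self._setup(rng, [1_050_000])
        perm = list(rng.permutation(expr.values.columns))
        expr2 = ExpressionMatrix(values=expr.values[perm],
                                 tissue_labels=expr.tissue_labels,
                                 effective_library_sizes=
                                 expr.effective_library_sizes)
        a = find_targets(expr, regions, gene_expr, genes, "liver")
        b = find_targets(expr2, regions, gene_expr[perm], genes, "liver")
        assert [(r.erna_id, r.partner_id, round(r.rho, 12)) for r in a] == \
               [(r.erna_id, r.partner_id, round(r.rho, 12)) for r in b]

    def test_planted_pairs_recovered_with_high_sensitivity(self, rng):
        """Planted rho=0.7 eRNA–gene pairs pass the |rho| ≥ 0.3, P < 0.05
        gate in ≥ 90% of simulations at n = 40."""
        hits = trials = 0
        for _ in range(100):
            expr, regions, gene_expr, genes = self._setup(rng, [1_050_000],
                                                          rho=0.7)
            out = find_targets(expr, regions, gene_expr, genes, "liver")
            trials += 1
            hits += any(r.erna_id == "e0" and r.partner_id == "g0"
                        for r in out)
        assert hits / trials >= 0.9


class TestFindRegulators:
    def test_identical_profile_retained_with_rho_one(self, rng):
        expr, latent = _expression(2, 20, rng)
        tfs = pd.DataFrame([expr.values.iloc[0].to_numpy()], index=["tf1"],
                           columns=expr.values.columns)
        out = find_regulators(expr, tfs, ["tf1"])
        rec = next(r for r in out if r.erna_id == "e0")
        assert rec.rho == pytest.approx(1.0)

    def test_empty_tf_list_rejected(self, rng):
        expr, _ = _expression(2, 20, rng)
        with pytest.raises(ValueError):
            find_regulators(expr, pd.DataFrame(), [])

    def test_absent_tf_skipped(self, rng):
        expr, _ = _expression(2, 20, rng)
        tfs = pd.DataFrame([expr.values.iloc[0].to_numpy()], index=["tf1"],
                           columns=expr.values.columns)
        out = find_regulators(expr, tfs, ["tf1", "ghost"])
        assert all(r.partner_id == "tf1" for r in out)

    def test_null_retention_near_joint_null_rate(self, rng):
        """Independent noise pairs pass the joint |rho| ≥ 0.3 AND P < 0.05
        gate at about the rate expected under the null (n = 20: the rho
        cut is the binding constraint)."""
        from scipy.stats import rankdata

        n = 20
        expr, _ = _expression(50, n, rng)
        tfs = pd.DataFrame(np.exp(rng.normal(0, 1, size=(20, n))),
                           index=[f"tf{j}" for j in range(20)],
                           columns=expr.values.columns)
        out = find_regulators(expr, tfs, list(tfs.index))
        rate = len(out) / (50 * 20)
        # Monte-Carlo estimate of P(|rho| ≥ 0.3 and p < 0.05) at n = 20
        null = 0
        m = 4000
        for _ in range(m):
            a, b = rng.normal(size=n), rng.normal(size=n)
            rho, p = spearman_rho(a, b)
            null += (abs(rho) >= 0.3) and (p < 0.05)
        expected = null / m
        assert rate == pytest.approx(expected, abs=0.03)


class TestQtlEnrichment:
    SIZES = {"chr1": 200_000_000}

    def _regions(self, positions):
        return [GenomicInterval("chr1", p, p + 6000) for p in positions]

    def test_association_distance_rule(self):
        qtl = GenomicInterval("chr1", 50_000_000, 50_100_000)
        near = self._regions([50_100_000 + 1_900_000])  # 1.9 Mb away
        far = self._regions([50_100_000 + 2_100_000])  # 2.1 Mb away
        background = self._regions([150_000_000])
        (res_near,) = qtl_enrichment(near, [("t", qtl)], background)
        (res_far,) = qtl_enrichment(far, [("t", qtl)], background)
        assert res_near.table[0][0] == 1
        assert res_far.table[0][0] == 0

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            qtl_enrichment(self._regions([0]), [], [])

    def test_enriched_and_null_rates_on_fixture(self):
        """Planted enriched traits are flagged in ≥ 90% of seeds; null traits
        at roughly the nominal 5% level."""
        sizes = {f"chr{i + 1}": 120_000_000 for i in range(10)}
        enr, nul = [], []
        for seed in range(40):
            ernas = C.make_clustered_intervals(sizes, 200, 1,
                                               cluster_span_bp=10_000,
                                               seed=seed)
            qtls, enriched = C.make_qtl_fixture(ernas, 10, 0.5, seed=seed,
                                                chrom_sizes=sizes)
            background = shuffle_intervals(ernas, sizes, seed=seed + 10_000)
            for r in qtl_enrichment(ernas, qtls, background):
                (enr if r.trait in enriched else nul).append(r.significant)
        assert np.mean(enr) >= 0.9
        assert np.mean(nul) <= 0.1

    def test_shuffle_preserves_lengths_and_bounds(self, rng):
        ivs = self._regions(list(rng.integers(0, 150_000_000, 50)))
        out = shuffle_intervals(ivs, self.SIZES, seed=3)
        assert sorted(len(iv) for iv in out) == sorted(len(iv) for iv in ivs)
        assert all(0 <= iv.start and iv.end <= 200_000_000 for iv in out)


class TestConservationFilter:
    @staticmethod
    def _hit(q, s, identity, evalue):
        return BlastHit(q, s, identity, evalue)

    def test_identity_and_evalue_gates(self):
        hits = [self._hit("q1", "s1", 0.49, 1e-10),
                self._hit("q2", "s1", 0.9, 1e-4)]
        assert conservation_filter(hits) == {}

    def test_best_hit_lowest_evalue(self):
        hits = [self._hit("q", "s1", 0.8, 1e-8),
                self._hit("q", "s2", 0.7, 1e-9)]
        assert conservation_filter(hits)["q"].subject_id == "s2"

    def test_ties_broken_by_identity_then_subject(self):
        hits = [self._hit("q", "sB", 0.8, 1e-8),
                self._hit("q", "sA", 0.8, 1e-8),
                self._hit("q", "sC", 0.9, 1e-8)]
        assert conservation_filter(hits)["q"].subject_id == "sC"
        hits2 = [self._hit("q", "sB", 0.8, 1e-8),
                 self._hit("q", "sA", 0.8, 1e-8)]
        assert conservation_filter(hits2)["q"].subject_id == "sA"
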