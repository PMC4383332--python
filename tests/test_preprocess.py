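"""Filtering rules, normalization, HWE exact test, LD, coverage QC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wildqtl.datatypes import ExpressionMatrix, GeneAnnotation, GenotypeMatrix
from wildqtl import preprocess as pp


def _expr(counts: np.ndarray) -> ExpressionMatrix:
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(counts.shape[0])],
        columns=[f"s{i}" for i in range(counts.shape[1])],
    )
    return ExpressionMatrix(counts=df)


class TestGeneFilters:
    def test_ten_percent_rule_is_strict(self):
        # 20 individuals; non-zero in exactly 2 (10%) -> removed; in 3 -> kept
        counts = np.zeros((2, 20), dtype=int)
        counts[0, :2] = 1000
        counts[1, :3] = 1000
        kept = pp.filter_genes(_expr(counts), min_mean=0)
        assert list(kept.counts.index) == ["g1"]

    def test_mean_rule_is_inclusive(self):
        counts = np.array([[10] * 10, [9] * 10, [0] * 10])
        kept = pp.filter_genes(_expr(counts))
        assert list(kept.counts.index) == ["g0"]

    def test_exclusion_list(self):
        counts = np.full((2, 10), 100)
        kept = pp.filter_genes(_expr(counts), exclude=["g0"])
        assert list(kept.counts.index) == ["g1"]

    def test_empty_result_raises(self):
        with pytest.raises(ValueError):
            pp.filter_genes(_expr(np.zeros((2, 10), dtype=int)))


class TestRpkm:
    def test_arithmetic_and_scaling(self):
        counts = pd.DataFrame({"s0": [100, 0]}, index=["g0", "g1"])
        lengths = pd.Series([1000, 500], index=["g0", "g1"])
        totals = pd.Series([1e7], index=["s0"])
        rpkm = pp.compute_rpkm(counts, lengths, totals)
        assert rpkm.loc["g0", "s0"] == pytest.approx(10.0)
        assert rpkm.loc["g1", "s0"] == 0.0
        doubled = pp.compute_rpkm(counts, lengths, totals * 2)
        assert np.allclose(doubled.to_numpy(), rpkm.to_numpy() / 2)

    def test_zero_total_rejected(self):
        counts = pd.DataFrame({"s0": [1]}, index=["g0"])
        with pytest.raises(ValueError):
            pp.compute_rpkm(counts, pd.Series([100], index=["g0"]), pd.Series([0], index=["s0"]))


class TestNormalization:
    def test_exact_quantiles_on_tie_free_input(self, rng):
        # the per-gene inverse-normal step maps any tie-free vector onto the
        # exact Blom quantiles (mean 0 to machine precision)
        n = 25
        expected = np.sort(pp.rank_inverse_normal(rng.normal(size=n)))
        for _ in range(5):
            out = pp.rank_inverse_normal(rng.normal(size=n))
            assert np.allclose(np.sort(out), expected, atol=1e-12)
            assert abs(out.mean()) < 1e-12

    def test_per_gene_distribution_after_double_qn(self, rng):
        # cross-sample QN introduces within-gene ties (shared reference
        # values), which average ranks then merge: the per-gene output is
        # standard normal up to that small distortion
        expr = _expr(np.exp(rng.normal(4, 1, size=(30, 25))))
        norm = pp.normalize_expression(expr).normalized.to_numpy()
        assert np.all(np.abs(norm.mean(axis=1)) < 0.02)
        assert np.allclose(norm.std(axis=1), norm.std(axis=1).mean(), atol=0.05)

    def test_idempotent_per_gene_step(self, rng):
        values = rng.normal(size=40)
        once = pp.rank_inverse_normal(values)
        twice = pp.rank_inverse_normal(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_identical_rank_order_gives_identical_vectors(self, rng):
        base = rng.normal(size=(20, 15))
        expr = _expr(np.exp(base).round(3) * 1000)
        norm = pp.normalize_expression(expr).normalized
        # two genes with the same cross-sample rank order
        order = np.argsort(base[0])
        g_a = np.empty(15)
        g_a[order] = np.arange(15)
        counts = expr.counts.copy()
        counts.iloc[1] = (g_a + 1) * 7  # same ranks as gene 0's pattern
        counts.iloc[0] = (g_a + 1) * 3
        norm = pp.normalize_expression(ExpressionMatrix(counts=counts)).normalized
        assert np.allclose(norm.iloc[0], norm.iloc[1], atol=1e-12)

    def test_all_tied_gene_flagged(self):
        counts = np.vstack([np.full(10, 7), np.arange(10) + 1])
        out = pp.normalize_expression(_expr(counts))
        assert out.all_tied_genes == ["g0"]


class TestPcRegression:
    def test_k0_identity_and_orthogonality(self, rng):
        expr = _expr(rng.poisson(100, size=(40, 30)))
        norm = pp.normalize_expression(expr)
        same = pp.regress_out_pcs(norm, k=0)
        assert np.allclose(same.normalized.to_numpy(), norm.normalized.to_numpy())
        pcs = pp.expression_pcs(norm, 10)
        resid = pp.regress_out_pcs(norm, k=10).normalized.to_numpy()
        for pc in pcs:
            corr = resid @ pc
            assert np.all(np.abs(corr) < 1e-8)

    def test_k_too_large_rejected(self, rng):
        norm = pp.normalize_expression(_expr(rng.poisson(100, size=(5, 8))))
        with pytest.raises(ValueError):
            pp.regress_out_pcs(norm, k=8)


def _hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Direct enumeration over heterozygote counts using exact factorials."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    n_rare = min(n_a, n_b)

    # P(het | allele counts) = 2^het n! / (aa! het! bb!) * n_a! n_b! / (2n)!
    def p_exact(het: int) -> float:
        aa = (n_rare - het) // 2
        bb = (2 * n - n_rare - het) // 2
        num = (
            math.log(2) * het
            + math.lgamma(n + 1)
            - math.lgamma(aa + 1)
            - math.lgamma(het + 1)
            - math.lgamma(bb + 1)
            + math.lgamma(n_a + 1)
            + math.lgamma(n_b + 1)
            - math.lgamma(2 * n + 1)
        )
        return math.exp(num)

    hets = range(n_rare % 2, n_rare + 1, 2)
    probs = {h: p_exact(h) for h in hets}
    p_obs = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


class TestHweExact:
    def test_monomorphic_p_one(self):
        assert pp.hwe_exact_test(50, 0, 0) == 1.0

    def test_all_het_matches_enumeration(self):
        assert pp.hwe_exact_test(0, 50, 0) == pytest.approx(_hwe_oracle(0, 50, 0), abs=1e-12)

    def test_balanced_table(self):
        assert pp.hwe_exact_test(25, 50, 25) == pytest.approx(_hwe_oracle(25, 50, 25), abs=1e-12)

    def test_enumeration_oracle_all_tables_n_le_30(self):
        for n in range(1, 31):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = pp.hwe_exact_test(n_aa, n_ab, n_bb)
                    want = _hwe_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, abs=1e-9), (n_aa, n_ab, n_bb)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pp.hwe_exact_test(0, 0, 0)


def _toy_genotypes(G, pos=None, qual=None, depth=None, chrom="chr1"):
    n, p = G.shape
    pos = pos if pos is not None else (np.arange(p) + 1) * 1000
    sites = pd.DataFrame(
        dict(
            snp_id=[f"s{j}" for j in range(p)],
            chrom=chrom,
            pos=pos,
            ref="A",
            alt="G",
            qual=qual if qual is not None else np.full(p, 500.0),
        )
    )
    return GenotypeMatrix(
        samples=[f"i{i}" for i in range(n)],
        sites=sites,
        genotypes=np.asarray(G, float),
        depth=depth,
    )


class TestVariantFilters:
    def test_missingness_boundary_12_of_63(self):
        G = np.tile(np.array([0.0, 1.0, 2.0] * 21)[:, None], (1, 2))
        G[:13, 0] = np.nan  # 13/63 missing -> removed
        G[:12, 1] = np.nan  # 12/63 -> kept
        gm = _toy_genotypes(G)
        kept, log = pp.filter_variants(gm, annotation=None, hwe_alpha=0.0)
        assert list(kept.sites["snp_id"]) == ["s1"]
        assert log["missingness"] == 1

    def test_quality_boundary(self):
        G = np.tile(np.array([0.0, 1.0, 2.0] * 10)[:, None], (1, 2))
        gm = _toy_genotypes(G, qual=np.array([99.0, 100.0]))
        kept, log = pp.filter_variants(gm, annotation=None, hwe_alpha=0.0)
        assert list(kept.sites["snp_id"]) == ["s1"]
        assert log["quality"] == 1

    def test_gene_proximity_boundary_inclusive(self):
        ann = GeneAnnotation(
            genes=pd.DataFrame(
                dict(gene_id=["g"], chrom=["chr1"], start=[1_000_000], end=[1_010_000],
                     strand=["+"], gc=[0.45])
            ),
            exons=pd.DataFrame(
                dict(gene_id=["g"], chrom=["chr1"], start=[1_000_000], end=[1_010_000])
            ),
        )
        G = np.tile(np.array([0.0, 1.0, 2.0] * 10)[:, None], (1, 2))
        gm = _toy_genotypes(G, pos=np.array([1_210_000, 1_210_001]))
        kept, log = pp.filter_variants(gm, annotation=ann, hwe_alpha=0.0)
        assert list(kept.sites["snp_id"]) == ["s0"]
        assert log["gene_proximity"] == 1

    def test_monomorphic_and_coverage(self):
        G = np.column_stack([np.zeros(30), np.tile([0.0, 1, 2], 10)])
        depth = np.column_stack([np.full(30, 10.0), np.full(30, 4.9)])
        gm = _toy_genotypes(G, depth=depth)
        kept, log = pp.filter_variants(gm, annotation=None, hwe_alpha=0.0)
        assert kept.n_sites == 0
        assert log["monomorphic"] == 1 and log["coverage"] == 1

    def test_order_independence(self, rng):
        # each rule is evaluated on the raw matrix, so the intersection is
        # order-free; verify against manual single-rule applications
        G = rng.choice([0.0, 1.0, 2.0, np.nan], size=(63, 40), p=[0.4, 0.3, 0.2, 0.1])
        qual = rng.gamma(3, 60, size=40).round()
        gm = _toy_genotypes(G, qual=qual)
        kept, _ = pp.filter_variants(gm, annotation=None)
        fails = np.zeros(40, dtype=bool)
        for j in range(40):
            col = G[:, j]
            obs = col[~np.isnan(col)]
            mono = len(np.unique(obs)) < 2
            miss = np.isnan(col).mean() > 0.19
            if len(obs):
                aa, ab, bb = (obs == 0).sum(), (obs == 1).sum(), (obs == 2).sum()
                hwe = pp.hwe_exact_test(aa, ab, bb) < 0.05
            else:
                hwe = False
            fails[j] = mono or miss or hwe or (qual[j] < 100)
        assert set(kept.sites["snp_id"]) == {f"s{j}" for j in np.flatnonzero(~fails)}


class TestImpute:
    def test_no_missing_unchanged(self, rng):
        G = np.tile(np.array([0.0, 1, 2] * 10)[:, None], (1, 3))
        gm = _toy_genotypes(G)
        out, mask = pp.impute_missing(gm, rng)
        assert np.array_equal(out.genotypes, G)
        assert mask.sum() == 0

    def test_all_missing_site_rejected(self, rng):
        G = np.full((10, 1), np.nan)
        with pytest.raises(ValueError):
            pp.impute_missing(_toy_genotypes(G), rng)

    def test_imputed_mean_tracks_allele_frequency(self):
        # alt freq 0.3 among observed -> mean imputed dosage ~ 0.6
        G = np.tile(np.array([0.0] * 40 + [1.0] * 20 + [2.0] * 10 + [np.nan] * 30)[:, None], (1, 1))
        draws = []
        for seed in range(200):
            out, _ = pp.impute_missing(_toy_genotypes(G), np.random.default_rng(seed))
            draws.append(out.genotypes[70:, 0].mean())
        f = 40 / 70 * 0 + 20 / 70 * 0.5 + 10 / 70 * 1.0  # alt freq among observed
        assert abs(np.mean(draws) - 2 * f) < 0.03

    def test_zero_frequency_imputes_zero(self):
        G = np.array([[0.0], [0.0], [np.nan]])
        out, _ = pp.impute_missing(_toy_genotypes(G), np.random.default_rng(0))
        assert out.genotypes[2, 0] == 0.0


class TestLdDecay:
    def test_duplicated_snp_r2_one(self, rng):
        col = rng.choice([0.0, 1.0, 2.0], size=100, p=[0.3, 0.5, 0.2])
        G = np.column_stack([col, col])
        gm = _toy_genotypes(G, pos=np.array([1000, 2000]))
        ld = pp.estimate_ld_decay(gm, n_bins=2)
        comb = ld[(ld["maf_group"] == "combined") & (ld["n_pairs"] > 0)]
        assert comb["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_pair_beyond_100kb_excluded(self, rng):
        col = rng.choice([0.0, 1.0, 2.0], size=100, p=[0.3, 0.5, 0.2])
        G = np.column_stack([col, col])
        gm = _toy_genotypes(G, pos=np.array([1000, 102_000]))
        ld = pp.estimate_ld_decay(gm)
        assert ld["n_pairs"].sum() == 0

    def test_independent_snps_small_sample_floor(self, rng):
        n = 200
        G = rng.binomial(2, 0.3, size=(n, 60)).astype(float)
        gm = _toy_genotypes(G, pos=(np.arange(60) + 1) * 1500)
        ld = pp.estimate_ld_decay(gm)
        comb = ld[ld["maf_group"] == "combined"]
        pooled = (comb["mean_r2"] * comb["n_pairs"]).sum() / comb["n_pairs"].sum()
        assert pooled == pytest.approx(1.0 / (n - 1), rel=0.5)


class TestCoverageQc:
    def test_identical_depth_zero_ks(self):
        G = np.tile(np.array([0.0, 1, 2] * 10)[:, None], (1, 4))
        depth = np.full((30, 4), 20.0)
        table, d, p = pp.coverage_by_genotype_qc(_toy_genotypes(G, depth=depth))
        assert d == 0.0
        assert np.allclose(table.to_numpy(), 20.0)

    def test_absent_class_is_nan(self):
        G = np.tile(np.array([0.0, 1] * 15)[:, None], (1, 2))
        depth = np.full((30, 2), 10.0)
        table, _, _ = pp.coverage_by_genotype_qc(_toy_genotypes(G, depth=depth))
        assert table["hom_alt"].isna().all()

    def test_ks_matches_hand_computed_gap(self):
        # hom-ref per-site means {1,2,3}, hom-alt {2.5, 3.5, 4.5}: max CDF gap 2/3
        ref = np.array([1.0, 2.0, 3.0])
        alt = np.array([2.5, 3.5, 4.5])
        d = stats.ks_2samp(ref, alt).statistic
        assert d == pytest.approx(2.0 / 3.0)

    def test_ref_bias_injected(self):
        from wildqtl.synthetic_data import PopulationConfig, ReadSimConfig, generate_annotation, generate_genotypes

        cfg = PopulationConfig(n_individuals=60, n_genes=20, n_chromosomes=2, seed=4)
        ann = generate_annotation(cfg, np.random.default_rng(0))
        geno, _ = generate_genotypes(cfg, ann, ReadSimConfig(ref_mapping_bias=0.3), np.random.default_rng(1))
        table, d, p = pp.coverage_by_genotype_qc(geno)
        assert table["hom_ref"].mean() > table["hom_alt"].mean()
        assert p < 0.01


class TestCisWindowIndex:
    def test_matches_interval_scan(self, small_dataset):
        ann = small_dataset.annotation
        sites = small_dataset.genotypes.sites
        windows = pp.cis_window_index(ann, sites)
        genes = ann.genes.set_index("gene_id")
        for gid, idx in windows.items():
            g = genes.loc[gid]
            expected = [
                j
                for j in sites.index
                if sites.loc[j, "chrom"] == g["chrom"]
                and g["start"] - 200_000 <= sites.loc[j, "pos"] <= g["end"] + 200_000
            ]
            assert sorted(idx.tolist()) == expected
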