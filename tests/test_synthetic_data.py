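"""Generator invariants: determinism, spectra, LD, kinship, calibration."""

import numpy as np
import pandas as pd
import pytest

from wildqtl.datatypes import GenotypeMatrix
from wildqtl.eqtl_lmm import compute_kinship
from wildqtl.synthetic_data import (
    PopulationConfig,
    ReadSimConfig,
    TrueEffects,
    _draw_maf,
    generate_annotation,
    generate_dataset,
    generate_genotypes,
    preset_config,
    simulate_allelic_counts,
    simulate_expression,
)


def _fresh_rng(seed=0):
    return np.random.default_rng(seed)


class TestAnnotation:
    def test_exons_inside_genes_and_counts(self):
        cfg = PopulationConfig(n_genes=200, n_chromosomes=20, seed=5)
        ann = generate_annotation(cfg)
        assert len(ann.genes) == 200
        assert ann.genes["chrom"].nunique() == 20
        merged = ann.exons.merge(ann.genes, on=["gene_id", "chrom"], suffixes=("", "_g"))
        assert (merged["start"] >= merged["start_g"]).all()
        assert (merged["end"] <= merged["end_g"]).all()
        assert ann.exons.groupby("gene_id").size().min() >= 1

    def test_genes_non_overlapping_per_chromosome(self):
        ann = generate_annotation(PopulationConfig(n_genes=100, n_chromosomes=4, seed=2))
        for _, sub in ann.genes.groupby("chrom"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] > s["end"].to_numpy()[:-1]).all()

    def test_determinism(self):
        cfg = PopulationConfig(n_genes=30, seed=9)
        a1 = generate_annotation(cfg)
        a2 = generate_annotation(cfg)
        pd.testing.assert_frame_equal(a1.genes, a2.genes)
        pd.testing.assert_frame_equal(a1.exons, a2.exons)

    def test_rejects_impossible_placement(self):
        cfg = PopulationConfig(n_genes=50, n_chromosomes=1, chromosome_length=2_000_000, seed=0)
        with pytest.raises(ValueError):
            generate_annotation(cfg)


class TestGenotypes:
    def test_dataset_determinism_bit_for_bit(self):
        cfg = preset_config("baboon", seed=42, n_genes=12)
        d1 = generate_dataset(cfg)
        d2 = generate_dataset(cfg)
        np.testing.assert_array_equal(d1.genotypes.genotypes, d2.genotypes.genotypes)
        pd.testing.assert_frame_equal(d1.expression.counts, d2.expression.counts)
        pd.testing.assert_frame_equal(d1.allelic.table, d2.allelic.table)

    def test_maf_spectrum_contrast(self):
        rng = _fresh_rng(7)
        inter = _draw_maf("intermediate_rich", 10_000, rng)
        rare = _draw_maf("rare_rich", 10_000, rng)
        assert inter.mean() > rare.mean()
        assert inter.min() >= 0.02 and inter.max() <= 0.5
        assert rare.min() >= 0.02 and rare.max() <= 0.5

    def test_sample_maf_positive_and_in_windows(self, small_dataset):
        g = small_dataset.genotypes
        assert (g.maf() > 0).all()
        genes = small_dataset.annotation.genes
        for chrom, sub in g.sites.groupby("chrom"):
            gsub = genes[genes["chrom"] == chrom]
            for pos in sub["pos"]:
                assert (
                    (pos >= gsub["start"] - 200_000) & (pos <= gsub["end"] + 200_000)
                ).any()

    def test_related_fraction_cap(self):
        cfg = PopulationConfig(related_pair_fraction=0.6)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_kinship_sibs_vs_unrelated(self):
        # enough sib pairs and chromosomes that the mosaic variance averages out
        cfg = PopulationConfig(
            n_individuals=80, n_genes=120, n_chromosomes=24,
            snps_per_gene_mean=40, related_pair_fraction=0.4,
            meiosis_segment_length=1e6, seed=77,
        )
        ann = generate_annotation(cfg, _fresh_rng(1))
        geno, phi = generate_genotypes(cfg, ann, rng=_fresh_rng(2))
        est = compute_kinship(geno, standardize=True).K / 2.0
        iu = np.triu_indices(80, 1)
        sib = phi[iu] == 0.25
        assert sib.sum() >= 10
        assert abs(est[iu][sib].mean() - 0.25) < 0.05
        assert abs(est[iu][~sib].mean()) < 0.05

    def test_ld_decay_monotone(self, small_dataset):
        from wildqtl.preprocess import estimate_ld_decay

        ld = estimate_ld_decay(small_dataset.genotypes, max_dist=100_000, n_bins=5)
        comb = ld[ld["maf_group"] == "combined"].sort_values("dist_lo")
        r2 = comb["mean_r2"].to_numpy()
        assert np.all(np.diff(r2) <= 0.01)  # non-increasing up to MC noise

    def test_ld_independence_limit(self):
        cfg = PopulationConfig(n_individuals=100, n_genes=20, n_chromosomes=2,
                               ld_decay_length=1e-3, related_pair_fraction=0.0, seed=3)
        ann = generate_annotation(cfg, _fresh_rng(4))
        geno, _ = generate_genotypes(cfg, ann, rng=_fresh_rng(5))
        G = np.nan_to_num(geno.genotypes)
        # adjacent-SNP r^2 should hover near the no-LD sampling floor 1/(n-1)
        r2 = []
        for j in range(G.shape[1] - 1):
            a, b = G[:, j], G[:, j + 1]
            if a.std() > 0 and b.std() > 0:
                r2.append(np.corrcoef(a, b)[0, 1] ** 2)
        assert np.mean(r2) < 3.0 / (100 - 1)


class TestExpression:
    def test_variance_bookkeeping_pve_half(self):
        # pve_cis = 0.5 at high depth: squared correlation between the causal
        # dosage and log counts should come back ~0.5.  (Rank-inverse-normal
        # re-Gaussianization compresses the genotype-class separation of the
        # mixture slightly, so the exact-variance check lives on the log
        # scale, where counts are linear in the latent trait.)

        cfg = PopulationConfig(n_individuals=1000, n_genes=80, n_chromosomes=8,
                               snps_per_gene_mean=5, related_pair_fraction=0.0,
                               missing_rate=0.0, seed=8)
        ann = generate_annotation(cfg, _fresh_rng(10))
        geno, _ = generate_genotypes(cfg, ann, rng=_fresh_rng(11))
        gene_chrom = ann.genes.set_index("gene_id")["chrom"]
        rows = []
        rloc = _fresh_rng(13)
        for gid in ann.genes["gene_id"]:
            # pick one causal SNP per gene; beta chosen so var(x beta) = 1 = non-cis var
            cands = geno.sites.index[geno.sites["chrom"] == gene_chrom[gid]]
            j = int(rloc.choice(cands))
            x = geno.genotypes[:, j]
            beta = 1.0 / x.std()
            rows.append(dict(gene_id=gid, causal_snp=geno.sites.loc[j, "snp_id"],
                             beta_cis=beta, sigma_u2=0.0, sigma_f2=0.0, sigma_e2=1.0,
                             pve_cis_true=0.5, pve_trans_true=0.0,
                             allelic_imbalance=float(np.tanh(beta / 2))))
        truth = TrueEffects(effects=pd.DataFrame(rows))
        readcfg = ReadSimConfig(count_dispersion=1e-4, base_mean=5e4, base_log_sd=1.0,
                                lib_size_sd=0.0, n_hidden_factors=0, signal_log_sd=0.3)
        expr = simulate_expression(geno, ann, truth, None, readcfg, _fresh_rng(12))
        counts = expr.counts
        r2 = []
        lookup = {s: i for i, s in enumerate(geno.sites["snp_id"])}
        for row in truth.effects.itertuples():
            x = geno.genotypes[:, lookup[row.causal_snp]]
            logc = np.log1p(counts.loc[row.gene_id].to_numpy(float))
            r2.append(np.corrcoef(x, logc)[0, 1] ** 2)
        assert abs(np.mean(r2) - 0.5) < 0.05

    def test_degenerate_noise_constant_counts(self):
        cfg = PopulationConfig(n_individuals=40, n_genes=4, n_chromosomes=1,
                               snps_per_gene_mean=4, related_pair_fraction=0.0, seed=21)
        ann = generate_annotation(cfg, _fresh_rng(0))
        geno, _ = generate_genotypes(cfg, ann, rng=_fresh_rng(1))
        rows = [dict(gene_id=g, causal_snp=None, beta_cis=0.0, sigma_u2=0.0,
                     sigma_f2=0.0, sigma_e2=1e-12, pve_cis_true=0.0,
                     pve_trans_true=0.0, allelic_imbalance=0.0)
                for g in ann.genes["gene_id"]]
        truth = TrueEffects(effects=pd.DataFrame(rows))
        readcfg = ReadSimConfig(count_dispersion=0.0, base_mean=1e6, base_log_sd=0.0,
                                lib_size_sd=0.0, n_hidden_factors=0)
        expr = simulate_expression(geno, ann, truth, None, readcfg, _fresh_rng(2))
        counts = expr.counts.to_numpy(float)
        cv = counts.std(axis=1) / counts.mean(axis=1)
        assert (cv < 0.01).all()  # Poisson noise only, at depth 1e6

    def test_gc_bias_injected_positive(self):
        cfg = preset_config("baboon", seed=13, n_genes=60)
        readcfg = ReadSimConfig(gc_bias_slope=0.5)
        ds = generate_dataset(cfg, readcfg=readcfg)
        from wildqtl.preprocess import compute_rpkm

        rpkm = compute_rpkm(ds.expression.counts, ds.expression.gene_meta["length"])
        log_rpkm_mean = np.log1p(rpkm).mean(axis=1)
        gc = ds.expression.gene_meta["gc"]
        r = np.corrcoef(gc, log_rpkm_mean)[0, 1]
        assert r > 0.1


class TestAllelicCounts:
    @staticmethod
    def _one_gene_panel(n=400, seed=0, depth=200.0, rho=0.0):
        cfg = PopulationConfig(n_individuals=n, n_genes=8, n_chromosomes=2,
                               snps_per_gene_mean=6, exonic_snp_fraction=1.0,
                               related_pair_fraction=0.0, missing_rate=0.0, seed=seed)
        ann = generate_annotation(cfg, _fresh_rng(seed))
        geno, _ = generate_genotypes(cfg, ann, rng=_fresh_rng(seed + 1))
        readcfg = ReadSimConfig(mean_site_depth=depth, overdispersion_rho=rho)
        return cfg, ann, geno, readcfg

    @staticmethod
    def _truth(ann, geno, a, rng):
        rows = []
        for gid in ann.genes["gene_id"]:
            chrom = ann.genes.set_index("gene_id").loc[gid, "chrom"]
            cands = geno.sites.index[geno.sites["chrom"] == chrom]
            j = int(rng.choice(cands))
            beta = 2 * np.arctanh(a) if a else 0.0
            rows.append(dict(gene_id=gid, causal_snp=geno.sites.loc[j, "snp_id"] if a else None,
                             beta_cis=beta, sigma_u2=0.0, sigma_f2=0.0, sigma_e2=1.0,
                             pve_cis_true=0.0, pve_trans_true=0.0, allelic_imbalance=a))
        return TrueEffects(effects=pd.DataFrame(rows))

    def test_null_pooled_fraction_half(self):
        _, ann, geno, readcfg = self._one_gene_panel(seed=30)
        truth = self._truth(ann, geno, 0.0, _fresh_rng(1))
        ac = simulate_allelic_counts(geno, ann, truth, readcfg, _fresh_rng(2))
        pooled = ac.table["x_plus"].sum() / ac.table["total"].sum()
        assert abs(pooled - 0.5) < 0.01

    def test_imbalance_definition(self):
        _, ann, geno, readcfg = self._one_gene_panel(seed=31)
        truth = self._truth(ann, geno, 0.5, _fresh_rng(3))
        ac = simulate_allelic_counts(geno, ann, truth, readcfg, _fresh_rng(4), phase_mode="direct")
        frac = ac.table["x_plus"] / ac.table["total"]
        assert abs(frac.mean() - 0.75) < 0.02

    def test_overdispersion_inflates_variance(self):
        _, ann, geno, readcfg0 = self._one_gene_panel(seed=32, depth=60.0, rho=0.0)
        readcfg1 = ReadSimConfig(mean_site_depth=60.0, overdispersion_rho=0.1)
        truth = self._truth(ann, geno, 0.0, _fresh_rng(5))
        ac0 = simulate_allelic_counts(geno, ann, truth, readcfg0, _fresh_rng(6), phase_mode="direct")
        ac1 = simulate_allelic_counts(geno, ann, truth, readcfg1, _fresh_rng(6), phase_mode="direct")
        v0 = (ac0.table["x_plus"] / ac0.table["total"]).var()
        v1 = (ac1.table["x_plus"] / ac1.table["total"]).var()
        assert v1 > v0 * 2  # beta-binomial variance inflation 1 + (y-1)rho

    def test_calibration_slope(self):
        # pooled fractions across genes regress on 0.5 + a/2 with slope ~1
        _, ann, geno, readcfg = self._one_gene_panel(n=300, seed=33, depth=500.0)
        rng = _fresh_rng(7)
        a_values = rng.uniform(-0.8, 0.8, size=len(ann.genes))
        rows = []
        for gid, a in zip(ann.genes["gene_id"], a_values):
            rows.append(dict(gene_id=gid, causal_snp="x", beta_cis=1.0, sigma_u2=0.0,
                             sigma_f2=0.0, sigma_e2=1.0, pve_cis_true=0.0,
                             pve_trans_true=0.0, allelic_imbalance=float(a)))
        truth = TrueEffects(effects=pd.DataFrame(rows))
        ac = simulate_allelic_counts(geno, ann, truth, readcfg, _fresh_rng(8), phase_mode="direct")
        obs = ac.table.groupby("gene_id").apply(
            lambda t: t["x_plus"].sum() / t["total"].sum(), include_groups=False
        )
        expected = pd.Series(0.5 + a_values / 2.0, index=ann.genes["gene_id"])
        slope = np.polyfit(expected.loc[obs.index], obs, 1)[0]
        assert abs(slope - 1.0) < 0.05

    def test_sites_without_hets_omitted(self, small_dataset):
        t = small_dataset.allelic.table
        assert (t.groupby("site_id").size() >= 1).all()
        assert (t["total"] > 0).all()


def test_non_eqtl_genes_have_zero_effects(small_dataset):
    eff = small_dataset.truth.effects
    null = eff["causal_snp"].isna()
    assert (eff.loc[null, "beta_cis"] == 0).all()
    assert (eff.loc[null, "allelic_imbalance"] == 0).all()
    assert eff["pve_cis_true"].between(0, 1, inclusive="left").all()
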