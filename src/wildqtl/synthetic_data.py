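"""Synthetic genotype/expression/allelic-count generator.

Emulates the statistical structure of a small outbred RNA-seq eQTL cohort:
a few dozen individuals, dense cis-SNPs around each gene, population-specific
minor-allele-frequency spectra, distance-decaying linkage disequilibrium,
low-level background relatedness with a handful of sibling pairs, planted
cis-eQTL effects, a polygenic trans component, covariate effects, and
beta-binomially overdispersed allelic read counts at exonic heterozygous
sites.  Every draw is reproducible from a single integer seed.

The genotype model is a founder-haplotype copier: each chromosome carries a
finite pool of founder haplotypes whose alleles come from a latent Gaussian
autoregression with inter-site correlation ``exp(-d/L)`` (``L`` = LD decay
length); every sampled haplotype is a mosaic of founders.  A finite pool
produces the low-level background relatedness seen in wild populations
(expected kinship between "unrelated" pairs ~ 1/pool size), and sibling
pairs drawn from shared simulated parents supply the upper kinship tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AllelicCounts, ExpressionMatrix, GeneAnnotation, GenotypeMatrix

__all__ = [
    "PopulationConfig",
    "ReadSimConfig",
    "TrueEffects",
    "SyntheticDataset",
    "PRESETS",
    "preset_config",
    "generate_annotation",
    "generate_genotypes",
    "draw_true_effects",
    "sample_covariates",
    "simulate_expression",
    "simulate_allelic_counts",
    "generate_dataset",
    "write_dataset",
]

CIS_WINDOW = 200_000  # bp on either side of the gene body


@dataclass
class PopulationConfig:
    """Shape of the simulated population and its variant panel.

    ``maf_spectrum`` is ``"intermediate_rich"`` (Beta(0.8, 0.8) folded MAF,
    truncated to [0.02, 0.5]; balanced genotype classes, as in an older,
    admixed population) or ``"rare_rich"`` (1/x-weighted neutral-SFS grid on
    [0.02, 0.5]; rare-variant-heavy, human-outbred-like).
    """

    n_individuals: int = 63
    n_genes: int = 200
    n_chromosomes: int = 20
    snps_per_gene_mean: float = 45.4
    snp_count_shape: float = 0.65  # gamma shape; small => overdispersed counts
    maf_spectrum: str = "intermediate_rich"
    ld_decay_length: float = 20_000.0
    related_pair_fraction: float = 0.10
    n_founder_haplotypes: int = 66
    copy_segment_length: float = 500_000.0  # founder-mosaic segment scale
    meiosis_segment_length: float = 5_000_000.0  # crossover scale for siblings
    exonic_snp_fraction: float = 0.30
    missing_rate: float = 0.01
    chromosome_length: int | None = None  # bp cap per chromosome; None = grow
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.snps_per_gene_mean <= 0:
            raise ValueError("snps_per_gene_mean must be positive")
        if self.ld_decay_length <= 0:
            raise ValueError("ld_decay_length must be positive")
        if self.related_pair_fraction > 0.5:
            raise ValueError("related_pair_fraction must be <= 0.5")
        if self.maf_spectrum not in ("intermediate_rich", "rare_rich"):
            raise ValueError(f"unknown maf_spectrum {self.maf_spectrum!r}")


@dataclass
class ReadSimConfig:
    """Read-level and count-level noise model.

    ``overdispersion_rho`` is the beta-binomial intra-class correlation of
    allelic counts (0 = pure binomial).  ``ref_mapping_bias`` shifts the
    expected alternate-allele read fraction down by that amount at every
    heterozygous site, mimicking reads with non-reference alleles failing to
    map.  ``count_dispersion`` is the gene-level negative-binomial
    dispersion alpha (var = mu + alpha*mu^2).  ``gc_bias_slope`` shifts the
    log-mean count by slope * standardized gene GC, shared across samples up
    to per-sample amplitude jitter (``gc_jitter_sd``, a fraction of the
    shared slope) — amplification GC bias is protocol-driven and mostly
    common to a uniformly prepared batch.
    """

    mean_site_depth: float = 30.0
    overdispersion_rho: float = 0.02
    ref_mapping_bias: float = 0.0
    count_dispersion: float = 0.2
    gc_bias_slope: float = 0.0
    gc_jitter_sd: float = 0.1
    base_mean: float = 60.0  # median expected count per gene
    base_log_sd: float = 1.0
    signal_log_sd: float = 1.0  # log-scale amplitude of the latent trait
    lib_size_sd: float = 0.25
    het_depth_boost: float = 0.08
    n_hidden_factors: int = 3  # shared batch/environment factors

    def validate(self) -> None:
        for name in ("mean_site_depth", "count_dispersion"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0 <= self.overdispersion_rho < 1:
            raise ValueError("overdispersion_rho must be in [0, 1)")
        if self.ref_mapping_bias < 0:
            raise ValueError("ref_mapping_bias must be >= 0")


@dataclass
class TrueEffects:
    """Ground truth for parameter-recovery tests.

    ``effects`` has one row per gene: ``gene_id, causal_snp, beta_cis,
    sigma_u2, sigma_f2, sigma_e2, pve_cis_true, pve_trans_true,
    allelic_imbalance``.  Genes
    without an eQTL have ``causal_snp = None``, ``beta_cis = 0`` and
    ``allelic_imbalance = 0``.  ``covariate_betas`` is gene x covariate
    (latent-trait scale).
    """

    effects: pd.DataFrame
    covariate_betas: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        e = self.effects
        for col in ("pve_cis_true", "pve_trans_true"):
            if len(e) and ((e[col] < 0) | (e[col] >= 1)).any():
                raise ValueError(f"{col} must lie in [0, 1)")
        null = e["causal_snp"].isna()
        if len(e) and (e.loc[null, "beta_cis"] != 0).any():
            raise ValueError("non-eQTL genes must have beta_cis = 0")
        if len(e) and (e.loc[null, "allelic_imbalance"] != 0).any():
            raise ValueError("non-eQTL genes must have allelic_imbalance = 0")


@dataclass
class SyntheticDataset:
    config: PopulationConfig
    readcfg: ReadSimConfig
    annotation: GeneAnnotation
    genotypes: GenotypeMatrix
    kinship_true: np.ndarray  # pairwise kinship coefficients (phi)
    truth: TrueEffects
    covariates: pd.DataFrame
    expression: ExpressionMatrix
    allelic: AllelicCounts


# Presets mirror the two cohorts whose contrast motivates the power analyses:
# an admixed wild-baboon-like panel (63 individuals, ~45 intermediate-frequency
# SNPs per gene, long-range LD) and a human-YRI-like panel (69 individuals,
# ~20 rare-skewed SNPs per gene, short-range LD).
PRESETS: dict[str, dict] = {
    "baboon": dict(
        n_individuals=63,
        snps_per_gene_mean=45.4,
        snp_count_shape=0.65,
        maf_spectrum="intermediate_rich",
        ld_decay_length=20_000.0,
        related_pair_fraction=0.10,
        beta_mean=0.96,
    ),
    "yri": dict(
        n_individuals=69,
        snps_per_gene_mean=20.3,
        snp_count_shape=1.0,
        maf_spectrum="rare_rich",
        ld_decay_length=5_000.0,
        related_pair_fraction=0.0,
        beta_mean=0.80,
    ),
}


def preset_config(name: str, **overrides) -> PopulationConfig:
    """Build a :class:`PopulationConfig` from a named preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    params = {k: v for k, v in PRESETS[name].items() if k != "beta_mean"}
    params.update(overrides)
    return PopulationConfig(**params)


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: PopulationConfig, rng: np.random.Generator | None = None) -> GeneAnnotation:
    """Place non-overlapping genes with exon structure on chromosomes.

    Genes are assigned to chromosomes round-robin and laid out left to right
    with inter-gene gaps large enough that cis windows rarely collide.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    gene_rows = []
    exon_rows = []
    cursor = {c: 250_000 for c in range(config.n_chromosomes)}
    for g in range(config.n_genes):
        chrom_i = g % config.n_chromosomes
        chrom = f"chr{chrom_i + 1}"
        length = int(np.clip(np.exp(rng.normal(np.log(12_000), 0.6)), 2_000, 100_000))
        gap = int(300_000 + rng.exponential(200_000))
        start = cursor[chrom_i] + gap
        end = start + length - 1
        if config.chromosome_length is not None and end + 250_000 > config.chromosome_length:
            raise ValueError(
                f"cannot place {config.n_genes} genes on {config.n_chromosomes} "
                f"chromosomes of length {config.chromosome_length}"
            )
        cursor[chrom_i] = end
        strand = "+" if rng.random() < 0.5 else "-"
        gc = float(np.clip(rng.normal(0.45, 0.08), 0.25, 0.72))
        gene_id = f"G{g + 1:04d}"
        gene_rows.append((gene_id, chrom, start, end, strand, gc))
        n_exons = 1 + rng.poisson(3)
        if n_exons == 1 or length < 60 * n_exons:
            exon_rows.append((gene_id, chrom, start, end))
        else:
            # alternate exon/intron segments spanning [start, end]
            cuts = np.sort(rng.choice(np.arange(1, length - 1), size=2 * (n_exons - 1), replace=False))
            bounds = np.concatenate([[0], cuts, [length]])
            for k in range(0, len(bounds) - 1, 2):
                ex_start = start + int(bounds[k])
                ex_end = start + int(bounds[k + 1]) - 1
                if ex_end >= ex_start:
                    exon_rows.append((gene_id, chrom, ex_start, ex_end))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "gc"])
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    return GeneAnnotation(genes=genes, exons=exons)


# ---------------------------------------------------------------------------
# genotypes


def _draw_maf(spectrum: str, size: int, rng: np.random.Generator) -> np.ndarray:
    if spectrum == "intermediate_rich":
        # Beta(0.8, 0.8) restricted to [0.02, 0.5]
        out = np.empty(size)
        filled = 0
        while filled < size:
            draw = rng.beta(0.8, 0.8, size=2 * (size - filled) + 8)
            draw = draw[(draw >= 0.02) & (draw <= 0.5)]
            take = min(len(draw), size - filled)
            out[filled : filled + take] = draw[:take]
            filled += take
        return out
    # rare_rich: neutral-SFS 1/x weights on a grid over [0.02, 0.5]
    grid = np.linspace(0.02, 0.5, 400)
    w = 1.0 / grid
    w /= w.sum()
    return rng.choice(grid, size=size, p=w)


def _founder_haplotypes(
    alt_freq: np.ndarray, pos: np.ndarray, n_hap: int, decay: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent-Gaussian AR(1) haplotypes: corr(z_j, z_{j-1}) = exp(-d/L)."""
    p = len(pos)
    z = np.empty((n_hap, p))
    eps = rng.standard_normal((n_hap, p))
    z[:, 0] = eps[:, 0]
    if p > 1:
        r = np.exp(-np.diff(pos) / decay)
        s = np.sqrt(1.0 - r**2)
        for j in range(1, p):
            z[:, j] = r[j - 1] * z[:, j - 1] + s[j - 1] * eps[:, j]
    thresh = stats.norm.ppf(alt_freq)
    return (z < thresh[None, :]).astype(np.uint8)


def _mosaic(founders: np.ndarray, pos: np.ndarray, seg_len: float, rng: np.random.Generator) -> np.ndarray:
    """One haplotype copied from a founder pool with exp-distributed segments."""
    p = len(pos)
    if p == 1:
        switch = np.zeros(0, dtype=bool)
    else:
        switch = rng.random(p - 1) < 1.0 - np.exp(-np.diff(pos) / seg_len)
    seg_id = np.concatenate([[0], np.cumsum(switch)])
    choices = rng.integers(0, founders.shape[0], size=seg_id[-1] + 1)
    return founders[choices[seg_id], np.arange(p)]


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, pos: np.ndarray, seg_len: float, rng: np.random.Generator) -> np.ndarray:
    """Recombine two parental haplotypes into one gamete."""
    p = len(pos)
    if p == 1:
        switch = np.zeros(0, dtype=bool)
    else:
        switch = rng.random(p - 1) < 0.5 * (1.0 - np.exp(-2.0 * np.diff(pos) / seg_len))
    which = (np.concatenate([[rng.integers(0, 2)], np.cumsum(switch)]) % 2).astype(int)
    stacked = np.stack([hap_a, hap_b])
    return stacked[which, np.arange(p)]


def generate_genotypes(
    config: PopulationConfig,
    annotation: GeneAnnotation,
    readcfg: ReadSimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate the variant panel and genotypes; return (matrix, true kinship).

    True kinship is the matrix of pairwise kinship coefficients phi implied
    by the sampling design: 1/pool-size between "unrelated" pairs, 1/4 for
    sibling pairs, 1/2 on the diagonal.  The realized genomic relationship
    matrix estimates 2*phi off-diagonal.
    """
    config.validate()
    readcfg = readcfg or ReadSimConfig()
    readcfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    n = config.n_individuals
    genes = annotation.genes

    # --- SNP positions per gene ------------------------------------------------
    site_frames = []
    for _, gene in genes.iterrows():
        lam = rng.gamma(config.snp_count_shape, config.snps_per_gene_mean / config.snp_count_shape)
        n_snps = rng.poisson(lam)
        if n_snps == 0:
            continue
        n_exonic = rng.binomial(n_snps, config.exonic_snp_fraction)
        pos = []
        exons = annotation.exons[annotation.exons["gene_id"] == gene["gene_id"]]
        if n_exonic and len(exons):
            widths = (exons["end"] - exons["start"] + 1).to_numpy()
            pick = rng.choice(len(exons), size=n_exonic, p=widths / widths.sum())
            for k in pick:
                pos.append(int(rng.integers(exons.iloc[k]["start"], exons.iloc[k]["end"] + 1)))
        lo = max(1, gene["start"] - CIS_WINDOW)
        hi = gene["end"] + CIS_WINDOW
        pos.extend(int(x) for x in rng.integers(lo, hi + 1, size=n_snps - len(pos)))
        site_frames.append(pd.DataFrame({"chrom": gene["chrom"], "pos": sorted(set(pos))}))
    if not site_frames:
        raise ValueError("no SNPs generated; increase snps_per_gene_mean")
    sites = pd.concat(site_frames, ignore_index=True).drop_duplicates(["chrom", "pos"])
    chrom_order = {f"chr{i+1}": i for i in range(config.n_chromosomes)}
    sites["_c"] = sites["chrom"].map(chrom_order)
    sites = sites.sort_values(["_c", "pos"]).drop(columns="_c").reset_index(drop=True)

    p_total = len(sites)
    maf = _draw_maf(config.maf_spectrum, p_total, rng)
    alt_is_minor = rng.random(p_total) < 0.5
    alt_freq = np.where(alt_is_minor, maf, 1.0 - maf)

    # --- haplotypes per chromosome --------------------------------------------
    n_sib_pairs = int(round(config.related_pair_fraction * n / 2))
    n_unrelated = n - 2 * n_sib_pairs
    haps = np.zeros((2, n, p_total), dtype=np.uint8)
    for chrom, idx in sites.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        pos = sites.loc[idx, "pos"].to_numpy(float)
        founders = _founder_haplotypes(alt_freq[idx], pos, config.n_founder_haplotypes, config.ld_decay_length, rng)
        for i in range(n_unrelated):
            for h in (0, 1):
                haps[h, i, idx] = _mosaic(founders, pos, config.copy_segment_length, rng)
        for pair in range(n_sib_pairs):
            parents = [
                [_mosaic(founders, pos, config.copy_segment_length, rng) for _ in (0, 1)] for _ in (0, 1)
            ]
            for child in (0, 1):
                i = n_unrelated + 2 * pair + child
                for par in (0, 1):
                    haps[par, i, idx] = _meiosis(
                        parents[par][0], parents[par][1], pos, config.meiosis_segment_length, rng
                    )

    genotypes = haps.sum(axis=0).astype(float)

    if config.missing_rate > 0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes[miss] = np.nan

    # drop sites monomorphic among observed calls (post-condition: MAF > 0)
    with np.errstate(invalid="ignore"):
        obs_min = np.nanmin(genotypes, axis=0)
        obs_max = np.nanmax(genotypes, axis=0)
    keep = np.flatnonzero(obs_min < obs_max)
    sites = sites.iloc[keep].reset_index(drop=True)
    genotypes = genotypes[:, keep]
    haps = haps[:, :, keep]
    alt_freq = alt_freq[keep]
    p_total = len(sites)

    # --- site metadata, depth, missingness -------------------------------------
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=p_total)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    qual = np.round(rng.gamma(3.0, 150.0, size=p_total), 1)

    site_depth = np.exp(rng.normal(np.log(max(readcfg.mean_site_depth, 1e-6)), 0.4, size=p_total))
    ind_factor = np.exp(rng.normal(0.0, 0.2, size=n))
    class_mult = np.ones((n, p_total))
    class_mult[genotypes == 1] = 1.0 + readcfg.het_depth_boost
    class_mult[genotypes == 2] = max(0.0, 1.0 - readcfg.ref_mapping_bias)
    depth = rng.poisson(site_depth[None, :] * ind_factor[:, None] * class_mult).astype(float)

    sites = sites.assign(
        snp_id=[f"snp_{c}_{p}" for c, p in zip(sites["chrom"], sites["pos"])],
        ref=ref,
        alt=alt,
        qual=qual,
    )[["snp_id", "chrom", "pos", "ref", "alt", "qual"]]

    samples = [f"ind{i+1:03d}" for i in range(n)]
    gm = GenotypeMatrix(samples=samples, sites=sites, genotypes=genotypes, depth=depth, haplotypes=haps)

    phi = np.full((n, n), 1.0 / config.n_founder_haplotypes)
    for pair in range(n_sib_pairs):
        i = n_unrelated + 2 * pair
        phi[i, i + 1] = phi[i + 1, i] = 0.25
    np.fill_diagonal(phi, 0.5)
    return gm, phi


# ---------------------------------------------------------------------------
# true effects and covariates

# Median per-gene PVE targets for demographic/environmental covariates in a
# blood-expression cohort of this kind; sex contributes less than age or
# maternal social connectedness.
DEFAULT_COVARIATE_PVE = {"age": 0.0189, "sci_m": 0.019, "sex": 0.0082}


def _cis_snps(annotation: GeneAnnotation, sites: pd.DataFrame) -> dict[str, np.ndarray]:
    """Gene -> positional indices of SNPs within the cis window."""
    out: dict[str, np.ndarray] = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        idx = sub.index.to_numpy()
        for _, gene in annotation.genes[annotation.genes["chrom"] == chrom].iterrows():
            lo = np.searchsorted(pos, gene["start"] - CIS_WINDOW, side="left")
            hi = np.searchsorted(pos, gene["end"] + CIS_WINDOW, side="right")
            out[gene["gene_id"]] = idx[lo:hi]
    for gid in annotation.genes["gene_id"]:
        out.setdefault(gid, np.array([], dtype=int))
    return out


def draw_true_effects(
    annotation: GeneAnnotation,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator,
    eqtl_gene_fraction: float = 0.10,
    beta_mean: float = 0.96,
    beta_sd: float = 0.30,
    trans_share_mean: float = 0.25,
    factor_share: float = 0.20,
    covariate_pve: dict[str, float] | None = None,
) -> TrueEffects:
    """Plant cis-eQTL in a fraction of genes plus trans/factor/covariate shares.

    The latent trait is z = x*beta + u + hidden factors + covariates + eps.
    The non-cis components are specified as variance shares of a unit total:
    trans share t (per gene, Beta-distributed around ``trans_share_mean``),
    shared-hidden-factor share ``factor_share`` (batch/environment structure
    that expression-PC correction is meant to remove), covariate shares, and
    residual sigma_e^2 = 1 - t - f - sum(c).  The cis effect beta is then on
    the same scale as the power-simulation convention (effect against ~unit
    background variance).  The per-gene allelic imbalance is tanh(beta/2),
    sign-matched to the causal alternate allele.
    """
    if covariate_pve is None:
        covariate_pve = dict(DEFAULT_COVARIATE_PVE)
    genes = annotation.genes["gene_id"].to_list()
    windows = _cis_snps(annotation, genotypes.sites)
    eligible = [g for g in genes if len(windows[g]) > 0]
    n_eqtl = int(round(eqtl_gene_fraction * len(genes)))
    eqtl_genes = set(rng.choice(eligible, size=min(n_eqtl, len(eligible)), replace=False))

    cov_total = float(sum(covariate_pve.values()))
    t_cap = max(0.9 - factor_share - cov_total, 0.05)
    rows = []
    cov_beta_rows = []
    for gid in genes:
        t = float(np.clip(rng.beta(2.0, 2.0 * (1.0 - trans_share_mean) / trans_share_mean), 0.0, t_cap))
        if gid in eqtl_genes:
            snp_idx = int(rng.choice(windows[gid]))
            snp_id = genotypes.sites.iloc[snp_idx]["snp_id"]
            beta = float(rng.choice([-1, 1]) * max(0.1, rng.normal(beta_mean, beta_sd)))
            x = genotypes.genotypes[:, snp_idx]
            vx = float(np.nanvar(x))
            a = float(np.tanh(beta / 2.0))
        else:
            snp_id, beta, vx, a = None, 0.0, 0.0, 0.0
        var_cis = beta**2 * vx
        total = var_cis + 1.0  # non-cis variance sums to 1 by construction
        rows.append(
            dict(
                gene_id=gid,
                causal_snp=snp_id,
                beta_cis=beta,
                sigma_u2=t,
                sigma_f2=factor_share,
                sigma_e2=max(1.0 - t - factor_share - cov_total, 0.05),
                pve_cis_true=var_cis / total,
                pve_trans_true=t / total,
                allelic_imbalance=a,
            )
        )
        cov_beta_rows.append({k: np.sqrt(s) * rng.choice([-1, 1]) for k, s in covariate_pve.items()})
    effects = pd.DataFrame(rows)
    cov_betas = pd.DataFrame(cov_beta_rows, index=effects["gene_id"])
    return TrueEffects(effects=effects, covariate_betas=cov_betas)


def sample_covariates(samples: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Demographic/behavioural covariates, standardized to unit variance."""
    n = len(samples)
    raw = pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n).astype(float),
            "age": 4.0 + rng.gamma(8.0, 1.2, size=n),
            "sci_m": rng.normal(0.0, 1.0, size=n),
        },
        index=samples,
    )
    return (raw - raw.mean()) / raw.std(ddof=0)


# ---------------------------------------------------------------------------
# expression counts


def simulate_expression(
    genotypes: GenotypeMatrix,
    annotation: GeneAnnotation,
    truth: TrueEffects,
    covariates: pd.DataFrame | None,
    readcfg: ReadSimConfig,
    rng: np.random.Generator,
    kinship: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Draw gene-level read counts monotone in the latent genetic trait.

    The latent trait per gene is z = x_causal*beta + u + covariates + eps with
    eps ~ N(0,1) and u ~ MVN(0, sigma_u^2 * K).  Counts are negative binomial
    with log-mean = base + signal_log_sd * z + GC distortion + library offset.
    """
    readcfg.validate()
    n = genotypes.n_individuals
    genes = annotation.genes
    eff = truth.effects.set_index("gene_id")
    if not np.isfinite(eff["sigma_u2"]).all():
        raise ValueError("non-finite trans variance component")

    if kinship is None:
        K = _standardized_grm(genotypes.genotypes)
    else:
        K = np.asarray(kinship, dtype=float)
    # Cholesky with jitter for PSD-but-singular K
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))

    # shared hidden factors (batch/environment structure across genes)
    n_factors = readcfg.n_hidden_factors
    factors = rng.standard_normal((n_factors, n)) if n_factors > 0 else None

    snp_lookup = {s: i for i, s in enumerate(genotypes.sites["snp_id"])}
    z = np.empty((len(genes), n))
    for gi, gid in enumerate(genes["gene_id"]):
        row = eff.loc[gid]
        zi = np.sqrt(max(row["sigma_e2"], 0.0)) * rng.standard_normal(n)
        zi = zi + np.sqrt(max(row["sigma_u2"], 0.0)) * (L @ rng.standard_normal(n))
        if factors is not None and row["sigma_f2"] > 0:
            loadings = rng.normal(0.0, np.sqrt(row["sigma_f2"] / n_factors), size=n_factors)
            zi = zi + loadings @ factors
        if isinstance(row["causal_snp"], str):
            x = genotypes.genotypes[:, snp_lookup[row["causal_snp"]]]
            x = np.where(np.isnan(x), np.nanmean(x), x)
            zi = zi + row["beta_cis"] * x
        if covariates is not None and truth.covariate_betas is not None:
            cb = truth.covariate_betas.loc[gid]
            for name, b in cb.items():
                if name in covariates.columns:
                    zi = zi + b * covariates[name].to_numpy()
        z[gi] = zi

    base = np.exp(rng.normal(np.log(readcfg.base_mean), readcfg.base_log_sd, size=len(genes)))
    lib = rng.normal(0.0, readcfg.lib_size_sd, size=n)
    gc = genes["gc"].to_numpy()
    gc_sd = gc.std() if gc.std() > 0 else 1.0
    gcz = (gc - gc.mean()) / gc_sd
    gc_jit = rng.normal(0.0, readcfg.gc_jitter_sd, size=n)
    log_mu = (
        np.log(base)[:, None]
        + readcfg.signal_log_sd * z
        + readcfg.gc_bias_slope * (1.0 + gc_jit)[None, :] * gcz[:, None]
        + lib[None, :]
    )
    mu = np.exp(np.clip(log_mu, -20, 20))
    alpha = readcfg.count_dispersion
    if alpha > 0:
        lam = rng.gamma(1.0 / alpha, alpha * mu)
    else:
        lam = mu
    counts = rng.poisson(lam)

    gene_meta = pd.DataFrame(
        {"length": annotation.gene_lengths().to_numpy(), "gc": gc}, index=genes["gene_id"]
    )
    counts_df = pd.DataFrame(counts, index=genes["gene_id"], columns=genotypes.samples)
    counts_df.index.name = "gene_id"
    return ExpressionMatrix(counts=counts_df, gene_meta=gene_meta)


def _standardized_grm(genotypes: np.ndarray) -> np.ndarray:
    """Allele-frequency-standardized GRM (used as the simulation kinship)."""
    X = np.array(genotypes, dtype=float)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X) - mu
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = X[:, keep] / sd[keep]
    return Xs @ Xs.T / Xs.shape[1]


# ---------------------------------------------------------------------------
# allelic counts


def simulate_allelic_counts(
    genotypes: GenotypeMatrix,
    annotation: GeneAnnotation,
    truth: TrueEffects,
    readcfg: ReadSimConfig,
    rng: np.random.Generator,
    phase_mode: str = "haplotype",
) -> AllelicCounts:
    """Beta-binomial allelic read counts at exonic heterozygous sites.

    ``phase_mode="haplotype"`` (default) phases each heterozygote's expected
    alternate-read fraction through the simulated haplotypes: only
    individuals heterozygous at the causal SNP show imbalance, with sign
    set by whether the exonic alternate allele rides the same haplotype as
    the causal alternate allele.  ``phase_mode="direct"`` applies
    E[x+/y] = 0.5 + a/2 to every heterozygote (the idealized, fully-phased
    regime used by calibration tests).
    """
    readcfg.validate()
    if phase_mode not in ("haplotype", "direct"):
        raise ValueError("phase_mode must be 'haplotype' or 'direct'")
    sites = genotypes.sites
    snp_lookup = {s: i for i, s in enumerate(sites["snp_id"])}
    eff = truth.effects.set_index("gene_id")
    rho = readcfg.overdispersion_rho
    conc = (1.0 - rho) / rho if rho > 0 else None

    rows = []
    for _, gene in annotation.genes.iterrows():
        gid = gene["gene_id"]
        exons = annotation.exons[annotation.exons["gene_id"] == gid]
        chrom_sites = sites[sites["chrom"] == gene["chrom"]]
        in_exon = np.zeros(len(chrom_sites), dtype=bool)
        pos = chrom_sites["pos"].to_numpy()
        for _, ex in exons.iterrows():
            in_exon |= (pos >= ex["start"]) & (pos <= ex["end"])
        a = float(eff.loc[gid, "allelic_imbalance"])
        causal = eff.loc[gid, "causal_snp"]
        causal_j = snp_lookup.get(causal) if isinstance(causal, str) else None
        for j in chrom_sites.index[in_exon]:
            g = genotypes.genotypes[:, j]
            hets = np.flatnonzero(g == 1)
            if len(hets) == 0:
                continue  # omitted, not emitted empty
            site_factor = np.exp(rng.normal(0.0, 0.4))
            y = rng.poisson(readcfg.mean_site_depth * site_factor, size=len(hets))
            ok = y > 0
            hets, y = hets[ok], y[ok]
            if len(hets) == 0:
                continue
            if phase_mode == "direct" or causal_j is None or genotypes.haplotypes is None:
                delta = np.ones(len(hets))
            else:
                h = genotypes.haplotypes
                alt_on_0 = h[0, hets, j] == 1  # which haplotype carries the exonic alt
                c0 = h[0, hets, causal_j].astype(int)
                c1 = h[1, hets, causal_j].astype(int)
                delta = np.where(alt_on_0, c0 - c1, c1 - c0).astype(float)
            theta0 = np.clip(0.5 + delta * a / 2.0 - readcfg.ref_mapping_bias, 0.02, 0.98)
            if conc is not None:
                theta = rng.beta(theta0 * conc, (1.0 - theta0) * conc)
            else:
                theta = theta0
            x_plus = rng.binomial(y, theta)
            srow = sites.loc[j]
            for k, i in enumerate(hets):
                rows.append(
                    (
                        srow["snp_id"],
                        gid,
                        srow["chrom"],
                        int(srow["pos"]),
                        float(srow["qual"]),
                        genotypes.samples[i],
                        int(x_plus[k]),
                        int(y[k]),
                    )
                )
    table = pd.DataFrame(rows, columns=AllelicCounts.REQUIRED)
    return AllelicCounts(table=table)


# ---------------------------------------------------------------------------
# orchestration


def generate_dataset(
    config: PopulationConfig,
    readcfg: ReadSimConfig | None = None,
    eqtl_gene_fraction: float = 0.10,
    beta_mean: float | None = None,
    covariate_pve: dict[str, float] | None = None,
) -> SyntheticDataset:
    """Generate a complete dataset (annotation, genotypes, truth, counts)."""
    config.validate()
    readcfg = readcfg or ReadSimConfig()
    ss = np.random.SeedSequence(config.seed)
    r_ann, r_geno, r_truth, r_cov, r_expr, r_ase = (np.random.default_rng(s) for s in ss.spawn(6))
    annotation = generate_annotation(config, r_ann)
    genotypes, phi = generate_genotypes(config, annotation, readcfg, r_geno)
    truth = draw_true_effects(
        annotation,
        genotypes,
        r_truth,
        eqtl_gene_fraction=eqtl_gene_fraction,
        beta_mean=0.96 if beta_mean is None else beta_mean,
        covariate_pve=covariate_pve,
    )
    covariates = sample_covariates(genotypes.samples, r_cov)
    expression = simulate_expression(genotypes, annotation, truth, covariates, readcfg, r_expr)
    allelic = simulate_allelic_counts(genotypes, annotation, truth, readcfg, r_ase)
    return SyntheticDataset(
        config=config,
        readcfg=readcfg,
        annotation=annotation,
        genotypes=genotypes,
        kinship_true=phi,
        truth=truth,
        covariates=covariates,
        expression=expression,
        allelic=allelic,
    )


def write_dataset(dataset: SyntheticDataset, directory: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write VCF/GFF3/TSV files; refuses to overwrite unless asked."""
    from . import io as wio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "genotypes.vcf",
        "gff": directory / "genes.gff3",
        "counts": directory / "counts.tsv",
        "allelic": directory / "allelic_counts.tsv",
        "covariates": directory / "covariates.tsv",
        "truth": directory / "truth.tsv",
    }
    if not overwrite:
        existing = [str(p) for p in paths.values() if p.exists()]
        if existing:
            raise FileExistsError(f"refusing to overwrite {existing}; pass overwrite=True")
    wio.write_vcf(dataset.genotypes, paths["vcf"])
    wio.write_gff3(dataset.annotation, paths["gff"])
    wio.write_counts_tsv(dataset.expression, paths["counts"])
    wio.write_allelic_tsv(dataset.allelic, paths["allelic"])
    dataset.covariates.rename_axis("sample").to_csv(paths["covariates"], sep="\t")
    truth = dataset.truth.effects.copy()
    if dataset.truth.covariate_betas is not None:
        cb = dataset.truth.covariate_betas.add_prefix("beta_cov_")
        truth = truth.merge(cb, left_on="gene_id", right_index=True)
    truth.to_csv(paths["truth"], sep="\t", index=False, na_rep=".")
    return paths
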