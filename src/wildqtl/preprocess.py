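"""Gene/variant filtering, normalization, PC correction and genotype QC.

Implements the upstream half of the analysis: expression filters (non-zero
in more than 10% of individuals, mean count >= 10), double quantile
normalization (across samples, then rank-inverse-normal per gene), removal
of the top expression PCs, the six variant filters (monomorphic,
missingness, HWE, quality, gene proximity, coverage), HWE exact testing,
naive genotype imputation, frequency-matched LD decay curves, and the
coverage-by-genotype-class diagnostic.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneAnnotation, GenotypeMatrix

__all__ = [
    "filter_genes",
    "compute_rpkm",
    "normalize_expression",
    "gc_bias_correlation",
    "regress_out_pcs",
    "hwe_exact_test",
    "filter_variants",
    "impute_missing",
    "cis_window_index",
    "estimate_ld_decay",
    "coverage_by_genotype_qc",
]

CIS_WINDOW = 200_000


# ---------------------------------------------------------------------------
# expression


def filter_genes(
    expr: ExpressionMatrix,
    min_frac_nonzero: float = 0.10,
    min_mean: float = 10.0,
    exclude: list[str] | None = None,
) -> ExpressionMatrix:
    """Keep genes with non-zero counts in *more than* ``min_frac_nonzero`` of
    individuals and mean count >= ``min_mean``; drop any explicitly excluded
    gene (e.g. a globin gene dominating blood libraries)."""
    counts = expr.counts
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    frac_nonzero = (counts > 0).mean(axis=1)
    keep = (frac_nonzero > min_frac_nonzero) & (counts.mean(axis=1) >= min_mean)
    if exclude:
        keep &= ~counts.index.isin(exclude)
    if not keep.any():
        raise ValueError("no genes pass the expression filters")
    meta = expr.gene_meta.loc[keep[keep].index] if expr.gene_meta is not None else None
    return ExpressionMatrix(counts=counts.loc[keep], gene_meta=meta)


def compute_rpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, totals: pd.Series | None = None
) -> pd.DataFrame:
    """Reads per kilobase of exon per million mapped reads.

    ``totals`` defaults to each sample's column sum.
    """
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise ValueError("per-sample totals must be positive")
    return counts * 1e9 / np.outer(lengths.to_numpy(), totals.to_numpy())


def _quantile_normalize_across_samples(values: np.ndarray) -> np.ndarray:
    """Map each column onto the mean of the sorted columns (classic QN)."""
    order = np.argsort(values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n_rows = values.shape[0]
    rows = np.arange(n_rows)
    for j in range(values.shape[1]):
        ranks[order[:, j], j] = rows
    reference = np.sort(values, axis=0).mean(axis=1)
    out = reference[ranks]
    # average reference values over ties within each column
    for j in range(values.shape[1]):
        col = values[:, j]
        uniq, inv, cnt = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < n_rows:
            sums = np.bincount(inv, weights=out[:, j])
            out[:, j] = (sums / cnt)[inv]
    return out


def rank_inverse_normal(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse normal transform of a 1-D array (average ranks)."""
    n = len(values)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))


def normalize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Double quantile normalization.

    Step 1 quantile-normalizes samples onto their common mean distribution
    (on log counts); step 2 maps each gene onto standard-normal quantiles via
    the Blom rank-inverse-normal transform.  The result is standard normal
    per gene, which removes any gene-level distortion shared across samples
    (library depth, gene GC effects).
    """
    counts = expr.counts.to_numpy(dtype=float)
    step1 = _quantile_normalize_across_samples(np.log1p(counts))
    normalized = np.empty_like(step1)
    flagged = []
    for gi in range(step1.shape[0]):
        if np.all(counts[gi] == counts[gi, 0]):  # no rank information at all
            flagged.append(expr.counts.index[gi])
            normalized[gi] = 0.0
            continue
        normalized[gi] = rank_inverse_normal(step1[gi])
    norm_df = pd.DataFrame(normalized, index=expr.counts.index, columns=expr.counts.columns)
    out = ExpressionMatrix(counts=expr.counts, normalized=norm_df, gene_meta=expr.gene_meta)
    out.all_tied_genes = flagged  # type: ignore[attr-defined]
    return out


def gc_bias_correlation(values: pd.DataFrame, gc: pd.Series, per_sample: bool = True) -> pd.Series | float:
    """Correlation between gene GC content and expression values.

    With ``per_sample=True`` returns one Pearson correlation per sample
    (across genes); otherwise the pooled correlation using per-gene means.
    Used before/after normalization to show GC bias removal.
    """
    gc = gc.reindex(values.index).to_numpy()
    if per_sample:
        out = {}
        for s in values.columns:
            v = values[s].to_numpy()
            out[s] = float(stats.pearsonr(gc, v)[0]) if np.std(v) > 0 else np.nan
        return pd.Series(out)
    means = values.mean(axis=1).to_numpy()
    return float(stats.pearsonr(gc, means)[0])


def regress_out_pcs(expr: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Residualize normalized expression on its own top-k principal components.

    PCs are the top right singular vectors over individuals; the residual
    matrix is orthogonal to each removed PC.
    """
    if expr.normalized is None:
        raise ValueError("normalize_expression must run first")
    Y = expr.normalized.to_numpy(dtype=float)
    n = Y.shape[1]
    if k >= n:
        raise ValueError(f"k={k} must be < n_individuals={n}")
    if k == 0:
        resid = Y
    else:
        Yc = Y - Y.mean(axis=1, keepdims=True)
        # individuals-space PCs of the gene x individual matrix
        _, _, vt = np.linalg.svd(Yc, full_matrices=False)
        pcs = vt[:k]  # k x n, orthonormal
        resid = Yc - (Yc @ pcs.T) @ pcs
    out_df = pd.DataFrame(resid, index=expr.normalized.index, columns=expr.normalized.columns)
    return ExpressionMatrix(counts=expr.counts, normalized=out_df, gene_meta=expr.gene_meta)


def expression_pcs(expr: ExpressionMatrix, k: int) -> np.ndarray:
    """Top-k expression PCs over individuals (k x n, orthonormal rows)."""
    Y = expr.normalized.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Yc, full_matrices=False)
    return vt[:k]


# ---------------------------------------------------------------------------
# variants


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Two-sided: sums the probabilities of all heterozygote counts (given the
    allele counts) that are no more probable than the observed one.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_a = 2 * n_aa + n_ab  # rare-allele label is irrelevant to the test
    n_b = 2 * n_bb + n_ab
    n_rare = min(n_a, n_b)
    obs_het = n_ab
    # heterozygote counts share n_rare's parity
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het | allele counts) up to a constant:
    #   2^het * n! / (n_aa! n_ab! n_bb!) with n_aa = (n_rare - het)/2 etc.
    n_common = 2 * n - n_rare
    logp = np.array(
        [
            h * math.log(2.0)
            - math.lgamma((n_rare - h) / 2 + 1)
            - math.lgamma(h + 1)
            - math.lgamma((n_common - h) / 2 + 1)
            for h in het_values
        ]
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[np.searchsorted(het_values, obs_het)]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def _genotype_class_counts(genotypes: np.ndarray) -> np.ndarray:
    """Per-site counts of (hom-ref, het, hom-alt), ignoring missing."""
    out = np.zeros((genotypes.shape[1], 3), dtype=int)
    for g in (0, 1, 2):
        out[:, g] = np.nansum(genotypes == g, axis=0)
    return out


def filter_variants(
    genotypes: GenotypeMatrix,
    annotation: GeneAnnotation | None = None,
    max_missing_frac: float = 12.0 / 63.0,  # "more than 12 of 63" as a fraction
    hwe_alpha: float = 0.05,
    min_qual: float = 100.0,
    min_mean_depth: float = 5.0,
    cis_window: int = CIS_WINDOW,
) -> tuple[GenotypeMatrix, pd.Series]:
    """Apply the six variant filters; returns (filtered matrix, removal log).

    Rules (each evaluated on the unfiltered matrix, so their order is
    irrelevant): (i) monomorphic in the sample; (ii) missing in strictly more
    than ``max_missing_frac`` of individuals; (iii) Hardy-Weinberg exact
    p < ``hwe_alpha``; (iv) quality score below ``min_qual``; (v) farther
    than ``cis_window`` bp from every gene (inclusive boundary); (vi) mean
    depth below ``min_mean_depth``.
    """
    G = genotypes.genotypes
    n_sites = genotypes.n_sites
    counts3 = _genotype_class_counts(G)

    poly_fail = (counts3[:, 0] + counts3[:, 1] == 0) | (counts3[:, 1] + counts3[:, 2] == 0)
    miss_fail = genotypes.missing_fraction() > max_missing_frac
    hwe_p = np.array(
        [hwe_exact_test(*c) if c.sum() > 0 else np.nan for c in counts3]
    )
    hwe_fail = hwe_p < hwe_alpha
    qual_fail = genotypes.sites["qual"].to_numpy() < min_qual
    if genotypes.depth is not None:
        depth_fail = genotypes.depth.mean(axis=0) < min_mean_depth
    else:
        depth_fail = np.zeros(n_sites, dtype=bool)
    if annotation is not None:
        near_gene = np.zeros(n_sites, dtype=bool)
        for chrom, sub in genotypes.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            hit = np.zeros(len(pos), dtype=bool)
            for _, gene in annotation.genes[annotation.genes["chrom"] == chrom].iterrows():
                hit |= (pos >= gene["start"] - cis_window) & (pos <= gene["end"] + cis_window)
            near_gene[sub.index.to_numpy()] = hit
        gene_fail = ~near_gene
    else:
        gene_fail = np.zeros(n_sites, dtype=bool)

    removal_log = pd.Series(
        {
            "monomorphic": int(poly_fail.sum()),
            "missingness": int(miss_fail.sum()),
            "hwe": int(np.nansum(hwe_fail)),
            "quality": int(qual_fail.sum()),
            "gene_proximity": int(gene_fail.sum()),
            "coverage": int(depth_fail.sum()),
        }
    )
    keep = ~(poly_fail | miss_fail | np.nan_to_num(hwe_fail) | qual_fail | gene_fail | depth_fail)
    return genotypes.take_sites(np.flatnonzero(keep)), removal_log


def impute_missing(genotypes: GenotypeMatrix, rng: np.random.Generator) -> tuple[GenotypeMatrix, np.ndarray]:
    """Fill missing genotypes by sampling from HWE probabilities at the
    observed alternate-allele frequency.  Returns (matrix, imputed mask)."""
    G = genotypes.genotypes.copy()
    mask = np.isnan(G)
    for j in np.flatnonzero(mask.any(axis=0)):
        obs = G[~mask[:, j], j]
        if len(obs) == 0:
            raise ValueError(f"site {genotypes.sites.iloc[j]['snp_id']} has no observed genotypes")
        f = obs.mean() / 2.0
        probs = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        G[mask[:, j], j] = rng.choice(3, size=mask[:, j].sum(), p=probs)
    out = GenotypeMatrix(
        samples=list(genotypes.samples),
        sites=genotypes.sites.copy(),
        genotypes=G,
        depth=genotypes.depth,
        haplotypes=genotypes.haplotypes,
    )
    return out, mask


def cis_window_index(
    annotation: GeneAnnotation, sites: pd.DataFrame, window: int = CIS_WINDOW
) -> dict[str, np.ndarray]:
    """Gene -> ordered positional indices of SNPs within +/- window of the
    gene body (inclusive at both endpoints)."""
    out: dict[str, np.ndarray] = {g: np.array([], dtype=int) for g in annotation.genes["gene_id"]}
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            order = np.argsort(pos, kind="stable")
            sub = sub.iloc[order]
            pos = pos[order]
        idx = sub.index.to_numpy()
        for _, gene in annotation.genes[annotation.genes["chrom"] == chrom].iterrows():
            lo = np.searchsorted(pos, gene["start"] - window, side="left")
            hi = np.searchsorted(pos, gene["end"] + window, side="right")
            out[gene["gene_id"]] = idx[lo:hi]
    return out


def estimate_ld_decay(
    genotypes: GenotypeMatrix,
    max_dist: int = 100_000,
    n_bins: int = 10,
    min_maf: float = 0.10,
) -> pd.DataFrame:
    """Frequency-matched LD decay: r^2 between dosages for SNP pairs within
    ``max_dist``, restricted to pairs whose MAFs fall in the same subgroup
    ((10-20], (20-30], (30-40], (40-50] percent).  Returns a tidy table of
    (maf_group, distance bin, mean r^2, n pairs) plus a pooled "combined"
    group."""
    maf = genotypes.maf()
    edges = np.array([0.10, 0.20, 0.30, 0.40, 0.50])
    labels = ["(10-20%]", "(20-30%]", "(30-40%]", "(40-50%]"]
    bin_edges = np.linspace(0, max_dist, n_bins + 1)
    records: list[tuple] = []
    G = genotypes.genotypes
    for gi, label in enumerate(labels):
        in_group = (maf > edges[gi]) & (maf <= edges[gi + 1])
        for chrom, sub in genotypes.sites.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()[in_group[sub.index.to_numpy()]]
            if len(idx) < 2:
                continue
            pos = genotypes.sites.loc[idx, "pos"].to_numpy()
            for a in range(len(idx) - 1):
                for b in range(a + 1, len(idx)):
                    d = pos[b] - pos[a]
                    if d > max_dist:
                        break
                    x, y = G[:, idx[a]], G[:, idx[b]]
                    ok = ~(np.isnan(x) | np.isnan(y))
                    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                        continue
                    r = np.corrcoef(x[ok], y[ok])[0, 1]
                    records.append((label, float(d), float(r * r)))
    pairs = pd.DataFrame(records, columns=["maf_group", "dist", "r2"])
    rows = []
    for group, sub in list(pairs.groupby("maf_group")) + [("combined", pairs)]:
        binned = pd.cut(sub["dist"], bin_edges, include_lowest=True)
        agg = sub.groupby(binned, observed=False)["r2"].agg(["mean", "size"])
        for (interval, row) in agg.iterrows():
            rows.append((group, interval.left, interval.right, row["mean"], int(row["size"])))
    return pd.DataFrame(rows, columns=["maf_group", "dist_lo", "dist_hi", "mean_r2", "n_pairs"])


def coverage_by_genotype_qc(genotypes: GenotypeMatrix) -> tuple[pd.DataFrame, float, float]:
    """Mean read depth per genotype class per site, and a two-sample KS test
    comparing the hom-ref vs hom-alt per-site mean-depth distributions.

    Returns (per-site table with NaN for absent classes, KS D, KS p).
    """
    if genotypes.depth is None:
        raise ValueError("no per-sample depth available")
    G, D = genotypes.genotypes, genotypes.depth
    cols = {}
    for g, name in ((0, "hom_ref"), (1, "het"), (2, "hom_alt")):
        sel = G == g
        with np.errstate(invalid="ignore"):
            cols[name] = np.where(sel.sum(axis=0) > 0, np.nansum(np.where(sel, D, 0), axis=0) / sel.sum(axis=0), np.nan)
    table = pd.DataFrame(cols, index=genotypes.sites["snp_id"])
    ref = table["hom_ref"].dropna()
    alt = table["hom_alt"].dropna()
    if len(ref) == 0 or len(alt) == 0:
        return table, np.nan, np.nan
    ks = stats.ks_2samp(ref, alt)
    return table, float(ks.statistic), float(ks.pvalue)
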