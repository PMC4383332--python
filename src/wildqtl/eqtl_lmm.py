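"""Kinship-aware cis-eQTL mapping.

Per-SNP association uses the linear mixed model

    y = mu + x * beta + u + eps,   u ~ MVN(0, sigma_u^2 K),  eps ~ MVN(0, sigma_e^2 I)

with K = X X^T / p the genomic relationship matrix.  Fitting works in the
eigenbasis of K, where the marginal covariance is diagonal and the
likelihood reduces to a weighted regression profiled over
lambda = sigma_u^2 / sigma_e^2; lambda is optimized by Brent search on
log10(lambda) in [-5, 5].  The Wald statistic beta/se is referred to
t(n - 2).  Gene-level significance comes from an empirical FDR that
compares observed per-gene minimum p-values with those from permuted
expression labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import ExpressionMatrix, GenotypeMatrix, KinshipMatrix

__all__ = [
    "compute_kinship",
    "LmmFit",
    "fit_lmm",
    "map_cis_eqtl",
    "empirical_fdr",
    "local_structure_control",
]

LOG10_LAMBDA_RANGE = (-5.0, 5.0)


def compute_kinship(genotypes: GenotypeMatrix | np.ndarray, standardize: bool = False) -> KinshipMatrix:
    """K = X X^T / p from column-centered dosages.

    Centering is required for K to measure relatedness; with
    ``standardize=True`` columns are additionally scaled to unit variance
    (the allele-frequency-standardized GRM, whose off-diagonal estimates
    twice the kinship coefficient).  Missing entries are mean-imputed for
    the product only.
    """
    X = genotypes.genotypes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    if X.shape[1] == 0:
        raise ValueError("kinship requires at least one SNP")
    mu = np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(X), mu, X) - mu
    if standardize:
        sd = Xc.std(axis=0)
        keep = sd > 0
        Xc = Xc[:, keep] / sd[keep]
    K = Xc @ Xc.T / Xc.shape[1]
    return KinshipMatrix(K=K, n_snps=Xc.shape[1])


@dataclass
class LmmFit:
    beta: float
    se: float
    sigma_u2: float
    sigma_e2: float
    p_value: float
    log_likelihood: float
    degenerate: bool = False  # x constant in the tested individuals


def _profile_loglik(log10_lam: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profile ML log-likelihood at fixed lambda (rotated coordinates).

    Returns (loglik, beta_hat vector, XtWX inverse, sigma_e2_hat).
    """
    lam = 10.0**log10_lam
    w = 1.0 / (lam * d + 1.0)
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    XtWy = Xw.T @ yr
    try:
        XtWX_inv = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        XtWX_inv = np.linalg.pinv(XtWX)
    bhat = XtWX_inv @ XtWy
    resid = yr - Xr @ bhat
    n = len(yr)
    rss = float(resid @ (w * resid))
    sigma_e2 = max(rss / n, 1e-300)
    ll = -0.5 * (n * np.log(2 * np.pi * sigma_e2) + n - np.log(w).sum())
    return ll, bhat, XtWX_inv, sigma_e2


def fit_lmm(
    y: np.ndarray,
    x: np.ndarray,
    kinship: KinshipMatrix | None,
) -> LmmFit:
    """ML fit of the single-SNP LMM; Wald p-value against t(n-2).

    ``kinship=None`` uses K = I (the fit then reduces exactly to OLS simple
    regression).  The Wald se uses the df-corrected residual variance
    RSS_w/(n-2) so that the K = I path matches the OLS t-test.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = len(y)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if np.nanstd(x) == 0:
        return LmmFit(beta=0.0, se=np.nan, sigma_u2=0.0, sigma_e2=float(np.var(y)), p_value=1.0,
                      log_likelihood=np.nan, degenerate=True)
    x = np.where(np.isnan(x), np.nanmean(x), x)
    if kinship is None:
        d = np.zeros(n)
        yr, Xr = y, np.column_stack([np.ones(n), x])
        best_l10 = LOG10_LAMBDA_RANGE[0]
    else:
        d, U = kinship.eigendecomposition()
        yr = U.T @ y
        Xr = U.T @ np.column_stack([np.ones(n), x])
        res = optimize.minimize_scalar(
            lambda l10: -_profile_loglik(l10, d, yr, Xr)[0],
            bounds=LOG10_LAMBDA_RANGE,
            method="bounded",
            options={"xatol": 1e-6},
        )
        best_l10 = float(res.x)
        # guard against boundary optima beating the interior optimum
        for cand in LOG10_LAMBDA_RANGE:
            if _profile_loglik(cand, d, yr, Xr)[0] > _profile_loglik(best_l10, d, yr, Xr)[0]:
                best_l10 = cand
    ll, bhat, XtWX_inv, sigma_e2 = _profile_loglik(best_l10, d, yr, Xr)
    lam = 10.0**best_l10
    rss = sigma_e2 * n
    se = float(np.sqrt(rss / (n - 2) * XtWX_inv[1, 1]))
    beta = float(bhat[1])
    tstat = beta / se
    p = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
    return LmmFit(
        beta=beta,
        se=se,
        sigma_u2=lam * sigma_e2,
        sigma_e2=sigma_e2,
        p_value=max(p, np.nextafter(0, 1)),
        log_likelihood=ll,
    )


def lmm_loglik_dense(y: np.ndarray, x: np.ndarray, K: np.ndarray, lam: float) -> float:
    """Direct multivariate-normal profile log-likelihood at fixed lambda.

    Independent of the rotated-coordinate path; used as a numerical oracle.
    """
    n = len(y)
    V = lam * K + np.eye(n)
    Vinv = np.linalg.inv(V)
    X = np.column_stack([np.ones(n), x])
    bhat = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    r = y - X @ bhat
    rss = float(r @ Vinv @ r)
    sigma_e2 = rss / n
    sign, logdet = np.linalg.slogdet(V)
    return -0.5 * (n * np.log(2 * np.pi * sigma_e2) + n + logdet)


def _fit_snps_grid(
    yr: np.ndarray, onesr: np.ndarray, Xr: np.ndarray, d: np.ndarray, grid_l10: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profile-ML over a log10-lambda grid, vectorized across (lambda, SNP).

    Returns (beta, p_value, loglik) per SNP, each at its own grid-optimal
    lambda.  Weighted simple regression with intercept is done in closed
    form; the weighted cross-products for every lambda are three matmuls.
    """
    n, p = Xr.shape
    lam = 10.0 ** np.asarray(grid_l10)
    W = 1.0 / (lam[:, None] * d[None, :] + 1.0)  # L x n
    logw_sum = np.log(W).sum(axis=1)  # L
    a11 = W @ (onesr * onesr)  # L
    a1y = W @ (onesr * yr)
    yy = W @ (yr * yr)
    a1x = (W * onesr) @ Xr  # L x p
    axy = (W * yr) @ Xr
    axx = W @ (Xr * Xr)
    det = a11[:, None] * axx - a1x**2
    det = np.where(det <= 0, np.nan, det)
    beta = (a11[:, None] * axy - a1x * a1y[:, None]) / det
    alpha = (a1y[:, None] - a1x * beta) / a11[:, None]
    rss = (
        yy[:, None]
        - 2 * alpha * a1y[:, None]
        - 2 * beta * axy
        + alpha**2 * a11[:, None]
        + 2 * alpha * beta * a1x
        + beta**2 * axx
    )
    rss = np.maximum(rss, 1e-300)
    with np.errstate(invalid="ignore"):
        ll = -0.5 * (n * np.log(2 * np.pi * rss / n) + n - logw_sum[:, None])
    ll = np.where(np.isnan(ll), -np.inf, ll)
    best = np.argmax(ll, axis=0)  # per SNP
    cols = np.arange(p)
    best_ll = ll[best, cols]
    best_beta = beta[best, cols]
    best_rss = rss[best, cols]
    se = np.sqrt(best_rss / (n - 2) * (a11[best] / det[best, cols]))
    tstat = best_beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    return (
        np.nan_to_num(best_beta),
        np.clip(np.where(np.isfinite(pval), pval, 1.0), np.nextafter(0, 1), 1.0),
        best_ll,
    )


def map_cis_eqtl(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    kinship: KinshipMatrix | None = None,
    n_grid: int = 40,
    return_all: bool = False,
    annotation_pos: pd.DataFrame | None = None,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Test every (gene, cis-SNP) pair; keep the best SNP per gene.

    ``expr.normalized`` must already be PC-corrected.  Genes with zero cis
    SNPs are reported with ``n_snps = 0`` and NaN statistics (untested).
    Ties in minimum p are broken by distance to the gene (when gene
    coordinates are supplied via ``annotation_pos``, indexed by gene id with
    ``start``/``end``), then by SNP index.
    """
    Y = expr.normalized.to_numpy(dtype=float)
    genes = list(expr.normalized.index)
    G = genotypes.genotypes
    n = G.shape[0]
    if kinship is not None:
        d, U = kinship.eigendecomposition()
        onesr = U.T @ np.ones(n)
        grid_l10 = np.linspace(*LOG10_LAMBDA_RANGE, n_grid)
    else:
        d, U = np.zeros(n), None
        onesr = np.ones(n)
        # K = I: weights are constant in lambda, one grid point suffices (OLS)
        grid_l10 = np.array([LOG10_LAMBDA_RANGE[0]])

    gene_rows = []
    snp_tables = []
    for gi, gene in enumerate(genes):
        idx = np.asarray(windows.get(gene, []), dtype=int)
        if len(idx) == 0:
            gene_rows.append(dict(gene_id=gene, best_snp=None, beta=np.nan, p_value=np.nan, n_snps=0))
            continue
        X = G[:, idx]
        col_mu = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mu, X)
        variable = X.std(axis=0) > 0
        y = Y[gi]
        yr = U.T @ y if U is not None else y
        Xr = U.T @ X if U is not None else X
        beta = np.zeros(len(idx))
        pval = np.ones(len(idx))
        if variable.any():
            b, p, _ = _fit_snps_grid(yr, onesr, Xr[:, variable], d, grid_l10)
            beta[variable] = b
            pval[variable] = p
        order = np.argsort(pval, kind="stable")
        best_local = order[0]
        min_p = pval[best_local]
        ties = np.flatnonzero(np.isclose(pval, min_p, rtol=0, atol=0))
        if len(ties) > 1 and annotation_pos is not None and gene in annotation_pos.index:
            start = annotation_pos.loc[gene, "start"]
            end = annotation_pos.loc[gene, "end"]
            pos = genotypes.sites.iloc[idx]["pos"].to_numpy()
            dist = np.maximum(0, np.maximum(start - pos, pos - end))
            ties = ties[np.lexsort((ties, dist[ties]))]
            best_local = ties[0]
        best_snp = genotypes.sites.iloc[idx[best_local]]["snp_id"]
        gene_rows.append(
            dict(gene_id=gene, best_snp=best_snp, beta=float(beta[best_local]),
                 p_value=float(pval[best_local]), n_snps=int(variable.sum()))
        )
        if return_all:
            snp_tables.append(
                pd.DataFrame(
                    dict(
                        gene_id=gene,
                        snp_id=genotypes.sites.iloc[idx]["snp_id"].to_numpy(),
                        beta=beta,
                        p_value=pval,
                    )
                )
            )
    gene_table = pd.DataFrame(gene_rows)
    if return_all:
        return gene_table, pd.concat(snp_tables, ignore_index=True) if snp_tables else pd.DataFrame()
    return gene_table


def permutation_min_p(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    kinship: KinshipMatrix | None,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-gene minimum p-values from expression matrices with permuted
    individual labels; permutation destroys both signal and relatedness."""
    out = []
    Yn = expr.normalized
    for _ in range(n_perm):
        perm = rng.permutation(Yn.shape[1])
        permuted = ExpressionMatrix(
            counts=expr.counts,
            normalized=pd.DataFrame(Yn.to_numpy()[:, perm], index=Yn.index, columns=Yn.columns),
            gene_meta=expr.gene_meta,
        )
        table = map_cis_eqtl(permuted, genotypes, windows, kinship)
        out.append(table["p_value"].to_numpy())
    return np.concatenate(out) if out else np.array([])


def empirical_fdr(
    observed_p: np.ndarray,
    permuted_p: np.ndarray,
    n_perm: int,
    fdr: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-based q-values for per-gene minimum p-values.

    For a threshold t, FDR(t) = (mean permuted count <= t) / (observed
    count <= t); q(gene) = min over t >= p_gene of FDR(t), capped at 1 and
    monotonized so q is non-decreasing in p.  Returns (q, significant mask
    at ``fdr``).  NaN p-values (untested genes) get q = NaN.
    """
    observed_p = np.asarray(observed_p, float)
    permuted_p = np.asarray(permuted_p, float)
    permuted_p = permuted_p[~np.isnan(permuted_p)]
    q = np.full_like(observed_p, np.nan)
    tested = ~np.isnan(observed_p)
    p_tested = observed_p[tested]
    if p_tested.size == 0:
        return q, np.zeros_like(observed_p, bool)
    order = np.argsort(p_tested, kind="stable")
    sorted_p = p_tested[order]
    n_obs_le = np.arange(1, len(sorted_p) + 1)
    n_perm_le = np.searchsorted(np.sort(permuted_p), sorted_p, side="right")
    fdr_at_t = (n_perm_le / max(n_perm, 1)) / n_obs_le
    # q at threshold = min FDR over larger thresholds, then cap and monotonize
    q_sorted = np.minimum.accumulate(fdr_at_t[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q_vals = np.empty_like(q_sorted)
    q_vals[order] = q_sorted
    q[tested] = q_vals
    return q, np.where(np.isnan(q), False, q <= fdr)


def local_structure_control(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    annotation_chrom: pd.Series,
    k: int = 2,
) -> ExpressionMatrix:
    """Residualize each gene on the top-k genotype PCs of its own chromosome.

    A control for local ancestry structure: if admixture tracts in cis drive
    apparent eQTL, removing same-chromosome genotype PCs should erase them.
    Chromosomes with fewer than k+1 SNPs are left uncorrected.
    """
    if expr.normalized is None:
        raise ValueError("normalized expression required")
    if k == 0:
        return expr
    Y = expr.normalized.to_numpy(dtype=float).copy()
    pcs_by_chrom: dict[str, np.ndarray | None] = {}
    for chrom, sub in genotypes.sites.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        if len(idx) < k + 1:
            pcs_by_chrom[chrom] = None
            continue
        X = genotypes.genotypes[:, idx]
        mu = np.nanmean(X, axis=0)
        Xc = np.where(np.isnan(X), mu, X) - mu
        _, _, vt = np.linalg.svd(Xc.T, full_matrices=False)  # rows: individual-space PCs
        pcs_by_chrom[chrom] = vt[:k]
    for gi, gene in enumerate(expr.normalized.index):
        chrom = annotation_chrom.get(gene)
        pcs = pcs_by_chrom.get(chrom)
        if pcs is None:
            continue
        y = Y[gi] - Y[gi].mean()
        Y[gi] = y - (y @ pcs.T) @ pcs
    out = pd.DataFrame(Y, index=expr.normalized.index, columns=expr.normalized.columns)
    return ExpressionMatrix(counts=expr.counts, normalized=out, gene_meta=expr.gene_meta)
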