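"""Beta-binomial allele-specific expression testing.

For each exonic SNP, reads carrying the alternate allele in heterozygous
individual i follow

    x_i^+ | y_i ~ Binomial(y_i, theta),   theta ~ Beta(alpha, beta),

i.e. the counts are beta-binomial across individuals.  ASE is tested with a
likelihood-ratio test of H0: alpha = beta (balanced) against the free
(alpha, beta) alternative.  Because read-count overdispersion makes the
nominal chi-square(1) reference anti-conservative, gene-level significance
relies on an empirical null built by re-drawing each heterozygote's x^+
from a donor site elsewhere in the genome with the same total read count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import AllelicCounts
from .eqtl_lmm import empirical_fdr

__all__ = [
    "filter_ase_sites",
    "betabinom_loglik",
    "AseFit",
    "fit_ase_lrt",
    "empirical_null_ase",
    "summarize_ase_genes",
]


def filter_ase_sites(
    allelic: AllelicCounts,
    min_qual: float = 10.0,
    min_reads_per_ind: int = 5,
    min_individuals: int = 2,
    min_total_reads: int = 300,
    total_reads_inclusive: bool = False,
) -> AllelicCounts:
    """Site filters for ASE testing.

    Keeps sites with quality strictly greater than ``min_qual``, strictly
    more than ``min_individuals`` heterozygotes having strictly more than
    ``min_reads_per_ind`` reads, and strictly more than ``min_total_reads``
    reads summed over heterozygotes (``total_reads_inclusive=True`` switches
    the last rule to >=, the reading used in some summaries).
    """
    t = allelic.table
    if len(t) == 0:
        return AllelicCounts(table=t.copy())
    per_site = t.groupby("site_id").agg(
        qual=("qual", "first"),
        total=("total", "sum"),
        n_deep=("total", lambda s: int((s > min_reads_per_ind).sum())),
    )
    ok = per_site["qual"] > min_qual
    ok &= per_site["n_deep"] > min_individuals
    if total_reads_inclusive:
        ok &= per_site["total"] >= min_total_reads
    else:
        ok &= per_site["total"] > min_total_reads
    keep = t["site_id"].isin(per_site.index[ok])
    return AllelicCounts(table=t[keep].reset_index(drop=True))


def betabinom_loglik(alpha: float, beta: float, x: np.ndarray, y: np.ndarray) -> float:
    """Sum of log beta-binomial pmfs over heterozygotes.

    log pmf = log C(y, x) + betaln(x + alpha, y - x + beta) - betaln(alpha, beta)
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    log_choose = special.gammaln(y + 1) - special.gammaln(x + 1) - special.gammaln(y - x + 1)
    ll = log_choose + special.betaln(x + alpha, y - x + beta) - special.betaln(alpha, beta)
    return float(ll.sum())


@dataclass
class AseFit:
    alpha: float
    beta: float
    logl0: float
    logl1: float
    lrt: float
    p_nominal: float
    effect: float  # logit of the fitted alternate-haplotype fraction
    z: float  # sign(effect) * sqrt(LRT)
    converged: bool = True


def _neg_ll_core(a: float, b: float, x: np.ndarray, y: np.ndarray) -> float:
    """Negative beta-binomial log-likelihood without the data-only
    binomial-coefficient term (constant in alpha, beta)."""
    return float(len(x) * special.betaln(a, b) - special.betaln(x + a, y - x + b).sum())


def fit_ase_lrt(x: np.ndarray, y: np.ndarray) -> AseFit:
    """Maximum-likelihood beta-binomial LRT for one site.

    The null maximizes over alpha = beta (1-D in log alpha); the alternative
    over (log alpha, log beta) by Nelder-Mead from a method-of-moments start
    plus fallback starts.  A failed alternative search falls back to the
    null point (LRT = 0, conservative).  The nominal p refers 2*(l1-l0) to
    chi-square(1); downstream significance uses the empirical null instead.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or np.any(y <= 0):
        raise ValueError("need >= 1 heterozygote with positive total reads")
    log_choose = float(
        (special.gammaln(y + 1) - special.gammaln(x + 1) - special.gammaln(y - x + 1)).sum()
    )

    def neg_null(log_a: float) -> float:
        a = np.exp(log_a)
        return _neg_ll_core(a, a, x, y)

    n_het = len(x)

    def neg_alt(params: np.ndarray) -> tuple[float, np.ndarray]:
        a, b = np.exp(np.clip(params, -30, 30))
        nll = _neg_ll_core(a, b, x, y)
        psi_ab = special.digamma(a + b)
        psi_tot = special.digamma(y + a + b).sum()
        da = special.digamma(x + a).sum() - psi_tot + n_het * (psi_ab - special.digamma(a))
        db = special.digamma(y - x + b).sum() - psi_tot + n_het * (psi_ab - special.digamma(b))
        return nll, -np.array([da * a, db * b])  # chain rule for log params

    res0 = optimize.minimize_scalar(neg_null, bounds=(-6.0, 14.0), method="bounded")
    logl0 = -res0.fun + log_choose

    frac = x.sum() / y.sum()
    frac = min(max(frac, 1e-3), 1 - 1e-3)
    m = float(np.mean(x / y))
    v = max(float(np.var(x / y)), 1e-6)
    conc = max(m * (1 - m) / v - 1.0, 0.5)  # moment start for alpha+beta
    starts = [
        np.log([max(frac * conc, 1e-2), max((1 - frac) * conc, 1e-2)]),
        np.array([res0.x, res0.x]),
    ]
    best = None
    for s0 in starts:
        res = optimize.minimize(neg_alt, s0, jac=True, method="L-BFGS-B",
                                bounds=[(-7.0, 15.0)] * 2,
                                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < res0.fun - 1e-9:
            break  # first start already beats the null
    if best.fun > res0.fun:  # alpha = beta is nested: fall back to the null point
        best_x = np.array([res0.x, res0.x])
        best_fun = res0.fun
    else:
        best_x, best_fun = best.x, best.fun
    logl1 = -best_fun + log_choose
    a_hat, b_hat = np.exp(np.clip(best_x, -30, 30))
    lrt = max(2.0 * (logl1 - logl0), 0.0)
    p_nom = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    effect = float(special.logit(a_hat / (a_hat + b_hat)))
    mean_frac = float(np.mean(x / y))
    z = float(np.sign(mean_frac - 0.5) * np.sqrt(lrt))
    return AseFit(
        alpha=float(a_hat),
        beta=float(b_hat),
        logl0=float(logl0),
        logl1=float(logl1),
        lrt=float(lrt),
        p_nominal=max(p_nom, np.nextafter(0, 1)),
        effect=effect,
        z=z,
        converged=bool(np.isfinite(best_fun)),
    )


def fit_all_sites(allelic: AllelicCounts) -> pd.DataFrame:
    """Per-site beta-binomial LRT table."""
    rows = []
    for (site, gene), sub in allelic.table.groupby(["site_id", "gene_id"], sort=False):
        fit = fit_ase_lrt(sub["x_plus"].to_numpy(), sub["total"].to_numpy())
        rows.append(
            dict(site_id=site, gene_id=gene, n_het=len(sub), lrt=fit.lrt,
                 p_value=fit.p_nominal, effect=fit.effect, z=fit.z,
                 alpha=fit.alpha, beta=fit.beta, converged=fit.converged)
        )
    return pd.DataFrame(rows)


def empirical_null_ase(
    allelic: AllelicCounts,
    rng: np.random.Generator,
    n_reps: int = 20,
    y_tolerance: float = 0.05,
) -> pd.DataFrame:
    """Total-read-matched resampled null.

    For each replicate, every heterozygote's x^+ is replaced by an x^+
    drawn from a heterozygous observation at a *different* site with the
    same total read count y (falling back to donors within +/-
    ``y_tolerance``*y when no exact match exists elsewhere); the LRT is
    recomputed in full.  Returns the per-gene minimum null p per replicate
    (columns: gene_id, rep, p_value).
    """
    t = allelic.table
    if len(t) == 0:
        return pd.DataFrame(columns=["gene_id", "rep", "p_value"])
    # donor pools: per total-read value, the x+ draws and their site ids
    xs_all = t["x_plus"].to_numpy()
    sites_all = t["site_id"].to_numpy()
    y_all = t["total"].to_numpy()
    pool_idx: dict[int, np.ndarray] = {
        int(yv): np.flatnonzero(y_all == yv) for yv in np.unique(y_all)
    }
    y_keys = np.array(sorted(pool_idx))

    # per site: one donor-fraction array per unique y (built once, reused
    # across replicates); fractions are rescaled to the recipient depth only
    # in the tolerance-matched fallback (exact matches keep x+ as-is)
    site_groups = list(t.groupby(["site_id", "gene_id"], sort=False))
    donors_per_site: list[tuple[str, str, np.ndarray, list[np.ndarray], list[bool]]] = []
    skipped: set[str] = set()
    for (site, gene), sub in site_groups:
        ys = sub["total"].to_numpy()
        donor_arrays: list[np.ndarray] = []
        exact_flags: list[bool] = []
        usable = True
        for yv in ys:
            idx = pool_idx[int(yv)]
            idx = idx[sites_all[idx] != site]
            if len(idx):
                donor_arrays.append(xs_all[idx])
                exact_flags.append(True)
                continue
            lo, hi = yv * (1 - y_tolerance), yv * (1 + y_tolerance)
            near = y_keys[(y_keys >= lo) & (y_keys <= hi)]
            fracs: list[np.ndarray] = []
            for k in near:
                kidx = pool_idx[int(k)]
                kidx = kidx[sites_all[kidx] != site]
                if len(kidx):
                    fracs.append(xs_all[kidx] / float(k))
            if not fracs:
                usable = False
                break
            donor_arrays.append(np.concatenate(fracs))
            exact_flags.append(False)
        if usable:
            donors_per_site.append((site, gene, ys.astype(float), donor_arrays, exact_flags))
        else:
            skipped.add(site)

    rows = []
    for rep in range(n_reps):
        null_rows = []
        for site, gene, ys, donor_arrays, exact_flags in donors_per_site:
            xs = np.empty(len(ys))
            for i, (arr, exact) in enumerate(zip(donor_arrays, exact_flags)):
                draw = arr[rng.integers(0, len(arr))]
                xs[i] = draw if exact else round(draw * ys[i])
            fit = fit_ase_lrt(xs, ys)
            null_rows.append((gene, fit.p_nominal))
        null_df = pd.DataFrame(null_rows, columns=["gene_id", "p_value"])
        gene_min = null_df.groupby("gene_id")["p_value"].min().reset_index()
        gene_min["rep"] = rep
        rows.append(gene_min)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["gene_id", "p_value", "rep"])
    out.attrs["skipped_sites"] = sorted(skipped)
    return out[["gene_id", "rep", "p_value"]]


def summarize_ase_genes(
    site_fits: pd.DataFrame,
    null_min_p: pd.DataFrame,
    n_reps: int,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Per-gene best site with empirical q-values at the given FDR."""
    fits = site_fits[site_fits["converged"]].copy()
    best = fits.sort_values(["gene_id", "p_value"], kind="stable").groupby("gene_id").head(1)
    best = best.sort_values("gene_id").reset_index(drop=True)
    q, sig = empirical_fdr(
        best["p_value"].to_numpy(), null_min_p["p_value"].to_numpy(), n_perm=n_reps, fdr=fdr
    )
    best["q_value"] = q
    best["significant"] = sig
    return best.rename(columns={"site_id": "best_site"})
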