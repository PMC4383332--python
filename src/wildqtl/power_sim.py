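"""eQTL power simulations and the winner's-curse analysis.

The simulation design plants a causal cis-SNP in 10% of genes, adds its
effect to standard-normal residuals, runs the full mapping + empirical-FDR
pipeline, and scores power as the proportion of planted genes recovered at
a 10% empirical FDR.  Effects are parameterized either as a constant effect
size beta (power then depends on the causal MAF through var(x)) or as the
proportion of expression variance explained (PVE; power is then
MAF-invariant by construction).  Scenario switches mirror the contrasts
that separate a high-diversity, high-LD panel from a human-like panel:
masking the causal SNP (forcing detection through LD proxies) and thinning
per-gene SNP density to a target distribution.

The winner's-curse analysis re-runs the masked, constant-beta design at a
small effect (beta = 0.75) and correlates the estimated |beta| of detected
eQTL with MAF: at modest sample sizes the selection threshold inflates
estimates most where power is lowest (low MAF), producing a strong negative
correlation even though the true effect is constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, KinshipMatrix
from .eqtl_lmm import empirical_fdr, map_cis_eqtl, permutation_min_p

__all__ = [
    "PowerScenario",
    "plant_eqtl",
    "beta_from_pve",
    "simulate_power_expression",
    "run_power_scenario",
    "thin_snp_density",
    "winners_curse_analysis",
    "power_by_maf_quartile",
]

DEFAULT_EFFECT_GRID = tuple(np.round(np.arange(0.25, 2.51, 0.25), 2))
DEFAULT_PVE_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


@dataclass
class PowerScenario:
    """One power-simulation design.

    ``grid`` lists effect sizes (``parameterization="effect_size"``) or PVE
    values (``parameterization="pve"``).  ``thin_to`` optionally gives a
    target per-gene SNP-count sample to thin the panel toward.
    """

    parameterization: str = "effect_size"
    grid: tuple = DEFAULT_EFFECT_GRID
    eqtl_gene_fraction: float = 0.10
    mask_causal: bool = False
    thin_to: np.ndarray | None = None
    replicates: int = 10
    fdr: float = 0.10
    n_perm: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parameterization not in ("effect_size", "pve"):
            raise ValueError("parameterization must be 'effect_size' or 'pve'")
        if not 0 < self.eqtl_gene_fraction < 1:
            raise ValueError("eqtl_gene_fraction must lie in (0, 1)")


def beta_from_pve(pve: float, var_x: float) -> float:
    """|beta| that explains ``pve`` of trait variance at unit residual
    variance: beta^2 var(x) / (beta^2 var(x) + 1) = pve."""
    if not 0 < pve < 1:
        raise ValueError("pve must lie in (0, 1)")
    if var_x <= 0:
        raise ValueError("var_x must be positive")
    return float(np.sqrt(pve / ((1.0 - pve) * var_x)))


def plant_eqtl(
    genes: list[str],
    windows: dict[str, np.ndarray],
    genotypes: GenotypeMatrix,
    value: float,
    parameterization: str,
    eqtl_gene_fraction: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Choose eQTL genes and causal SNPs; return the truth table.

    Exactly round(fraction * n_genes) genes with at least one cis SNP
    receive one causal SNP drawn uniformly from their window; the remaining
    genes are null.  beta signs are random (power is sign-invariant).
    A fraction of 0 yields an all-null truth table.
    """
    if not 0 <= eqtl_gene_fraction < 1:
        raise ValueError("eqtl_gene_fraction must lie in [0, 1)")
    eligible = [g for g in genes if len(windows.get(g, [])) > 0]
    n_eqtl = int(round(eqtl_gene_fraction * len(genes)))
    chosen = set(rng.choice(eligible, size=min(n_eqtl, len(eligible)), replace=False))
    maf = genotypes.maf()
    rows = []
    for g in genes:
        if g in chosen:
            j = int(rng.choice(windows[g]))
            x = genotypes.genotypes[:, j]
            var_x = float(np.nanvar(x))
            if parameterization == "pve":
                beta = beta_from_pve(value, var_x)
            else:
                beta = float(value)
            beta *= rng.choice([-1.0, 1.0])
            rows.append(dict(gene_id=g, causal_idx=j, beta=beta, causal_maf=float(maf[j]), var_x=var_x))
        else:
            rows.append(dict(gene_id=g, causal_idx=-1, beta=0.0, causal_maf=np.nan, var_x=np.nan))
    return pd.DataFrame(rows)


def simulate_power_expression(
    truth: pd.DataFrame, genotypes: GenotypeMatrix, rng: np.random.Generator
) -> ExpressionMatrix:
    """z = x_causal * beta + N(0,1) residuals, per gene (latent scale)."""
    n = genotypes.n_individuals
    Z = rng.standard_normal((len(truth), n))
    for i, row in enumerate(truth.itertuples()):
        if row.causal_idx >= 0:
            x = genotypes.genotypes[:, row.causal_idx]
            x = np.where(np.isnan(x), np.nanmean(x), x)
            Z[i] += row.beta * x
    df = pd.DataFrame(Z, index=truth["gene_id"], columns=genotypes.samples)
    return ExpressionMatrix(counts=df, normalized=df)


def thin_snp_density(
    windows: dict[str, np.ndarray],
    target_counts: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Subsample each gene's cis SNPs toward a target count distribution.

    Counts are quantile-matched: the gene at the q-th quantile of the source
    per-gene SNP-count distribution is thinned to the q-th quantile of the
    target distribution (capped at its own count, so thinning never adds
    SNPs).  Matching by rank rather than by independent redraws makes
    "target = source" an identity and preserves the count ordering across
    genes; which SNPs are dropped is random.
    """
    target_counts = np.asarray(target_counts, dtype=float)
    genes = [g for g in windows if len(windows[g])]
    src = np.array([len(windows[g]) for g in genes], dtype=float)
    from scipy.stats import rankdata

    q = (rankdata(src, method="average") - 0.5) / len(src)
    targets = np.quantile(target_counts, q, method="closest_observation")
    out = {g: windows[g] for g in windows if len(windows[g]) == 0}
    for g, k_t, avail in zip(genes, targets, src):
        idx = windows[g]
        k = int(min(round(k_t), avail))
        if k >= len(idx):
            out[g] = idx
        else:
            out[g] = np.sort(rng.choice(idx, size=max(k, 1), replace=False))
    return out


def _run_one_replicate(
    genotypes: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    kinship: KinshipMatrix | None,
    scenario: PowerScenario,
    value: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    genes = list(windows.keys())
    truth = plant_eqtl(
        genes, windows, genotypes, value, scenario.parameterization, scenario.eqtl_gene_fraction, rng
    )
    expr = simulate_power_expression(truth, genotypes, rng)
    test_windows = windows
    if scenario.thin_to is not None:
        test_windows = thin_snp_density(windows, scenario.thin_to, rng)
    if scenario.mask_causal:
        masked = {}
        causal = dict(zip(truth["gene_id"], truth["causal_idx"]))
        for g, idx in test_windows.items():
            masked[g] = idx[idx != causal.get(g, -1)]
        test_windows = masked
    table = map_cis_eqtl(expr, genotypes, test_windows, kinship)
    perm_p = permutation_min_p(expr, genotypes, test_windows, kinship, scenario.n_perm, rng)
    q, sig = empirical_fdr(table["p_value"].to_numpy(), perm_p, scenario.n_perm, scenario.fdr)
    table = table.assign(q_value=q, significant=sig).rename(columns={"beta": "beta_hat"})
    detail = truth.merge(table, on="gene_id")
    maf = genotypes.maf()
    snp_pos = {s: i for i, s in enumerate(genotypes.sites["snp_id"])}
    detail["best_maf"] = [
        maf[snp_pos[s]] if isinstance(s, str) else np.nan for s in detail["best_snp"]
    ]
    return detail


def run_power_scenario(
    genotypes: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    scenario: PowerScenario,
    kinship: KinshipMatrix | None = None,
    return_detail: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Power and realized FDR per (grid value, replicate).

    A planted gene counts as recovered when it is significant at the
    scenario FDR, whichever cis SNP is the best hit; a gene whose only SNP
    was masked is untestable and counts as not recovered.
    """
    ss = np.random.SeedSequence(scenario.seed)
    results = []
    details = []
    for value in scenario.grid:
        for rep in range(scenario.replicates):
            rng = np.random.default_rng(ss.spawn(1)[0])
            detail = _run_one_replicate(genotypes, windows, kinship, scenario, float(value), rng)
            is_eqtl = detail["causal_idx"] >= 0
            detected = detail["significant"].fillna(False).astype(bool)
            n_sig = int(detected.sum())
            power = float((detected & is_eqtl).sum() / max(is_eqtl.sum(), 1))
            realized_fdr = float((detected & ~is_eqtl).sum() / n_sig) if n_sig else np.nan
            mean_beta = float(detail.loc[detected & is_eqtl, "beta_hat"].abs().mean())
            results.append(
                dict(value=float(value), replicate=rep, power=power,
                     realized_fdr=realized_fdr, mean_abs_beta_detected=mean_beta,
                     n_discoveries=n_sig)
            )
            if return_detail:
                detail = detail.assign(value=float(value), replicate=rep)
                details.append(detail)
    res = pd.DataFrame(results)
    if return_detail:
        return res, pd.concat(details, ignore_index=True)
    return res


def power_by_maf_quartile(detail: pd.DataFrame) -> pd.DataFrame:
    """Power stratified by causal-SNP MAF quartile (pooled over replicates)."""
    planted = detail[detail["causal_idx"] >= 0].copy()
    planted["maf_quartile"] = pd.qcut(planted["causal_maf"], 4, labels=[1, 2, 3, 4], duplicates="drop")
    out = (
        planted.groupby("maf_quartile", observed=True)
        .agg(power=("significant", "mean"), n=("significant", "size"))
        .reset_index()
    )
    return out


def winners_curse_analysis(
    genotypes: GenotypeMatrix,
    windows: dict[str, np.ndarray],
    kinship: KinshipMatrix | None = None,
    beta: float = 0.75,
    mask_causal: bool = True,
    replicates: int = 10,
    fdr: float = 0.10,
    n_perm: int = 10,
    eqtl_gene_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Constant-small-effect simulation; correlation of |beta_hat| with MAF
    among detected eQTL.

    Returns (per-detected-eQTL table, Pearson r); r is NaN when nothing is
    detected.  MAF is taken from the best SNP (the causal is masked by
    default, as in the design this analysis diagnoses).  On small gene
    panels a higher ``eqtl_gene_fraction`` populates the detected set the
    way a genome-wide panel would.
    """
    scenario = PowerScenario(
        parameterization="effect_size",
        grid=(beta,),
        mask_causal=mask_causal,
        replicates=replicates,
        fdr=fdr,
        n_perm=n_perm,
        eqtl_gene_fraction=eqtl_gene_fraction,
        seed=seed,
    )
    _, detail = run_power_scenario(genotypes, windows, scenario, kinship, return_detail=True)
    is_eqtl = detail["causal_idx"] >= 0
    detected = detail["significant"].fillna(False).astype(bool) & is_eqtl
    hits = detail.loc[detected, ["gene_id", "replicate", "causal_maf", "best_maf", "beta_hat"]].copy()
    hits["abs_beta_hat"] = hits["beta_hat"].abs()
    maf_col = "best_maf" if mask_causal else "causal_maf"
    if len(hits) < 3 or hits[maf_col].std() == 0:
        return hits, float("nan")
    r = float(np.corrcoef(hits["abs_beta_hat"], hits[maf_col])[0, 1])
    return hits, r
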