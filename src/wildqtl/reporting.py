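"""Cross-method concordance and positional-enrichment summaries.

Ties the eQTL and ASE results together: hypergeometric overlap of the two
significant gene sets, correlation of effect sizes for genes significant in
both, enrichment of eQTL SNPs near transcription start sites relative to
the tested background, and the distance profile of ASE similarity between
site pairs within genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneAnnotation

__all__ = [
    "hypergeometric_overlap",
    "effect_concordance",
    "relative_positions",
    "positional_enrichment",
    "ase_distance_profile",
]

N_BODY_BINS = 20


def hypergeometric_overlap(set_a: set, set_b: set, universe: set) -> tuple[int, float]:
    """Upper-tail hypergeometric p for the overlap of two gene sets."""
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))
    return k, min(p, 1.0)


def effect_concordance(
    table1: pd.DataFrame,
    table2: pd.DataFrame,
    key: str = "gene_id",
    col1: str = "beta",
    col2: str = "effect",
) -> tuple[float, float, int]:
    """Pearson correlation of effects across the joined records."""
    joined = table1[[key, col1]].merge(table2[[key, col2]], on=key).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need >= 3 joined records")
    a, b = joined[col1].to_numpy(float), joined[col2].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), n


def relative_positions(
    snp_table: pd.DataFrame, annotation: GeneAnnotation
) -> pd.DataFrame:
    """Strand-aware position of each SNP relative to its gene.

    Input rows need ``gene_id`` and ``pos``.  Output adds ``zone``
    (upstream/gene_body/downstream, polarized TSS->TES), ``flank_bp``
    (signed distance, negative upstream of the TSS; NaN inside the body)
    and ``body_bin`` (1..20 over the half-open span [TSS, TES); the TSS
    falls in bin 1; NaN outside the body).
    """
    genes = annotation.genes.set_index("gene_id")
    zones, flanks, bins = [], [], []
    for row in snp_table.itertuples():
        g = genes.loc[row.gene_id]
        pos = row.pos
        if g["strand"] == "+":
            tss, tes = g["start"], g["end"]
            offset = pos - tss
            length = tes - tss + 1
        else:
            tss, tes = g["end"], g["start"]
            offset = tss - pos
            length = tss - tes + 1
        if offset < 0:
            zones.append("upstream")
            flanks.append(float(offset))
            bins.append(np.nan)
        elif offset >= length:
            zones.append("downstream")
            flanks.append(float(offset - length + 1))
            bins.append(np.nan)
        else:
            zones.append("gene_body")
            flanks.append(np.nan)
            bins.append(int(offset * N_BODY_BINS // length) + 1)
    out = snp_table.copy()
    out["zone"] = zones
    out["flank_bp"] = flanks
    out["body_bin"] = bins
    return out


def positional_enrichment(
    eqtl_snps: pd.DataFrame,
    background_snps: pd.DataFrame,
    annotation: GeneAnnotation,
    flank_bin_bp: int = 20_000,
    max_flank: int = 200_000,
) -> tuple[pd.DataFrame, float, float]:
    """Density of eQTL SNPs vs the tested background by relative position.

    Both inputs need ``gene_id`` and ``pos`` columns (each SNP paired with
    the gene it was tested against).  Positions are collapsed onto a common
    axis: negative flank bins upstream, body bins 1..20, positive flank
    bins downstream.  Returns (per-bin table with densities and enrichment
    ratio, KS D, KS p) where the KS test compares the two relative-coordinate
    distributions.
    """
    def axis_coord(rel: pd.DataFrame) -> np.ndarray:
        # map to a continuous axis: [-1, 0) upstream, [0, 1) body, [1, 2) downstream
        coord = np.empty(len(rel))
        up = rel["zone"] == "upstream"
        down = rel["zone"] == "downstream"
        body = rel["zone"] == "gene_body"
        coord[up.to_numpy()] = np.maximum(rel.loc[up, "flank_bp"], -max_flank) / max_flank
        coord[body.to_numpy()] = (rel.loc[body, "body_bin"] - 0.5) / N_BODY_BINS
        coord[down.to_numpy()] = 1.0 + np.minimum(rel.loc[down, "flank_bp"], max_flank) / max_flank
        return coord

    rel_e = relative_positions(eqtl_snps, annotation)
    rel_b = relative_positions(background_snps, annotation)
    coord_e = axis_coord(rel_e)
    coord_b = axis_coord(rel_b)

    n_flank_bins = max_flank // flank_bin_bp
    edges = np.concatenate(
        [
            np.linspace(-1, 0, n_flank_bins + 1)[:-1],
            np.linspace(0, 1, N_BODY_BINS + 1)[:-1],
            np.linspace(1, 2, n_flank_bins + 1),
        ]
    )
    dens_e, _ = np.histogram(coord_e, bins=edges, density=False)
    dens_b, _ = np.histogram(coord_b, bins=edges, density=False)
    frac_e = dens_e / max(dens_e.sum(), 1)
    frac_b = dens_b / max(dens_b.sum(), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(frac_b > 0, frac_e / frac_b, np.nan)
    table = pd.DataFrame(
        dict(bin_lo=edges[:-1], bin_hi=edges[1:], n_eqtl=dens_e, n_background=dens_b,
             frac_eqtl=frac_e, frac_background=frac_b, enrichment=ratio)
    )
    if len(coord_e) and len(coord_b):
        ks = stats.ks_2samp(coord_e, coord_b)
        return table, float(ks.statistic), float(ks.pvalue)
    return table, float("nan"), float("nan")


def ase_distance_profile(
    site_table: pd.DataFrame,
    bin_maxima: tuple = (1e2, 1e3, 1e4, 1e5, 1e6),
) -> pd.DataFrame:
    """Mean |Delta |z|| between within-gene site pairs, binned by distance.

    ``site_table`` needs ``gene_id``, ``pos`` and ``z``.  Each bin spans
    from the previous maximum (0 for the first) to its labeled maximum.
    Genes with a single tested site are skipped.
    """
    pairs = []
    for _, sub in site_table.groupby("gene_id"):
        if len(sub) < 2:
            continue
        pos = sub["pos"].to_numpy(float)
        z = np.abs(sub["z"].to_numpy(float))
        for a in range(len(sub) - 1):
            for b in range(a + 1, len(sub)):
                pairs.append((abs(pos[b] - pos[a]), abs(z[a] - z[b])))
    if not pairs:
        return pd.DataFrame(columns=["dist_lo", "dist_hi", "mean_abs_dz", "n_pairs"])
    arr = pd.DataFrame(pairs, columns=["dist", "dz"])
    edges = np.concatenate([[0.0], np.asarray(bin_maxima, float)])
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (arr["dist"] > lo) & (arr["dist"] <= hi)
        if sel.any():
            rows.append((lo, hi, float(arr.loc[sel, "dz"].mean()), int(sel.sum())))
    return pd.DataFrame(rows, columns=["dist_lo", "dist_hi", "mean_abs_dz", "n_pairs"])
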