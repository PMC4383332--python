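"""End-to-end orchestration: preprocess -> eQTL -> ASE -> reporting.

Each stage writes its tables under the configured output directory and a
manifest (JSON) records seeds, thresholds and per-stage record counts so
the filtering accounting can be reproduced from the logs alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import eqtl_lmm, preprocess, reporting
from .io import RunConfig, load_dataset

__all__ = ["run_pipeline"]


def _stage_seeds(seed: int) -> dict[str, np.random.Generator]:
    names = ["impute", "eqtl_perm", "ase_null"]
    ss = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, ss)}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dict.

    Any stage failure raises after writing a partial manifest naming the
    failed stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rngs = _stage_seeds(config.seed)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def _write_manifest() -> None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    stage = "load"
    try:
        genotypes, expr, allelic, annotation, covariates = load_dataset(
            config.vcf, config.gff, config.counts, config.allelic, config.covariates
        )
        manifest["stages"]["load"] = {
            "n_samples": genotypes.n_individuals,
            "n_sites": genotypes.n_sites,
            "n_genes": len(expr.counts),
            "dropped_samples": expr.counts.attrs.get("dropped_samples", []),
        }

        # ---------------- preprocess ----------------
        stage = "preprocess"
        expr = preprocess.filter_genes(expr, config.min_frac_nonzero, config.min_mean_count)
        expr = preprocess.normalize_expression(expr)
        filtered, removal_log = preprocess.filter_variants(
            genotypes,
            annotation,
            max_missing_frac=config.max_missing_frac,
            hwe_alpha=config.hwe_alpha,
            min_qual=config.min_qual,
            min_mean_depth=config.min_mean_depth,
            cis_window=config.cis_window,
        )
        imputed, imputed_mask = preprocess.impute_missing(filtered, rngs["impute"])
        kinship = eqtl_lmm.compute_kinship(imputed)
        corrected = preprocess.regress_out_pcs(expr, k=min(config.n_expression_pcs, expr.counts.shape[1] - 1))
        if config.local_structure_pcs > 0:
            chrom_of = annotation.genes.set_index("gene_id")["chrom"]
            corrected = eqtl_lmm.local_structure_control(
                corrected, imputed, chrom_of, k=config.local_structure_pcs
            )
        expr.normalized.to_csv(out_dir / "normalized_expression.tsv", sep="\t")
        manifest["stages"]["preprocess"] = {
            "genes_kept": len(expr.counts),
            "sites_kept": imputed.n_sites,
            "variant_removals": removal_log.to_dict(),
            "imputed_cells": int(imputed_mask.sum()),
        }

        windows = preprocess.cis_window_index(annotation, imputed.sites, config.cis_window)

        # ---------------- eQTL ----------------
        eqtl_table = None
        if config.run_eqtl:
            stage = "eqtl"
            eqtl_table = eqtl_lmm.map_cis_eqtl(
                corrected, imputed, windows, kinship,
                annotation_pos=annotation.genes.set_index("gene_id")[["start", "end"]],
            )
            perm_p = eqtl_lmm.permutation_min_p(
                corrected, imputed, windows, kinship, config.n_eqtl_perms, rngs["eqtl_perm"]
            )
            q, sig = eqtl_lmm.empirical_fdr(
                eqtl_table["p_value"].to_numpy(), perm_p, config.n_eqtl_perms, config.fdr
            )
            eqtl_table = eqtl_table.assign(q_value=q, significant=sig)
            eqtl_table.to_csv(out_dir / "eqtl_genes.tsv", sep="\t", index=False, na_rep=".")
            manifest["stages"]["eqtl"] = {
                "genes_tested": int((eqtl_table["n_snps"] > 0).sum()),
                "significant": int(eqtl_table["significant"].sum()),
            }
        else:
            manifest["stages"]["eqtl"] = "skipped"

        # ---------------- ASE ----------------
        ase_table = None
        if config.run_ase and allelic is not None:
            stage = "ase"
            kept = ase_mod.filter_ase_sites(
                allelic,
                min_qual=config.ase_min_qual,
                min_reads_per_ind=config.ase_min_reads_per_ind,
                min_individuals=config.ase_min_individuals,
                min_total_reads=config.ase_min_total_reads,
            )
            site_fits = ase_mod.fit_all_sites(kept)
            if len(site_fits):
                null_p = ase_mod.empirical_null_ase(kept, rngs["ase_null"], n_reps=config.n_ase_null_reps)
                ase_table = ase_mod.summarize_ase_genes(
                    site_fits, null_p, config.n_ase_null_reps, fdr=config.fdr
                )
                site_fits.to_csv(out_dir / "ase_sites.tsv", sep="\t", index=False, na_rep=".")
                ase_table.to_csv(out_dir / "ase_genes.tsv", sep="\t", index=False, na_rep=".")
            manifest["stages"]["ase"] = {
                "sites_kept": int(kept.table["site_id"].nunique()),
                "genes_tested": 0 if ase_table is None else len(ase_table),
                "significant": 0 if ase_table is None else int(ase_table["significant"].sum()),
            }
        else:
            manifest["stages"]["ase"] = "skipped"

        # ---------------- reporting ----------------
        if config.run_report and eqtl_table is not None and ase_table is not None:
            stage = "report"
            universe = set(eqtl_table["gene_id"]) & set(ase_table["gene_id"])
            sig_e = set(eqtl_table.loc[eqtl_table["significant"], "gene_id"]) & universe
            sig_a = set(ase_table.loc[ase_table["significant"], "gene_id"]) & universe
            if universe:
                k, p_overlap = reporting.hypergeometric_overlap(sig_e, sig_a, universe)
            else:
                k, p_overlap = 0, float("nan")
            try:
                r, p_r, n_joined = reporting.effect_concordance(
                    eqtl_table.dropna(subset=["beta"]), ase_table, col1="beta", col2="effect"
                )
            except ValueError:
                r, p_r, n_joined = float("nan"), float("nan"), 0
            snp_pos = dict(zip(imputed.sites["snp_id"], imputed.sites["pos"]))
            eqtl_sig_snps = eqtl_table.loc[eqtl_table["significant"] & eqtl_table["best_snp"].notna()]
            eqtl_snp_df = pd.DataFrame(
                {"gene_id": eqtl_sig_snps["gene_id"], "pos": [snp_pos[s] for s in eqtl_sig_snps["best_snp"]]}
            )
            bg_rows = [
                {"gene_id": g, "pos": imputed.sites.iloc[j]["pos"]}
                for g, idx in windows.items()
                for j in idx
            ]
            bg_df = pd.DataFrame(bg_rows, columns=["gene_id", "pos"])
            enr, ks_d, ks_p = reporting.positional_enrichment(eqtl_snp_df, bg_df, annotation)
            enr.to_csv(out_dir / "positional_enrichment.tsv", sep="\t", index=False)
            summary = {
                "overlap": k,
                "overlap_p": p_overlap,
                "effect_r": r,
                "effect_r_p": p_r,
                "n_joined": n_joined,
                "position_ks_d": ks_d,
                "position_ks_p": ks_p,
            }
            with open(out_dir / "concordance.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            manifest["stages"]["report"] = summary
        else:
            manifest["stages"]["report"] = "skipped"
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest()
        raise
    _write_manifest()
    return manifest
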