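"""Readers, writers and run configuration.

Formats: VCF 4.2 (GT and DP per sample, QUAL column), GFF3 for gene/exon
annotation, and tab-separated tables with header rows ('.' for missing).
Coordinates stay 1-based in files and in the in-memory ``sites``/``genes``
tables; all readers validate ordering and sample consistency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import AllelicCounts, ExpressionMatrix, GeneAnnotation, GenotypeMatrix

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_gff3",
    "write_gff3",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_allelic_tsv",
    "write_allelic_tsv",
    "read_covariates_tsv",
    "RunConfig",
    "load_dataset",
]


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load genotypes, QUAL and per-sample DP from a VCF via cyvcf2.

    Rejects VCFs whose positions are not strictly increasing within a
    chromosome (duplicated or unsorted sites), reporting the record number.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    depths = []
    last: dict[str, int] = {}
    for i, rec in enumerate(vcf):
        if rec.CHROM in last and rec.POS <= last[rec.CHROM]:
            raise ValueError(
                f"VCF positions out of order at record {i + 1} ({rec.CHROM}:{rec.POS})"
            )
        last[rec.CHROM] = rec.POS
        gt = np.asarray(rec.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage = np.where(gt == 3, 2.0, gt)
        dosage[gt == 2] = np.nan
        dosages.append(dosage)
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        depths.append(dp[:, 0].astype(float) if dp is not None else np.full(len(samples), np.nan))
        rows.append(
            (
                rec.ID if rec.ID else f"snp_{rec.CHROM}_{rec.POS}",
                rec.CHROM,
                rec.POS,
                rec.REF,
                rec.ALT[0] if rec.ALT else ".",
                float(rec.QUAL) if rec.QUAL is not None else np.nan,
            )
        )
    vcf.close()
    sites = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt", "qual"])
    G = np.asarray(dosages).T if dosages else np.zeros((len(samples), 0))
    D = np.asarray(depths).T if depths else None
    if D is not None and np.isnan(D).all():
        D = None
    return GenotypeMatrix(samples=samples, sites=sites, genotypes=G, depth=D)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT:DP per sample."""
    G = genotypes.genotypes
    D = genotypes.depth
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=wildqtl\n")
        for chrom in genotypes.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes.samples) + "\n")
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, site in genotypes.sites.iterrows():
            cells = []
            for i in range(genotypes.n_individuals):
                g = G[i, j]
                gt = "./." if np.isnan(g) else gt_codes[float(g)]
                dp = "." if D is None or np.isnan(D[i, j]) else str(int(D[i, j]))
                cells.append(f"{gt}:{dp}")
            qual = "." if pd.isna(site["qual"]) else f"{site['qual']:g}"
            fh.write(
                f"{site['chrom']}\t{site['pos']}\t{site['snp_id']}\t{site['ref']}\t"
                f"{site['alt']}\t{qual}\t.\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in annotation.genes.iterrows():
            attrs = f"ID={g['gene_id']};gc_content={g['gc']:.4f}"
            fh.write(
                f"{g['chrom']}\twildqtl\tgene\t{g['start']}\t{g['end']}\t.\t{g['strand']}\t.\t{attrs}\n"
            )
            exons = annotation.exons[annotation.exons["gene_id"] == g["gene_id"]]
            for k, (_, ex) in enumerate(exons.iterrows(), 1):
                fh.write(
                    f"{ex['chrom']}\twildqtl\texon\t{ex['start']}\t{ex['end']}\t.\t{g['strand']}\t.\t"
                    f"ID={g['gene_id']}.exon{k};Parent={g['gene_id']}\n"
                )


def read_gff3(path: str | Path) -> GeneAnnotation:
    """Parse genes and exons from GFF3 via gffutils (in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    gene_rows = []
    exon_rows = []
    for gene in db.features_of_type("gene"):
        gc = float(gene.attributes.get("gc_content", [np.nan])[0])
        gene_rows.append((gene.id, gene.seqid, gene.start, gene.end, gene.strand, gc))
        for ex in db.children(gene, featuretype="exon"):
            exon_rows.append((gene.id, ex.seqid, ex.start, ex.end))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "gc"])
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])
    return GeneAnnotation(genes=genes, exons=exons)


# ---------------------------------------------------------------------------
# TSV tables


def write_counts_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.counts.copy()
    out.index.name = "gene_id"
    if expr.gene_meta is not None:
        meta = expr.gene_meta[["length", "gc"]]
        out = meta.join(out)
        out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    meta = None
    if {"length", "gc"} <= set(df.columns):
        meta = df[["length", "gc"]]
        df = df.drop(columns=["length", "gc"])
    return ExpressionMatrix(counts=df, gene_meta=meta)


def write_allelic_tsv(allelic: AllelicCounts, path: str | Path) -> None:
    allelic.table.to_csv(path, sep="\t", index=False, na_rep=".")


def read_allelic_tsv(path: str | Path) -> AllelicCounts:
    df = pd.read_csv(path, sep="\t", na_values=".")
    return AllelicCounts(table=df)


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample", na_values=".")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """All pipeline thresholds with their standard defaults."""

    vcf: str = "genotypes.vcf"
    gff: str = "genes.gff3"
    counts: str = "counts.tsv"
    allelic: str = "allelic_counts.tsv"
    covariates: str | None = "covariates.tsv"
    out_dir: str = "results"
    cis_window: int = 200_000
    fdr: float = 0.10
    n_expression_pcs: int = 10
    local_structure_pcs: int = 0  # 2 enables the same-chromosome control
    hwe_alpha: float = 0.05
    min_qual: float = 100.0
    max_missing_frac: float = 12.0 / 63.0
    min_mean_depth: float = 5.0
    min_frac_nonzero: float = 0.10
    min_mean_count: float = 10.0
    ase_min_qual: float = 10.0
    ase_min_reads_per_ind: int = 5
    ase_min_individuals: int = 2
    ase_min_total_reads: int = 300
    n_eqtl_perms: int = 10
    n_ase_null_reps: int = 20
    run_eqtl: bool = True
    run_ase: bool = True
    run_report: bool = True
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_dataset(
    vcf: str | Path,
    gff: str | Path,
    counts: str | Path,
    allelic: str | Path | None = None,
    covariates: str | Path | None = None,
) -> tuple[GenotypeMatrix, ExpressionMatrix, AllelicCounts | None, GeneAnnotation, pd.DataFrame | None]:
    """Load and harmonize all inputs; sample ids are intersected.

    Samples present in some tables but not others are dropped with a
    recorded report (``.attrs['dropped_samples']`` on the expression
    counts frame).
    """
    genotypes = read_vcf(vcf)
    annotation = read_gff3(gff)
    expr = read_counts_tsv(counts)
    ase = read_allelic_tsv(allelic) if allelic else None
    cov = read_covariates_tsv(covariates) if covariates else None

    shared = [s for s in genotypes.samples if s in set(expr.counts.columns)]
    if not shared:
        raise ValueError(
            "no shared samples between VCF and counts; "
            f"VCF has {genotypes.samples[:5]}..., counts has {list(expr.counts.columns)[:5]}..."
        )
    dropped = sorted(
        (set(genotypes.samples) | set(expr.counts.columns)) - set(shared)
    )
    if set(shared) != set(genotypes.samples):
        genotypes = genotypes.take_samples(shared)
    expr_counts = expr.counts[shared]
    expr = ExpressionMatrix(counts=expr_counts, gene_meta=expr.gene_meta)
    expr.counts.attrs["dropped_samples"] = dropped
    if ase is not None and len(ase.table):
        ase = AllelicCounts(table=ase.table[ase.table["sample"].isin(shared)].reset_index(drop=True))
    if cov is not None:
        cov = cov.reindex(shared)
    return genotypes, expr, ase, annotation, cov
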