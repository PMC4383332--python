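"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Genotypes are alternate-allele dosages in {0, 1, 2}; missing entries are
  ``NaN`` in the float matrix.
* Genomic coordinates are stored 1-based inclusive (VCF/GFF3 convention);
  any half-open arithmetic is local to the function doing it.
* Expression matrices are genes x individuals; genotype matrices are
  individuals x SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "AllelicCounts",
    "KinshipMatrix",
]


@dataclass
class GeneAnnotation:
    """Gene and exon coordinates.

    ``genes``: one row per gene with columns
    ``gene_id, chrom, start, end, strand, gc`` (start/end 1-based inclusive,
    TSS = start on '+' strand, = end on '-').
    ``exons``: one row per exon with columns ``gene_id, chrom, start, end``.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    def gene_lengths(self) -> pd.Series:
        """Total exonic length (bp) per gene, for RPKM."""
        ex = self.exons
        lengths = (ex["end"] - ex["start"] + 1).groupby(ex["gene_id"]).sum()
        return lengths.reindex(self.genes["gene_id"]).astype(int)

    def __post_init__(self) -> None:
        if len(self.genes) and (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene start must be <= end")


@dataclass
class GenotypeMatrix:
    """Alt-allele dosages with per-site metadata.

    ``genotypes`` is individuals x SNPs (float, NaN = missing). ``sites``
    has one row per SNP: ``snp_id, chrom, pos, ref, alt, qual`` plus
    optional depth summaries. ``depth`` (same shape as genotypes) carries
    per-individual read depth when available. ``haplotypes`` (2, n, p) is
    retained by the simulator for phasing; real data loaders leave it None.
    """

    samples: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    depth: np.ndarray | None = None
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def alt_freq(self) -> np.ndarray:
        """Per-site alternate allele frequency, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency (folded alt frequency)."""
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def missing_fraction(self) -> np.ndarray:
        return np.mean(np.isnan(self.genotypes), axis=0)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (positional)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            genotypes=self.genotypes[:, index],
            depth=None if self.depth is None else self.depth[:, index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, index],
        )

    def take_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in keep]
        return GenotypeMatrix(
            samples=list(keep),
            sites=self.sites.copy(),
            genotypes=self.genotypes[idx],
            depth=None if self.depth is None else self.depth[idx],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, idx],
        )


@dataclass
class ExpressionMatrix:
    """Gene-level read counts and (optionally) normalized values.

    Both frames are genes x individuals with gene ids as index and sample
    ids as columns. ``gene_meta`` is indexed by gene id with at least
    ``length`` (exonic bp) and ``gc`` columns when known.
    """

    counts: pd.DataFrame
    normalized: pd.DataFrame | None = None
    gene_meta: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class AllelicCounts:
    """Per-site, per-heterozygote allelic read counts.

    ``table`` columns: ``site_id, gene_id, chrom, pos, qual, sample,
    x_plus, total`` where ``x_plus`` counts reads carrying the site's
    alternate allele and ``total`` all reads overlapping the site.
    """

    table: pd.DataFrame

    REQUIRED = ["site_id", "gene_id", "chrom", "pos", "qual", "sample", "x_plus", "total"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"allelic count table missing columns {missing}")
        t = self.table
        if len(t) and ((t["x_plus"] < 0).any() or (t["x_plus"] > t["total"]).any()):
            raise ValueError("require 0 <= x_plus <= total")


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix K = X Xᵀ / p (X column-centered)."""

    K: np.ndarray
    n_snps: int
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-8):
            raise ValueError("K must be symmetric")

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached (eigenvalues, eigenvectors); eigenvalues clipped at 0."""
        if self._eig is None:
            d, u = np.linalg.eigh(self.K)
            self._eig = (np.clip(d, 0.0, None), u)
        return self._eig
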