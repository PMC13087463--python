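"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
* Phenotype BED anchors are stored as read: 0-based half-open (BED).
* Variant positions are stored 1-based (VCF convention) everywhere internally.
* Variant ids follow one canonical builder: ``{chrom}_{pos}_{ref}_{alt}_{build}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_BUILD = "b38"

#: fraction of missing genotypes above which a variant is dropped outright
MAX_MISSING_FRACTION = 0.10


def variant_id(chrom: str, pos: int, ref: str, alt: str, build: str = DEFAULT_BUILD) -> str:
    """Canonical variant identifier: chrom_pos_ref_alt_build."""
    return f"{chrom}_{pos}_{ref}_{alt}_{build}"


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Normalized gene x sample expression with genomic anchors.

    ``anchors`` is indexed by gene id with columns chrom/start/end (BED
    conventions); ``values`` shares the gene index, columns are sample ids.
    """

    anchors: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.anchors.index.duplicated().any():
            dups = self.anchors.index[self.anchors.index.duplicated()].tolist()
            raise ValueError(f"duplicate phenotype ids: {dups}")
        if not self.anchors.index.equals(self.values.index):
            raise ValueError("anchors and values must share a gene index")

    @property
    def gene_ids(self) -> list[str]:
        return self.anchors.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return len(self.anchors)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sort_genomic(self) -> "ExpressionMatrix":
        order = self.anchors.sort_values(["chrom", "start"], kind="mergesort").index
        return ExpressionMatrix(self.anchors.loc[order], self.values.loc[order])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        ids = list(gene_ids)
        return ExpressionMatrix(self.anchors.loc[ids], self.values.loc[ids])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.anchors, self.values[list(sample_ids)])

    def genes_on(self, chrom: str) -> list[str]:
        return self.anchors.index[self.anchors["chrom"] == chrom].tolist()

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.anchors["chrom"]))


def read_phenotype_bed(path: str | Path) -> ExpressionMatrix:
    """Read a GTEx-dialect phenotype BED (chrom/start/end/phenotype_id + samples).

    Genes are returned sorted by (chrom, start). Duplicate phenotype ids and
    non-numeric expression cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = ["chrom", "start", "end", "phenotype_id"] + list(df.columns[4:])
    if df["phenotype_id"].duplicated().any():
        dups = df.loc[df["phenotype_id"].duplicated(), "phenotype_id"].tolist()
        raise ValueError(f"duplicate phenotype ids in {path}: {dups}")
    sample_cols = list(df.columns[4:])
    values = df[sample_cols]
    for col in sample_cols:
        coerced = pd.to_numeric(values[col], errors="coerce")
        if coerced.isna().any() and not values[col].isna().any():
            bad = df.loc[coerced.isna(), "phenotype_id"].iloc[0]
            raise ValueError(f"non-numeric expression value at phenotype {bad!r}, sample {col!r}")
    anchors = df[["chrom", "start", "end"]].copy()
    anchors["chrom"] = anchors["chrom"].astype(str)
    anchors.index = pd.Index(df["phenotype_id"], name="phenotype_id")
    vals = values.astype(float)
    vals.index = anchors.index
    return ExpressionMatrix(anchors, vals).sort_genomic()


def write_phenotype_bed(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.anchors.copy()
    out.insert(3, "phenotype_id", expr.anchors.index)
    out.columns = ["#chr", "start", "end", "phenotype_id"]
    out = pd.concat([out.reset_index(drop=True), expr.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (variants x samples, alt-allele counts in [0, 2])."""

    variant_ids: list[str]
    chrom: list[str]
    positions: np.ndarray  # 1-based
    ref: list[str]
    alt: list[str]
    dosages: np.ndarray  # variants x samples, float
    sample_ids: list[str]
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.maf is None:
            self.maf = compute_maf(self.dosages)
        else:
            self.maf = np.asarray(self.maf, dtype=float)
            if self.dosages.size and not np.allclose(self.maf, compute_maf(self.dosages), atol=1e-12):
                raise ValueError("stored maf does not match dosages")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_region(self, chrom: str, start: int, end: int) -> "GenotypeMatrix":
        """1-based inclusive region subset."""
        keep = [
            i
            for i in range(self.n_variants)
            if self.chrom[i] == chrom and start <= self.positions[i] <= end
        ]
        return self.subset_variants(keep)

    def subset_variants(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            [self.variant_ids[i] for i in idx],
            [self.chrom[i] for i in idx],
            self.positions[idx] if len(idx) else np.empty(0, dtype=int),
            [self.ref[i] for i in idx],
            [self.alt[i] for i in idx],
            self.dosages[idx] if len(idx) else np.empty((0, self.n_samples)),
            self.sample_ids,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            self.variant_ids,
            self.chrom,
            self.positions,
            self.ref,
            self.alt,
            self.dosages[:, cols] if self.dosages.size else self.dosages.reshape(self.n_variants, 0),
            list(sample_ids),
        )


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per variant from diploid dosages."""
    if dosages.size == 0:
        return np.empty(dosages.shape[0])
    af = dosages.mean(axis=1) / 2.0
    return np.minimum(af, 1.0 - af)


def read_genotypes(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
    maf_floor: float = 0.05,
    build: str = DEFAULT_BUILD,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    ``region`` is (chrom, start, end), 1-based inclusive. Dosage is the count
    of alt alleles; the MAF floor is inclusive ("0.05 or more" retained).
    Missing genotypes are mean-imputed per variant; variants missing in more
    than 10% of samples are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    vids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if region is not None:
            chrom, start, end = region
            if rec.CHROM != chrom or not (start <= rec.POS <= end):
                continue
        if len(rec.ALT) != 1:
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue  # SNPs only
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012=False → 3=hom-alt, 2=unknown)
        gts = rec.genotype.array()
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan
        dos = alleles.sum(axis=1)
        miss = np.isnan(dos)
        if miss.mean() > MAX_MISSING_FRACTION:
            continue
        if miss.any():
            dos[miss] = np.nanmean(dos)
        maf = min(dos.mean() / 2.0, 1.0 - dos.mean() / 2.0)
        if maf < maf_floor:
            continue
        vids.append(variant_id(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], build))
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(dos)
    dosages = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return GenotypeMatrix(vids, chroms, np.array(positions, dtype=int), refs, alts, dosages, samples)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-call dosages back out as a minimal VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(geno.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.sample_ids) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for i in range(geno.n_variants):
            calls = [gt_codes[int(round(d))] for d in geno.dosages[i]]
            fh.write(
                f"{geno.chrom[i]}\t{geno.positions[i]}\t{geno.variant_ids[i]}\t"
                f"{geno.ref[i]}\t{geno.alt[i]}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Gene with transcript intervals and strand-derived TSS list (1-based)."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r} for {self.gene_id}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def tss_list(self) -> list[int]:
        # TSS = transcript start on +, transcript end on -
        if self.strand == "+":
            return [s for s, _ in self.transcripts]
        return [e for _, e in self.transcripts]

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.transcripts), max(e for _, e in self.transcripts))

    def overlaps(self, other: "GeneModel") -> bool:
        a, b = self.span, other.span
        return self.chrom == other.chrom and a[0] <= b[1] and b[0] <= a[1]


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a GTF-derived gene table (one row per transcript).

    Columns: gene_id, chrom, strand, transcript_start, transcript_end.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "strand", "transcript_start", "transcript_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid strand values: {df.loc[bad, 'strand'].unique().tolist()}")
    models = []
    for gid, grp in df.groupby("gene_id", sort=False):
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=str(grp["chrom"].iloc[0]),
                strand=grp["strand"].iloc[0],
                transcripts=list(zip(grp["transcript_start"].astype(int), grp["transcript_end"].astype(int))),
            )
        )
    return models


def write_gene_table(models: Sequence[GeneModel], path: str | Path) -> None:
    rows = [
        {"gene_id": m.gene_id, "chrom": m.chrom, "strand": m.strand, "transcript_start": s, "transcript_end": e}
        for m in models
        for s, e in m.transcripts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GWAS summary stats
# ---------------------------------------------------------------------------


@dataclass
class GwasStats:
    trait_id: str
    variant_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    n: int | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if len(self.beta) != len(self.variant_ids) or len(self.se) != len(self.variant_ids):
            raise ValueError("beta/se length mismatch with variant_ids")
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    def subset(self, variant_ids: Sequence[str]) -> "GwasStats":
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        idx = [pos[v] for v in variant_ids]
        return GwasStats(self.trait_id, list(variant_ids), self.beta[idx], self.se[idx], self.n)


def read_gwas_stats(
    path: str | Path,
    cohort_variants: Sequence[str] | None = None,
    trait_id: str | None = None,
) -> GwasStats:
    """Read GWAS summary stats TSV (variant_id + beta/se, or z/n).

    With only z and n, se is reconstructed as 1/sqrt(n) and beta = z*se
    (standardized scale — sufficient for approximate Bayes factors).
    Variants absent from ``cohort_variants`` are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t")
    if "variant_id" not in df.columns:
        raise ValueError("GWAS stats require a variant_id column")
    if trait_id is None:
        trait_id = df["trait_id"].iloc[0] if "trait_id" in df.columns else Path(path).stem
    n = int(df["n"].iloc[0]) if "n" in df.columns else None
    if {"beta", "se"} <= set(df.columns):
        beta = df["beta"].to_numpy(float)
        se = df["se"].to_numpy(float)
    elif {"z", "n"} <= set(df.columns):
        se = 1.0 / np.sqrt(df["n"].to_numpy(float))
        beta = df["z"].to_numpy(float) * se
    else:
        raise ValueError("GWAS stats need beta/se columns or z/n columns")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    vids = df["variant_id"].astype(str).tolist()
    n_dropped = 0
    if cohort_variants is not None:
        known = set(cohort_variants)
        keep = [i for i, v in enumerate(vids) if v in known]
        n_dropped = len(vids) - len(keep)
        if n_dropped:
            log.info("dropped %d GWAS variants absent from cohort", n_dropped)
        vids = [vids[i] for i in keep]
        beta, se = beta[keep], se[keep]
    stats = GwasStats(trait_id, vids, beta, se, n)
    stats.n_dropped = n_dropped
    return stats


def write_gwas_stats(stats: GwasStats, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "trait_id": stats.trait_id,
            "variant_id": stats.variant_ids,
            "beta": stats.beta,
            "se": stats.se,
        }
    )
    if stats.n is not None:
        df["n"] = stats.n
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Covariates + sample intersection
# ---------------------------------------------------------------------------


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Covariates TSV: rows = covariates, columns = samples (GTEx layout)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_covariates(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index_label="ID", float_format="%.10g")


def intersect_samples(*sample_lists: Sequence[str]) -> list[str]:
    """Deterministic, order-stable intersection (order of the first list)."""
    if not sample_lists:
        return []
    common = set(sample_lists[0])
    for sl in sample_lists[1:]:
        common &= set(sl)
    return [s for s in sample_lists[0] if s in common]
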