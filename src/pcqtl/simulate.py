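"""Synthetic cohorts with known ground truth for every pipeline stage.

Genotypes are built from a latent first-order autoregressive Gaussian per
haplotype, thresholded at each variant's allele frequency, which yields
LD-structured diploid dosages. Cluster expression mixes a shared latent
factor, a shared causal-variant effect, private variant effects, and
correlated noise; a positive linear-scale channel is generated through the
allelic fold-change model so effect-size estimators have ground truth.

One global seed governs all draws; per-stage substreams are spawned
deterministically so stages can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    GenotypeMatrix,
    GwasStats,
    variant_id,
    write_covariates,
    write_gene_table,
    write_gwas_stats,
    write_phenotype_bed,
    write_vcf,
)

_STAGE_KEYS = {"genotypes": 11, "expression": 13, "covariates": 17, "gwas": 19, "gwas_geno": 23}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_KEYS[stage]]))


@dataclass
class ClusterSpec:
    n_genes: int = 4
    gene_loadings: list[float] = field(default_factory=list)  # defaults to all 1
    shared_factor_sd: float = 1.0
    shared_effect_size: float = 0.0  # causal-dosage effect on the shared factor, SD units
    private_effect_sizes: list[float] = field(default_factory=list)  # per gene, SD units
    noise_correlation: float = 0.0
    noise_sd: float = 1.0
    # alternating-sign causal effect: weak per gene, concentrated in a
    # contrast PC orthogonal to the shared factor (the novel-pcQTL mechanism)
    contrast_effect_size: float = 0.0
    afc_log2: list[float] = field(default_factory=list)  # per gene, linear channel truth

    def __post_init__(self) -> None:
        if not self.gene_loadings:
            self.gene_loadings = [1.0] * self.n_genes
        if not self.private_effect_sizes:
            self.private_effect_sizes = [0.0] * self.n_genes
        if not self.afc_log2:
            self.afc_log2 = [0.0] * self.n_genes


@dataclass
class GwasSpec:
    shared_causal: bool = True
    gwas_n: int = 5000
    effect_size: float = 0.15  # SD units; 0 = null GWAS
    trait_id: str = "trait1"


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 500
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_decay: float = 0.8
    chrom: str = "chr1"
    region_start: int = 1_000_000  # 1-based position of the first variant
    variant_spacing: int = 1_000
    cluster: ClusterSpec = field(default_factory=ClusterSpec)
    n_covariates: int = 3
    gwas: GwasSpec = field(default_factory=GwasSpec)
    causal_index: int | None = None  # defaults to the middle variant

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_variants <= 0:
            raise ValueError("sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must be in [0, 1)")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


def _haplotypes(rng: np.random.Generator, n_hap: int, p: int, ld: float, maf: np.ndarray) -> np.ndarray:
    z = np.empty((n_hap, p))
    z[:, 0] = rng.standard_normal(n_hap)
    if p > 1:
        eps = rng.standard_normal((n_hap, p - 1)) * np.sqrt(1.0 - ld**2)
        for j in range(1, p):
            z[:, j] = ld * z[:, j - 1] + eps[:, j - 1]
    thresholds = stats.norm.ppf(maf)
    return (z < thresholds[None, :]).astype(float)


def simulate_genotypes(cfg: SimConfig, n_samples: int | None = None, stage: str = "genotypes") -> GenotypeMatrix:
    """LD-structured diploid dosages for ``cfg.n_variants`` SNPs."""
    rng = _rng(cfg.seed, stage)
    n = n_samples if n_samples is not None else cfg.n_samples
    p = cfg.n_variants
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=p)
    haps = _haplotypes(rng, 2 * n, p, cfg.ld_decay, maf)
    dosages = (haps[0::2] + haps[1::2]).T  # variants x samples
    positions = cfg.region_start + cfg.variant_spacing * np.arange(p)
    vids = [variant_id(cfg.chrom, int(pos), "A", "G") for pos in positions]
    samples = [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(vids, [cfg.chrom] * p, positions, ["A"] * p, ["G"] * p, dosages, samples)


def causal_index(cfg: SimConfig) -> int:
    return cfg.causal_index if cfg.causal_index is not None else cfg.n_variants // 2


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def gene_models_for(cfg: SimConfig) -> list[GeneModel]:
    """Synthetic single-transcript gene models spread across the window."""
    n = cfg.cluster.n_genes
    span = cfg.variant_spacing * (cfg.n_variants - 1)
    starts = cfg.region_start + (np.arange(n) + 0.5) / (n + 1) * span
    return [
        GeneModel(
            gene_id=f"gene{i}",
            chrom=cfg.chrom,
            strand="+" if i % 2 == 0 else "-",
            transcripts=[(int(s), int(s) + 5_000)],
        )
        for i, s in enumerate(starts)
    ]


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def simulate_cluster_expression(
    cfg: SimConfig, genotypes: GenotypeMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Normalized and positive linear-scale expression for the cluster genes.

    gene_i = loading_i * (factor + shared_effect * causal dosage)
             + private_effect_i * private dosage_i + correlated noise.
    The linear channel runs each gene's ground-truth aFC through the allelic
    model e = c * (2 - g + g*k)/2 with log-normal noise. Returns (normalized,
    linear, truth registry).
    """
    spec = cfg.cluster
    rng = _rng(cfg.seed, "expression")
    n = genotypes.n_samples
    ci = causal_index(cfg)
    g_causal = _standardize(genotypes.dosages[ci])

    factor = rng.standard_normal(n) * spec.shared_factor_sd + spec.shared_effect_size * g_causal

    # equicorrelated noise across genes
    rho = spec.noise_correlation
    shared_noise = rng.standard_normal(n)
    private_idx = []
    values = np.empty((spec.n_genes, n))
    for i in range(spec.n_genes):
        noise = spec.noise_sd * (np.sqrt(rho) * shared_noise + np.sqrt(1 - rho) * rng.standard_normal(n))
        pi_idx = (ci + 5 * (i + 1)) % cfg.n_variants
        private_idx.append(pi_idx)
        g_priv = _standardize(genotypes.dosages[pi_idx])
        contrast = (1 if i % 2 == 0 else -1) * spec.contrast_effect_size * g_causal
        values[i] = spec.gene_loadings[i] * factor + spec.private_effect_sizes[i] * g_priv + contrast + noise

    models = gene_models_for(cfg)
    anchors = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "start": [m.span[0] - 1 for m in models],
            "end": [m.span[1] for m in models],
        },
        index=pd.Index([m.gene_id for m in models], name="phenotype_id"),
    )
    norm = ExpressionMatrix(anchors, pd.DataFrame(values, index=anchors.index, columns=genotypes.sample_ids))

    # linear channel via the allelic model, ground-truth aFC per gene, tied to
    # the variant that actually drives the gene (private if present, else shared)
    afc_variant_idx = [
        private_idx[i] if spec.private_effect_sizes[i] != 0 else ci for i in range(spec.n_genes)
    ]
    linear = np.empty_like(values)
    for i in range(spec.n_genes):
        g = genotypes.dosages[afc_variant_idx[i]]
        k = 2.0 ** spec.afc_log2[i]
        mean = 100.0 * (2.0 - g + g * k) / 2.0
        linear[i] = mean * 2.0 ** (0.05 * rng.standard_normal(n))
    lin = ExpressionMatrix(anchors.copy(), pd.DataFrame(linear, index=anchors.index, columns=genotypes.sample_ids))

    truth = {
        "causal_variant": genotypes.variant_ids[ci],
        "causal_index": ci,
        "shared_effect_size": spec.shared_effect_size,
        "gene_loadings": list(spec.gene_loadings),
        "private_effect_sizes": list(spec.private_effect_sizes),
        "private_variant_ids": [genotypes.variant_ids[j] for j in private_idx],
        "afc_log2": list(spec.afc_log2),
        "afc_variant_ids": [genotypes.variant_ids[j] for j in afc_variant_idx],
        "gene_ids": [m.gene_id for m in models],
    }
    return norm, lin, truth


def simulate_covariates(cfg: SimConfig, sample_ids: list[str]) -> pd.DataFrame:
    rng = _rng(cfg.seed, "covariates")
    values = rng.standard_normal((cfg.n_covariates, len(sample_ids)))
    return pd.DataFrame(values, index=[f"cov{i}" for i in range(cfg.n_covariates)], columns=sample_ids)


# ---------------------------------------------------------------------------
# GWAS
# ---------------------------------------------------------------------------


def simulate_gwas(
    cfg: SimConfig, genotypes: GenotypeMatrix, causal_variant: str | None = None
) -> GwasStats:
    """Per-variant beta/se from an independent trait cohort with the same LD.

    The causal variant defaults to the expression causal variant when
    ``cfg.gwas.shared_causal`` else to a variant far from it. Effect size 0
    gives a null GWAS.
    """
    rng = _rng(cfg.seed, "gwas")
    gcfg = cfg.gwas
    cohort = simulate_genotypes(cfg, n_samples=gcfg.gwas_n, stage="gwas_geno")
    if causal_variant is None:
        ci = causal_index(cfg) if gcfg.shared_causal else (causal_index(cfg) + cfg.n_variants // 2) % cfg.n_variants
    else:
        ci = genotypes.variant_ids.index(causal_variant)
    y = gcfg.effect_size * _standardize(cohort.dosages[ci]) + rng.standard_normal(gcfg.gwas_n)
    X = cohort.dosages.T
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    beta = Xc.T @ yc / sxx
    dof = gcfg.gwas_n - 2
    rss = (yc @ yc) - beta * (Xc.T @ yc)
    se = np.sqrt(np.clip(rss, 0, None) / dof / sxx)
    stats_out = GwasStats(gcfg.trait_id, list(cohort.variant_ids), beta, se, gcfg.gwas_n)
    stats_out.truth_causal = cohort.variant_ids[ci]  # type: ignore[attr-defined]
    return stats_out


# ---------------------------------------------------------------------------
# Presets & full-cohort emission
# ---------------------------------------------------------------------------


def preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named scenario presets.

    distributed_weak: per-gene effects ~0.15 SD spread over 4 genes — single
    gene scans miss, a cluster PC detects (the novel-pcQTL mechanism).
    strong_single_gene: one gene with a 1 SD private effect.
    null: correlated cluster, no genetic effect.
    uncorrelated: no shared factor and no effects at all.
    """
    if name == "distributed_weak":
        # ~0.15 SD per-gene effects with alternating sign: below single-gene
        # detection at n = 500, but concentrated in a contrast PC
        cluster = ClusterSpec(
            n_genes=4,
            shared_effect_size=0.0,
            contrast_effect_size=0.15,
            gene_loadings=[1.0, 1.0, 1.0, 1.0],
            shared_factor_sd=1.0,
            noise_sd=1.0,
            afc_log2=[0.2, -0.2, 0.2, -0.2],
        )
    elif name == "strong_single_gene":
        cluster = ClusterSpec(
            n_genes=4,
            shared_effect_size=0.0,
            private_effect_sizes=[1.0, 0.0, 0.0, 0.0],
            afc_log2=[1.0, 0.0, 0.0, 0.0],
        )
    elif name == "null":
        cluster = ClusterSpec(n_genes=4, shared_effect_size=0.0)
    elif name == "uncorrelated":
        cluster = ClusterSpec(n_genes=4, shared_factor_sd=0.0, gene_loadings=[0.0] * 4)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return SimConfig(seed=seed, cluster=cluster, **overrides)


def emit_cohort(cfg: SimConfig, outdir: str | Path) -> dict:
    """Write a full synthetic cohort (BED/VCF/TSV/JSON) plus truth registry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno = simulate_genotypes(cfg)
    norm, lin, truth = simulate_cluster_expression(cfg, geno)
    cov = simulate_covariates(cfg, geno.sample_ids)
    gwas = simulate_gwas(cfg, geno)
    models = gene_models_for(cfg)

    write_vcf(geno, outdir / "genotypes.vcf")
    write_phenotype_bed(norm, outdir / "expression.bed")
    write_phenotype_bed(lin, outdir / "expression_linear.bed")
    write_covariates(cov, outdir / "covariates.tsv")
    write_gwas_stats(gwas, outdir / "gwas.tsv")
    write_gene_table(models, outdir / "genes.tsv")

    truth = dict(truth)
    truth["gwas_causal_variant"] = getattr(gwas, "truth_causal", None)
    truth["config"] = asdict(cfg)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return truth
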