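"""Credible-set effect summaries and strand-aware QTL-to-TSS distances."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .finemap import CredibleSet
from .io_formats import GeneModel

NEAR_TSS_BP = 250


def pip_weighted_afc(cs: CredibleSet, log2_afc_by_variant: dict[str, float]) -> float:
    """PIP-weighted mean log2 aFC of the credible set on one gene.

    sum_i PIP_i * log2(aFC_i) / sum_i PIP_i over the set's member variants.
    """
    missing = [v for v in cs.variant_ids if v not in log2_afc_by_variant]
    if missing:
        raise KeyError(f"no nominal aFC for credible-set variants: {missing}")
    pips = np.asarray(cs.pips, float)
    total = pips.sum()
    if total == 0:
        raise ValueError(f"credible set {cs.cs_id} has zero total PIP")
    afcs = np.array([log2_afc_by_variant[v] for v in cs.variant_ids])
    return float(np.sum(pips * afcs) / total)


@dataclass
class CredibleSetEffect:
    cs_id: str
    gene_ids: list[str]
    pip_weighted_log2_afc: np.ndarray  # per gene, signed
    max_abs_afc: float
    cv_abs_afc: float  # nan when undefined (all-zero effects)


def effect_dispersion(abs_afc: np.ndarray) -> tuple[float, float]:
    """(max, coefficient of variation) of per-gene |log2 aFC| values.

    CV uses the sample standard deviation (n-1). An all-zero vector has an
    undefined CV, returned as nan.
    """
    v = np.abs(np.asarray(abs_afc, float))
    if len(v) < 2:
        raise ValueError("effect dispersion needs >= 2 genes")
    max_abs = float(v.max())
    mean = v.mean()
    if mean == 0:
        return max_abs, float("nan")
    return max_abs, float(v.std(ddof=1) / mean)


def summarize_credible_set_effects(
    cs: CredibleSet, per_gene_afc: dict[str, dict[str, float]]
) -> CredibleSetEffect:
    """PIP-weighted effect of one credible set on every cluster gene.

    ``per_gene_afc`` maps gene id -> {variant id -> nominal log2 aFC}.
    """
    genes = list(per_gene_afc)
    effects = np.array([pip_weighted_afc(cs, per_gene_afc[g]) for g in genes])
    max_abs, cv = effect_dispersion(effects)
    return CredibleSetEffect(cs.cs_id, genes, effects, max_abs, cv)


@dataclass
class TssDistance:
    cs_group_id: str
    dist_closest_gene: float  # signed bp of the min-|d| (lead, transcript) pair
    dist_closest_egene: float  # same, restricted to eGenes; nan if none
    near_tss: bool  # |dist_closest_gene| < 250


def _signed_distance(variant_pos: int, tss: int, strand: str) -> int:
    # + strand: variant - TSS; - strand: TSS - variant
    return variant_pos - tss if strand == "+" else tss - variant_pos


def tss_distance(
    lead_positions: list[int],
    genes: list[GeneModel],
    egene_ids: set[str] | None = None,
    group_id: str = "",
    near_bp: int = NEAR_TSS_BP,
) -> TssDistance:
    """Minimum lead-variant-to-TSS distance over all (lead, transcript) pairs.

    Reports the signed value of the minimum-absolute-distance pair, for all
    cluster genes and restricted to eGenes. All transcripts of each gene are
    used.
    """
    if not lead_positions or not genes:
        raise ValueError("need at least one lead variant and one gene")
    egene_ids = egene_ids or set()

    def best(models: list[GeneModel]) -> float:
        dists = [
            _signed_distance(pos, tss, m.strand)
            for m in models
            for tss in m.tss_list
            for pos in lead_positions
        ]
        if not dists:
            return float("nan")
        return float(min(dists, key=abs))

    d_gene = best(genes)
    d_egene = best([m for m in genes if m.gene_id in egene_ids])
    return TssDistance(
        cs_group_id=group_id,
        dist_closest_gene=d_gene,
        dist_closest_egene=d_egene,
        near_tss=abs(d_gene) < near_bp,
    )
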