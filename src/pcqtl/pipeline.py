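"""End-to-end orchestration: simulate/ingest -> clusters -> PCs -> fine-map ->
scan/FDR -> colocalize -> group -> effects.

``run_end_to_end`` keeps everything in memory (the route tests and the
acceptance script use); the file-based stage runner in :mod:`pcqtl.cli`
wraps it and writes the TSV outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster_calling, coloc_grouping, effects_annotation, pc_phenotypes, qtl_stats
from .config import PipelineConfig
from .finemap import CredibleSet, SusieFit, finemap_phenotype
from .io_formats import ExpressionMatrix, GeneModel, GenotypeMatrix, GwasStats
from .preprocess import residualize

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    clusters: list = field(default_factory=list)
    cluster_pcs: dict = field(default_factory=dict)  # cluster_id -> ClusterPCs
    shared_variance: dict = field(default_factory=dict)
    credible_sets: list[CredibleSet] = field(default_factory=list)
    fits: dict[str, SusieFit] = field(default_factory=dict)
    permutation: dict[str, qtl_stats.PermutationResult] = field(default_factory=dict)
    qvalues: dict[str, dict[str, float]] = field(default_factory=dict)  # condition -> pid -> q
    coloc_results: list = field(default_factory=list)
    groups: list = field(default_factory=list)
    novel_flags: dict[str, bool] = field(default_factory=dict)
    gwas_links: list = field(default_factory=list)
    effects: dict[str, effects_annotation.CredibleSetEffect] = field(default_factory=dict)
    distances: dict[str, effects_annotation.TssDistance] = field(default_factory=dict)
    egene_ids: set = field(default_factory=set)

    @property
    def eqtl_sets(self) -> list[CredibleSet]:
        return [cs for cs in self.credible_sets if cs.source == "eQTL"]

    @property
    def pcqtl_sets(self) -> list[CredibleSet]:
        return [cs for cs in self.credible_sets if cs.source == "pcQTL"]


def _window_for(cluster, geno: GenotypeMatrix, window_bp: int) -> GenotypeMatrix:
    start, end = cluster.span
    return geno.subset_region(cluster.chrom, max(start - window_bp, 1), end + window_bp)


def run_end_to_end(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    gene_models: list[GeneModel] | None = None,
    gwas: GwasStats | None = None,
    linear_expr: ExpressionMatrix | None = None,
    config: PipelineConfig | None = None,
    run_permutations: bool = True,
) -> PipelineResult:
    """Run the full workflow on in-memory inputs.

    ``linear_expr`` (positive scale) enables aFC effect summaries; ``gwas``
    enables GWAS colocalization and linking. Sample sets must already agree.
    """
    cfg = config or PipelineConfig()
    res = PipelineResult(cfg)
    model_map = {m.gene_id: m for m in gene_models} if gene_models else {}

    # --- preprocess ---------------------------------------------------------
    if covariates is not None:
        expr = residualize(expr, covariates)

    # --- clusters -----------------------------------------------------------
    for chrom in expr.chroms:
        if len(expr.genes_on(chrom)) < 2:
            continue
        corr = cluster_calling.spearman_matrix(expr, chrom)
        found = cluster_calling.call_clusters(
            corr, chrom, max_size=cfg.max_cluster_size, cluster_prefix=f"{cfg.tissue}_cl"
        )
        for cl in found:
            cl.tissue = cfg.tissue
            cl.correlation_sign_class = cluster_calling.classify_sign(corr, cl)
        if model_map:
            cluster_calling.annotate_spans(found, model_map)
        else:
            for cl in found:
                sub = expr.subset_genes(cl.gene_ids)
                cl.span = (int(sub.anchors["start"].min()) + 1, int(sub.anchors["end"].max()))
        res.clusters.extend(found)
    if not res.clusters:
        log.info("no clusters called; stopping after cluster stage")
        return res

    # --- PCs ----------------------------------------------------------------
    phenotypes: dict[str, np.ndarray] = {}
    pheno_cluster: dict[str, str] = {}
    for cl in res.clusters:
        pcs = pc_phenotypes.cluster_pca(expr, cl)
        res.cluster_pcs[cl.cluster_id] = pcs
        res.shared_variance[cl.cluster_id] = pc_phenotypes.normalized_shared_variance(pcs)
        for k, pid in enumerate(pcs.pc_ids()):
            phenotypes[pid] = pcs.scores[:, k]
            pheno_cluster[pid] = cl.cluster_id
        for g in cl.gene_ids:
            phenotypes[g] = expr.values.loc[g].to_numpy(float)
            pheno_cluster[g] = cl.cluster_id

    # --- fine-mapping -------------------------------------------------------
    windows: dict[str, GenotypeMatrix] = {
        cl.cluster_id: _window_for(cl, geno, cfg.window_bp) for cl in res.clusters
    }
    for pid, y in phenotypes.items():
        win = windows[pheno_cluster[pid]]
        if win.n_variants == 0:
            continue
        fit, sets = finemap_phenotype(
            y,
            win.dosages.T,
            win.variant_ids,
            pid,
            L=cfg.susie_L,
            coverage=cfg.coverage,
            min_abs_corr=cfg.purity,
        )
        res.fits[pid] = fit
        res.credible_sets.extend(sets)

    # --- permutation FDR ----------------------------------------------------
    if run_permutations:
        for pid, y in phenotypes.items():
            win = windows[pheno_cluster[pid]]
            if win.n_variants == 0:
                continue
            res.permutation[pid] = qtl_stats.permutation_pass(
                y, win.dosages.T, B=cfg.n_permutations, seed=cfg.seed, phenotype_id=pid,
                variant_ids=win.variant_ids,
            )
        conditions = {
            "eqtl": [p for p in res.permutation if ":PC" not in p],
            "pcqtl": [p for p in res.permutation if ":PC" in p],
            "joint": list(res.permutation),
        }
        for cond, pids in conditions.items():
            if not pids:
                continue
            ps = np.array([res.permutation[p].empirical_p_beta for p in pids])
            qs = qtl_stats.qvalues(ps)
            res.qvalues[cond] = dict(zip(pids, qs))
            for p, q in zip(pids, qs):
                if cond == "joint":
                    res.permutation[p].q_value = q

    # --- colocalization & grouping -----------------------------------------
    by_cluster: dict[str, list[CredibleSet]] = {}
    for cs in res.credible_sets:
        by_cluster.setdefault(pheno_cluster[cs.phenotype_id], []).append(cs)

    gwas_rows = []
    for cid, sets in by_cluster.items():
        win = windows[cid]
        signals = [
            coloc_grouping.SignalBF(cs.cs_id, cs.source, win.variant_ids, cs.lbf_variable)
            for cs in sets
        ]
        for i in range(len(signals)):
            for j in range(i + 1, len(signals)):
                res.coloc_results.append(
                    coloc_grouping.coloc_pair(
                        signals[i], signals[j], cfg.coloc_p1, cfg.coloc_p2, cfg.coloc_p12
                    )
                )
        if gwas is not None and signals:
            gwas_common = [v for v in gwas.variant_ids if v in set(win.variant_ids)]
            if gwas_common:
                gbf = coloc_grouping.wakefield_abf(gwas.subset(gwas_common), cfg.gwas_prior_sd)
                lead = gwas_common[int(np.argmax(gbf.lbf))]
                for sig in signals:
                    cres = coloc_grouping.coloc_pair(gbf, sig, cfg.coloc_p1, cfg.coloc_p2, cfg.coloc_p12)
                    res.coloc_results.append(cres)
                    gwas_rows.append((lead, gwas.trait_id, cfg.tissue, sig.source, cres.pp_h4))

    sources = {cs.cs_id: cs.source for cs in res.credible_sets}
    res.groups = coloc_grouping.build_groups(sources, res.coloc_results, cfg.coloc_threshold)
    res.novel_flags = coloc_grouping.classify_novel_pcqtls(res.groups)
    if gwas_rows:
        res.gwas_links = coloc_grouping.link_gwas(gwas_rows, cfg.coloc_threshold)

    # --- effects & distances ------------------------------------------------
    cs_by_id = {cs.cs_id: cs for cs in res.credible_sets}
    res.egene_ids = {cs.phenotype_id for cs in res.eqtl_sets}
    if linear_expr is not None:
        afc_cache: dict[tuple[str, str], dict[str, float]] = {}
        for cid, sets in by_cluster.items():
            win = windows[cid]
            cl = next(c for c in res.clusters if c.cluster_id == cid)
            per_gene: dict[str, dict[str, float]] = {}
            for g in cl.gene_ids:
                key = (cid, g)
                if key not in afc_cache:
                    y_lin = linear_expr.values.loc[g].to_numpy(float)
                    afcs = qtl_stats.nominal_afc_scan(y_lin, win.dosages.T)
                    afc_cache[key] = dict(zip(win.variant_ids, afcs))
                per_gene[g] = afc_cache[key]
            for cs in sets:
                if len(per_gene) >= 2:
                    res.effects[cs.cs_id] = effects_annotation.summarize_credible_set_effects(cs, per_gene)

    if gene_models:
        pos_by_vid = dict(zip(geno.variant_ids, geno.positions))
        for grp in res.groups:
            members = [cs_by_id[s] for s in grp.member_signal_ids]
            cid = pheno_cluster[members[0].phenotype_id]
            cl = next(c for c in res.clusters if c.cluster_id == cid)
            leads = [int(pos_by_vid[cs.lead_variant]) for cs in members if cs.lead_variant in pos_by_vid]
            models = [model_map[g] for g in cl.gene_ids if g in model_map]
            grp.egene_ids = sorted(
                {cs.phenotype_id for cs in members if cs.source == "eQTL"}
            )
            if leads and models:
                res.distances[grp.group_id] = effects_annotation.tss_distance(
                    leads, models, set(grp.egene_ids), grp.group_id, cfg.near_tss_bp
                )

    return res
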