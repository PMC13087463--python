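"""Structural/functional cluster annotations and enrichment statistics.

Nine cluster labels are assigned from generic annotation tables; enrichment
of real vs. null clusters is a covariate-adjusted logistic regression
(label as dependent variable proxy via cluster status, adjusting for gene
count and log cluster length), skipped when any expected contingency cell is
below 5. Credible sets additionally get PIP-weighted variant-annotation
probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster_calling import GeneCluster
from .finemap import CredibleSet
from .io_formats import GeneModel

log = logging.getLogger(__name__)

PROMOTER_WINDOW_BP = 1000
ENHANCER_SCORE_FLOOR = 0.1
MIN_EXPECTED_CELL = 5.0

CATEGORIES = [
    "bidirectional_promoter",
    "same_strand_promoter",
    "overlap_opposite",
    "overlap_same",
    "shared_enhancer",
    "paralogs",
    "shared_go_bp",
    "cross_ctcf",
    "cross_tad",
]


@dataclass
class AnnotationResources:
    """Generic annotation tables consumed by :func:`annotate_cluster`.

    enhancer_links: columns gene_id, element_id, score, element_class
    paralog_pairs: columns gene_a, gene_b
    go_terms: columns gene_id, term
    ctcf_peaks / tad_boundaries: columns chrom, start, end (1-based inclusive)
    """

    enhancer_links: pd.DataFrame | None = None
    paralog_pairs: pd.DataFrame | None = None
    go_terms: pd.DataFrame | None = None
    ctcf_peaks: pd.DataFrame | None = None
    tad_boundaries: pd.DataFrame | None = None


@dataclass
class ClusterAnnotation:
    cluster_id: str
    is_null: bool
    labels: dict[str, bool | None]  # None = resource missing
    n_genes: int
    log_length: float


def _share_promoter(a: GeneModel, b: GeneModel) -> bool:
    return any(abs(ta - tb) <= PROMOTER_WINDOW_BP for ta in a.tss_list for tb in b.tss_list)


def annotate_cluster(
    cluster: GeneCluster,
    gene_models: dict[str, GeneModel],
    resources: AnnotationResources,
) -> ClusterAnnotation:
    """Assign the nine boolean labels to one cluster.

    Promoter sharing tests every transcript 5' end pair at <= 1000 bp with the
    strand condition; overlap labels exclude promoter-sharing pairs; shared
    enhancers need a common genic/intergenic element with score > 0.1;
    cross_ctcf / cross_tad test interval containment in the cluster span.
    Labels whose resource is missing are None, never 0.
    """
    models = [gene_models[g] for g in cluster.gene_ids]
    pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1 :]]

    labels: dict[str, bool | None] = {}
    labels["bidirectional_promoter"] = any(
        a.strand != b.strand and _share_promoter(a, b) for a, b in pairs
    )
    labels["same_strand_promoter"] = any(
        a.strand == b.strand and _share_promoter(a, b) for a, b in pairs
    )
    labels["overlap_opposite"] = any(
        a.strand != b.strand and a.overlaps(b) and not _share_promoter(a, b) for a, b in pairs
    )
    labels["overlap_same"] = any(
        a.strand == b.strand and a.overlaps(b) and not _share_promoter(a, b) for a, b in pairs
    )

    enh = resources.enhancer_links
    if enh is None:
        labels["shared_enhancer"] = None
    else:
        ok = enh[(enh["score"] > ENHANCER_SCORE_FLOOR) & enh["element_class"].isin(["genic", "intergenic"])]
        by_gene = ok.groupby("gene_id")["element_id"].agg(set).to_dict()
        labels["shared_enhancer"] = any(
            bool(by_gene.get(a.gene_id, set()) & by_gene.get(b.gene_id, set())) for a, b in pairs
        )

    par = resources.paralog_pairs
    if par is None:
        labels["paralogs"] = None
    else:
        pset = {frozenset(t) for t in zip(par["gene_a"], par["gene_b"])}
        labels["paralogs"] = any(frozenset((a.gene_id, b.gene_id)) in pset for a, b in pairs)

    go = resources.go_terms
    if go is None:
        labels["shared_go_bp"] = None
    else:
        terms = go.groupby("gene_id")["term"].agg(set).to_dict()
        labels["shared_go_bp"] = any(
            bool(terms.get(a.gene_id, set()) & terms.get(b.gene_id, set())) for a, b in pairs
        )

    span = (min(m.span[0] for m in models), max(m.span[1] for m in models))
    for key, table in (("cross_ctcf", resources.ctcf_peaks), ("cross_tad", resources.tad_boundaries)):
        if table is None:
            labels[key] = None
        else:
            on_chrom = table[table["chrom"].astype(str) == cluster.chrom]
            labels[key] = bool(
                ((on_chrom["start"] >= span[0]) & (on_chrom["end"] <= span[1])).any()
            )

    length = max(span[1] - span[0], 1)
    return ClusterAnnotation(
        cluster_id=cluster.cluster_id,
        is_null=cluster.is_null,
        labels=labels,
        n_genes=cluster.n,
        log_length=float(np.log(length)),
    )


@dataclass
class EnrichmentResult:
    category: str
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p: float
    skipped: bool = False
    skip_reason: str = ""
    separation: bool = False


def _expected_cells(labels: np.ndarray, is_real: np.ndarray) -> np.ndarray:
    """Marginal-product expected counts of the 2x2 label x real/null table."""
    n = len(labels)
    row = np.array([np.sum(labels == 0), np.sum(labels == 1)])
    col = np.array([np.sum(is_real == 0), np.sum(is_real == 1)])
    return np.outer(row, col) / n


def logistic_enrichment(
    annotations: list[ClusterAnnotation], category: str
) -> EnrichmentResult:
    """Enrichment odds ratio of a label in real vs. null clusters.

    Logistic regression of cluster status on the label with gene count and
    log cluster length as covariates; the reported OR is exp(label coef)
    with a Wald 95% CI. Skipped when any expected 2x2 cell is < 5.
    """
    import statsmodels.api as sm

    usable = [a for a in annotations if a.labels.get(category) is not None]
    if not any(a.is_null for a in usable) or not any(not a.is_null for a in usable):
        return EnrichmentResult(category, np.nan, np.nan, np.nan, np.nan, True, "need real and null clusters")
    labels = np.array([int(a.labels[category]) for a in usable])
    is_real = np.array([int(not a.is_null) for a in usable])
    expected = _expected_cells(labels, is_real)
    if expected.min() < MIN_EXPECTED_CELL:
        return EnrichmentResult(
            category, np.nan, np.nan, np.nan, np.nan, True,
            f"expected cell {expected.min():.1f} < {MIN_EXPECTED_CELL:g}",
        )
    covs = np.column_stack([[a.n_genes for a in usable], [a.log_length for a in usable]]).astype(float)
    covs = covs[:, covs.std(axis=0) > 0]  # constant covariates are collinear with the intercept
    X = np.column_stack([np.ones(len(usable)), labels, covs])
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(is_real, X).fit(disp=0, maxiter=200)
        coef = fit.params[1]
        se = fit.bse[1]
        p = fit.pvalues[1]
        separation = not np.isfinite(se) or se > 50
    except Exception as exc:  # perfect separation and kin
        log.warning("logistic fit failed for %s: %s", category, exc)
        return EnrichmentResult(category, np.nan, 0.0, np.inf, np.nan, False, "", True)
    if separation:
        return EnrichmentResult(category, float(np.exp(coef)), 0.0, np.inf, np.nan, False, "", True)
    return EnrichmentResult(
        category,
        float(np.exp(coef)),
        float(np.exp(coef - 1.959963984540054 * se)),
        float(np.exp(coef + 1.959963984540054 * se)),
        float(p),
        False,
    )


def enrichment_table(annotations: list[ClusterAnnotation]) -> pd.DataFrame:
    rows = []
    for cat in CATEGORIES:
        r = logistic_enrichment(annotations, cat)
        rows.append(
            {
                "category": r.category,
                "odds_ratio": r.odds_ratio,
                "ci95_low": r.ci95_low,
                "ci95_high": r.ci95_high,
                "p": r.p,
                "skipped": r.skipped,
                "skip_reason": r.skip_reason,
            }
        )
    return pd.DataFrame(rows)


def pip_weighted_annotation(
    cs: CredibleSet,
    variant_annotations: pd.DataFrame,
    normalize: bool = True,
) -> pd.Series:
    """PIP-weighted annotation probability per boolean annotation column.

    ``variant_annotations`` is indexed by variant id with 0/1 columns. With
    ``normalize`` (default) the weighted sum is divided by the total PIP so
    values lie in [0, 1] even for 95% credible sets.
    """
    missing = [v for v in cs.variant_ids if v not in variant_annotations.index]
    if missing:
        raise KeyError(f"variants missing annotation rows: {missing}")
    sub = variant_annotations.loc[cs.variant_ids].astype(float)
    pips = np.asarray(cs.pips, float)
    weighted = sub.mul(pips, axis=0).sum(axis=0)
    if normalize:
        weighted = weighted / pips.sum()
    return weighted
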