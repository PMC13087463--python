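"""Sliding-window detection of neighboring co-expressed gene clusters.

Per chromosome, Spearman correlations between all gene pairs are tested at a
Bonferroni threshold of 0.05 / C(N, 2). Windows of size n = 50 down to 2 are
scanned left to right; a window becomes a cluster when at least 70% of its
pairs are significantly correlated (0.7 * C(n, 2) <= m) and none of its genes
is already clustered, so every gene ends up in the largest cluster available
at its location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

MAX_CLUSTER_SIZE = 50
MIN_CLUSTER_SIZE = 2
ACCEPT_FRACTION = 0.7
CORR_ALPHA = 0.05


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman evidence for the genes of one chromosome."""

    gene_ids: list[str]  # chromosome order
    rho: np.ndarray
    pvals: np.ndarray
    sig: np.ndarray  # boolean, post-Bonferroni

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)


@dataclass
class GeneCluster:
    cluster_id: str
    gene_ids: list[str]  # ordered, contiguous in chromosome order
    chrom: str
    m: int  # significant within-cluster pairs
    span: tuple[int, int] = (0, 0)
    correlation_sign_class: str = ""
    is_null: bool = False
    flagged_crossmap: bool = False
    tissue: str = ""

    @property
    def n(self) -> int:
        return len(self.gene_ids)


def spearman_matrix(expr: ExpressionMatrix, chrom: str) -> CorrelationMatrix:
    """Spearman correlation matrix for all genes on one chromosome.

    Significance uses Bonferroni over all C(N, 2) pairs on the chromosome.
    Constant gene vectors yield undefined rho and never count as significant.
    """
    genes = expr.genes_on(chrom)
    if len(genes) < 2:
        raise ValueError(f"need >= 2 genes on {chrom}, found {len(genes)}")
    sub = expr.subset_genes(genes)
    mat = sub.values.to_numpy(float)
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation testing")
    N = len(genes)
    constant = mat.std(axis=1) == 0
    if constant.any():
        log.warning("constant expression vectors on %s: %s", chrom, [genes[i] for i in np.where(constant)[0]])
    rho = np.full((N, N), np.nan)
    pvals = np.full((N, N), np.nan)
    ok = np.where(~constant)[0]
    if len(ok) >= 2:  # spearmanr refuses constant inputs; run on the rest
        r, p = stats.spearmanr(mat[ok], axis=1)
        if len(ok) == 2:  # scalar return for 2 variables
            r = np.array([[1.0, r], [r, 1.0]])
            p = np.array([[0.0, p], [p, 0.0]])
        rho[np.ix_(ok, ok)] = r
        pvals[np.ix_(ok, ok)] = p
    np.fill_diagonal(pvals, 0.0)
    np.fill_diagonal(rho, 1.0)
    threshold = CORR_ALPHA / comb(N, 2)
    with np.errstate(invalid="ignore"):
        sig = pvals < threshold
    sig &= ~np.isnan(rho)
    sig[constant, :] = False
    sig[:, constant] = False
    np.fill_diagonal(sig, False)
    return CorrelationMatrix(genes, rho, pvals, sig)


def window_accept(sig_submatrix: np.ndarray) -> bool:
    """Accept a candidate window iff 0.7 * C(n, 2) <= m significant pairs."""
    n = sig_submatrix.shape[0]
    iu = np.triu_indices(n, k=1)
    m = int(sig_submatrix[iu].sum())
    return ACCEPT_FRACTION * comb(n, 2) <= m


def call_clusters(
    corr: CorrelationMatrix,
    chrom: str = "",
    max_size: int = MAX_CLUSTER_SIZE,
    min_size: int = MIN_CLUSTER_SIZE,
    cluster_prefix: str = "cluster",
) -> list[GeneCluster]:
    """Scan windows from ``max_size`` down to ``min_size``, left to right.

    A window is recorded iff it passes :func:`window_accept` and none of its
    genes already belongs to a cluster, so each recorded cluster is the
    largest accepted window at its location and clusters are disjoint.
    """
    N = corr.n_genes
    clustered = np.zeros(N, dtype=bool)
    clusters: list[GeneCluster] = []
    for n in range(min(max_size, N), min_size - 1, -1):
        for start in range(0, N - n + 1):
            idx = np.arange(start, start + n)
            if clustered[idx].any():
                continue
            sub = corr.sig[np.ix_(idx, idx)]
            if window_accept(sub):
                iu = np.triu_indices(n, k=1)
                m = int(sub[iu].sum())
                genes = [corr.gene_ids[i] for i in idx]
                cid = f"{cluster_prefix}_{chrom}_{len(clusters)}" if chrom else f"{cluster_prefix}_{len(clusters)}"
                clusters.append(GeneCluster(cid, genes, chrom, m))
                clustered[idx] = True
    return clusters


def classify_sign(corr: CorrelationMatrix, cluster: GeneCluster) -> str:
    """Sign class from significant within-cluster correlations only."""
    idx = [corr.index_of(g) for g in cluster.gene_ids]
    signs = []
    for i, a in enumerate(idx):
        for b in idx[i + 1 :]:
            if corr.sig[a, b]:
                signs.append(np.sign(corr.rho[a, b]))
    if not signs:
        return "none"
    if all(s > 0 for s in signs):
        return "all-positive"
    if all(s < 0 for s in signs):
        return "all-negative"
    return "mixed"


def annotate_spans(
    clusters: Sequence[GeneCluster], gene_models: dict[str, "object"]
) -> None:
    """Fill each cluster's span from member gene transcript extents (in place)."""
    for cl in clusters:
        models = [gene_models[g] for g in cl.gene_ids if g in gene_models]
        if models:
            cl.span = (min(m.span[0] for m in models), max(m.span[1] for m in models))


def flag_crossmappable(clusters: Sequence[GeneCluster], blacklist: set[str]) -> None:
    """Flag (never remove) clusters containing cross-mappable genes."""
    for cl in clusters:
        cl.flagged_crossmap = any(g in blacklist for g in cl.gene_ids)


def sample_null_clusters(
    expr: ExpressionMatrix,
    clusters: Sequence[GeneCluster],
    seed: int,
    n_nulls: int | None = None,
    max_null_size: int = 5,
) -> list[GeneCluster]:
    """Sample windows of 2-5 unclustered neighboring genes as null clusters.

    The null size distribution matches the relative size distribution of the
    real clusters (sizes capped at ``max_null_size``). Candidate windows must
    contain no clustered gene. Reproducible under ``seed``; if fewer
    candidates than requested exist at some size, all are returned with a
    warning.
    """
    rng = np.random.default_rng(seed)
    clustered_genes = {g for cl in clusters for g in cl.gene_ids}
    real_sizes = [cl.n for cl in clusters if 2 <= cl.n <= max_null_size]
    if not real_sizes:
        return []
    if n_nulls is None:
        n_nulls = len(real_sizes)
    sizes, counts = np.unique(real_sizes, return_counts=True)
    probs = counts / counts.sum()
    wanted = rng.multinomial(n_nulls, probs)
    nulls: list[GeneCluster] = []
    for size, want in zip(sizes, wanted):
        if want == 0:
            continue
        candidates: list[tuple[str, list[str]]] = []
        for chrom in expr.chroms:
            genes = expr.genes_on(chrom)
            for start in range(0, len(genes) - size + 1):
                window = genes[start : start + size]
                if not any(g in clustered_genes for g in window):
                    candidates.append((chrom, window))
        if len(candidates) < want:
            log.warning("only %d null candidates of size %d (wanted %d)", len(candidates), size, want)
            chosen = list(range(len(candidates)))
        else:
            chosen = rng.choice(len(candidates), size=want, replace=False).tolist()
        for k, ci in enumerate(chosen):
            chrom, window = candidates[ci]
            nulls.append(
                GeneCluster(f"null_{chrom}_{size}_{k}", window, chrom, m=0, is_null=True)
            )
    return nulls


def clusters_to_frame(clusters: Sequence[GeneCluster]):
    import pandas as pd

    return pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "chrom": [c.chrom for c in clusters],
            "genes": [",".join(c.gene_ids) for c in clusters],
            "n": [c.n for c in clusters],
            "m": [c.m for c in clusters],
            "span_start": [c.span[0] for c in clusters],
            "span_end": [c.span[1] for c in clusters],
            "sign_class": [c.correlation_sign_class for c in clusters],
            "is_null": [c.is_null for c in clusters],
            "flagged_crossmap": [c.flagged_crossmap for c in clusters],
        }
    )
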