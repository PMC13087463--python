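"""Per-cluster principal-component phenotypes and normalized shared variance.

PCA is run on per-gene standardized expression, i.e. on the gene-gene
correlation matrix, so that squared correlation-scale loadings of PC1 equal
the per-gene variance explained and the shared-variance statistic hits its
0%/100% endpoints exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_calling import GeneCluster
from .io_formats import ExpressionMatrix


@dataclass
class ClusterPCs:
    """PCA of one cluster's standardized expression.

    ``loadings[i, k]`` is the correlation-scale loading of PC(k+1) on gene i:
    eigenvector element times sqrt(eigenvalue) of the gene-gene correlation
    matrix, so the squared loadings of PC k sum to eigenvalue k over genes.
    """

    cluster_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    scores: np.ndarray  # samples x n PCs
    loadings: np.ndarray  # n genes x n PCs, correlation scale
    eigenvalues: np.ndarray  # length n, descending
    var_explained: np.ndarray  # eigenvalue fractions

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def pc_ids(self) -> list[str]:
        return [f"{self.cluster_id}:PC{k + 1}" for k in range(self.n)]


def cluster_pca(expr: ExpressionMatrix, cluster: GeneCluster) -> ClusterPCs:
    """Eigendecompose the cluster's gene-gene correlation matrix.

    All n PCs are returned as phenotypes. PC signs are fixed so the gene with
    the largest |loading| on each PC has a positive loading.
    """
    sub = expr.subset_genes(cluster.gene_ids)
    Z = sub.values.to_numpy(float)  # genes x samples
    n, s = Z.shape
    if n < 2:
        raise ValueError("cluster PCA needs >= 2 genes")
    if s < n:
        raise ValueError(f"need at least n={n} samples, got {s}")
    sd = Z.std(axis=1, ddof=1)
    if np.any(sd == 0):
        zero = [cluster.gene_ids[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance genes in cluster {cluster.cluster_id}: {zero}")
    Zs = (Z - Z.mean(axis=1, keepdims=True)) / sd[:, None]
    C = np.corrcoef(Z)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: max-|loading| gene positive
    for k in range(n):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    loadings = evecs * np.sqrt(evals)[None, :]
    scores = Zs.T @ evecs  # samples x PCs
    return ClusterPCs(
        cluster_id=cluster.cluster_id,
        gene_ids=list(cluster.gene_ids),
        sample_ids=sub.sample_ids,
        scores=scores,
        loadings=loadings,
        eigenvalues=evals,
        var_explained=evals / evals.sum(),
    )


def normalized_shared_variance(pcs: ClusterPCs) -> float:
    """Shared-variance percentage of PC1: (sum_i l_i^2 - 1) / (n - 1) * 100.

    100 for a perfectly correlated cluster, 0 for uncorrelated genes.
    """
    if pcs.n < 2:
        raise ValueError("shared variance needs >= 2 genes")
    sum_sq = float(np.sum(pcs.loadings[:, 0] ** 2))  # == eigenvalue 1
    return (sum_sq - 1.0) / (pcs.n - 1.0) * 100.0


def pcs_to_expression(pcs: ClusterPCs, cluster: GeneCluster) -> ExpressionMatrix:
    """Emit PC phenotypes in the phenotype BED dialect.

    Each PC is anchored at the cluster span (BED half-open), with phenotype id
    ``cluster_id:PCk``.
    """
    ids = pcs.pc_ids()
    start, end = cluster.span
    anchors = pd.DataFrame(
        {"chrom": cluster.chrom, "start": max(start - 1, 0), "end": end},
        index=pd.Index(ids, name="phenotype_id"),
    )
    values = pd.DataFrame(pcs.scores.T, index=anchors.index, columns=pcs.sample_ids)
    return ExpressionMatrix(anchors, values)
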