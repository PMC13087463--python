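from math import comb

import numpy as np
import pytest
from scipy import stats

from pcqtl import cluster_calling as cc

from conftest import make_expression


def sig_corr(gene_ids, sig_pairs, rho_vals=None):
    """Build a CorrelationMatrix directly from a set of significant pairs."""
    n = len(gene_ids)
    sig = np.zeros((n, n), dtype=bool)
    rho = np.eye(n)
    for (i, j) in sig_pairs:
        sig[i, j] = sig[j, i] = True
        r = 0.9 if rho_vals is None else rho_vals[(i, j)]
        rho[i, j] = rho[j, i] = r
    return cc.CorrelationMatrix(list(gene_ids), rho, np.where(sig, 0.0, 1.0), sig)


# ---------------------------------------------------------------------------
# spearman_matrix
# ---------------------------------------------------------------------------


def test_monotone_transform_gives_rho_one(rng):
    x = rng.standard_normal(30)
    expr = make_expression(np.vstack([x, np.exp(x)]))
    corr = cc.spearman_matrix(expr, "chr1")
    assert corr.rho[0, 1] == pytest.approx(1.0)
    assert corr.sig[0, 1]


def test_negated_gene_gives_rho_minus_one(rng):
    x = rng.standard_normal(30)
    expr = make_expression(np.vstack([x, -x]))
    corr = cc.spearman_matrix(expr, "chr1")
    assert corr.rho[0, 1] == pytest.approx(-1.0)


def test_spearman_matches_rank_then_pearson_oracle(rng):
    vals = rng.integers(0, 5, size=(6, 30)).astype(float)  # heavy ties
    expr = make_expression(vals)
    corr = cc.spearman_matrix(expr, "chr1")
    ranks = np.vstack([stats.rankdata(row) for row in vals])
    oracle = np.corrcoef(ranks)
    np.testing.assert_allclose(corr.rho, oracle, atol=1e-12)


def test_bonferroni_divisor_counts_chromosome_pairs(rng):
    n = 6
    expr = make_expression(rng.standard_normal((n, 25)))
    corr = cc.spearman_matrix(expr, "chr1")
    threshold = 0.05 / comb(n, 2)
    expected = (corr.pvals < threshold) & ~np.eye(n, dtype=bool)
    np.testing.assert_array_equal(corr.sig, expected)


def test_constant_gene_never_significant(rng):
    vals = rng.standard_normal((3, 20))
    vals[1] = 2.5
    expr = make_expression(vals)
    corr = cc.spearman_matrix(expr, "chr1")
    assert not corr.sig[1].any() and not corr.sig[:, 1].any()


# ---------------------------------------------------------------------------
# window_accept: direct arithmetic on the acceptance rule
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n,n_sig,expected",
    [
        (3, 3, True),   # 0.7*3 = 2.1 <= 3
        (4, 4, False),  # 0.7*6 = 4.2 > 4
        (2, 1, True),   # 0.7*1 = 0.7 <= 1
        (4, 5, True),   # 0.7*6 = 4.2 <= 5
        (3, 2, False),  # 0.7*3 = 2.1 > 2
    ],
)
def test_window_accept_rule(n, n_sig, expected):
    sig = np.zeros((n, n), dtype=bool)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)][:n_sig]
    for i, j in pairs:
        sig[i, j] = sig[j, i] = True
    assert cc.window_accept(sig) is expected


# ---------------------------------------------------------------------------
# call_clusters
# ---------------------------------------------------------------------------


def test_three_gene_cluster_called_and_rest_unclustered():
    corr = sig_corr([f"g{i}" for i in range(5)], [(0, 1), (0, 2), (1, 2)])
    clusters = cc.call_clusters(corr, "chr1")
    assert len(clusters) == 1
    assert clusters[0].gene_ids == ["g0", "g1", "g2"]
    assert clusters[0].m == 3


def test_full_four_gene_cluster_absorbs_subwindows():
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    corr = sig_corr([f"g{i}" for i in range(4)], pairs)
    clusters = cc.call_clusters(corr, "chr1")
    assert len(clusters) == 1
    assert clusters[0].n == 4


def test_no_significant_pairs_empty_result():
    corr = sig_corr(["g0", "g1", "g2"], [])
    assert cc.call_clusters(corr, "chr1") == []


def brute_force_clusters(sig, max_size=50):
    """Independent oracle: enumerate every window, then select greedily by
    (size desc, start asc), keeping windows disjoint from earlier picks."""
    N = sig.shape[0]
    windows = []
    for n in range(2, min(max_size, N) + 1):
        for start in range(N - n + 1):
            idx = list(range(start, start + n))
            m = sum(sig[i, j] for i in idx for j in idx if i < j)
            if 0.7 * comb(n, 2) <= m:
                windows.append((n, start))
    windows.sort(key=lambda w: (-w[0], w[1]))
    taken = set()
    chosen = []
    for n, start in windows:
        members = set(range(start, start + n))
        if not (members & taken):
            chosen.append(tuple(range(start, start + n)))
            taken |= members
    return sorted(chosen)


@pytest.mark.parametrize("n_genes", [2, 3, 4, 5, 6, 7, 8])
def test_equivalence_with_bruteforce_enumeration(n_genes, rng):
    local = np.random.default_rng(n_genes * 101)
    for _ in range(60):
        upper = local.random((n_genes, n_genes)) < 0.4
        sig = np.triu(upper, 1)
        sig = sig | sig.T
        corr = sig_corr([f"g{i}" for i in range(n_genes)],
                        [(i, j) for i in range(n_genes) for j in range(i + 1, n_genes) if sig[i, j]])
        got = sorted(tuple(corr.index_of(g) for g in cl.gene_ids) for cl in cc.call_clusters(corr, "c"))
        assert got == brute_force_clusters(sig)


def test_clusters_partition_genes_uniquely(rng):
    n = 12
    local = np.random.default_rng(5)
    sig = np.triu(local.random((n, n)) < 0.5, 1)
    sig = sig | sig.T
    corr = sig_corr([f"g{i}" for i in range(n)],
                    [(i, j) for i in range(n) for j in range(i + 1, n) if sig[i, j]])
    clusters = cc.call_clusters(corr, "c")
    seen = [g for cl in clusters for g in cl.gene_ids]
    assert len(seen) == len(set(seen))


def test_permuted_samples_yield_no_clusters(rng):
    # destroy correlation per gene; Bonferroni should leave ~0 clusters
    vals = rng.standard_normal((10, 60))
    for row in vals:
        rng.shuffle(row)
    expr = make_expression(vals)
    corr = cc.spearman_matrix(expr, "chr1")
    assert len(cc.call_clusters(corr, "chr1")) == 0


# ---------------------------------------------------------------------------
# sign classification
# ---------------------------------------------------------------------------


def test_sign_all_positive():
    corr = sig_corr(["a", "b", "c"], [(0, 1), (1, 2)], {(0, 1): 0.8, (1, 2): 0.7})
    cl = cc.GeneCluster("x", ["a", "b", "c"], "c", 2)
    assert cc.classify_sign(corr, cl) == "all-positive"


def test_sign_mixed():
    corr = sig_corr(["a", "b", "c"], [(0, 1), (1, 2)], {(0, 1): 0.8, (1, 2): -0.7})
    cl = cc.GeneCluster("x", ["a", "b", "c"], "c", 2)
    assert cc.classify_sign(corr, cl) == "mixed"


def test_sign_all_negative_pair():
    corr = sig_corr(["a", "b"], [(0, 1)], {(0, 1): -0.6})
    cl = cc.GeneCluster("x", ["a", "b"], "c", 1)
    assert cc.classify_sign(corr, cl) == "all-negative"


# ---------------------------------------------------------------------------
# null cluster sampling
# ---------------------------------------------------------------------------


def test_null_sizes_match_real_distribution_pairs_only(rng):
    expr = make_expression(rng.standard_normal((30, 20)))
    clusters = [cc.GeneCluster(f"c{i}", [f"g{2*i}", f"g{2*i+1}"], "chr1", 1) for i in range(3)]
    nulls = cc.sample_null_clusters(expr, clusters, seed=1)
    assert nulls and all(nl.n == 2 for nl in nulls)
    assert all(nl.is_null for nl in nulls)


def test_null_sampling_reproducible(rng):
    expr = make_expression(rng.standard_normal((40, 20)))
    clusters = [cc.GeneCluster("c0", ["g0", "g1"], "chr1", 1),
                cc.GeneCluster("c1", ["g5", "g6", "g7"], "chr1", 3)]
    a = cc.sample_null_clusters(expr, clusters, seed=7)
    b = cc.sample_null_clusters(expr, clusters, seed=7)
    assert [n.gene_ids for n in a] == [n.gene_ids for n in b]


def test_null_candidates_avoid_clustered_genes(rng):
    expr = make_expression(rng.standard_normal((20, 20)))
    clusters = [cc.GeneCluster("c0", ["g5", "g6"], "chr1", 1)]
    nulls = cc.sample_null_clusters(expr, clusters, seed=3, n_nulls=50)
    for nl in nulls:
        assert "g5" not in nl.gene_ids and "g6" not in nl.gene_ids


def test_null_size_shares_within_sampling_error(rng):
    # 100 real clusters at (90%, 7%, 3%) sizes 2/3/4
    expr = make_expression(rng.standard_normal((400, 10)), spacing=1000)
    clusters = []
    gi = 0
    for size, count in [(2, 90), (3, 7), (4, 3)]:
        for _ in range(count):
            clusters.append(cc.GeneCluster(f"c{gi}", [f"g{gi + k}" for k in range(size)], "chr1", comb(size, 2)))
            gi += size
    nulls = cc.sample_null_clusters(expr, clusters, seed=11, n_nulls=100)
    sizes = np.array([nl.n for nl in nulls])
    share2 = np.mean(sizes == 2)
    # binomial sampling error around 0.9 with n=100 -> sd ~ 0.03
    assert abs(share2 - 0.9) < 0.1


def test_crossmap_flagging():
    clusters = [cc.GeneCluster("c0", ["a", "b"], "c", 1), cc.GeneCluster("c1", ["x", "y"], "c", 1)]
    cc.flag_crossmappable(clusters, {"b"})
    assert clusters[0].flagged_crossmap and not clusters[1].flagged_crossmap
    assert len(clusters) == 2  # flagged, not removed
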