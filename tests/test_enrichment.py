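import numpy as np
import pandas as pd
import pytest

from pcqtl import enrichment as en
from pcqtl.cluster_calling import GeneCluster
from pcqtl.finemap import CredibleSet
from pcqtl.io_formats import GeneModel


def gm(gid, strand, start, end, chrom="chr1"):
    return GeneModel(gid, chrom, strand, [(start, end)])


def cluster_of(models, cid="cl", is_null=False):
    return GeneCluster(cid, [m.gene_id for m in models], models[0].chrom, m=1, is_null=is_null)


def annotate(models, resources=None):
    cl = cluster_of(models)
    return en.annotate_cluster(cl, {m.gene_id: m for m in models}, resources or en.AnnotationResources())


# ---------------------------------------------------------------------------
# the nine labels
# ---------------------------------------------------------------------------


def test_bidirectional_promoter():
    # opposite strands, 5' ends 500 bp apart
    a = gm("a", "+", 10_000, 15_000)     # TSS 10000
    b = gm("b", "-", 5_000, 9_500)       # TSS 9500
    ann = annotate([a, b])
    assert ann.labels["bidirectional_promoter"] is True
    assert ann.labels["same_strand_promoter"] is False


def test_same_strand_promoter():
    a = gm("a", "+", 10_000, 15_000)
    b = gm("b", "+", 10_800, 20_000)
    ann = annotate([a, b])
    assert ann.labels["same_strand_promoter"] is True
    assert ann.labels["bidirectional_promoter"] is False


def test_promoter_requires_1000bp():
    a = gm("a", "+", 10_000, 15_000)
    b = gm("b", "-", 2_000, 8_900)  # TSS 8900, 1100 bp away
    ann = annotate([a, b])
    assert ann.labels["bidirectional_promoter"] is False


def test_overlap_excludes_promoter_sharing():
    # overlapping, opposite strands, TSSs far apart -> overlap_opposite
    a = gm("a", "+", 10_000, 30_000)
    b = gm("b", "-", 20_000, 50_000)
    ann = annotate([a, b])
    assert ann.labels["overlap_opposite"] is True
    # overlapping but sharing a promoter -> excluded from overlap labels
    c = gm("c", "+", 10_000, 30_000)
    d = gm("d", "-", 9_800, 25_000)  # TSS 25000... choose -: TSS = end = 25000
    # make 5' ends close: d TSS at 10_500
    d = gm("d", "-", 5_000, 10_500)
    ann2 = annotate([c, d])
    assert ann2.labels["bidirectional_promoter"] is True
    assert ann2.labels["overlap_opposite"] is False


def test_overlap_same_strand():
    a = gm("a", "+", 10_000, 30_000)
    b = gm("b", "+", 25_000, 50_000)
    ann = annotate([a, b])
    assert ann.labels["overlap_same"] is True


def test_shared_enhancer_score_rule():
    a = gm("a", "+", 10_000, 15_000)
    b = gm("b", "+", 40_000, 45_000)
    links = pd.DataFrame(
        {
            "gene_id": ["a", "b"],
            "element_id": ["e1", "e1"],
            "score": [0.05, 0.05],
            "element_class": ["genic", "genic"],
        }
    )
    ann = annotate([a, b], en.AnnotationResources(enhancer_links=links))
    assert ann.labels["shared_enhancer"] is False  # score 0.05 <= 0.1
    links2 = links.assign(score=[0.2, 0.3])
    ann2 = annotate([a, b], en.AnnotationResources(enhancer_links=links2))
    assert ann2.labels["shared_enhancer"] is True
    links3 = links2.assign(element_class=["promoter", "promoter"])
    ann3 = annotate([a, b], en.AnnotationResources(enhancer_links=links3))
    assert ann3.labels["shared_enhancer"] is False


def test_paralogs_and_go():
    a = gm("a", "+", 1000, 2000)
    b = gm("b", "+", 9000, 10_000)
    res = en.AnnotationResources(
        paralog_pairs=pd.DataFrame({"gene_a": ["b"], "gene_b": ["a"]}),
        go_terms=pd.DataFrame({"gene_id": ["a", "b", "b"], "term": ["GO:1", "GO:2", "GO:1"]}),
    )
    ann = annotate([a, b], res)
    assert ann.labels["paralogs"] is True
    assert ann.labels["shared_go_bp"] is True


def test_cross_ctcf_containment():
    a = gm("a", "+", 10_000, 20_000)
    b = gm("b", "+", 30_000, 40_000)
    midpoint_peak = pd.DataFrame({"chrom": ["chr1"], "start": [24_000], "end": [26_000]})
    outside_peak = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [52_000]})
    assert annotate([a, b], en.AnnotationResources(ctcf_peaks=midpoint_peak)).labels["cross_ctcf"] is True
    assert annotate([a, b], en.AnnotationResources(ctcf_peaks=outside_peak)).labels["cross_ctcf"] is False


def test_missing_resource_flagged_none():
    a = gm("a", "+", 1000, 2000)
    b = gm("b", "+", 3000, 4000)
    ann = annotate([a, b])
    for cat in ("shared_enhancer", "paralogs", "shared_go_bp", "cross_ctcf", "cross_tad"):
        assert ann.labels[cat] is None


def test_annotation_symmetric_in_gene_order():
    a = gm("a", "+", 10_000, 30_000)
    b = gm("b", "-", 20_000, 50_000)
    ann_ab = annotate([a, b])
    ann_ba = annotate([b, a])
    assert ann_ab.labels == ann_ba.labels


# ---------------------------------------------------------------------------
# logistic enrichment
# ---------------------------------------------------------------------------


def make_annotations(n_real_labeled, n_real, n_null_labeled, n_null, rng=None):
    anns = []
    for i in range(n_real):
        anns.append(en.ClusterAnnotation(f"r{i}", False, {"paralogs": i < n_real_labeled}, 2, 10.0))
    for i in range(n_null):
        anns.append(en.ClusterAnnotation(f"n{i}", True, {"paralogs": i < n_null_labeled}, 2, 10.0))
    return anns


def test_or_matches_2x2_closed_form():
    anns = make_annotations(30, 100, 10, 100)
    res = en.logistic_enrichment(anns, "paralogs")
    expected = (30 * 90) / (70 * 10)
    assert res.odds_ratio == pytest.approx(expected, rel=1e-4)
    assert res.ci95_low < expected < res.ci95_high


def test_balanced_label_or_near_one(rng):
    anns = make_annotations(30, 100, 30, 100)
    res = en.logistic_enrichment(anns, "paralogs")
    assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)
    assert res.ci95_low < 1.0 < res.ci95_high


def test_expected_cell_skip_rule():
    # label rate so low the expected labeled-null cell < 5
    anns = make_annotations(8, 100, 0, 100)
    res = en.logistic_enrichment(anns, "paralogs")
    assert res.skipped
    assert "expected cell" in res.skip_reason


def test_ci_covers_one_on_random_labels():
    covered = 0
    reps = 200
    for rep in range(reps):
        rng = np.random.default_rng(rep)
        anns = []
        for i in range(120):
            anns.append(en.ClusterAnnotation(f"r{i}", False, {"paralogs": bool(rng.random() < 0.4)}, 2, 10.0))
        for i in range(120):
            anns.append(en.ClusterAnnotation(f"n{i}", True, {"paralogs": bool(rng.random() < 0.4)}, 2, 10.0))
        res = en.logistic_enrichment(anns, "paralogs")
        if res.skipped or res.separation:
            continue
        covered += res.ci95_low <= 1.0 <= res.ci95_high
    assert covered / reps > 0.9


# ---------------------------------------------------------------------------
# PIP-weighted variant annotations
# ---------------------------------------------------------------------------


def make_cs(variants, pips):
    return CredibleSet("cs", "ph", list(variants), np.asarray(pips, float), purity=1.0)


def test_all_annotated_probability_one():
    cs = make_cs(["v0", "v1"], [0.7, 0.25])
    table = pd.DataFrame({"cCRE": [1, 1]}, index=["v0", "v1"])
    probs = en.pip_weighted_annotation(cs, table)
    assert probs["cCRE"] == pytest.approx(1.0)


def test_single_variant_equals_indicator():
    cs = make_cs(["v0"], [0.96])
    table = pd.DataFrame({"missense": [1], "cCRE": [0]}, index=["v0"])
    probs = en.pip_weighted_annotation(cs, table)
    assert probs["missense"] == pytest.approx(1.0)
    assert probs["cCRE"] == pytest.approx(0.0)


def test_mixed_set_matches_hand_computation():
    pips = [0.4, 0.3, 0.2, 0.05]
    cs = make_cs([f"v{i}" for i in range(4)], pips)
    table = pd.DataFrame({"cCRE": [1, 0, 1, 0]}, index=[f"v{i}" for i in range(4)])
    probs = en.pip_weighted_annotation(cs, table)
    assert probs["cCRE"] == pytest.approx((0.4 + 0.2) / sum(pips))
    unnorm = en.pip_weighted_annotation(cs, table, normalize=False)
    assert unnorm["cCRE"] == pytest.approx(0.6)


def test_missing_annotation_row_error():
    cs = make_cs(["v0", "vX"], [0.5, 0.5])
    table = pd.DataFrame({"cCRE": [1]}, index=["v0"])
    with pytest.raises(KeyError):
        en.pip_weighted_annotation(cs, table)
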