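"""Pairwise colocalization of QTL/GWAS signals and credible-set grouping.

Each signal contributes a per-variant log Bayes factor vector (the SuSiE
``lbf_variable`` row for QTL credible sets, Wakefield approximate Bayes
factors for GWAS). Pairs are scored by the five-hypothesis enumeration
(H0 no signal, H1/H2 one trait only, H3 two distinct variants, H4 one shared
variant) with all sums in log space. Colocalized QTL credible sets
(PP_H4 >= 0.75) form the edges of an undirected graph whose connected
components are the credible set groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .io_formats import GwasStats

log = logging.getLogger(__name__)

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 5e-6
DEFAULT_GWAS_PRIOR_SD = 0.15
COLOC_EDGE_THRESHOLD = 0.75


@dataclass
class SignalBF:
    """Per-variant log Bayes factors for one association signal."""

    signal_id: str
    source: str  # eQTL | pcQTL | GWAS
    variant_ids: list[str]
    lbf: np.ndarray

    def __post_init__(self) -> None:
        self.lbf = np.asarray(self.lbf, float)
        if len(self.lbf) != len(self.variant_ids):
            raise ValueError("lbf length mismatch")
        if not np.all(np.isfinite(self.lbf)):
            raise ValueError(f"non-finite lbf in signal {self.signal_id}")


def wakefield_abf(gwas: GwasStats, prior_sd: float = DEFAULT_GWAS_PRIOR_SD) -> SignalBF:
    """Wakefield approximate Bayes factors from GWAS beta/se.

    lbf_j = 0.5*log(se_j^2/(se_j^2+W)) + 0.5*z_j^2*W/(se_j^2+W), W = prior_sd^2.
    """
    if np.any(gwas.se <= 0):
        raise ValueError("GWAS standard errors must be positive")
    W = prior_sd**2
    se2 = gwas.se**2
    z2 = (gwas.beta / gwas.se) ** 2
    lbf = 0.5 * np.log(se2 / (se2 + W)) + 0.5 * z2 * W / (se2 + W)
    return SignalBF(gwas.trait_id, "GWAS", list(gwas.variant_ids), lbf)


@dataclass
class ColocResult:
    signal_a: str
    signal_b: str
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float

    @property
    def colocalized(self) -> bool:
        return self.pp_h4 >= COLOC_EDGE_THRESHOLD

    def pp(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when equal."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_pair(
    a: SignalBF,
    b: SignalBF,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
) -> ColocResult:
    """Five-hypothesis colocalization posterior for two signals.

    Variant sets are intersected first; a non-overlapping pair returns
    pp_h4 = 0 with a warning rather than an error.
    """
    common = [v for v in a.variant_ids if v in set(b.variant_ids)]
    if not common:
        log.warning("signals %s and %s share no variants", a.signal_id, b.signal_id)
        return ColocResult(a.signal_id, b.signal_id, 1.0, 0.0, 0.0, 0.0, 0.0)
    ia = {v: i for i, v in enumerate(a.variant_ids)}
    ib = {v: i for i, v in enumerate(b.variant_ids)}
    la = a.lbf[[ia[v] for v in common]]
    lb = b.lbf[[ib[v] for v in common]]

    sum_a = float(logsumexp(la))
    sum_b = float(logsumexp(lb))
    sum_diag = float(logsumexp(la + lb))
    # sum over j != k of exp(la_j + lb_k) = sum_a * sum_b - diagonal
    sum_off = _logdiffexp(sum_a + sum_b, sum_diag)

    lh = np.array(
        [
            0.0,  # H0
            np.log(p1) + sum_a,
            np.log(p2) + sum_b,
            (np.log(p1) + np.log(p2) + sum_off) if np.isfinite(sum_off) else -np.inf,
            np.log(p12) + sum_diag,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(a.signal_id, b.signal_id, *pp.tolist())


@dataclass
class CredibleSetGroup:
    """Connected component of colocalized QTL credible sets."""

    group_id: str
    member_signal_ids: list[str]
    sources: dict[str, str]  # signal id -> eQTL | pcQTL
    egene_ids: list[str] = field(default_factory=list)
    gwas_links: list[tuple[str, str]] = field(default_factory=list)  # (variant, trait)

    @property
    def group_type(self) -> str:
        kinds = {self.sources[s] for s in self.member_signal_ids}
        if kinds == {"pcQTL"}:
            return "pcQTL-only"
        if kinds == {"eQTL"}:
            return "eQTL-only"
        return "both"

    @property
    def novel_pcqtl(self) -> bool:
        return self.group_type == "pcQTL-only"


def build_groups(
    signal_sources: dict[str, str],
    coloc_results: list[ColocResult],
    threshold: float = COLOC_EDGE_THRESHOLD,
    group_prefix: str = "group",
) -> list[CredibleSetGroup]:
    """Connected components of the QTL colocalization graph.

    Nodes are QTL credible sets (``signal_sources`` maps id -> eQTL/pcQTL);
    an edge joins two nodes when pp_h4 >= ``threshold``. Output order is
    deterministic (lexicographic by first member).
    """
    g = nx.Graph()
    g.add_nodes_from(signal_sources)
    for res in coloc_results:
        if res.signal_a in signal_sources and res.signal_b in signal_sources and res.pp_h4 >= threshold:
            g.add_edge(res.signal_a, res.signal_b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return [
        CredibleSetGroup(
            group_id=f"{group_prefix}_{i}",
            member_signal_ids=comp,
            sources={s: signal_sources[s] for s in comp},
        )
        for i, comp in enumerate(comps)
    ]


def classify_novel_pcqtls(groups: list[CredibleSetGroup]) -> dict[str, bool]:
    """A pcQTL credible set is novel iff its group has no eQTL member."""
    flags: dict[str, bool] = {}
    for grp in groups:
        novel = grp.group_type == "pcQTL-only"
        for sid in grp.member_signal_ids:
            if grp.sources[sid] == "pcQTL":
                flags[sid] = novel
    return flags


@dataclass
class GwasLink:
    gwas_variant: str
    trait_id: str
    tissue: str
    best_eqtl_pp_h4: float
    best_pcqtl_pp_h4: float

    @property
    def eqtl_linked(self) -> bool:
        return self.best_eqtl_pp_h4 >= COLOC_EDGE_THRESHOLD

    @property
    def pcqtl_only_linked(self) -> bool:
        return self.best_pcqtl_pp_h4 >= COLOC_EDGE_THRESHOLD and not self.eqtl_linked


def link_gwas(
    gwas_coloc: list[tuple[str, str, str, str, float]],
    threshold: float = COLOC_EDGE_THRESHOLD,
) -> list[GwasLink]:
    """Classify GWAS hits per (variant, trait, tissue) from QTL colocalizations.

    ``gwas_coloc`` rows are (gwas_variant, trait, tissue, qtl_source, pp_h4)
    with qtl_source in {eQTL, pcQTL}. A hit is eQTL-linked when any eQTL
    reaches pp_h4 >= threshold, and pcQTL-only-linked when some pcQTL does
    while every eQTL stays below it.
    """
    best: dict[tuple[str, str, str], dict[str, float]] = {}
    for variant, trait, tissue, source, pp_h4 in gwas_coloc:
        key = (variant, trait, tissue)
        entry = best.setdefault(key, {"eQTL": 0.0, "pcQTL": 0.0})
        entry[source] = max(entry[source], pp_h4)
    return [
        GwasLink(v, t, tis, scores["eQTL"], scores["pcQTL"])
        for (v, t, tis), scores in sorted(best.items())
    ]


def count_unique_hits(links: list[GwasLink], kind: str) -> int:
    """Unique GWAS hits collapsed by (variant, trait) across tissues.

    ``kind`` is 'eqtl' or 'pcqtl_only'. The same variant-trait pair in many
    tissues counts once; the same variant under two traits counts twice.
    """
    pairs = set()
    for link in links:
        hit = link.eqtl_linked if kind == "eqtl" else link.pcqtl_only_linked
        if hit:
            pairs.add((link.gwas_variant, link.trait_id))
    return len(pairs)
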