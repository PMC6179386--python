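"""Edge-overlap validation and gene-set enrichment of top candidates.

Co-abundance edges are validated by their overlap with reference interaction
networks (two-sided Fisher exact test on the 2x2 table of shared-protein
pairs). Top prioritized proteins — cut off where per-rank empirical p-values
from random degree-matched seed sets stay below alpha — are characterized by
upper-tail hypergeometric gene-set enrichment with BH adjustment, and the
significantly enriched sets are connected into a pathway network weighted by
the Jaccard index of their top-protein memberships.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .networks import log_degree_bins
from .prioritize import RankingTable, SeedSet, score

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with an optional explicit universe."""

    sets: dict[str, frozenset]
    universe: frozenset | None = None

    def __post_init__(self) -> None:
        if any(not s for s in self.sets.values()):
            raise ValueError("gene sets must be non-empty")

    @property
    def annotated_universe(self) -> frozenset:
        if self.universe is not None:
            return self.universe
        out: set = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)


@dataclass
class EdgeOverlapResult:
    """Fisher exact enrichment of one edge set in another."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    table: tuple[int, int, int, int]  # a=both, b=coa-only, c=reference-only, d=neither
    haldane: bool = False


def _edge_key_set(net: nx.Graph, nodes: set) -> set:
    return {tuple(sorted((u, v))) for u, v in net.edges if u in nodes and v in nodes and u != v}


def edge_overlap_enrichment(coa: nx.Graph, reference: nx.Graph) -> EdgeOverlapResult:
    """Is the co-abundance edge set enriched in a reference interaction set?

    Both networks are pruned to their shared proteins; the universe is all
    unordered shared-protein pairs. The two-sided p-value comes from the exact
    conditional (minimum-likelihood) Fisher test; the odds ratio is the sample
    OR ad/bc with a Haldane 0.5 correction (flagged) when a cell is zero, and
    the CI is the Woolf log-OR interval.
    """
    shared = set(coa.nodes) & set(reference.nodes)
    m = len(shared)
    if m < 2:
        raise ValueError("need at least 2 shared proteins")
    universe = m * (m - 1) // 2
    e_coa = _edge_key_set(coa, shared)
    e_ref = _edge_key_set(reference, shared)
    a = len(e_coa & e_ref)
    b = len(e_coa - e_ref)
    c = len(e_ref - e_coa)
    d = universe - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if haldane else (a, b, c, d)
    odds = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = float(np.exp(np.log(odds) - 1.96 * se))
    ci_high = float(np.exp(np.log(odds) + 1.96 * se))
    if haldane:
        log.warning("zero cell in edge-overlap table; Haldane-corrected OR/CI reported")
    return EdgeOverlapResult(
        odds_ratio=float(odds),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        table=(a, b, c, d),
        haldane=haldane,
    )


def _random_seed_set(
    seeds: SeedSet, node_bin: dict, bins: dict, rng: np.random.Generator
) -> SeedSet:
    """Degree-bin-matched random seed set of the same size."""
    fallback = min(bins)
    chosen: set[str] = set()
    for s in sorted(seeds.members):
        pool = bins.get(node_bin.get(s, fallback), bins[fallback])
        pick = pool[rng.integers(pool.size)]
        for _ in range(50):  # prefer distinct members
            if pick not in chosen:
                break
            pick = pool[rng.integers(pool.size)]
        chosen.add(pick)
    return SeedSet.from_iterable(chosen)


def top_prioritized_cutoff(
    ranking: RankingTable,
    net: nx.Graph,
    seeds: SeedSet,
    n_real: int = 10_000,
    alpha: float = 0.01,
    rng_seed: int = 0,
    log_base: float = 2.0,
    method: str = "proximity",
) -> tuple[list[str], np.ndarray]:
    """Empirical-p rank cutoff for the "top prioritized" protein set.

    Null rankings are generated from degree-bin-matched random seed sets of
    the original size; for each rank position r the empirical p-value is the
    fraction of realizations whose score at rank r is at least the observed
    score there. The returned set is the observed top-r proteins for the
    largest r whose every position has p < alpha.
    """
    obs = np.sort(ranking.oriented_scores().to_numpy())[::-1]
    if alpha >= 1.0:  # vacuous threshold: everything passes
        return ranking.top(len(obs)), np.zeros(len(obs))
    mapped = seeds.mapped_to(net)
    node_bin, bins = log_degree_bins(net, log_base)
    rng = np.random.default_rng(rng_seed)
    exceed = np.zeros(len(obs), dtype=np.int64)
    for _ in range(n_real):
        rand_seeds = _random_seed_set(mapped, node_bin, bins, rng)
        null_scores = np.sort(score(net, rand_seeds, method=method).oriented_scores().to_numpy())[::-1]
        if null_scores.size != obs.size:  # DADA may exclude nodes; align by position
            null_scores = np.resize(null_scores, obs.size)
        exceed += null_scores >= obs
    p = exceed / n_real
    below = p < alpha
    cutoff = int(np.argmax(~below)) if not below.all() else len(obs)
    return ranking.top(cutoff), p


@dataclass
class EnrichmentRow:
    """One gene set's overlap with the query and its (adjusted) significance."""

    name: str
    overlap: int
    set_size: int
    p: float
    q: float
    members: tuple[str, ...]
    significant: bool = False


def hypergeometric_p(overlap: int, set_size: int, query_size: int, universe_size: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap)."""
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def hypergeometric_enrichment(
    query,
    sets: GeneSetCollection,
    universe=None,
    q_max: float = 0.05,
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment of a query set, BH-adjusted.

    The universe defaults to all proteins annotated in the collection; gene
    sets and the query are intersected with it. Rows are flagged significant
    at q <= q_max and returned sorted by p-value then name.
    """
    uni = frozenset(universe) if universe is not None else sets.annotated_universe
    if not uni:
        raise ValueError("empty universe")
    q_set = set(query) & uni
    rows = []
    for name in sorted(sets.sets):
        members = sets.sets[name] & uni
        if not members:
            continue
        hit = tuple(sorted(q_set & members))
        p = hypergeometric_p(len(hit), len(members), len(q_set), len(uni))
        rows.append(
            EnrichmentRow(
                name=name, overlap=len(hit), set_size=len(members), p=p, q=1.0, members=hit
            )
        )
    if rows:
        adj = multipletests([r.p for r in rows], method="fdr_bh")[1]
        for row, qv in zip(rows, adj):
            row.q = float(qv)
            row.significant = row.q <= q_max
    rows.sort(key=lambda r: (r.p, r.name))
    return rows


def jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def pathway_network(
    rows: list[EnrichmentRow],
    sets: GeneSetCollection,
    top_proteins,
    j_min: float = 0.1,
) -> nx.Graph:
    """Jaccard similarity network over the significantly enriched sets.

    Nodes are significant gene sets with a ``neg_log_q`` size attribute; the
    Jaccard index is computed over the sets' members restricted to the top
    prioritized proteins, and edges with J < j_min are discarded.
    """
    top = set(top_proteins)
    g = nx.Graph()
    sig = [r for r in rows if r.significant]
    members = {}
    for r in sig:
        members[r.name] = sets.sets[r.name] & top
        g.add_node(r.name, q=r.q, neg_log_q=float(-np.log10(max(r.q, 1e-300))))
    for a, b in combinations(sorted(members), 2):
        j = jaccard(members[a], members[b])
        if j >= j_min and j > 0:
            g.add_edge(a, b, jaccard=j, weight=j)
    return g
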