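"""Interaction-network operations: de-noising, combination, nulls, summaries.

Networks are undirected ``networkx.Graph`` objects without self-loops or
parallel edges. Every edge carries:

* ``kind`` — "ppi", "coabundance", or "both" when supported by both sources;
* ``evidence`` — frozenset of experimental evidence flags (PPI edges);
* ``condition`` — stimulation-condition tag of co-abundance edges, or None;
* ``weight`` — positive traversal weight used by weighted shortest paths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

log = logging.getLogger(__name__)

EVIDENCE_TYPES = frozenset(
    {
        "binary-HT",
        "low-throughput",
        "co-complex",
        "regulatory",
        "kinase-substrate",
        "signaling",
        "metabolic",
    }
)
DEFAULT_DENOISE = frozenset({"low-throughput", "co-complex"})


def node_list(net: nx.Graph) -> list[str]:
    return sorted(net.nodes)


def to_sparse(net: nx.Graph, nodes: list[str] | None = None, weighted: bool = True):
    """CSR adjacency of the network plus the node ordering used."""
    nodes = nodes if nodes is not None else node_list(net)
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for u, v, data in net.edges(data=True):
        i, j = index[u], index[v]
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    mat = csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    return mat, nodes, index


def shortest_distance_matrix(
    net: nx.Graph, sources: list[str], weighted: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Distances from each source to every node: array (len(sources), n)."""
    mat, nodes, index = to_sparse(net, weighted=weighted)
    idx = [index[s] for s in sources]
    if not idx:
        raise ValueError("no sources mapped to the network")
    dist = dijkstra(mat, directed=False, indices=idx, unweighted=not weighted)
    return dist, nodes


def denoise_ppi(net: nx.Graph, remove: frozenset = DEFAULT_DENOISE) -> nx.Graph:
    """Drop PPI edges supported only by noisy evidence classes.

    An edge is removed iff its evidence set is non-empty and entirely
    contained in ``remove`` (default: individual low-throughput experiments
    and co-complex inferences); mixed-evidence edges survive. Nodes left
    isolated are dropped.
    """
    out = net.copy()
    doomed = [
        (u, v)
        for u, v, data in out.edges(data=True)
        if data.get("evidence") and frozenset(data["evidence"]) <= remove
    ]
    out.remove_edges_from(doomed)
    out.remove_nodes_from([v for v in out if out.degree(v) == 0])
    return out


def extract_lcc(net: nx.Graph) -> nx.Graph:
    """Largest connected component; size ties broken by smallest member id."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(net))
    biggest = max(len(c) for c in comps)
    # among components of maximal size, the one holding the lexicographically
    # smallest member wins
    best = min((c for c in comps if len(c) == biggest), key=min)
    return net.subgraph(best).copy()


def combine_networks(
    ppi: nx.Graph, coa: nx.Graph, w_ppi: float = 1.0, w_coa: float = 1.0
) -> nx.Graph:
    """Superimpose a co-abundance network on a PPI network.

    Node and edge sets are unioned. Edges present in both networks get class
    "both" and the minimum of the two weights, so that under w_coa < w_ppi
    the co-abundance evidence dominates traversal. Condition tags from the
    co-abundance side are preserved. Idempotent when reapplied with the same
    co-abundance network.
    """
    if w_ppi <= 0 or w_coa <= 0:
        raise ValueError("weights must be positive")
    out = nx.Graph()
    out.add_nodes_from(ppi.nodes)
    out.add_nodes_from(coa.nodes)

    def weight_for(kind: str) -> float:
        return {"ppi": w_ppi, "coabundance": w_coa, "both": min(w_ppi, w_coa)}[kind]

    for u, v, data in ppi.edges(data=True):
        kind = data.get("kind", "ppi")
        out.add_edge(u, v, **{**data, "kind": kind, "weight": weight_for(kind)})
    for u, v, data in coa.edges(data=True):
        if out.has_edge(u, v):
            prev = out[u][v]
            kind = "both" if {prev.get("kind"), data.get("kind", "coabundance")} >= {"ppi", "coabundance"} or "both" in (prev.get("kind"), data.get("kind")) else "coabundance"
            merged = {**prev, **{k: v2 for k, v2 in data.items() if v2 is not None}}
            merged["evidence"] = frozenset(prev.get("evidence") or ()) | frozenset(data.get("evidence") or ())
            merged["kind"] = kind
            merged["weight"] = weight_for(kind)
            merged["condition"] = data.get("condition") or prev.get("condition")
            out.add_edge(u, v, **merged)
        else:
            kind = data.get("kind", "coabundance")
            out.add_edge(u, v, **{**data, "kind": kind, "weight": weight_for(kind)})
    return out


def remove_negative_edges(
    combined: nx.Graph,
    corr,
    r_neg_threshold: float = -0.90,
    q_max: float = 0.01,
) -> nx.Graph:
    """Drop PPI-class edges whose endpoints are significantly anti-correlated.

    A pure PPI edge is removed when the pair's correlation r <= r_neg_threshold
    with Q* <= q_max in ``corr`` (a CorrelationResult). Co-abundance-class
    edges are never touched by this operation.
    """
    index = corr.index_of()
    q = corr.q if corr.q is not None else np.zeros_like(corr.r)
    out = combined.copy()
    doomed = []
    for u, v, data in out.edges(data=True):
        if data.get("kind") != "ppi":
            continue
        i, j = index.get(u), index.get(v)
        if i is None or j is None:
            continue
        if corr.valid is not None and not corr.valid[i, j]:
            continue
        if corr.r[i, j] <= r_neg_threshold and q[i, j] <= q_max:
            doomed.append((u, v))
    out.remove_edges_from(doomed)
    return out


def log_degree_bins(net: nx.Graph, log_base: float = 2.0):
    """Logarithmic degree binning: bin(d) = floor(log_base d), degree >= 1.

    Returns (node -> bin id, bin id -> sorted node array). Degree-0 nodes are
    excluded from eligibility.
    """
    node_bin: dict[str, int] = {}
    bins: dict[int, list[str]] = {}
    for v in node_list(net):
        d = net.degree(v)
        if d < 1:
            continue
        b = int(math.floor(math.log(d, log_base)))
        node_bin[v] = b
        bins.setdefault(b, []).append(v)
    return node_bin, {b: np.array(members) for b, members in bins.items()}


def _bin_pool(bins: dict[int, np.ndarray], center: int, widen: int) -> np.ndarray:
    members = [bins[b] for b in bins if abs(b - center) <= widen]
    return np.concatenate(members) if members else np.array([])


def degree_preserving_random_edges(
    ppi: nx.Graph,
    template: nx.Graph,
    log_base: float = 2.0,
    rng_seed: int = 0,
    edge_weight: float | None = None,
) -> nx.Graph:
    """Add |template| random edges with degree-matched endpoints to ``ppi``.

    For every template edge (u, v) a new edge is created between nodes drawn
    uniformly from the logarithmic degree bins of u and v in the PPI network.
    Draws producing self-loops or existing edges are rejected and redrawn (up
    to 1000 attempts, after which the bins are widened one level at a time).
    Added edges are tagged ``random=True`` and never alter existing edges, so
    removing them restores the input exactly.
    """
    if template.number_of_edges() < 1:
        raise ValueError("template must have at least one edge")
    rng = np.random.default_rng(rng_seed)
    node_bin, bins = log_degree_bins(ppi, log_base)
    max_bin = max(bins) if bins else 0
    fallback = min(bins) if bins else 0
    out = ppi.copy()
    for u, v, data in sorted(template.edges(data=True), key=lambda e: tuple(sorted(e[:2]))):
        bu = node_bin.get(u, fallback)
        bv = node_bin.get(v, fallback)
        w = edge_weight if edge_weight is not None else float(data.get("weight", 1.0))
        placed = False
        widen = 0
        while not placed:
            pool_u = _bin_pool(bins, bu, widen)
            pool_v = _bin_pool(bins, bv, widen)
            if pool_u.size == 0 or pool_v.size == 0:
                raise RuntimeError("cannot place random edge: empty degree bins")
            for _ in range(1000):
                a = pool_u[rng.integers(pool_u.size)]
                b = pool_v[rng.integers(pool_v.size)]
                if a != b and not out.has_edge(a, b):
                    out.add_edge(
                        a,
                        b,
                        kind="coabundance",
                        evidence=frozenset(),
                        condition="random",
                        weight=w,
                        random=True,
                    )
                    placed = True
                    break
            if not placed:
                widen += 1
                log.info("widening degree bins to +-%d for template edge (%s, %s)", widen, u, v)
                if widen > max_bin + 1:
                    raise RuntimeError(f"cannot place a random edge for template pair ({u}, {v})")
    return out


@dataclass
class NetworkSummary:
    """Topological summary computed on the largest connected component."""

    n_nodes: int
    n_edges: int
    density_pct: float
    average_degree: float
    average_clustering: float
    diameter: int
    average_shortest_path_length: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "density_pct": self.density_pct,
            "average_degree": self.average_degree,
            "average_clustering": self.average_clustering,
            "diameter": self.diameter,
            "average_shortest_path_length": self.average_shortest_path_length,
        }


def network_summary(net: nx.Graph) -> NetworkSummary:
    """Standard unweighted topology statistics on the LCC.

    Density is reported as a percentage of possible node pairs; the diameter
    and average shortest path length use hop counts.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    lcc = extract_lcc(net)
    n, m = lcc.number_of_nodes(), lcc.number_of_edges()
    mat, nodes, _ = to_sparse(lcc, weighted=False)
    if n > 1:
        dist = dijkstra(mat, directed=False, unweighted=True)
        iu = np.triu_indices(n, k=1)
        pair_d = dist[iu]
        aspl = float(pair_d.mean())
        diam = int(pair_d.max())
    else:
        aspl, diam = 0.0, 0
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        density_pct=100.0 * 2 * m / (n * (n - 1)) if n > 1 else 0.0,
        average_degree=2 * m / n if n else 0.0,
        average_clustering=float(nx.average_clustering(lcc)),
        diameter=diam,
        average_shortest_path_length=aspl,
    )
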