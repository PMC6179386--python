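"""Seed-proximity drug-target prioritization.

Every node of the (combined) network is scored by its topological proximity
to a set of seed proteins (known drug targets). Four schemes are provided:

* proximity score  PS(c) = sum_s I(s) / (d_cs + 1)          (higher = better)
* kernel distance  dk(c) = -ln[ sum_s exp(-(d_cs + 1)) / |S| ] (lower = better)
* random walk with restart (RWR) stationary probabilities    (higher = better)
* DADA, the degree-adjusted RWR (seed-restart / uniform-restart ratio)

d_cs is the minimum total traversal weight over paths; co-abundance and PPI
links may carry different weights w_C, w_P so the ratio w_C/w_P modulates how
much the condition-specific edges shape the ranking. With all weights equal
the distance reduces to the hop count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .networks import combine_networks, node_list, shortest_distance_matrix, to_sparse

log = logging.getLogger(__name__)


@dataclass
class SeedSet:
    """Seed proteins with importance weights I(s) (default 1.0 for all)."""

    members: tuple[str, ...]
    weights: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_iterable(cls, ids, weights=None) -> "SeedSet":
        members = tuple(sorted(set(ids)))
        w = {m: 1.0 for m in members}
        if weights:
            w.update({k: float(v) for k, v in weights.items() if k in w})
        if any(x <= 0 for x in w.values()):
            raise ValueError("seed weights must be positive")
        return cls(members=members, weights=w)

    def mapped_to(self, net: nx.Graph) -> "SeedSet":
        present = tuple(m for m in self.members if m in net)
        if not present:
            raise ValueError("no seeds map onto the network")
        return SeedSet(members=present, weights={m: self.weights.get(m, 1.0) for m in present})

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class RankingTable:
    """Per-protein score, rank (1 = best) and percentile (rank 1 -> 100).

    ``ascending`` records the score orientation: True when a lower score is
    better (kernel distance), False otherwise. Ties are broken by protein
    identifier so outputs are deterministic.
    """

    frame: pd.DataFrame  # columns: protein, score, rank, percentile
    method: str
    ascending: bool = False
    params: dict = field(default_factory=dict)

    def oriented_scores(self) -> pd.Series:
        """Scores transformed so that larger is always better."""
        s = self.frame.set_index("protein")["score"]
        return -s if self.ascending else s

    def rank_of(self, protein: str) -> int:
        row = self.frame.loc[self.frame.protein == protein]
        if row.empty:
            raise KeyError(protein)
        return int(row["rank"].iloc[0])

    def top(self, n: int) -> list[str]:
        return list(self.frame.sort_values("rank").protein.iloc[:n])


def _make_ranking(
    scores: pd.Series, method: str, ascending: bool, params: dict | None = None
) -> RankingTable:
    order = scores.reset_index()
    order.columns = ["protein", "score"]
    order = order.sort_values(
        ["score", "protein"], ascending=[ascending, True], kind="mergesort"
    ).reset_index(drop=True)
    n = len(order)
    order["rank"] = np.arange(1, n + 1)
    order["percentile"] = 100.0 * (n - order["rank"]) / (n - 1) if n > 1 else 100.0
    return RankingTable(frame=order, method=method, ascending=ascending, params=params or {})


def weighted_shortest_distances(
    net: nx.Graph, sources, targets=None, weighted: bool = True
) -> pd.DataFrame:
    """Minimum-total-weight distances d*_cs.

    Returns a DataFrame indexed by node (candidates, or ``targets`` if given)
    with one column per source; unreachable pairs are +inf. With all edge
    weights equal to w the distances are w times the BFS hop counts.
    """
    sources = sorted(sources)
    dist, nodes = shortest_distance_matrix(net, sources, weighted=weighted)
    table = pd.DataFrame(dist.T, index=nodes, columns=sources)
    if targets is not None:
        table = table.loc[sorted(targets)]
    return table


def proximity_score(
    net: nx.Graph, seeds: SeedSet, weighted: bool = True
) -> RankingTable:
    """PS(c) = sum over seeds of I(s)/(d_cs + 1); descending ranking.

    Seeds score themselves (d = 0 contributes I(s)); seeds unreachable from a
    candidate contribute nothing, and a candidate disconnected from every seed
    scores 0.
    """
    mapped = seeds.mapped_to(net)
    d = weighted_shortest_distances(net, mapped.members, weighted=weighted)
    w = np.array([mapped.weights[s] for s in d.columns])
    contrib = w / (d.to_numpy() + 1.0)
    contrib[~np.isfinite(contrib)] = 0.0
    scores = pd.Series(contrib.sum(axis=1), index=d.index)
    return _make_ranking(scores, "proximity", ascending=False, params={"weighted": weighted})


def kernel_score(net: nx.Graph, seeds: SeedSet, weighted: bool = True) -> RankingTable:
    """Kernel distance dk(c) = -ln[ mean_s exp(-(d_cs+1)) ]; ascending ranking."""
    mapped = seeds.mapped_to(net)
    d = weighted_shortest_distances(net, mapped.members, weighted=weighted)
    damp = np.exp(-(d.to_numpy() + 1.0))
    damp[~np.isfinite(d.to_numpy())] = 0.0
    mean_damp = damp.mean(axis=1)
    with np.errstate(divide="ignore"):
        dk = -np.log(mean_damp)
    scores = pd.Series(dk, index=d.index)
    return _make_ranking(scores, "kernel", ascending=True, params={"weighted": weighted})


def _rwr_vector(
    net: nx.Graph,
    restart_vector: np.ndarray,
    restart: float,
    tol: float,
    max_iter: int,
    nodes: list[str],
) -> np.ndarray:
    mat, _, _ = to_sparse(net, nodes=nodes, weighted=False)
    colsum = np.asarray(mat.sum(axis=0)).ravel()
    colsum[colsum == 0] = 1.0
    # column-normalized adjacency
    w = mat.multiply(1.0 / colsum)
    p = restart_vector.copy()
    for _ in range(max_iter):
        new = (1.0 - restart) * (w @ p) + restart * restart_vector
        if np.abs(new - p).sum() < tol:
            return new
        p = new
    raise RuntimeError("random walk with restart did not converge")


def rwr_score(
    net: nx.Graph,
    seeds: SeedSet,
    restart: float = 0.75,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> RankingTable:
    """Random walk with restart from the seed set (unweighted adjacency).

    Iterates p <- (1 - restart) W p + restart e with e uniform over the seeds
    until the L1 change falls below ``tol``; the stationary probabilities sum
    to 1 and concentrate on the seeds as restart -> 1.
    """
    if not 0 < restart < 1:
        raise ValueError("restart must be in (0, 1)")
    mapped = seeds.mapped_to(net)
    nodes = node_list(net)
    index = {v: i for i, v in enumerate(nodes)}
    e = np.zeros(len(nodes))
    e[[index[s] for s in mapped.members]] = 1.0 / len(mapped)
    p = _rwr_vector(net, e, restart, tol, max_iter, nodes)
    return _make_ranking(
        pd.Series(p, index=nodes), "rwr", ascending=False, params={"restart": restart}
    )


def dada_score(
    net: nx.Graph,
    seeds: SeedSet,
    restart: float = 0.75,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> RankingTable:
    """Degree-aware RWR: seed-restart probabilities over uniform-restart ones.

    The uniform-restart walk captures pure degree bias; dividing by it
    penalizes hubs that attract probability regardless of seed placement. On
    regular graphs the reference is flat and the ordering equals plain RWR.
    Nodes with a zero reference score (cannot happen on a connected graph) are
    excluded with a log message.
    """
    if not 0 < restart < 1:
        raise ValueError("restart must be in (0, 1)")
    mapped = seeds.mapped_to(net)
    nodes = node_list(net)
    index = {v: i for i, v in enumerate(nodes)}
    e = np.zeros(len(nodes))
    e[[index[s] for s in mapped.members]] = 1.0 / len(mapped)
    p = _rwr_vector(net, e, restart, tol, max_iter, nodes)
    uniform = np.full(len(nodes), 1.0 / len(nodes))
    ref = _rwr_vector(net, uniform, restart, tol, max_iter, nodes)
    ok = ref > 0
    if not ok.all():
        log.warning("excluding %d nodes with zero degree-bias reference", int((~ok).sum()))
    ratio = pd.Series(p[ok] / ref[ok], index=np.array(nodes)[ok])
    return _make_ranking(ratio, "dada", ascending=False, params={"restart": restart})


SCORERS = {
    "proximity": proximity_score,
    "kernel": kernel_score,
    "rwr": rwr_score,
    "dada": dada_score,
}


def score(net: nx.Graph, seeds: SeedSet, method: str = "proximity", **kwargs) -> RankingTable:
    """Dispatch to one of the four prioritization schemes."""
    try:
        scorer = SCORERS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}") from None
    return scorer(net, seeds, **kwargs)


def optimize_weight_ratio(
    ppi: nx.Graph,
    coa: nx.Graph,
    seeds: SeedSet,
    ratio_grid,
    k: int = 7,
    rng_seed: int = 0,
    method: str = "proximity",
) -> tuple[float, pd.DataFrame]:
    """Scan the co-abundance/PPI weight ratio for the best CV mean AUROC.

    For each ratio w_C/w_P (w_P fixed at 1) the combined network is rebuilt
    and k-fold cross-validated prioritization is run with identical folds;
    the ratio with the highest mean fold AUROC wins, ties going to the
    smallest ratio. Ratio 0 would make co-abundance paths free and is
    dropped with a warning.
    """
    from .evaluate import cv_auroc, kfold_split  # local import: avoids cycle

    grid = sorted(set(float(r) for r in ratio_grid))
    positive = [r for r in grid if r > 0]
    if len(positive) < len(grid):
        log.warning("dropping non-positive weight ratios from the grid")
    if not positive:
        raise ValueError("ratio grid must contain positive values")
    folds = kfold_split(seeds, k=k, rng_seed=rng_seed)
    rows = []
    for ratio in positive:
        combined = combine_networks(ppi, coa, w_ppi=1.0, w_coa=ratio)
        aurocs = cv_auroc(combined, seeds, folds, method=method)
        rows.append({"ratio": ratio, "mean_auroc": float(np.mean(aurocs))})
    table = pd.DataFrame(rows)
    best = table.loc[table.mean_auroc.idxmax()]
    # idxmax returns the first maximum; grid is ascending so ties -> smallest
    return float(best.ratio), table
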