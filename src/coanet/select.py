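"""Final candidate selection: triple filter, combined ranking, proximity test.

The genome-wide prioritization ranking is reduced to a short candidate list by
intersecting (i) the top-N network-prioritized proteins — N chosen at the ROC
point maximizing sensitivity + specificity — with (ii) the top-k proteins by
relative abundance versus baseline and (iii) the top-k genes by expression
fold change. Candidates are then re-ranked by the combined score
R_comb = (N_prior + N_abun + N_expr) / 3, where the three ranks are
re-normalized within the filtered candidate set. The closeness of the final
list to known drug targets is tested against a degree-preserving random-node
null (z-score and empirical p = P(D_r < D), so small p means closer than
random).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .abundance import RelativeAbundance
from .evaluate import roc_points
from .networks import log_degree_bins, shortest_distance_matrix
from .prioritize import RankingTable

log = logging.getLogger(__name__)


def youden_cutoff(points: np.ndarray) -> tuple[int, float]:
    """Index and value of the ROC point maximizing TPR + (1 - FPR).

    ``points`` is an array of (FPR, TPR) rows; ties go to the earliest
    (smallest-cutoff) point.
    """
    if len(points) < 2:
        raise ValueError("degenerate ROC: need at least two points")
    j = points[:, 1] - points[:, 0]
    idx = int(np.argmax(j))  # argmax returns the first maximum
    return idx, float(j[idx])


def optimal_rank_cutoff(ranking: RankingTable, positives) -> int:
    """Rank cutoff N at the Youden-optimal point of the ranking's ROC curve.

    Walking down the ranking, N is the number of proteins kept when the sum of
    sensitivity and specificity is maximal; ties resolve to the smallest N.
    """
    pts = roc_points(ranking, positives)
    scores = ranking.oriented_scores()
    pos_mask = scores.index.isin(set(positives))
    n_pos = int(pos_mask.sum())
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positives and negatives")
    idx, _ = youden_cutoff(pts[1:])  # skip the (0, 0) origin
    # convert the ROC point back to a rank count
    tp = pts[1:][idx, 1] * n_pos
    fp = pts[1:][idx, 0] * n_neg
    return int(round(tp + fp))


def filter_candidates(
    ranking: RankingTable,
    n_top: int,
    abundance: RelativeAbundance,
    expr_scores: pd.Series,
    top_k: int = 500,
    seeds=(),
    abundance_mode: str = "per-timepoint",
) -> list[str]:
    """Triple filter: network rank, abundance difference, expression change.

    Keeps proteins that are simultaneously (a) within the top ``n_top`` of the
    network prioritization, (b) within the top ``top_k`` by relative abundance
    — at any single time point (default) or by total score — and (c) within
    the top ``top_k`` by expression fold change. Known seed targets are
    removed from the result. Returns a sorted list; empty results produce a
    warning, not an error.
    """
    top_net = set(ranking.top(n_top))
    if abundance_mode == "per-timepoint":
        abun: set[str] = set()
        for col in abundance.profile.columns:
            abun |= set(abundance.profile[col].nlargest(top_k).index)
    elif abundance_mode == "total":
        abun = set(abundance.total.nlargest(top_k).index)
    else:
        raise ValueError(f"unknown abundance_mode {abundance_mode!r}")
    top_expr = set(expr_scores.nlargest(top_k).index)
    candidates = (top_net & abun & top_expr) - set(seeds)
    if not candidates:
        log.warning("triple filter produced an empty candidate set")
    return sorted(candidates)


@dataclass
class CombinedRanking:
    """Within-candidate ranks per criterion and the combined score R_comb."""

    frame: pd.DataFrame  # protein, N_prior, N_abun, N_expr, R_comb, final_rank


def _dense_rank(values: pd.Series, ascending: bool) -> pd.Series:
    """1..M permutation ranks, deterministic ties by protein identifier."""
    order = values.reset_index()
    order.columns = ["protein", "value"]
    order = order.sort_values(["value", "protein"], ascending=[ascending, True], kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.protein)
    return ranks


def combined_rank(
    candidates,
    ranking: RankingTable,
    abun_total: pd.Series,
    expr_scores: pd.Series,
) -> CombinedRanking:
    """R_comb = (N_prior + N_abun + N_expr) / 3 over the filtered candidates.

    Each criterion is re-ranked within the candidate set (1 = best): network
    rank ascending, abundance total and expression fold change descending.
    Final order is ascending R_comb, ties broken by N_prior then identifier.
    """
    cands = sorted(candidates)
    missing = [c for c in cands if c not in abun_total.index or c not in expr_scores.index]
    if missing:
        raise ValueError(f"candidates missing from score tables: {missing[:5]}")
    net_rank = ranking.frame.set_index("protein")["rank"].loc[cands]
    n_prior = _dense_rank(net_rank, ascending=True)
    n_abun = _dense_rank(abun_total.loc[cands], ascending=False)
    n_expr = _dense_rank(expr_scores.loc[cands], ascending=False)
    frame = pd.DataFrame(
        {
            "protein": cands,
            "N_prior": n_prior.loc[cands].to_numpy(),
            "N_abun": n_abun.loc[cands].to_numpy(),
            "N_expr": n_expr.loc[cands].to_numpy(),
        }
    )
    frame["R_comb"] = frame[["N_prior", "N_abun", "N_expr"]].mean(axis=1)
    frame = frame.sort_values(["R_comb", "N_prior", "protein"], kind="mergesort").reset_index(
        drop=True
    )
    frame["final_rank"] = np.arange(1, len(frame) + 1)
    return CombinedRanking(frame=frame)


@dataclass
class ProximityStats:
    """Candidate-to-target distance summary against a degree-matched null.

    D is the mean over candidates of their mean hop distance to all reachable
    targets; the null redraws the candidates from their logarithmic degree
    bins. z = (D - mean D_r) / sd D_r and p_emp = P(D_r < D): small p means
    the candidates sit closer to the targets than degree-matched random
    proteins.
    """

    D: float
    null_mean: float
    null_sd: float
    z: float
    p_emp: float
    null_D: list[float] = field(default_factory=list)
    observed_histogram: dict[int, int] = field(default_factory=dict)
    null_histogram: dict[int, float] = field(default_factory=dict)
    # one-sided per-length enrichment: fraction of null realizations with at
    # least as many candidate-target pairs at that path length as observed
    histogram_p_emp: dict[int, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "D": self.D,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_emp": self.p_emp,
            "observed_histogram": {str(k): v for k, v in self.observed_histogram.items()},
            "null_histogram": {str(k): v for k, v in self.null_histogram.items()},
            "histogram_p_emp": {str(k): v for k, v in self.histogram_p_emp.items()},
        }


def _mean_distance_and_hist(dist: np.ndarray):
    """Mean-of-means distance and path-length histogram from a |C| x |T| block."""
    finite = np.isfinite(dist)
    reachable = finite.any(axis=1)
    if not reachable.any():
        raise ValueError("no candidate can reach any target")
    with np.errstate(invalid="ignore"):
        d_c = np.where(
            reachable, np.nansum(np.where(finite, dist, np.nan), axis=1) / finite.sum(axis=1), np.nan
        )
    d_mean = float(np.nanmean(d_c))
    lengths, counts = np.unique(dist[finite].astype(int), return_counts=True)
    return d_mean, dict(zip(lengths.tolist(), counts.tolist())), int((~reachable).sum())


def candidate_target_proximity(
    net: nx.Graph,
    candidates,
    targets,
    n_real: int = 1000,
    log_base: float = 2.0,
    rng_seed: int = 0,
) -> ProximityStats:
    """Average shortest distance D from candidates to targets, with null.

    d_c is a candidate's mean hop distance to all (reachable) targets and D
    averages d_c over candidates. Each of ``n_real`` null realizations
    replaces every candidate with a node drawn uniformly from its logarithmic
    degree bin and recomputes D. Unreachable pairs are excluded from the means
    (logged).
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    cands = sorted(c for c in candidates if c in net)
    targs = sorted(t for t in targets if t in net)
    if not cands or not targs:
        raise ValueError("candidates and targets must map onto the network")
    dist, nodes = shortest_distance_matrix(net, targs, weighted=False)
    index = {v: i for i, v in enumerate(nodes)}
    block = dist.T  # (n, |T|)
    obs_block = block[[index[c] for c in cands]]
    D, obs_hist, n_excluded = _mean_distance_and_hist(obs_block)
    if n_excluded:
        log.info("excluded %d candidates with no reachable target", n_excluded)

    node_bin, bins = log_degree_bins(net, log_base)
    fallback = min(bins)
    rng = np.random.default_rng(rng_seed)
    null_D = []
    null_hist_acc: dict[int, float] = {}
    hist_exceed: dict[int, int] = {k: 0 for k in obs_hist}
    for _ in range(n_real):
        draw = [
            bins.get(node_bin.get(c, fallback), bins[fallback])[
                rng.integers(len(bins.get(node_bin.get(c, fallback), bins[fallback])))
            ]
            for c in cands
        ]
        rand_block = block[[index[v] for v in draw]]
        d_r, hist_r, _ = _mean_distance_and_hist(rand_block)
        null_D.append(d_r)
        for length, count in hist_r.items():
            null_hist_acc[length] = null_hist_acc.get(length, 0.0) + count
        for length, count in obs_hist.items():
            hist_exceed[length] += hist_r.get(length, 0) >= count
    null_arr = np.array(null_D)
    null_mean = float(null_arr.mean())
    null_sd = float(null_arr.std(ddof=1)) if n_real > 1 else float("nan")
    z = (D - null_mean) / null_sd if null_sd and np.isfinite(null_sd) and null_sd > 0 else float("nan")
    p_emp = float(np.mean(null_arr < D))
    null_hist = {k: v / n_real for k, v in sorted(null_hist_acc.items())}
    hist_p = {k: hist_exceed[k] / n_real for k in sorted(hist_exceed)}
    return ProximityStats(
        D=D,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p_emp=p_emp,
        null_D=[float(x) for x in null_D],
        observed_histogram=dict(sorted(obs_hist.items())),
        null_histogram=null_hist,
        histogram_p_emp=hist_p,
    )
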