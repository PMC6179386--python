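"""Cross-validated performance assessment of the prioritization.

Known drug targets are split into k folds (k = 7 by default); in each fold
the training seeds drive the ranking and the held-out seeds are the positives.
The same partition is reused for every network variant compared, so fold-level
AUROCs are paired and a paired t-test quantifies the gain from co-abundance
edges. Degree-preserving random-edge networks provide the matched negative
control (empirical p = fraction of random realizations scoring at least as
well).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .networks import degree_preserving_random_edges, shortest_distance_matrix
from .prioritize import RankingTable, SeedSet, score

log = logging.getLogger(__name__)


def kfold_split(seeds: SeedSet, k: int = 7, rng_seed: int = 0):
    """Partition the seed set into k near-equal disjoint test folds.

    Returns a list of (train, test) tuples of member ids covering all seeds;
    the first ``len(seeds) mod k`` folds get one extra member. Deterministic
    for a fixed rng_seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(seeds) < k:
        raise ValueError("need at least k seeds")
    members = np.array(sorted(seeds.members))
    rng = np.random.default_rng(rng_seed)
    rng.shuffle(members)
    folds = np.array_split(members, k)
    out = []
    for test in folds:
        test_set = set(test)
        train = tuple(m for m in members if m not in test_set)
        out.append((tuple(sorted(train)), tuple(sorted(test))))
    return out


def auroc(ranking: RankingTable, positives) -> float:
    """Area under the ROC: P(random positive outranks random negative).

    Computed by the rank-sum (Mann-Whitney) formulation on the ranking's
    scores with average ranks for ties, so tied pairs count 1/2.
    """
    scores = ranking.oriented_scores()
    pos = [p for p in positives if p in scores.index]
    if not pos or len(pos) >= len(scores):
        raise ValueError("need both positives and negatives among ranked nodes")
    labels = scores.index.isin(set(pos))
    ranks = stats.rankdata(scores.to_numpy())
    n_pos = labels.sum()
    n_neg = len(scores) - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(ranking: RankingTable, positives) -> np.ndarray:
    """ROC step-curve points (FPR, TPR), one per distinct score plus (0,0)."""
    scores = ranking.oriented_scores()
    labels = scores.index.isin(set(positives))
    order = np.argsort(-scores.to_numpy(), kind="mergesort")
    y = labels[order]
    s = scores.to_numpy()[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    distinct = np.where(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tpr = tps[idx] / max(tps[-1], 1)
    fpr = fps[idx] / max(fps[-1], 1)
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


def pr_points(ranking: RankingTable, positives) -> np.ndarray:
    """Precision-recall points (recall, precision) along the ranking."""
    scores = ranking.oriented_scores()
    labels = scores.index.isin(set(positives))
    order = np.argsort(-scores.to_numpy(), kind="mergesort")
    y = labels[order]
    s = scores.to_numpy()[order]
    tps = np.cumsum(y)
    k = np.arange(1, len(y) + 1)
    distinct = np.where(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    recall = tps[idx] / max(tps[-1], 1)
    precision = tps[idx] / k[idx]
    return np.column_stack([recall, precision])


def _fold_ranking(net: nx.Graph, train, method: str, **kwargs) -> RankingTable:
    return score(net, SeedSet.from_iterable(train), method=method, **kwargs)


def _fold_auroc(ranking: RankingTable, train, test) -> float:
    """AUROC with training seeds removed from the evaluation pool."""
    frame = ranking.frame[~ranking.frame.protein.isin(set(train))]
    pruned = RankingTable(
        frame=frame.reset_index(drop=True), method=ranking.method, ascending=ranking.ascending
    )
    positives = [t for t in test if t in set(frame.protein)]
    return auroc(pruned, positives)


def cv_auroc(net: nx.Graph, seeds: SeedSet, folds, method: str = "proximity", **kwargs):
    """Per-fold AUROCs: train seeds score, held-out seeds are positives."""
    out = []
    for train, test in folds:
        train_in = [t for t in train if t in net]
        ranking = _fold_ranking(net, train_in, method, **kwargs)
        out.append(_fold_auroc(ranking, train_in, test))
    return out


@dataclass
class EvaluationResult:
    """Fold-level AUROCs for each network variant plus paired-test statistics."""

    fold_aurocs: dict[str, list[float]]
    mean_auroc: dict[str, float]
    t_stat: float | None
    p_value: float | None
    df: int
    degenerate: bool = False
    roc: dict[str, np.ndarray] = field(default_factory=dict)
    pr: dict[str, np.ndarray] = field(default_factory=dict)
    null_aurocs: list[float] = field(default_factory=list)
    empirical_p: float | None = None


def compare_networks_cv(
    variants: dict[str, nx.Graph],
    seeds: SeedSet,
    k: int = 7,
    rng_seed: int = 0,
    method: str = "proximity",
    **kwargs,
) -> EvaluationResult:
    """Paired k-fold comparison of network variants (e.g. PPI vs PPI+CoA).

    All variants share the identical fold partition; the paired t-test (df =
    k-1, two-tailed) compares the first two variants' fold AUROCs. Zero
    variance of the differences leaves the p-value undefined (flagged), not 0.
    Pooled ROC / PR point lists are collected across folds.
    """
    folds = kfold_split(seeds, k=k, rng_seed=rng_seed)
    fold_aurocs: dict[str, list[float]] = {}
    for name, net in variants.items():
        fold_aurocs[name] = cv_auroc(net, seeds, folds, method=method, **kwargs)
    names = list(variants)
    t_stat = p_value = None
    degenerate = False
    if len(names) >= 2:
        a = np.array(fold_aurocs[names[0]])
        b = np.array(fold_aurocs[names[1]])
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            degenerate = True
            log.warning("paired t-test undefined: zero variance of fold differences")
        else:
            t_stat, p_value = stats.ttest_rel(a, b)
            t_stat, p_value = float(t_stat), float(p_value)
    roc = {}
    pr = {}
    for name, net in variants.items():
        # pooled curve: score with all seeds held out fold by fold
        pts_scores = []
        pts_labels = []
        for train, test in folds:
            train_in = [t for t in train if t in net]
            ranking = _fold_ranking(net, train_in, method, **kwargs)
            s = ranking.oriented_scores()
            s = s[~s.index.isin(set(train_in))]
            pts_scores.append(s)
            pts_labels.append(s.index.isin(set(test)))
        s_all = pd.concat(pts_scores)
        labels = np.concatenate(pts_labels)
        fake = RankingTable(
            frame=pd.DataFrame(
                {"protein": np.arange(len(s_all)).astype(str), "score": s_all.to_numpy()}
            ),
            method=method,
            ascending=False,
        )
        positives = fake.frame.protein[labels]
        roc[name] = roc_points(fake, positives)
        pr[name] = pr_points(fake, positives)
    return EvaluationResult(
        fold_aurocs=fold_aurocs,
        mean_auroc={k_: float(np.mean(v)) for k_, v in fold_aurocs.items()},
        t_stat=t_stat,
        p_value=p_value,
        df=k - 1,
        degenerate=degenerate,
        roc=roc,
        pr=pr,
    )


def random_edge_control(
    ppi: nx.Graph,
    coa: nx.Graph,
    seeds: SeedSet,
    n_real: int = 20,
    rng_seed: int = 0,
    k: int = 7,
    w_coa: float = 1.0,
    method: str = "proximity",
) -> EvaluationResult:
    """Degree-preserving random-edge negative control for the AUROC gain.

    Each realization adds |E_CoA| random edges (endpoints drawn from the
    template endpoints' logarithmic degree bins) to the PPI network and
    re-runs the cross-validated prioritization with the same folds. The
    empirical p-value is the fraction of realizations whose mean AUROC is at
    least the co-abundance network's.
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    from .networks import combine_networks

    folds = kfold_split(seeds, k=k, rng_seed=rng_seed)
    observed_net = combine_networks(ppi, coa, w_ppi=1.0, w_coa=w_coa)
    observed = float(np.mean(cv_auroc(observed_net, seeds, folds, method=method)))
    null = []
    child_seeds = np.random.SeedSequence(rng_seed).generate_state(n_real) % (2**31)
    for i in range(n_real):
        rand_net = degree_preserving_random_edges(
            ppi, coa, rng_seed=int(child_seeds[i]), edge_weight=w_coa
        )
        null.append(float(np.mean(cv_auroc(rand_net, seeds, folds, method=method))))
    emp_p = float(np.mean([a >= observed for a in null]))
    return EvaluationResult(
        fold_aurocs={"observed": [observed]},
        mean_auroc={"observed": observed},
        t_stat=None,
        p_value=None,
        df=k - 1,
        null_aurocs=null,
        empirical_p=emp_p,
    )


@dataclass
class NavigabilityResult:
    """Per-variant distributions of node-to-target average hop distance."""

    distributions: dict[str, pd.Series]
    pairwise_p: pd.DataFrame  # Bonferroni-corrected two-sided Mann-Whitney


def navigability(variants: dict[str, nx.Graph], node_set, targets) -> NavigabilityResult:
    """How reachable are the targets from a node set, per network variant.

    For each node the mean hop distance to all reachable targets is computed;
    nodes with no reachable target are excluded (logged). Distributions are
    compared pairwise by two-sided Mann-Whitney U with Bonferroni correction
    (exact enumeration for small tie-free samples, normal approximation with
    tie correction otherwise).
    """
    dists: dict[str, pd.Series] = {}
    for name, net in variants.items():
        nodes_in = sorted(v for v in node_set if v in net)
        targ_in = sorted(t for t in targets if t in net)
        if not nodes_in or not targ_in:
            raise ValueError(f"node set or targets do not map onto variant {name!r}")
        d, all_nodes = shortest_distance_matrix(net, targ_in, weighted=False)
        frame = pd.DataFrame(d.T, index=all_nodes, columns=targ_in).loc[nodes_in]
        arr = frame.to_numpy()
        arr[~np.isfinite(arr)] = np.nan
        with np.errstate(invalid="ignore"):
            mean_d = np.nanmean(arr, axis=1)
        ok = np.isfinite(mean_d)
        if not ok.all():
            log.info("%s: excluding %d nodes with no reachable target", name, int((~ok).sum()))
        dists[name] = pd.Series(mean_d[ok], index=np.array(nodes_in)[ok])
    names = list(dists)
    pairs = list(combinations(names, 2))
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in pairs:
        x, y = dists[a].to_numpy(), dists[b].to_numpy()
        exact = len(x) <= 20 and len(y) <= 20 and len(np.unique(np.r_[x, y])) == len(x) + len(y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact" if exact else "asymptotic")
        p = min(1.0, float(res.pvalue) * len(pairs))
        pmat.loc[a, b] = pmat.loc[b, a] = p
    return NavigabilityResult(distributions=dists, pairwise_p=pmat)


def percentile_ranks(ranking: RankingTable, gene_set) -> list[float]:
    """Percentile ranks of the gene-set members present in the ranking."""
    frame = ranking.frame.set_index("protein")
    present = [g for g in sorted(set(gene_set)) if g in frame.index]
    if not present:
        raise ValueError("gene set does not intersect the ranking")
    return [float(frame.loc[g, "percentile"]) for g in present]
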