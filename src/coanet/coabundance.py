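"""Condition-specific co-abundance network construction.

Two proteins are linked in a condition when their time-course abundance
profiles correlate strongly and the correlation is significant against a
permutation null. For every pair the Pearson correlation r is computed; an
empirical p-value P* = r_> / N counts the fraction of N profile-shuffled
permutations whose correlation exceeds the observed one; P* values are
adjusted to Q* by Benjamini-Hochberg step-up. Edges require r >= 0.90 and
Q* <= 0.01 by default, the threshold at which a density sensitivity scan
shows the network density is maintained at 1% FDR.

Biweight midcorrelation and first-order partial correlation (controlling the
baseline condition) are provided as robustness alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceMatrix

log = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Symmetric correlation / significance matrices for one condition.

    ``valid`` flags pairs where both profiles have non-zero variance;
    undefined correlations are stored as 0 and excluded from edges.
    P* entries lie on the grid {0, 1/N, ..., 1} for N permutations and
    Q* >= P* elementwise (BH step-up never decreases a p-value).
    """

    proteins: list[str]
    r: np.ndarray
    method: str = "pearson"
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    n_permutations: int = 0
    control_label: str | None = None
    valid: np.ndarray | None = None
    condition: str = ""

    def index_of(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.proteins)}


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; rows with zero variance -> zeros."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    out = np.zeros_like(centered)
    out[ok] = centered[ok] / norms[ok, None]
    return out, ok


def _bicor_transform(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Biweight midcorrelation row transform (median/MAD weighting).

    u = (x - median) / (9 * MAD); weights (1 - u^2)^2 truncated at |u| >= 1.
    Rows with zero MAD cannot be robustly scaled and are flagged invalid.
    """
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    ok = (mad[:, 0] > 0)
    safe_mad = np.where(mad > 0, mad, 1.0)
    u = (x - med) / (9.0 * safe_mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    xt = (x - med) * w
    norms = np.linalg.norm(xt, axis=1)
    ok &= norms > 0
    out = np.zeros_like(xt)
    out[ok] = xt[ok] / norms[ok, None]
    return out, ok


def partial_correlation_from_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z from pairwise correlations."""
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0:
        return 0.0
    return (r_xy - r_xz * r_yz) / denom


def _pearson_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z, ok = _standardize_rows(x)
    r = z @ z.T
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    valid = np.outer(ok, ok)
    r[~valid] = 0.0
    np.fill_diagonal(r, 1.0)
    return r, valid


def _partial_matrix(
    x: np.ndarray, c: np.ndarray, control: str = "pairwise"
) -> tuple[np.ndarray, np.ndarray]:
    """First-order partial correlation controlling the baseline profiles.

    The control vector for pair (i, j) is the element-wise mean of the two
    proteins' baseline profiles (``control="pairwise"``), or the condition-wide
    mean baseline profile (``control="shared"``).
    """
    n = x.shape[0]
    xs, ok = _standardize_rows(x)
    r_xy = xs @ xs.T
    np.clip(r_xy, -1.0, 1.0, out=r_xy)
    out = np.zeros((n, n))
    valid = np.outer(ok, ok)
    if control == "shared":
        zs, zok = _standardize_rows(c.mean(axis=0, keepdims=True))
        rz = (xs @ zs[0]) if zok[0] else np.zeros(n)
        for i in range(n):
            for_j = np.array(
                [partial_correlation_from_r(r_xy[i, j], rz[i], rz[j]) for j in range(n)]
            )
            out[i] = for_j
    else:
        for i in range(n):
            zpair = (c[i][None, :] + c) / 2.0  # (n, t) control per pair
            zs, zok = _standardize_rows(zpair)
            r_xz = zs @ xs[i]  # corr(x_i, z_ij)
            r_yz = np.einsum("ij,ij->i", zs, xs)  # corr(x_j, z_ij)
            denom = np.sqrt(np.clip((1 - r_xz**2) * (1 - r_yz**2), 0.0, None))
            num = r_xy[i] - r_xz * r_yz
            row = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
            row[~zok] = 0.0
            out[i] = row
    out = (out + out.T) / 2.0
    np.clip(out, -1.0, 1.0, out=out)
    out[~valid] = 0.0
    np.fill_diagonal(out, 1.0)
    return out, valid


def correlation_matrix(
    abundance: AbundanceMatrix,
    method: str = "pearson",
    control: AbundanceMatrix | None = None,
    control_mode: str = "pairwise",
) -> CorrelationResult:
    """All-pairs profile correlation for one condition.

    ``method`` is one of pearson, bicor, partial. Partial correlation requires
    ``control`` (the baseline abundance matrix) sharing proteins and time
    points; each pair is adjusted for the baseline profiles. Zero-variance
    profiles yield undefined correlations recorded as 0 with a cleared
    validity flag.
    """
    if len(abundance.time_points) < 3:
        raise ValueError("need at least 3 time points")
    x = abundance.values()
    if method == "pearson":
        r, valid = _pearson_matrix(x)
    elif method == "bicor":
        z, ok = _bicor_transform(x)
        r = z @ z.T
        np.clip(r, -1.0, 1.0, out=r)
        valid = np.outer(ok, ok)
        r[~valid] = 0.0
        np.fill_diagonal(r, 1.0)
    elif method == "partial":
        if control is None:
            raise ValueError("partial correlation requires a control matrix")
        if control.time_points != abundance.time_points:
            raise ValueError("control must share time points")
        shared = [p for p in abundance.proteins if p in set(control.proteins)]
        if len(shared) < len(abundance.proteins):
            raise ValueError("control must cover all proteins")
        c = control.data.loc[abundance.proteins].to_numpy(dtype=float)
        r, valid = _partial_matrix(x, c, control=control_mode)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(
        proteins=abundance.proteins,
        r=r,
        method=method,
        valid=valid,
        control_label=control.condition if control is not None else None,
        condition=abundance.condition,
    )


def permutation_significance(
    abundance: AbundanceMatrix,
    method: str = "pearson",
    n_perm: int = 300,
    rng_seed: int = 0,
    control: AbundanceMatrix | None = None,
    shuffle: str = "one",
    pseudo_count: bool = False,
) -> CorrelationResult:
    """Permutation empirical p-values P* and BH-adjusted Q* for all pairs.

    Per permutation every protein's profile is shuffled over the time-point
    order and pairwise correlations are recomputed; by default only one member
    of each pair takes the shuffled profile (``shuffle="one"``), which is
    equivalent under exchangeability to shuffling both (``shuffle="both"``).
    P* = r_> / N, the fraction of permutations whose correlation strictly
    exceeds the observed one. With six time points there are only 720 distinct
    orderings, so permutations are Monte-Carlo sampled with replacement.
    ``pseudo_count`` switches to the conservative (r_> + 1)/(N + 1) estimate.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    result = correlation_matrix(abundance, method=method, control=control)
    rng = np.random.default_rng(rng_seed)
    x = abundance.values()
    n, t = x.shape
    exceed = np.zeros((n, n), dtype=np.int64)

    if method == "pearson":
        z, _ = _standardize_rows(x)
        for _ in range(n_perm):
            perm = rng.permuted(z, axis=1)
            rp = perm @ (perm.T if shuffle == "both" else z.T)
            np.clip(rp, -1.0, 1.0, out=rp)  # float error must not beat a perfect r
            exceed += rp > result.r
    else:
        for _ in range(n_perm):
            perm = rng.permuted(x, axis=1)
            data = pd.DataFrame(perm, index=abundance.proteins, columns=abundance.time_points)
            pr = correlation_matrix(
                AbundanceMatrix(condition=abundance.condition, data=data),
                method=method,
                control=control,
            ).r
            exceed += pr > result.r

    if pseudo_count:
        p = (exceed + 1).astype(float) / (n_perm + 1)
    else:
        p = exceed.astype(float) / n_perm
    if shuffle == "both":
        p = (p + p.T) / 2.0
    else:  # one member shuffled: the upper-triangle draw is the pair's realization
        p = np.triu(p, 1) + np.triu(p, 1).T
    np.fill_diagonal(p, 0.0)

    valid = result.valid if result.valid is not None else np.ones_like(p, dtype=bool)
    iu = np.triu_indices(n, k=1)
    mask = valid[iu]
    q = np.ones_like(p)
    if mask.any():
        adj = multipletests(p[iu][mask], method="fdr_bh")[1]
        qvec = np.ones(mask.size)
        qvec[mask] = adj
        q[iu] = qvec
        q = np.triu(q, 1) + np.triu(q, 1).T
    # invalid (zero-variance) pairs keep their literal permutation count in P*
    # but are barred from edges via Q* = 1 and the validity mask
    q[~valid] = 1.0
    np.fill_diagonal(p, 0.0)
    np.fill_diagonal(q, 0.0)

    result.p = p
    result.q = q
    result.n_permutations = n_perm
    return result


def density_sensitivity_scan(
    corr: CorrelationResult,
    r_grid: list[float],
    q_max: float = 0.01,
    rel_tol: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Edge count and density as a function of the correlation threshold.

    For each threshold the scan counts pairs with r >= threshold and
    Q* <= q_max. The selected threshold is the largest grid value whose
    density stays within ``rel_tol`` (relative) of the density at the
    preceding, lower grid value — the highest correlation that still
    "maintains" the network density.
    """
    if not r_grid:
        raise ValueError("empty threshold grid")
    grid = sorted(r_grid)
    n = len(corr.proteins)
    n_pairs = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    r = corr.r[iu]
    q = corr.q[iu] if corr.q is not None else np.zeros_like(r)
    ok = corr.valid[iu] if corr.valid is not None else np.ones_like(r, dtype=bool)
    rows = []
    for thr in grid:
        edges = int(np.sum(ok & (r >= thr) & (q <= q_max)))
        rows.append({"threshold": thr, "n_edges": edges, "density": edges / n_pairs if n_pairs else 0.0})
    table = pd.DataFrame(rows)
    selected = grid[0]
    for k in range(1, len(grid)):
        prev, cur = table.density[k - 1], table.density[k]
        maintained = cur == prev if prev == 0 else abs(cur - prev) <= rel_tol * prev
        if maintained:
            selected = grid[k]
    return table, selected


def build_coabundance_network(
    corr: CorrelationResult,
    r_threshold: float = 0.90,
    q_max: float = 0.01,
    condition: str | None = None,
) -> nx.Graph:
    """Binarize a correlation result into a co-abundance network.

    Edges link pairs with r >= r_threshold (ties included) and Q* <= q_max;
    proteins without any qualifying edge are excluded from the node set.
    """
    n = len(corr.proteins)
    q = corr.q if corr.q is not None else np.zeros((n, n))
    ok = corr.valid if corr.valid is not None else np.ones((n, n), dtype=bool)
    g = nx.Graph()
    label = condition if condition is not None else corr.condition
    iu, ju = np.triu_indices(n, k=1)
    keep = ok[iu, ju] & (corr.r[iu, ju] >= r_threshold) & (q[iu, ju] <= q_max)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(
            corr.proteins[i],
            corr.proteins[j],
            kind="coabundance",
            evidence=frozenset(),
            condition=label,
            weight=1.0,
            r=float(corr.r[i, j]),
            p=float(corr.p[i, j]) if corr.p is not None else None,
            q=float(q[i, j]),
        )
    if g.number_of_edges() == 0:
        log.info("co-abundance network for %s is empty at r>=%s, q<=%s", label, r_threshold, q_max)
    return g
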