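"""Synthetic scenario generator with planted ground truth.

Emulates the statistical structure the analysis assumes, at desk scale:

* a heavy-tailed ("scale-free") protein-protein interaction network,
* seed targets (known drug targets) planted with tunable network locality,
* per-condition six-time-point abundance profiles in which planted modules
  of proteins share a latent trajectory — these become co-abundance cliques —
  with a tunable fraction of module members placed adjacent to seed targets,
  so the resulting co-abundance edges shorten paths to the seeds,
* PSM-level tables consistent with the protein profiles,
* an expression fold-change table and pathway annotations in which planted
  "regulator" proteins carry top-decile fold changes and populate one true
  pathway.

Every quantity derives from a single master seed, so a scenario regenerates
bit-identically. The truth record stores module membership, regulators and
all generator parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix, PSMTable
from .enrich import GeneSetCollection
from .prioritize import SeedSet
from . import io

DEFAULT_TIME_POINTS = (0.0, 8.0, 12.0, 24.0, 48.0, 72.0)
EVIDENCE_CHOICES = ("binary-HT", "low-throughput", "co-complex")


def _child_seeds(rng_seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(rng_seed).generate_state(n) % (2**31)]


def generate_ppi_network(
    n_nodes: int,
    mean_degree: float = 12.0,
    model: str = "preferential-attachment",
    rng_seed: int = 0,
    evidence_proportions: tuple[float, float, float] = (0.5, 0.3, 0.2),
) -> nx.Graph:
    """Simple connected undirected PPI network with heavy-tailed degrees.

    ``model`` is "preferential-attachment" (Barabasi-Albert with
    m = mean_degree / 2) or "duplication-divergence". Evidence flags are
    assigned to edges at random with the given proportions, independent of
    topology. Nodes are labelled P00000, P00001, ...
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    if mean_degree < 2:
        raise ValueError("mean_degree must be >= 2")
    if mean_degree >= n_nodes - 1:
        raise ValueError("mean_degree must be < n_nodes - 1")
    seeds = _child_seeds(rng_seed, 3)
    if model == "preferential-attachment":
        m = max(1, int(round(mean_degree / 2)))
        g0 = nx.barabasi_albert_graph(n_nodes, m, seed=seeds[0])
    elif model == "duplication-divergence":
        retention = min(0.9, max(0.1, mean_degree / (mean_degree + 4.0)))
        g0 = nx.duplication_divergence_graph(n_nodes, retention, seed=seeds[0])
        # the growth process can leave small fragments; stitch them to the core
        comps = sorted(nx.connected_components(g0), key=len, reverse=True)
        rng = np.random.default_rng(seeds[1])
        core = sorted(comps[0])
        for comp in comps[1:]:
            g0.add_edge(sorted(comp)[0], core[rng.integers(len(core))])
    else:
        raise ValueError(f"unknown model {model!r}")
    width = len(str(n_nodes))
    mapping = {i: f"P{i:0{width}d}" for i in g0.nodes}
    g = nx.relabel_nodes(g0, mapping)
    rng = np.random.default_rng(seeds[2])
    flags = rng.choice(len(EVIDENCE_CHOICES), size=g.number_of_edges(), p=evidence_proportions)
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    for (u, v), f in zip(edges, flags):
        g.edges[u, v].update(
            kind="ppi",
            evidence=frozenset({EVIDENCE_CHOICES[int(f)]}),
            condition=None,
            weight=1.0,
        )
    return g


def plant_seed_targets(
    network: nx.Graph, n_targets: int, locality: float = 0.0, rng_seed: int = 0
) -> SeedSet:
    """Plant seed targets with tunable network locality.

    locality = 0 draws targets uniformly without replacement; locality = 1
    grows a connected neighborhood by breadth-first expansion from a random
    anchor; intermediate values place round(locality * n) targets by BFS
    growth and the rest uniformly. All seed weights are 1.0.
    """
    nodes = sorted(network.nodes)
    if n_targets >= len(nodes):
        raise ValueError("n_targets must be below the node count")
    rng = np.random.default_rng(rng_seed)
    n_local = int(round(locality * n_targets))
    chosen: list[str] = []
    if n_local > 0:
        anchor = nodes[rng.integers(len(nodes))]
        visited = {anchor}
        queue = [anchor]
        order = [anchor]
        while queue and len(order) < n_local:
            v = queue.pop(0)
            for u in sorted(network.neighbors(v)):
                if u not in visited:
                    visited.add(u)
                    order.append(u)
                    queue.append(u)
                    if len(order) >= n_local:
                        break
        chosen.extend(order[:n_local])
    remaining = [v for v in nodes if v not in set(chosen)]
    n_uniform = n_targets - len(chosen)
    if n_uniform > 0:
        idx = rng.choice(len(remaining), size=n_uniform, replace=False)
        chosen.extend(remaining[i] for i in idx)
    return SeedSet.from_iterable(chosen)


def _latent_trajectory(rng: np.random.Generator, n_points: int, amplitude: float) -> np.ndarray:
    """Smooth random curve: cumulative sum of Gaussian steps.

    Normalized to standard deviation ``amplitude`` over the time points so an
    "active" module always has a real dynamic range (an unnormalized random
    walk can come out near-flat, which would silently deactivate the module).
    """
    if amplitude == 0:
        return np.zeros(n_points)
    walk = np.r_[0.0, np.cumsum(rng.normal(0.0, 1.0, size=n_points - 1))]
    sd = walk.std()
    if sd == 0:  # vanishing chance; keep the draw count identical
        return np.zeros(n_points)
    return amplitude * walk / sd


def choose_module_members(
    network: nx.Graph,
    module_sizes,
    module_overlap_with_seeds: float,
    seeds: SeedSet | None,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Assign module members, a fraction of them drawn from the seed targets.

    The seed-overlap fraction of each module is filled from the seed set
    itself (known targets do participate in condition-specific co-regulation),
    spilling over into the seeds' network neighbors once the seeds are
    exhausted. This is what lets co-abundance edges shorten paths between
    held-out and training seeds.
    """
    nodes = sorted(network.nodes)
    if sum(module_sizes) > len(nodes):
        raise ValueError("module sizes exceed the node count")
    taken: set[str] = set()
    seed_adjacent: list[str] = []
    if seeds is not None and module_overlap_with_seeds > 0:
        seed_members = set(seeds.members)
        neighbors = sorted(
            {u for s in seeds.members if s in network for u in network.neighbors(s)}
            - seed_members
        )
        seed_pool = sorted(seed_members)
        rng.shuffle(seed_pool)
        rng.shuffle(neighbors)
        seed_adjacent = seed_pool + neighbors
    modules: list[list[str]] = []
    adj_cursor = 0
    for size in module_sizes:
        members: list[str] = []
        n_adj = int(round(module_overlap_with_seeds * size)) if seed_adjacent else 0
        while len(members) < n_adj and adj_cursor < len(seed_adjacent):
            cand = seed_adjacent[adj_cursor]
            adj_cursor += 1
            if cand not in taken:
                members.append(cand)
                taken.add(cand)
        rest = [v for v in nodes if v not in taken]
        idx = rng.choice(len(rest), size=size - len(members), replace=False)
        for i in idx:
            members.append(rest[i])
            taken.add(rest[i])
        modules.append(sorted(members))
    return modules


def generate_abundance_timecourse(
    network: nx.Graph,
    module_sizes,
    module_overlap_with_seeds: float = 0.0,
    noise_sd: float = 0.15,
    time_points=DEFAULT_TIME_POINTS,
    rng_seed: int = 0,
    seeds: SeedSet | None = None,
    n_background: int = 0,
    condition: str = "cond",
    module_members: list[list[str]] | None = None,
    background_members: list[str] | None = None,
    module_amplitudes=None,
    amplitude: float = 1.0,
) -> tuple[AbundanceMatrix, list[list[str]]]:
    """Per-condition abundance profiles with planted correlated modules.

    Proteins within a module share a smooth latent log-trajectory (cumulative
    Gaussian steps) plus i.i.d. Gaussian log-noise of standard deviation
    ``noise_sd``; background proteins get independent noise trajectories.
    Profiles are exponentiated and normalized so the value at t = 0 is exactly
    1. When ``seeds`` are given, round(module_overlap_with_seeds * size)
    members per module are drawn from the seed targets' network neighbors, so
    co-abundance edges can shorten paths to the seeds. Pass ``module_members``
    / ``background_members`` to reuse a membership across conditions, and
    ``module_amplitudes`` to silence modules in some conditions (amplitude 0
    leaves members indistinguishable from background).

    Returns the abundance matrix and the module membership used.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    tp = tuple(float(t) for t in time_points)
    if not tp or tp[0] != 0.0:
        raise ValueError("time points must start at 0")
    rng = np.random.default_rng(rng_seed)
    if module_members is None:
        module_members = choose_module_members(
            network, module_sizes, module_overlap_with_seeds, seeds, rng
        )
    if background_members is None:
        in_module = {v for mod in module_members for v in mod}
        rest = [v for v in sorted(network.nodes) if v not in in_module]
        idx = rng.choice(len(rest), size=min(n_background, len(rest)), replace=False)
        background_members = sorted(rest[i] for i in idx)
    amps = list(module_amplitudes) if module_amplitudes is not None else [amplitude] * len(
        module_members
    )
    nt = len(tp)
    rows = {}
    for mod, amp in zip(module_members, amps):
        latent = _latent_trajectory(rng, nt, amp)
        for prot in mod:
            eps = rng.normal(0.0, noise_sd, size=nt) if noise_sd > 0 else np.zeros(nt)
            logv = latent + eps
            rows[prot] = np.exp(logv - logv[0])
    for prot in background_members:
        eps = rng.normal(0.0, noise_sd, size=nt) if noise_sd > 0 else np.zeros(nt)
        rows[prot] = np.exp(eps - eps[0])
    data = pd.DataFrame.from_dict(rows, orient="index", columns=tp).sort_index()
    return AbundanceMatrix(condition=condition, data=data), module_members


def generate_psm_table(
    abundance: AbundanceMatrix,
    psm_count_range: tuple[int, int] = (12, 40),
    cv: float = 0.1,
    rng_seed: int = 0,
) -> PSMTable:
    """PSM-level table consistent with the protein profiles.

    Each protein receives a uniform random PSM count within the range; every
    PSM's channel intensities are the protein profile scaled by a random base
    intensity and multiplicative log-normal noise with coefficient of
    variation ``cv`` (cv = 0 reproduces the profile exactly after median
    aggregation).
    """
    lo, hi = psm_count_range
    if lo < 1:
        raise ValueError("minimum PSM count must be >= 1")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(rng_seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    tcols = list(abundance.time_points)
    records = []
    psm_id = 0
    for prot in abundance.proteins:
        profile = abundance.data.loc[prot].to_numpy()
        k = int(rng.integers(lo, hi + 1))
        for _ in range(k):
            base = 1e6 * rng.lognormal(0.0, 0.5)
            noise = rng.lognormal(0.0, sigma, size=len(tcols)) if cv > 0 else np.ones(len(tcols))
            intensities = base * profile * noise
            records.append([f"psm{psm_id:07d}", prot, *intensities])
            psm_id += 1
    frame = pd.DataFrame(records, columns=["psm_id", "protein_id", *tcols])
    return PSMTable(frame=frame)


def generate_expression_and_pathways(
    universe,
    regulators: dict[str, list[str]],
    n_pathways: int = 40,
    pathway_size_range: tuple[int, int] = (10, 80),
    true_pathway_size: int = 50,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, GeneSetCollection]:
    """Fold-change table and pathway collection with planted signal.

    ``regulators`` maps condition label -> planted regulator ids. Background
    log2 fold changes are standard normal; each condition's regulators receive
    values above the 95th background percentile plus a positive offset, which
    guarantees top-decile placement. One "true" pathway per condition contains
    that condition's regulators padded with random genes; the remaining
    pathways are random sets of uniform random size.
    """
    genes = sorted(universe)
    rng = np.random.default_rng(rng_seed)
    expr = {}
    for cond in sorted(regulators):
        fc = pd.Series(rng.normal(0.0, 1.0, size=len(genes)), index=genes)
        regs = [r for r in regulators[cond] if r in fc.index]
        floor = float(np.quantile(fc.drop(regs), 0.95))
        fc.loc[regs] = floor + 0.25 + np.abs(rng.normal(0.0, 0.5, size=len(regs)))
        expr[cond] = fc
    expression = pd.DataFrame(expr)
    sets: dict[str, frozenset] = {}
    for i in range(n_pathways):
        size = int(rng.integers(pathway_size_range[0], pathway_size_range[1] + 1))
        idx = rng.choice(len(genes), size=size, replace=False)
        sets[f"pathway{i:03d}"] = frozenset(genes[j] for j in idx)
    for cond in sorted(regulators):
        regs = list(regulators[cond])
        pad = [g for g in genes if g not in set(regs)]
        idx = rng.choice(len(pad), size=max(0, true_pathway_size - len(regs)), replace=False)
        sets[f"true_pathway_{cond}"] = frozenset(regs) | frozenset(pad[j] for j in idx)
    return expression, GeneSetCollection(sets=sets)


@dataclass
class SyntheticScenario:
    """A complete simulated study: inputs plus planted ground truth."""

    network: nx.Graph
    abundance: dict[str, AbundanceMatrix]
    seeds: SeedSet
    expression: pd.DataFrame
    pathways: GeneSetCollection
    truth: dict
    psm_tables: dict[str, PSMTable] | None = None
    baseline: str = "m0"
    stimulated: tuple[str, ...] = ("ifng", "il4")

    def write(self, out_dir) -> None:
        """Write all inputs as plain-text files under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_edge_list(self.network, out / "ppi_edges.tsv")
        for cond, ab in self.abundance.items():
            io.write_abundance(ab.data, out / f"abundance_{cond}.tsv")
        io.write_seed_list(self.seeds.members, out / "seeds.txt", weights=self.seeds.weights)
        io.write_fold_changes(self.expression, out / "expression_fold_changes.tsv")
        io.write_gmt(self.pathways.sets, out / "pathways.gmt")
        io.write_json(self.truth, out / "truth.json")
        if self.psm_tables:
            for cond, table in self.psm_tables.items():
                table.frame.to_csv(out / f"psms_{cond}.tsv", sep="\t", index=False)


def generate_scenario(
    n_nodes: int = 2000,
    mean_degree: float = 12.0,
    n_seeds: int = 150,
    seed_locality: float = 0.5,
    n_modules_per_condition: int = 3,
    module_size: int = 30,
    n_background: int = 340,
    module_overlap_with_seeds: float = 0.6,
    noise_sd: float = 0.15,
    time_points=DEFAULT_TIME_POINTS,
    n_regulators: int = 10,
    rng_seed: int = 0,
    include_psms: bool = False,
    baseline: str = "m0",
    stimulated: tuple[str, ...] = ("ifng", "il4"),
    network_model: str = "preferential-attachment",
) -> SyntheticScenario:
    """Generate the default study scenario.

    A shared proteome of ``n_modules_per_condition * len(stimulated)`` planted
    modules plus background proteins is measured in the baseline and every
    stimulated condition; each stimulated condition activates its own modules
    (latent amplitude 1) while the others stay flat, and the baseline is flat
    everywhere. Planted regulators are non-seed members of each condition's
    active modules; they receive top-decile expression fold changes and a
    dedicated true pathway.
    """
    seeds_int = _child_seeds(rng_seed, 8)
    network = generate_ppi_network(
        n_nodes, mean_degree, model=network_model, rng_seed=seeds_int[0]
    )
    seed_set = plant_seed_targets(network, n_seeds, locality=seed_locality, rng_seed=seeds_int[1])
    n_total_modules = n_modules_per_condition * len(stimulated)
    rng = np.random.default_rng(seeds_int[2])
    modules = choose_module_members(
        network, [module_size] * n_total_modules, module_overlap_with_seeds, seed_set, rng
    )
    in_module = {v for mod in modules for v in mod}
    rest = [v for v in sorted(network.nodes) if v not in in_module and v not in set(seed_set.members)]
    idx = rng.choice(len(rest), size=min(n_background, len(rest)), replace=False)
    background = sorted(rest[i] for i in idx)

    abundance: dict[str, AbundanceMatrix] = {}
    conditions = [baseline, *stimulated]
    active: dict[str, list[int]] = {baseline: []}
    for ci, cond in enumerate(stimulated):
        active[cond] = list(range(ci * n_modules_per_condition, (ci + 1) * n_modules_per_condition))
    for ci, cond in enumerate(conditions):
        amps = [1.0 if mi in active[cond] else 0.0 for mi in range(n_total_modules)]
        ab, _ = generate_abundance_timecourse(
            network,
            [module_size] * n_total_modules,
            noise_sd=noise_sd,
            time_points=time_points,
            rng_seed=seeds_int[3] + ci,
            condition=cond,
            module_members=modules,
            background_members=background,
            module_amplitudes=amps,
        )
        abundance[cond] = ab

    regulators: dict[str, list[str]] = {}
    reg_rng = np.random.default_rng(seeds_int[4])
    seed_members = set(seed_set.members)
    for cond in stimulated:
        pool = sorted(
            {v for mi in active[cond] for v in modules[mi]} - seed_members
        )
        pick = reg_rng.choice(len(pool), size=min(n_regulators, len(pool)), replace=False)
        regulators[cond] = sorted(pool[i] for i in pick)

    expression, pathways = generate_expression_and_pathways(
        sorted(network.nodes), regulators, rng_seed=seeds_int[5]
    )
    psm_tables = None
    if include_psms:
        psm_tables = {
            cond: generate_psm_table(ab, rng_seed=seeds_int[6] + ci)
            for ci, (cond, ab) in enumerate(sorted(abundance.items()))
        }
    truth = {
        "rng_seed": rng_seed,
        "parameters": {
            "n_nodes": n_nodes,
            "mean_degree": mean_degree,
            "n_seeds": n_seeds,
            "seed_locality": seed_locality,
            "n_modules_per_condition": n_modules_per_condition,
            "module_size": module_size,
            "n_background": n_background,
            "module_overlap_with_seeds": module_overlap_with_seeds,
            "noise_sd": noise_sd,
            "time_points": list(time_points),
            "n_regulators": n_regulators,
            "network_model": network_model,
        },
        "modules": [list(m) for m in modules],
        "active_modules": {c: active[c] for c in conditions},
        "background": background,
        "regulators": regulators,
        "seeds": list(seed_set.members),
    }
    return SyntheticScenario(
        network=network,
        abundance=abundance,
        seeds=seed_set,
        expression=expression,
        pathways=pathways,
        truth=truth,
        psm_tables=psm_tables,
        baseline=baseline,
        stimulated=tuple(stimulated),
    )
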