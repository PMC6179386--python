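"""End-to-end pipeline orchestration.

Runs abundance -> coabundance -> netops -> prioritize -> evaluate -> select ->
enrich over one or more stimulated conditions against a baseline, writing all
stage outputs plus a provenance manifest into a run directory. Every random
draw flows from the master seed through per-stage derived seeds recorded in
the manifest; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .abundance import AbundanceMatrix, PSMTable, aggregate_psms, filter_by_psm_count, relative_abundance
from .coabundance import build_coabundance_network, density_sensitivity_scan, permutation_significance
from .config import PipelineConfig
from .enrich import GeneSetCollection, edge_overlap_enrichment, hypergeometric_enrichment, pathway_network, top_prioritized_cutoff
from .evaluate import compare_networks_cv, kfold_split, random_edge_control
from .networks import combine_networks, denoise_ppi, extract_lcc, network_summary
from .prioritize import RankingTable, SeedSet, optimize_weight_ratio, score
from .select import candidate_target_proximity, combined_rank, filter_candidates, optimal_rank_cutoff
from .synthetic import generate_scenario

log = logging.getLogger(__name__)

STAGES = ("abundance", "coabundance", "netops", "prioritize", "evaluate", "select", "enrich")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    idx = STAGES.index(stage) if stage in STAGES else 97
    return int(np.random.SeedSequence((master, idx)).generate_state(1)[0] % (2**31))


def cv_pooled_cutoff(net, seeds: SeedSet, k: int, rng_seed: int, method: str = "proximity") -> int:
    """Youden-optimal rank cutoff from fold-pooled held-out scores.

    Scores from each fold (training seeds drive the ranking, training seeds
    excluded from the pool, held-out seeds are the positives) are pooled into
    one ROC curve; the pooled Youden cutoff divided by the number of folds
    gives the per-network rank cutoff N.
    """
    folds = kfold_split(seeds, k=k, rng_seed=rng_seed)
    frames = []
    labels = []
    for fi, (train, test) in enumerate(folds):
        train_in = [t for t in train if t in net]
        ranking = score(net, SeedSet.from_iterable(train_in), method=method)
        s = ranking.oriented_scores()
        s = s[~s.index.isin(set(train_in))]
        frames.append(pd.Series(s.to_numpy(), index=[f"{fi}:{p}" for p in s.index]))
        labels.extend(f"{fi}:{p}" for p in s.index[s.index.isin(set(test))])
    pooled = pd.concat(frames)
    fake = RankingTable(
        frame=pooled.rename("score").rename_axis("protein").reset_index(),
        method=method,
        ascending=False,
    )
    n_pooled = optimal_rank_cutoff(fake, labels)
    return max(1, int(round(n_pooled / len(folds))))


def _write_ranking(ranking: RankingTable, path) -> None:
    ranking.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _load_inputs(config: PipelineConfig):
    """Load user-supplied inputs or raise with the offending path."""
    for label, path in [("ppi", config.ppi_path), ("seeds", config.seeds_path)]:
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"missing {label} input: {path}")
    network = io.read_edge_list(config.ppi_path)
    members, weights = io.read_seed_list(config.seeds_path)
    seeds = SeedSet.from_iterable(members, weights)
    abundance = {}
    for cond, path in config.abundance_paths.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"missing abundance input for {cond}: {path}")
        abundance[cond] = AbundanceMatrix(condition=cond, data=io.read_abundance(path))
    psms = {}
    for cond, path in config.psm_paths.items():
        frame = pd.read_csv(path, sep="\t")
        frame.columns = list(frame.columns[:2]) + [float(str(c).lstrip("t")) for c in frame.columns[2:]]
        psms[cond] = PSMTable(frame=frame)
    expression = io.read_fold_changes(config.expression_path) if config.expression_path else None
    pathways = (
        GeneSetCollection(sets=io.read_gmt(config.gene_sets_path))
        if config.gene_sets_path
        else None
    )
    return network, abundance, psms or None, seeds, expression, pathways


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis; returns the provenance manifest.

    With ``config.simulate`` a synthetic scenario supplies all inputs (written
    under ``out_dir/inputs``); otherwise the configured paths are read. Stage
    outputs land in ``out_dir`` as TSV/JSON; the manifest records the config
    hash, per-stage derived seeds and output sizes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    truth = None
    if config.simulate:
        scenario = generate_scenario(
            n_nodes=config.sim_n_nodes,
            mean_degree=config.sim_mean_degree,
            n_seeds=config.sim_n_seeds,
            seed_locality=config.sim_seed_locality,
            n_modules_per_condition=config.sim_modules_per_condition,
            module_size=config.sim_module_size,
            n_background=config.sim_n_background,
            module_overlap_with_seeds=config.sim_module_overlap,
            noise_sd=config.sim_noise_sd,
            rng_seed=config.rng_seed,
            include_psms=config.sim_include_psms,
            baseline=config.baseline,
            stimulated=config.stimulated,
        )
        scenario.write(out / "inputs")
        network = scenario.network
        abundance = scenario.abundance
        psms = scenario.psm_tables
        seeds = scenario.seeds
        expression = scenario.expression
        pathways = scenario.pathways
        truth = scenario.truth
    else:
        network, abundance, psms, seeds, expression, pathways = _load_inputs(config)

    # ---- abundance -------------------------------------------------------
    sseed = stage_seed(config.rng_seed, "abundance")
    if psms:
        abundance = {
            cond: aggregate_psms(filter_by_psm_count(tbl, config.psm_min), condition=cond)
            for cond, tbl in psms.items()
        }
    # restrict to the proteome shared by all conditions
    common = None
    for ab in abundance.values():
        idx = set(ab.data.index)
        common = idx if common is None else common & idx
    for cond in list(abundance):
        abundance[cond] = AbundanceMatrix(
            condition=cond, data=abundance[cond].data.loc[sorted(common)]
        )
    rel = {}
    for cond in config.stimulated:
        rel[cond] = relative_abundance(abundance[cond], abundance[config.baseline])
        io.write_abundance(rel[cond].profile, out / f"relative_abundance_{cond}.tsv")
        io.write_abundance(abundance[cond].data, out / f"abundance_{cond}.tsv")
    io.write_abundance(abundance[config.baseline].data, out / f"abundance_{config.baseline}.tsv")
    manifest["stages"]["abundance"] = {
        "seed": sseed,
        "n_proteins": len(common),
        "conditions": sorted(abundance),
    }

    # ---- coabundance -----------------------------------------------------
    sseed = stage_seed(config.rng_seed, "coabundance")
    coa_nets = {}
    corr_results = {}
    for ci, cond in enumerate(config.stimulated):
        corr = permutation_significance(
            abundance[cond],
            method=config.correlation_method,
            n_perm=config.n_perm,
            rng_seed=sseed + ci,
            control=abundance[config.baseline] if config.correlation_method == "partial" else None,
        )
        corr_results[cond] = corr
        scan, _ = density_sensitivity_scan(
            corr, r_grid=[0.5, 0.6, 0.7, 0.8, 0.85, 0.9, 0.95], q_max=config.q_max
        )
        scan.to_csv(out / f"density_scan_{cond}.tsv", sep="\t", index=False, float_format="%.10g")
        coa = build_coabundance_network(
            corr, r_threshold=config.r_threshold, q_max=config.q_max, condition=cond
        )
        coa_nets[cond] = coa
        io.write_edge_list(coa, out / f"coabundance_{cond}.tsv", extra_attrs=("r", "p", "q"))
    manifest["stages"]["coabundance"] = {
        "seed": sseed,
        "edges": {c: coa_nets[c].number_of_edges() for c in coa_nets},
    }

    # ---- netops ----------------------------------------------------------
    sseed = stage_seed(config.rng_seed, "netops")
    ppi = denoise_ppi(network) if config.denoise else network
    ppi = extract_lcc(ppi)
    combined = {}
    ratios = {}
    for cond in config.stimulated:
        w = config.w_coa
        if config.optimize_ratio:
            w, table = optimize_weight_ratio(
                ppi, coa_nets[cond], seeds.mapped_to(ppi), config.ratio_grid,
                k=config.k_folds, rng_seed=sseed, method=config.method,
            )
            table.to_csv(out / f"ratio_scan_{cond}.tsv", sep="\t", index=False, float_format="%.10g")
        ratios[cond] = w
        combined[cond] = combine_networks(ppi, coa_nets[cond], w_ppi=1.0, w_coa=w)
        io.write_edge_list(combined[cond], out / f"combined_{cond}.tsv")
    io.write_json(network_summary(ppi).as_dict(), out / "ppi_summary.json")
    manifest["stages"]["netops"] = {
        "seed": sseed,
        "ppi_nodes": ppi.number_of_nodes(),
        "ppi_edges": ppi.number_of_edges(),
        "w_coa": ratios,
    }

    # ---- prioritize ------------------------------------------------------
    sseed = stage_seed(config.rng_seed, "prioritize")
    rankings = {}
    for cond in config.stimulated:
        rankings[cond] = score(combined[cond], seeds.mapped_to(combined[cond]), method=config.method)
        _write_ranking(rankings[cond], out / f"ranking_{cond}.tsv")
    manifest["stages"]["prioritize"] = {
        "seed": sseed,
        "n_ranked": {c: len(rankings[c].frame) for c in rankings},
    }

    # ---- evaluate --------------------------------------------------------
    sseed = stage_seed(config.rng_seed, "evaluate")
    eval_out = {}
    for cond in config.stimulated:
        seeds_ppi = seeds.mapped_to(ppi)
        res = compare_networks_cv(
            {"ppi_coa": combined[cond], "ppi": ppi},
            seeds_ppi,
            k=config.k_folds,
            rng_seed=sseed,
            method=config.method,
        )
        ctrl = random_edge_control(
            ppi, coa_nets[cond], seeds_ppi,
            n_real=config.n_random_edges, rng_seed=sseed, k=config.k_folds,
            w_coa=ratios[cond], method=config.method,
        )
        np.savetxt(out / f"roc_{cond}.tsv", res.roc["ppi_coa"], delimiter="\t",
                   header="fpr\ttpr", comments="", fmt="%.10g")
        np.savetxt(out / f"pr_{cond}.tsv", res.pr["ppi_coa"], delimiter="\t",
                   header="recall\tprecision", comments="", fmt="%.10g")
        eval_out[cond] = {
            "fold_aurocs": res.fold_aurocs,
            "mean_auroc": res.mean_auroc,
            "t_stat": res.t_stat,
            "p_value": res.p_value,
            "df": res.df,
            "degenerate": res.degenerate,
            "random_edge_null": ctrl.null_aurocs,
            "random_edge_empirical_p": ctrl.empirical_p,
        }
    io.write_json(eval_out, out / "evaluation.json")
    manifest["stages"]["evaluate"] = {
        "seed": sseed,
        "mean_auroc": {c: eval_out[c]["mean_auroc"] for c in eval_out},
    }

    # ---- select ----------------------------------------------------------
    sseed = stage_seed(config.rng_seed, "select")
    select_out = {}
    for cond in config.stimulated:
        n_cut = cv_pooled_cutoff(
            combined[cond], seeds.mapped_to(combined[cond]), k=config.k_folds,
            rng_seed=sseed, method=config.method,
        )
        expr_col = expression[cond] if expression is not None and cond in expression else None
        if expr_col is None:
            log.warning("no expression data for %s; skipping selection", cond)
            continue
        cands = filter_candidates(
            rankings[cond], n_cut, rel[cond], expr_col,
            top_k=config.top_k, seeds=seeds.members,
        )
        stats = None
        if cands:
            comb = combined_rank(cands, rankings[cond], rel[cond].total, expr_col)
            comb.frame.to_csv(out / f"candidates_{cond}.tsv", sep="\t", index=False,
                              float_format="%.10g")
            # distances measured on the enriched network: candidate-target
            # paths may traverse both PPI and co-abundance links
            stats = candidate_target_proximity(
                combined[cond], cands, seeds.mapped_to(combined[cond]).members,
                n_real=config.n_random_nodes, rng_seed=sseed,
            )
            io.write_json(stats.as_dict(), out / f"proximity_{cond}.json")
        select_out[cond] = {
            "rank_cutoff": n_cut,
            "n_candidates": len(cands),
            "proximity_z": stats.z if stats else None,
            "proximity_p_emp": stats.p_emp if stats else None,
        }
    manifest["stages"]["select"] = {"seed": sseed, **select_out}

    # ---- enrich ----------------------------------------------------------
    sseed = stage_seed(config.rng_seed, "enrich")
    enrich_out = {}
    for cond in config.stimulated:
        overlap = edge_overlap_enrichment(coa_nets[cond], ppi)
        top_set, _ = top_prioritized_cutoff(
            rankings[cond], combined[cond], seeds.mapped_to(combined[cond]),
            n_real=config.n_rank_perm, alpha=0.01, rng_seed=sseed, method=config.method,
        )
        with open(out / f"top_prioritized_{cond}.txt", "w") as fh:
            fh.write("\n".join(top_set) + ("\n" if top_set else ""))
        rows = []
        pw_edges = 0
        if pathways is not None and top_set:
            rows = hypergeometric_enrichment(top_set, pathways, q_max=config.enrich_q)
            frame = pd.DataFrame(
                [
                    {"set": r.name, "overlap": r.overlap, "set_size": r.set_size,
                     "p": r.p, "q": r.q, "significant": r.significant,
                     "members": ",".join(r.members)}
                    for r in rows
                ]
            )
            frame.to_csv(out / f"enrichment_{cond}.tsv", sep="\t", index=False,
                         float_format="%.10g")
            pw = pathway_network(rows, pathways, top_set, j_min=config.jaccard_min)
            io.write_edge_list(pw, out / f"pathway_network_{cond}.tsv")
            pw_edges = pw.number_of_edges()
        enrich_out[cond] = {
            "edge_overlap_or": overlap.odds_ratio,
            "edge_overlap_p": overlap.p_value,
            "n_top_prioritized": len(top_set),
            "n_significant_sets": sum(r.significant for r in rows),
            "pathway_network_edges": pw_edges,
        }
    manifest["stages"]["enrich"] = {"seed": sseed, **enrich_out}

    if truth is not None:
        manifest["truth_file"] = "inputs/truth.json"
    io.write_json(manifest, out / "manifest.json")
    return manifest
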