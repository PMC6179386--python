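import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coanet.abundance import aggregate_psms
from coanet.coabundance import build_coabundance_network, permutation_significance
from coanet.enrich import hypergeometric_p
from coanet.evaluate import cv_auroc, kfold_split
from coanet.networks import combine_networks, extract_lcc, shortest_distance_matrix
from coanet.synthetic import (
    generate_abundance_timecourse,
    generate_expression_and_pathways,
    generate_ppi_network,
    generate_psm_table,
    generate_scenario,
    plant_seed_targets,
)

from conftest import make_net


class TestPpiNetwork:
    def test_small_network_is_simple_connected(self):
        g = generate_ppi_network(10, 2, rng_seed=1)
        assert g.number_of_nodes() == 10
        assert g.number_of_edges() >= 9
        assert nx.is_connected(g)
        assert nx.number_of_selfloops(g) == 0

    def test_deterministic_for_fixed_seed(self):
        g1 = generate_ppi_network(50, 4, rng_seed=1)
        g2 = generate_ppi_network(50, 4, rng_seed=1)
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_heavy_tailed_degree_distribution(self):
        g = generate_ppi_network(2000, 12, rng_seed=7)
        degrees = np.array([d for _, d in g.degree])
        assert degrees.max() > 5 * degrees.mean()

    def test_duplication_divergence_model(self):
        g = generate_ppi_network(100, 6, model="duplication-divergence", rng_seed=2)
        assert g.number_of_nodes() == 100
        assert nx.is_connected(g)

    def test_evidence_flags_assigned(self):
        g = generate_ppi_network(30, 4, rng_seed=3)
        flags = {f for _, _, d in g.edges(data=True) for f in d["evidence"]}
        assert flags <= {"binary-HT", "low-throughput", "co-complex"}
        assert all(len(d["evidence"]) == 1 for _, _, d in g.edges(data=True))

    @pytest.mark.parametrize(
        "n,k", [(5, 2), (10, 1), (10, 9.5)], ids=["too-small", "degree-low", "degree-high"]
    )
    def test_invalid_parameters_rejected(self, n, k):
        with pytest.raises(ValueError):
            generate_ppi_network(n, k)


class TestSeedPlanting:
    def test_uniform_sampling_distinct_ids(self):
        g = generate_ppi_network(40, 4, rng_seed=0)
        s = plant_seed_targets(g, 5, locality=0.0, rng_seed=3)
        assert len(set(s.members)) == 5
        assert all(w == 1.0 for w in s.weights.values())

    def test_full_locality_on_path_graph_grows_subpath(self):
        g = make_net([(f"n{i:02d}", f"n{i+1:02d}") for i in range(19)])
        s = plant_seed_targets(g, 5, locality=1.0, rng_seed=3)
        assert nx.is_connected(g.subgraph(s.members))

    def test_partial_locality_shrinks_pairwise_distances(self):
        g = generate_ppi_network(800, 8, rng_seed=5)
        hops, nodes = shortest_distance_matrix(g, sorted(g.nodes), weighted=False)
        index = {v: i for i, v in enumerate(nodes)}

        def mean_pairwise(members):
            idx = [index[m] for m in members]
            block = hops[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), 1)
            return block[iu].mean()

        local = plant_seed_targets(g, 60, locality=0.5, rng_seed=9)
        rng = np.random.default_rng(10)
        uniform_means = [
            mean_pairwise(rng.choice(nodes, size=60, replace=False)) for _ in range(200)
        ]
        assert mean_pairwise(local.members) < np.mean(uniform_means)

    def test_too_many_targets_rejected(self):
        g = generate_ppi_network(20, 3, rng_seed=1)
        with pytest.raises(ValueError):
            plant_seed_targets(g, 20)


class TestAbundanceGenerator:
    def test_zero_noise_module_profiles_identical(self):
        g = generate_ppi_network(40, 4, rng_seed=1)
        ab, modules = generate_abundance_timecourse(g, [4], noise_sd=0.0, rng_seed=2)
        rows = ab.data.loc[modules[0]].to_numpy()
        assert np.allclose(rows, rows[0])
        r = np.corrcoef(rows)
        assert np.allclose(r, 1.0)

    def test_pure_noise_profiles_uncorrelated(self):
        g = generate_ppi_network(150, 4, rng_seed=3)
        ab, _ = generate_abundance_timecourse(
            g, [], noise_sd=10.0, rng_seed=4, n_background=100
        )
        x = ab.data.to_numpy()
        r = np.corrcoef(x)
        rng = np.random.default_rng(5)
        pairs = rng.integers(0, 100, size=(100, 2))
        vals = [abs(r[i, j]) for i, j in pairs if i != j]
        assert np.mean(vals) < 0.6

    def test_time_zero_column_exactly_one(self):
        g = generate_ppi_network(40, 4, rng_seed=1)
        ab, _ = generate_abundance_timecourse(g, [5], noise_sd=0.3, rng_seed=6, n_background=10)
        assert (ab.data[0.0] == 1.0).all()

    def test_negative_noise_rejected(self):
        g = generate_ppi_network(40, 4, rng_seed=1)
        with pytest.raises(ValueError):
            generate_abundance_timecourse(g, [4], noise_sd=-1.0)


class TestPsmGenerator:
    @pytest.fixture()
    def abundance(self):
        g = generate_ppi_network(40, 4, rng_seed=1)
        ab, _ = generate_abundance_timecourse(g, [6], noise_sd=0.2, rng_seed=2, n_background=6)
        return ab

    def test_noise_free_round_trip_is_exact(self, abundance):
        psms = generate_psm_table(abundance, psm_count_range=(3, 9), cv=0.0, rng_seed=3)
        back = aggregate_psms(psms)
        pd.testing.assert_frame_equal(
            back.data, abundance.data.sort_index(), check_exact=False, atol=1e-12
        )

    def test_single_psm_per_protein(self, abundance):
        psms = generate_psm_table(abundance, psm_count_range=(1, 1), cv=0.1, rng_seed=4)
        assert (psms.psm_counts() == 1).all()

    def test_noisy_aggregation_tracks_profiles(self, abundance):
        psms = generate_psm_table(abundance, psm_count_range=(5, 40), cv=0.1, rng_seed=2)
        back = aggregate_psms(psms)
        for prot in abundance.proteins:
            r = np.corrcoef(back.data.loc[prot], abundance.data.loc[prot])[0, 1]
            assert r > 0.95

    def test_invalid_parameters_rejected(self, abundance):
        with pytest.raises(ValueError):
            generate_psm_table(abundance, psm_count_range=(0, 5))
        with pytest.raises(ValueError):
            generate_psm_table(abundance, cv=-0.1)


class TestExpressionAndPathways:
    def test_regulators_in_top_decile(self):
        genes = [f"g{i:04d}" for i in range(2000)]
        regs = {"ifng": genes[:20], "il4": genes[50:70]}
        expr, _ = generate_expression_and_pathways(genes, regs, rng_seed=1)
        for cond, members in regs.items():
            cutoff = np.quantile(expr[cond], 0.9)
            assert (expr.loc[members, cond] >= cutoff).all()

    def test_true_pathway_enriched_in_regulators(self):
        genes = [f"g{i:04d}" for i in range(2000)]
        regs = {"ifng": genes[:20]}
        _, pathways = generate_expression_and_pathways(
            genes, regs, true_pathway_size=50, rng_seed=2
        )
        true_set = pathways.sets["true_pathway_ifng"]
        overlap = len(true_set & set(regs["ifng"]))
        assert overlap >= 4
        p = hypergeometric_p(overlap, 50, 20, 2000)
        assert p < 0.05

    def test_gmt_round_trip(self, tmp_path):
        from coanet import io

        genes = [f"g{i}" for i in range(100)]
        _, pathways = generate_expression_and_pathways(genes, {"c": genes[:5]}, rng_seed=3)
        path = tmp_path / "sets.gmt"
        io.write_gmt(pathways.sets, path)
        back = io.read_gmt(path)
        assert back == dict(pathways.sets)


class TestScenario:
    def test_regeneration_is_bit_identical(self, tmp_path):
        s1 = generate_scenario(n_nodes=200, n_seeds=20, module_size=8, n_background=40, rng_seed=5)
        s2 = generate_scenario(n_nodes=200, n_seeds=20, module_size=8, n_background=40, rng_seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        s1.write(d1)
        s2.write(d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_truth_record_consistent_with_scenario(self, small_scenario):
        sc = small_scenario
        nodes = set(sc.network.nodes)
        assert set(sc.seeds.members) <= nodes
        for mod in sc.truth["modules"]:
            assert set(mod) <= nodes
        for cond, regs in sc.truth["regulators"].items():
            assert set(regs) <= nodes
            assert not set(regs) & set(sc.seeds.members)
        assert set(sc.expression.index) == nodes

    def test_measured_proteome_shared_across_conditions(self, small_scenario):
        frames = [ab.data for ab in small_scenario.abundance.values()]
        for f in frames[1:]:
            assert list(f.index) == list(frames[0].index)

    def test_planted_signal_dose_response(self):
        """AUROC gain of PPI+CoA over PPI rises with module-seed overlap."""
        overlaps = [0.0, 0.25, 0.5, 0.75, 1.0]
        mean_gains = []
        for overlap in overlaps:
            gains = []
            for rep in range(3):
                sc = generate_scenario(
                    n_nodes=800,
                    mean_degree=8,
                    n_seeds=80,
                    module_size=16,
                    n_modules_per_condition=2,
                    n_background=120,
                    module_overlap_with_seeds=overlap,
                    rng_seed=100 + rep,
                )
                ppi = extract_lcc(sc.network)
                corr = permutation_significance(
                    sc.abundance["ifng"], n_perm=100, rng_seed=rep
                )
                coa = build_coabundance_network(corr)
                combined = combine_networks(ppi, coa, 1.0, 0.4)
                folds = kfold_split(sc.seeds, k=5, rng_seed=rep)
                gain = np.mean(cv_auroc(combined, sc.seeds, folds)) - np.mean(
                    cv_auroc(ppi, sc.seeds, folds)
                )
                gains.append(gain)
            mean_gains.append(np.mean(gains))
        rho, _ = sps.spearmanr(overlaps, mean_gains)
        assert rho > 0
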