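import itertools
import math

import networkx as nx
import numpy as np
import pytest

from coanet.networks import combine_networks
from coanet.prioritize import (
    SeedSet,
    dada_score,
    kernel_score,
    optimize_weight_ratio,
    proximity_score,
    rwr_score,
    weighted_shortest_distances,
)

from conftest import make_net


def brute_force_distance(net: nx.Graph, a: str, b: str) -> float:
    """Exhaustive minimum-total-weight path search (small graphs only)."""
    if a == b:
        return 0.0
    best = math.inf
    nodes = [v for v in net.nodes if v not in (a, b)]
    for k in range(len(nodes) + 1):
        for middle in itertools.permutations(nodes, k):
            path = (a, *middle, b)
            cost = 0.0
            ok = True
            for u, v in zip(path, path[1:]):
                if not net.has_edge(u, v):
                    ok = False
                    break
                cost += net[u][v]["weight"]
            if ok:
                best = min(best, cost)
    return best


class TestWeightedDistances:
    def test_mixed_edge_type_path_cost(self):
        net = make_net(
            [
                ("s", "a", {"kind": "coabundance", "weight": 0.4}),
                ("a", "b", {"kind": "coabundance", "weight": 0.4}),
                ("b", "c", {"kind": "ppi", "weight": 1.0}),
            ]
        )
        d = weighted_shortest_distances(net, ["s"])
        assert d.loc["c", "s"] == pytest.approx(1.8)

    def test_cheaper_long_route_preferred(self):
        net = make_net([("s", "a"), ("a", "b"), ("b", "t")])  # 3 ppi hops, cost 3
        for u, v in [("s", "c1"), ("c1", "c2"), ("c2", "c3"), ("c3", "c4"), ("c4", "t")]:
            net.add_edge(u, v, kind="coabundance", evidence=frozenset(), condition=None, weight=0.4)
        d = weighted_shortest_distances(net, ["s"])
        assert d.loc["t", "s"] == pytest.approx(2.0)

    def test_unit_weights_reduce_to_hop_counts(self):
        net = make_net([("a", "b"), ("b", "c"), ("c", "d")])
        d = weighted_shortest_distances(net, ["a"])
        hops = nx.single_source_shortest_path_length(net, "a")
        for node, h in hops.items():
            assert d.loc[node, "a"] == pytest.approx(h)

    def test_unreachable_is_infinite(self):
        net = make_net([("a", "b"), ("x", "y")])
        d = weighted_shortest_distances(net, ["a"])
        assert math.isinf(d.loc["x", "a"])


class TestProximityScore:
    def test_two_hop_candidate(self):
        net = make_net([("s", "a"), ("a", "b")])
        r = proximity_score(net, SeedSet.from_iterable(["s"]))
        assert r.frame.set_index("protein").loc["b", "score"] == pytest.approx(1 / 3)

    def test_seed_scores_itself(self):
        net = make_net([("s", "a")])
        r = proximity_score(net, SeedSet.from_iterable(["s"]))
        assert r.frame.set_index("protein").loc["s", "score"] == pytest.approx(1.0)

    def test_star_center_sums_seed_contributions(self):
        net = make_net([("c", "s1"), ("c", "s2"), ("c", "s3")])
        r = proximity_score(net, SeedSet.from_iterable(["s1", "s2", "s3"]))
        assert r.frame.set_index("protein").loc["c", "score"] == pytest.approx(1.5)

    def test_adding_an_edge_never_decreases_scores(self, small_scenario):
        net = small_scenario.network.copy()
        seeds = small_scenario.seeds
        before = proximity_score(net, seeds).frame.set_index("protein").score
        nodes = sorted(net.nodes)
        rng = np.random.default_rng(1)
        for _ in range(5):
            u, v = rng.choice(nodes, 2, replace=False)
            if not net.has_edge(u, v):
                net.add_edge(u, v, kind="ppi", evidence=frozenset(), condition=None, weight=1.0)
        after = proximity_score(net, seeds).frame.set_index("protein").score
        assert after.sub(before).min() >= -1e-12

    def test_rank_percentile_bijection(self):
        net = make_net([("s", "a"), ("a", "b"), ("b", "c")])
        r = proximity_score(net, SeedSet.from_iterable(["s"]))
        n = len(r.frame)
        recon = 1 + np.round((100.0 - r.frame.percentile) * (n - 1) / 100.0).astype(int)
        assert (recon == r.frame["rank"]).all()


class TestKernelScore:
    def test_single_seed_closed_form(self):
        net = make_net([("s", "a"), ("a", "b")])
        r = kernel_score(net, SeedSet.from_iterable(["s"]))
        assert r.frame.set_index("protein").loc["b", "score"] == pytest.approx(3.0)

    def test_equidistant_seeds_give_d_plus_one(self):
        net = make_net([("c", "s1"), ("c", "s2")])
        r = kernel_score(net, SeedSet.from_iterable(["s1", "s2"]))
        assert r.frame.set_index("protein").loc["c", "score"] == pytest.approx(2.0)

    def test_two_seed_mixture(self):
        net = make_net([("s1", "c"), ("c", "x"), ("x", "y"), ("y", "s2")])
        r = kernel_score(net, SeedSet.from_iterable(["s1", "s2"]))
        expected = -math.log((math.exp(-2) + math.exp(-4)) / 2)
        assert r.frame.set_index("protein").loc["c", "score"] == pytest.approx(expected, abs=1e-6)


class TestRwr:
    def test_two_node_stationary_solution(self):
        net = make_net([("n1", "n2")])
        r = rwr_score(net, SeedSet.from_iterable(["n1"]), restart=0.5, tol=1e-12)
        scores = r.frame.set_index("protein").score
        assert scores["n1"] == pytest.approx(2 / 3, abs=1e-9)
        assert scores["n2"] == pytest.approx(1 / 3, abs=1e-9)

    def test_high_restart_concentrates_on_seeds(self, small_scenario):
        net = small_scenario.network
        seeds = SeedSet.from_iterable(list(small_scenario.seeds.members)[:4])
        r = rwr_score(net, seeds, restart=0.999)
        scores = r.frame.set_index("protein").score
        for s in seeds.members:
            assert scores[s] == pytest.approx(1 / 4, abs=0.01)

    def test_probability_conservation(self, small_scenario):
        r = rwr_score(small_scenario.network, small_scenario.seeds)
        assert r.frame.score.sum() == pytest.approx(1.0, abs=1e-5)

    def test_invalid_restart_rejected(self):
        with pytest.raises(ValueError):
            rwr_score(make_net([("a", "b")]), SeedSet.from_iterable(["a"]), restart=1.0)


class TestDada:
    def test_regular_graph_preserves_rwr_order(self):
        net = make_net([(f"n{i}", f"n{(i+1) % 8}") for i in range(8)])  # cycle, 2-regular
        seeds = SeedSet.from_iterable(["n0", "n3"])
        rwr_order = list(rwr_score(net, seeds).frame.protein)
        dada_order = list(dada_score(net, seeds).frame.protein)
        assert rwr_order == dada_order

    def test_seedless_hub_demoted_below_equidistant_low_degree_node(self):
        # hub and c sit two hops from the seed; the hub soaks up walk
        # probability by degree alone, which the uniform-restart reference
        # cancels, so DADA flips their relative order
        net = make_net([("seed", "a"), ("a", "hub"), ("seed", "b"), ("b", "c")])
        for i in range(20):
            net.add_edge(
                "hub", f"leaf{i}", kind="ppi", evidence=frozenset(), condition=None, weight=1.0
            )
        seeds = SeedSet.from_iterable(["seed"])
        rwr = rwr_score(net, seeds)
        dada = dada_score(net, seeds)
        assert rwr.rank_of("hub") < rwr.rank_of("c")
        assert dada.rank_of("hub") > dada.rank_of("c")

    def test_all_seeds_gives_flat_ratios(self):
        net = make_net([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        seeds = SeedSet.from_iterable(["a", "b", "c", "d"])
        r = dada_score(net, seeds, tol=1e-12)
        assert np.allclose(r.frame.score, 1.0, atol=1e-6)


class TestOracleAgreement:
    def test_weighted_distances_match_exhaustive_search(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(10**6)))
            net = nx.Graph()
            net.add_nodes_from(f"v{i}" for i in range(n))
            for u, v in g.edges:
                net.add_edge(
                    f"v{u}", f"v{v}", kind="ppi", evidence=frozenset(), condition=None,
                    weight=float(rng.choice([0.1, 0.4, 1.0, 2.0])),
                )
            d = weighted_shortest_distances(net, ["v0"])
            for node in net.nodes:
                assert d.loc[node, "v0"] == pytest.approx(
                    brute_force_distance(net, node, "v0")
                )


class TestWeightRatioScan:
    def test_single_grid_point_returned(self, small_scenario):
        coa = make_net([("P000", "P001")], kind="coabundance")
        best, table = optimize_weight_ratio(
            small_scenario.network, coa, small_scenario.seeds, [1.0], k=4, rng_seed=0
        )
        assert best == 1.0
        assert len(table) == 1

    def test_tied_aurocs_return_smallest_ratio(self, small_scenario):
        # an empty co-abundance network makes every ratio equivalent
        best, table = optimize_weight_ratio(
            small_scenario.network, nx.Graph(), small_scenario.seeds, [0.5, 1.0, 2.0],
            k=4, rng_seed=0,
        )
        assert best == 0.5
        assert table.mean_auroc.nunique() == 1

    def test_nonpositive_ratios_dropped(self, small_scenario):
        coa = make_net([("P000", "P001")], kind="coabundance")
        best, table = optimize_weight_ratio(
            small_scenario.network, coa, small_scenario.seeds, [0.0, 1.0], k=4, rng_seed=0
        )
        assert list(table.ratio) == [1.0]
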