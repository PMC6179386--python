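import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coanet.abundance import AbundanceMatrix
from coanet.synthetic import generate_scenario


def make_net(edges, kind="ppi", **attrs):
    """Build a small network with sane edge-attribute defaults."""
    g = nx.Graph()
    for e in edges:
        u, v = e[:2]
        data = {
            "kind": kind,
            "evidence": frozenset(),
            "condition": None,
            "weight": 1.0,
        }
        if len(e) > 2:
            data.update(e[2])
        data.update(attrs)
        g.add_edge(u, v, **data)
    return g


def make_abundance(profiles: dict, time_points=(0, 8, 12, 24, 48, 72), condition="cond"):
    data = pd.DataFrame.from_dict(profiles, orient="index", columns=[float(t) for t in time_points])
    return AbundanceMatrix(condition=condition, data=data)


@pytest.fixture(scope="session")
def small_scenario():
    """Reduced planted scenario shared by the cheaper integration tests."""
    return generate_scenario(
        n_nodes=400,
        mean_degree=8,
        n_seeds=40,
        module_size=12,
        n_modules_per_condition=2,
        n_background=80,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def default_scenario():
    """The package-default study scenario (used by the acceptance tests)."""
    return generate_scenario(rng_seed=0)
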