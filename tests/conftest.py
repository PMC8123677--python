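import numpy as np
import pandas as pd
import pytest

from regulonsurv.matrix import ExpressionMatrix, Regulon, RegulonSet
from regulonsurv.synthetic import generate_planted_network, simulate_cohort


def truth_regulon_set(network) -> RegulonSet:
    """RegulonSet built directly from a planted network's ground truth."""
    regulons = {}
    for r in network.regulator_ids:
        entries = network.targets_of(r)
        regulons[r] = Regulon(
            regulator=r,
            targets=[t for t, _, _ in entries],
            signs={t: s for t, s, _ in entries},
        )
    return RegulonSet(regulons)


@pytest.fixture(scope="session")
def small_network():
    return generate_planted_network(
        5, 20, frac_negative=0.2, overlap_frac=0.0, seed=3
    )


@pytest.fixture(scope="session")
def planted_cohort(small_network):
    """Cohort with one active regulon (TF000) in half the tumours."""
    return simulate_cohort(
        small_network,
        {"TF000"},
        n_tumour=40,
        n_benign=12,
        delta=3.0,
        sigma=0.5,
        active_fraction=0.5,
        seed=4,
    )


@pytest.fixture()
def tiny_matrix():
    values = pd.DataFrame(
        {
            "s1": [2.0, 0.0, 3.0],
            "s2": [4.0, 1.0, 3.0],
            "s3": [6.0, 0.5, 3.0],
        },
        index=["gA", "gB", "gC"],
    )
    cond = pd.Series({"s1": "tumour", "s2": "benign", "s3": "benign"})
    return ExpressionMatrix(values, cond)


def random_small_graph(rng: np.random.Generator, max_nodes: int = 20):
    """Random directed graph for metric-oracle comparisons."""
    import networkx as nx

    n = int(rng.integers(2, max_nodes + 1))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    p = rng.uniform(0.05, 0.4)
    for a in range(n):
        for b in range(n):
            if a != b and rng.random() < p:
                g.add_edge(a, b)
    return g
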