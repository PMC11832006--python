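import numpy as np
import pandas as pd
import pytest

from mrpipe.data_io import CountMatrix, SignedNetwork, StateMatrix
from mrpipe.synthetic import SimulationConfig


@pytest.fixture
def small_counts() -> CountMatrix:
    counts = pd.DataFrame(
        {
            "R1": [10, 100, 50, 0],
            "R2": [12, 90, 55, 1],
            "T1": [80, 95, 52, 0],
            "T2": [9, 400, 48, 2],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    roles = pd.Series({"R1": "reference", "R2": "reference", "T1": "tumor", "T2": "tumor"})
    return CountMatrix(counts=counts, roles=roles)


@pytest.fixture
def chain_network() -> SignedNetwork:
    # A -(+)-> B -(-)-> C
    return SignedNetwork(edges=[("A", "B", 1), ("B", "C", -1)])


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


def random_signed_network(rng: np.random.Generator, n_nodes: int, n_edges: int) -> SignedNetwork:
    """Random signed digraph for oracle comparisons (parallel signs allowed)."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    triples = set()
    for _ in range(n_edges):
        u = nodes[rng.integers(n_nodes)]
        v = nodes[rng.integers(n_nodes)]
        if u == v:
            continue
        triples.add((u, v, 1 if rng.random() < 0.5 else -1))
    return SignedNetwork(edges=sorted(triples), nodes=set(nodes))


@pytest.fixture
def state_matrix() -> StateMatrix:
    values = pd.DataFrame(
        {"s1": [1, -1, 0], "s2": [1, 0, 1], "s3": [0, -1, -1]},
        index=["p1", "p2", "p3"],
    )
    return StateMatrix(values=values)
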