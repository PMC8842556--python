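import networkx as nx
import pandas as pd
import pytest

import rhcp


@pytest.fixture(scope="session")
def catalogue():
    return rhcp.load_catalogue("default")


@pytest.fixture(scope="session")
def small_fixture():
    """60 municipalities in 8 districts: fast enough for every unit test."""
    return rhcp.generate_country(seed=11, n_municipalities=60, n_districts=8)


@pytest.fixture(scope="session")
def medium_fixture():
    """300 municipalities in 20 districts (catchment-nesting scale)."""
    return rhcp.generate_country(seed=3, n_municipalities=300, n_districts=20)


@pytest.fixture(scope="session")
def full_fixture():
    """The national default scale: 2122 municipalities, 116 districts."""
    return rhcp.generate_country(seed=1)


@pytest.fixture(scope="session")
def small_engine(catalogue, small_fixture):
    return rhcp.ProfileEngine(catalogue, small_fixture)


@pytest.fixture(scope="session")
def small_profile(small_engine):
    return small_engine.build_profile(rhcp.ProfileRequest("M0005", 15.0, "D003"))


@pytest.fixture()
def line_network():
    """A - B (4 min) - C (5 min)."""
    edges = pd.DataFrame(
        {"from_id": ["A", "B"], "to_id": ["B", "C"], "minutes": [4.0, 5.0]}
    )
    return rhcp.build_network(edges)


@pytest.fixture()
def empty_facilities():
    return pd.DataFrame(columns=["facility_id", "facility_type", "municipality_id"])


def make_random_network(seed: int, n_nodes: int = 25, extra_edges: int = 30) -> nx.Graph:
    """Random connected network with integer minute weights.

    Integer weights keep shortest-path sums exactly representable, so
    different all-pairs algorithms must agree bit-for-bit.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    nodes = [f"N{i:02d}" for i in range(n_nodes)]
    rows = []
    for i in range(1, n_nodes):  # random spanning tree: connected by construction
        j = int(rng.integers(0, i))
        rows.append((nodes[i], nodes[j], float(rng.integers(1, 11))))
    for _ in range(extra_edges):
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            rows.append((nodes[int(i)], nodes[int(j)], float(rng.integers(1, 11))))
    edges = pd.DataFrame(rows, columns=["from_id", "to_id", "minutes"]).drop_duplicates(
        subset=["from_id", "to_id"]
    )
    return rhcp.build_network(edges, nodes)
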