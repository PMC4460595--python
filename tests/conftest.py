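import numpy as np
import pytest

import ppsnet as pn


def random_family(rng: np.random.Generator, n: int, edge_p: float = 0.3,
                  label: str = "fam", weight_scale: float = 1.0) -> pn.FamilyGraph:
    """Random weighted family graph on n vertices."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_p:
                w[i, j] = w[j, i] = weight_scale * (0.5 + rng.random())
    return pn.FamilyGraph(label, tuple(f"{label}_v{i}" for i in range(n)), w)


def random_attachment(rng: np.random.Generator, graph: pn.FamilyGraph,
                      edge_p: float = 0.5, weight_scale: float = 1.0,
                      query_id: str = "q") -> pn.QueryAttachment:
    vec = np.where(rng.random(graph.n_vertices) < edge_p,
                   weight_scale * (0.5 + rng.random(graph.n_vertices)), 0.0)
    return pn.QueryAttachment(query_id, vec)


@pytest.fixture
def clustered_hub() -> pn.FamilyGraph:
    return pn.fixture_clustered_hub()


@pytest.fixture
def star_vs_triangle():
    return pn.fixture_star_vs_triangle()


@pytest.fixture
def pyramid_demo():
    return pn.fixture_pyramid_demo()


@pytest.fixture(scope="session")
def small_benchmark():
    """Small separable synthetic benchmark shared across tests."""
    spec = pn.SimSpec(n_families=6, family_size=12, seed=7)
    table, members, queries = pn.simulate_score_network(spec)
    by_fam: dict[str, list[str]] = {}
    for sid, fam in members.items():
        by_fam.setdefault(fam, []).append(sid)
    model = pn.train(by_fam, table)
    return model, table, queries


@pytest.fixture(scope="session")
def full_benchmark():
    """The 20-family benchmark at the documented study conditions."""
    spec = pn.SimSpec(seed=1)
    table, members, queries = pn.simulate_score_network(spec)
    by_fam: dict[str, list[str]] = {}
    for sid, fam in members.items():
        by_fam.setdefault(fam, []).append(sid)
    model = pn.train(by_fam, table)
    return model, table, queries
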