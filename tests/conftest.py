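import numpy as np
import pytest

from seqspace import EdgeStore, make_world


@pytest.fixture(scope="session")
def world():
    """A small planted world shared by read-only tests."""
    return make_world(seed=11)


@pytest.fixture(scope="session")
def world_store(world, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("world_store")
    return EdgeStore.from_edges(
        world.edges, tmp / "edges.tsv", universe=[r.id for r in world.sequences]
    )


def random_edge_list(rng: np.random.Generator, n_nodes: int, n_edges: int):
    """Random weighted edges over node ids n0..n{n-1} (self-pairs excluded)."""
    ids = [f"n{i:05d}" for i in range(n_nodes)]
    edges = []
    seen = set()
    while len(edges) < n_edges:
        i, j = rng.integers(n_nodes, size=2)
        if i == j:
            continue
        a, b = (ids[i], ids[j]) if ids[i] < ids[j] else (ids[j], ids[i])
        if (a, b) in seen:
            continue
        seen.add((a, b))
        edges.append((a, b, float(rng.uniform(10, 300))))
    return ids, edges


@pytest.fixture
def make_store(tmp_path):
    counter = [0]

    def _make(ids, edges):
        counter[0] += 1
        return EdgeStore.from_edges(edges, tmp_path / f"edges{counter[0]}.tsv", universe=ids)

    return _make
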