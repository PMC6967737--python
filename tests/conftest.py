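import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcrwmda import SynthConfig, generate_dataset
from tcrwmda.io_formats import DiseaseDAG

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dag(root: str, edges: list[tuple[str, str]]) -> DiseaseDAG:
    """Build a DiseaseDAG from explicit child->parent edges (root included)."""
    g = nx.DiGraph()
    g.add_node(root)
    g.add_edges_from(edges)
    nodes = nx.descendants(g, root) | {root}
    return DiseaseDAG(root=root, graph=g.subgraph(nodes).copy())


@pytest.fixture(scope="session")
def default_bundle():
    """The default planted synthetic dataset (seed 1) plus its group map."""
    return generate_dataset(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """A smaller planted bundle for fast end-to-end checks."""
    return generate_dataset(
        SynthConfig(n_mirna=20, n_disease=15, n_lncrna=8, n_groups=3, seed=7)
    )


def random_rooted_dag(rng: np.random.Generator, n_nodes: int) -> DiseaseDAG:
    """Random DAG where every node is an ancestor of node '0' (the disease):
    node i >= 1 receives at least one child edge from some node j < i."""
    g = nx.DiGraph()
    names = [f"t{i}" for i in range(n_nodes)]
    g.add_node(names[0])
    for i in range(1, n_nodes):
        children = rng.choice(i, size=rng.integers(1, i + 1), replace=False)
        for j in children:
            g.add_edge(names[j], names[i])
    return DiseaseDAG(root=names[0], graph=g)
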