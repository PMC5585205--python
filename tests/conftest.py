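import networkx as nx
import numpy as np
import pytest

from omicnets import SimConfig, gen_expression, gen_interactome


@pytest.fixture(scope="session")
def small_expr():
    """Factorial expression matrix with planted clusters, desk scale."""
    cfg = SimConfig(seed=11, n_genes=60, cluster_effect=1.5)
    return gen_expression(cfg)


@pytest.fixture(scope="session")
def interactome():
    return gen_interactome(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def relabel(g: nx.Graph, prefix: str = "n") -> nx.Graph:
    return nx.relabel_nodes(g, {v: f"{prefix}{v}" for v in g.nodes()})
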