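import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirank.interactome import FF, PF, PP, Edge, build_interactome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_edges():
    """P1-P2-P3 protein triangle-free chain, one function pair F1->F2."""
    return {
        PP: [Edge("P1", "P2", PP), Edge("P2", "P3", PP)],
        PF: [Edge("P2", "F1", PF)],
        FF: [Edge("F1", "F2", FF)],
    }


@pytest.fixture
def toy_interactome(toy_edges):
    return build_interactome(toy_edges)


@pytest.fixture
def two_node_interactome():
    """Single undirected protein edge A-B."""
    return build_interactome({PP: [Edge("A", "B", PP)]})


def path_interactome(n):
    """Protein path P1-P2-...-Pn."""
    edges = [Edge(f"P{i}", f"P{i+1}", PP) for i in range(1, n)]
    return build_interactome({PP: edges})


def random_interactome(rng, n_proteins=50, n_functions=10, extra_edges=30):
    """Small random heterogeneous interactome for oracle comparisons."""
    pp = [Edge(f"P{i}", f"P{i+1}", PP) for i in range(n_proteins - 1)]
    for _ in range(extra_edges):
        i, j = rng.integers(n_proteins, size=2)
        if i != j:
            pp.append(Edge(f"P{i}", f"P{j}", PP))
    ff = [
        Edge(f"F{i}", f"F{(i - 1) // 2}", FF) for i in range(1, n_functions)
    ]
    pf = []
    for i in range(n_proteins):
        if rng.random() < 0.5:
            pf.append(Edge(f"P{i}", f"F{rng.integers(n_functions)}", PF))
    colls = {PP: pp, FF: ff}
    if pf:
        colls[PF] = pf
    return build_interactome(colls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
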