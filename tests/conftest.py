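import numpy as np
import pandas as pd
import pytest

from netprog.network import column_normalize, from_edges
from netprog.seeds import MutationCatalog, SignatureCollection, compute_start_probabilities


@pytest.fixture
def path_graph():
    """A - B - C path, normalized."""
    return column_normalize(from_edges([("A", "B"), ("B", "C")]))


@pytest.fixture
def two_node():
    return column_normalize(from_edges([("A", "B")]))


def random_connected_network(n, rng, extra_edges=None):
    """Random spanning tree plus extra random edges: connected by design."""
    names = [f"N{i:03d}" for i in range(n)]
    edges = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.append((names[j], names[i]))
    extra = extra_edges if extra_edges is not None else n
    for _ in range(extra):
        a, b = rng.choice(n, size=2, replace=False)
        edges.append((names[int(a)], names[int(b)]))
    return column_normalize(from_edges(edges))


def random_p0(network, rng, n_seeds=None):
    n = network.n_nodes
    k = n_seeds or max(2, n // 5)
    p = np.zeros(n)
    idx = rng.choice(n, size=k, replace=False)
    p[idx] = rng.uniform(0.1, 1.0, size=k)
    p /= p.sum()
    from netprog.seeds import StartProbabilityVector

    return StartProbabilityVector(p0=p, nodes=list(network.nodes), n=n)


@pytest.fixture
def abcd_network():
    """4-node network with evidence used in the start-probability examples."""
    net = column_normalize(
        from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")])
    )
    sigs = SignatureCollection({"s1": {"A", "B"}, "s2": {"A"}})
    muts = MutationCatalog({"C": 3})
    return net, sigs, muts


def make_clinical(time, event, stage=None, ctx=None, age=None, gender=None, prefix="S"):
    n = len(time)
    idx = pd.Index([f"{prefix}{i:03d}" for i in range(n)], name="sample")
    return pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int),
            "stage": stage if stage is not None else ["III"] * n,
            "age": age if age is not None else [60.0] * n,
            "gender": gender if gender is not None else ["F"] * n,
            "ctx": ctx if ctx is not None else [1] * n,
        },
        index=idx,
    )
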