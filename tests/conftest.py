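import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_balanced_table() -> pd.DataFrame:
    """3 lines x 2 treatments x 2 reps built so the ANOVA solutions are integers.

    Cell means chosen so MS_E = 2, MS_LT = 4, MS_L = 12, hence
    s2_e = 2, s2_LT = 1, s2_L = 2 and H2 = 0.6 exactly.
    """
    cells = {
        ("regular", "A"): 10, ("regular", "B"): 12, ("regular", "C"): 14,
        ("ethanol", "A"): 12, ("ethanol", "B"): 16, ("ethanol", "C"): 14,
    }
    rows = []
    for (t, l), m in cells.items():
        rows += [(l, t, "NA", 1, m - 1.0), (l, t, "NA", 2, m + 1.0)]
    return pd.DataFrame(rows, columns=["line", "treatment", "sex", "replicate", "value"])


@pytest.fixture(scope="session")
def small_panel():
    """A small but complete synthetic panel shared by I/O and pipeline tests."""
    from ethodev import synthdata

    cfg = synthdata.viability_config(
        n_lines=60, n_variants=400, n_genes=120, network_n_nodes=120,
        network_n_edges=150, embedded_cluster_size=10, n_causal=3,
        genome_length=6_000_000, seed=7,
    )
    return synthdata.simulate_panel(cfg)


def brute_force_subnetwork(graph: nx.Graph, candidates):
    """Independent one-bridge oracle by exhaustive candidate-pair enumeration.

    For every unordered candidate pair (a, b): keep the direct edge a-b if
    present, and for every common neighbour w outside the candidate set keep
    the path edges a-w and w-b.  Returns (edge set, recruited set,
    largest component node count).
    """
    from itertools import combinations

    cand = [c for c in candidates if c in graph]
    edges, recruited = set(), set()
    for a, b in combinations(sorted(cand), 2):
        if graph.has_edge(a, b):
            edges.add(tuple(sorted((a, b))))
        for w in set(graph.neighbors(a)) & set(graph.neighbors(b)):
            if w not in candidates:
                recruited.add(w)
                edges.add(tuple(sorted((a, w))))
                edges.add(tuple(sorted((w, b))))
    sub = nx.Graph(list(edges))
    largest = max((len(c) for c in nx.connected_components(sub)), default=0)
    return edges, recruited, largest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
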