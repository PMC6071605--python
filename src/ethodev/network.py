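"""Candidate-gene subnetwork extraction and largest-cluster randomization test.

Candidate genes from the association stage are mapped onto a global curated
gene-gene interaction network.  The extracted subnetwork keeps (a) every
direct interaction between two candidates and (b) every non-candidate
"bridge" gene that interacts with at least two distinct candidates, together
with its edges to those candidates — the one-bridge rule: every retained
edge lies on a candidate-candidate or candidate-bridge-candidate path.
Bridge genes are the computationally recruited genes.  Significance of the
largest connected cluster is assessed by re-running the extraction on random
gene sets of the same size: the empirical p-value is the fraction of
randomizations whose largest cluster strictly exceeds the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ConfigError, DataError

NULL_MODELS = ("uniform_nodes", "degree_matched")


@dataclass
class SubnetworkResult:
    """Extracted subnetwork plus (optionally) its randomization record."""

    graph: nx.Graph
    candidates: set[str]          # candidate genes present in the global graph
    recruited: set[str]           # bridge genes pulled in by the one-bridge rule
    unmatched: list[str]          # requested candidate ids absent from the graph
    largest_cluster_size: int
    components: list[list[str]] = field(default_factory=list)
    degrees: dict[str, int] = field(default_factory=dict)
    permutation: dict | None = None

    @property
    def candidate_in_graph(self) -> set[str]:
        return self.candidates & set(self.graph.nodes)

    def node_table(self):
        import pandas as pd

        rows = [
            (n, "candidate" if n in self.candidates else "recruited", d)
            for n, d in sorted(self.degrees.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "role", "degree"])


def _adjacency(graph: nx.Graph) -> dict[str, set]:
    return {n: set(graph.neighbors(n)) for n in graph.nodes}


def _extract_core(adj: dict[str, set], cand: set) -> tuple[list[tuple], set]:
    """One-bridge extraction on an adjacency-set map; returns (edges, recruited)."""
    edges = []
    for u in cand:
        for v in adj.get(u, ()):
            if v in cand and u < v:
                edges.append((u, v))
    counts: dict[str, list] = {}
    for u in cand:
        for v in adj.get(u, ()):
            if v not in cand:
                counts.setdefault(v, []).append(u)
    recruited = set()
    for v, us in counts.items():
        if len(set(us)) >= 2:
            recruited.add(v)
            edges.extend((v, u) for u in set(us))
    return edges, recruited


def _largest_component_size(edges: list[tuple]) -> int:
    """Node count of the largest connected component of the edge-induced graph."""
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    if not parent:
        return 0
    sizes: dict = {}
    for x in parent:
        r = find(x)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values())


def extract_subnetwork(global_graph: nx.Graph, candidates) -> SubnetworkResult:
    """Extract the direct + one-bridge subnetwork induced by a candidate set.

    Only nodes incident to a retained edge appear in the extracted graph;
    candidates with no connection drop out (they still count as matched
    candidates for the randomization null).  Candidate ids absent from the
    global graph are recorded in ``unmatched``.
    """
    candidates = set(candidates)
    if not candidates:
        raise DataError("candidate set is empty")
    nodes = set(global_graph.nodes)
    matched = candidates & nodes
    unmatched = sorted(candidates - nodes)
    adj = _adjacency(global_graph)
    edges, recruited = _extract_core(adj, matched)

    sub = nx.Graph()
    sub.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(sub)]
    comps.sort(key=lambda c: (-len(c), c))
    return SubnetworkResult(
        graph=sub,
        candidates=matched,
        recruited=recruited,
        unmatched=unmatched,
        largest_cluster_size=max((len(c) for c in comps), default=0),
        components=comps,
        degrees=dict(sub.degree()),
    )


def randomization_test(
    global_graph: nx.Graph,
    candidates,
    n_randomizations: int = 1000,
    null_model: str = "uniform_nodes",
    seed: int = 0,
) -> SubnetworkResult:
    """Largest-cluster significance against random same-size gene sets.

    Draws ``n_randomizations`` gene sets of the matched-candidate size from
    the global node set (``uniform_nodes``: uniformly without replacement;
    ``degree_matched``: one node per candidate from log2-degree bins), runs
    the one-bridge extraction on each, and counts draws whose largest
    cluster strictly exceeds the observed size.  Reports the literal
    empirical p = count/n and the add-one corrected (count+1)/(n+1).
    """
    if null_model not in NULL_MODELS:
        raise ConfigError(f"null_model must be one of {NULL_MODELS}")
    if n_randomizations < 1:
        raise ConfigError("n_randomizations must be >= 1")
    if len(set(candidates)) > global_graph.number_of_nodes():
        raise ConfigError("more candidates than nodes in the global graph")
    result = extract_subnetwork(global_graph, candidates)
    k = len(result.candidates)
    nodes = sorted(global_graph.nodes)
    if k == 0:
        raise DataError("no candidate matched the global graph")

    adj = _adjacency(global_graph)
    rng = np.random.default_rng(seed)
    observed = result.largest_cluster_size

    if null_model == "degree_matched":
        deg = dict(global_graph.degree())
        bins: dict[int, list] = {}
        for n in nodes:
            bins.setdefault(int(np.log2(deg[n] + 1)), []).append(n)
        cand_bins = [int(np.log2(deg[c] + 1)) for c in sorted(result.candidates)]

    sizes = np.empty(n_randomizations, dtype=int)
    for i in range(n_randomizations):
        if null_model == "uniform_nodes":
            draw = set(rng.choice(len(nodes), size=k, replace=False))
            sample = {nodes[j] for j in draw}
        else:
            sample = set()
            for b in cand_bins:
                pool = bins[b]
                sample.add(pool[int(rng.integers(len(pool)))])
        edges, _ = _extract_core(adj, sample)
        sizes[i] = _largest_component_size(edges)

    count = int((sizes > observed).sum())
    result.permutation = {
        "n_randomizations": int(n_randomizations),
        "null_model": null_model,
        "seed": int(seed),
        "observed_largest_cluster": int(observed),
        "count_exceeding": count,
        "p_value": count / n_randomizations,
        "p_value_add_one": (count + 1) / (n_randomizations + 1),
        "null_sizes": sizes.tolist(),
    }
    return result


def hub_ranking(result: SubnetworkResult, top_k: int | None = None):
    """Genes of the extracted subnetwork ordered by degree (ties: lexicographic).

    Carries candidate/recruited status; the top entry is the network's hub
    gene.  ``top_k`` truncates the list.
    """
    import pandas as pd

    if result.graph.number_of_nodes() == 0:
        raise DataError("extracted subnetwork is empty")
    tbl = result.node_table().sort_values(
        ["degree", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return tbl.head(top_k) if top_k else tbl


def degree_filter(result: SubnetworkResult, min_degree: int) -> nx.Graph:
    """Single-pass removal of extracted-graph nodes with degree < min_degree.

    Display-oriented: no iterative re-pruning, so surviving nodes may drop
    below the cutoff once their low-degree neighbours are gone.
    """
    if min_degree < 0:
        raise ConfigError("min_degree must be >= 0")
    keep = [n for n, d in result.graph.degree() if d >= min_degree]
    return result.graph.subgraph(keep).copy()
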