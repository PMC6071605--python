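#!/usr/bin/env python
"""Map candidate genes onto the interaction network and test cluster size.

Extracts the direct + one-bridge subnetwork around the GWAS candidate
genes, ranks hubs, applies the display degree filter (>=3 interactions),
and evaluates the largest cluster against 1,000 random same-size gene sets.
"""

import argparse
import json
from pathlib import Path

from ethodev import io, network


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--nperm", type=int, default=1000)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    panel_dir = args.results / "panel"
    out = args.results / "network"
    out.mkdir(parents=True, exist_ok=True)

    graph = io.read_edge_list(panel_dir / "network.tsv")
    cand = io.read_candidates(args.results / "assoc" / "candidate_genes.txt")
    res = network.randomization_test(graph, cand, n_randomizations=args.nperm,
                                     seed=args.seed)
    perm = res.permutation
    print(f"{len(cand)} candidate genes ({len(res.unmatched)} unmatched in graph); "
          f"subnetwork: {res.graph.number_of_nodes()} interconnected genes = "
          f"{len(res.candidate_in_graph)} candidate + {len(res.recruited)} recruited")
    print(f"largest cluster {perm['observed_largest_cluster']} genes; "
          f"p = {perm['p_value']:.4g} (add-one {perm['p_value_add_one']:.4g}) "
          f"over {args.nperm} randomizations")

    io.write_edge_list(out / "subnetwork_edges.tsv", res.graph)
    res.node_table().to_csv(out / "subnetwork_nodes.tsv", sep="\t", index=False)
    io.write_graphml(out / "subnetwork.graphml", res.graph)
    with open(out / "permutation.json", "w") as fh:
        json.dump(perm, fh, indent=1, sort_keys=True)
    if res.graph.number_of_nodes():
        hubs = network.hub_ranking(res)
        hubs.to_csv(out / "hub_ranking.tsv", sep="\t", index=False)
        top = hubs.iloc[0]
        print(f"hub gene: {top['gene']} ({top['role']}) with {top['degree']} interactions")
        filtered = network.degree_filter(res, 3)
        io.write_edge_list(out / "subnetwork_min_degree3.tsv", filtered)
        print(f"display filter (>=3 interactions): {filtered.number_of_nodes()} genes")


if __name__ == "__main__":
    main()
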