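#!/usr/bin/env python
"""Generate the synthetic study panels.

Writes a full viability panel (phenotypes, genotypes as TSV + VCF, gene
models, interaction network, truth record) plus replicate phenotype tables
for development time and the sexed locomotion assay, all at the study's
design: 200 lines x 2 media x 5 vials (39 lines x 20 replicates x 2 sexes
for locomotion).
"""

import argparse
from pathlib import Path

from ethodev import io, synthdata


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    panel_dir = args.results / "panel"
    cfg = synthdata.viability_config(seed=args.seed)
    panel = synthdata.simulate_panel(cfg)
    panel.write(panel_dir)
    print(f"viability panel: {cfg.n_lines} lines, {cfg.n_variants} variants, "
          f"{panel.network.number_of_edges()} interaction edges -> {panel_dir}")
    print(f"  planted: {len(panel.truth['causal_variants'])} causal variants in "
          f"{len(panel.truth['embedded_cluster'])}-gene module")

    dev = synthdata.simulate_phenotypes(
        synthdata.development_time_config(seed=args.seed + 1))
    io.write_phenotypes(panel_dir / "phenotypes_devtime.tsv", dev)
    loc = synthdata.simulate_phenotypes(
        synthdata.locomotion_config(seed=args.seed + 2))
    io.write_phenotypes(panel_dir / "phenotypes_locomotion.tsv", loc)
    print(f"development-time table ({len(dev)} rows) and sexed locomotion table "
          f"({len(loc)} rows) written")


if __name__ == "__main__":
    main()
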