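#!/usr/bin/env python
"""Partition phenotypic variance and estimate broad-sense heritability.

Fits the full factorial mixed model (and per-condition reduced models) to
each simulated trait, reports variance components, H2 and term p-values,
and summarises per-line ethanol sensitivity.
"""

import argparse
import json
from pathlib import Path

from ethodev import io, quantgen


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    panel_dir = args.results / "panel"

    rows = []
    summary_out = {}
    traits = {
        "viability": (panel_dir / "phenotypes.tsv", "full"),
        "development_time": (panel_dir / "phenotypes_devtime.tsv", "full"),
        "locomotion": (panel_dir / "phenotypes_locomotion.tsv", "sexed_full"),
    }
    for trait, (path, model) in traits.items():
        table = io.read_phenotypes(path)
        vd = quantgen.fit_variance_components(table, model)
        summary_out[trait] = {"full": vd.to_dict()}
        comp = "  ".join(f"s2_{k}={v:.4g}" for k, v in vd.components.items())
        print(f"{trait} ({model}): H2 = {vd.H2:.3f}   {comp}")
        print(f"  term p-values: " + "  ".join(f"{k}={v:.3g}" for k, v in vd.p_values.items()))
        rows.append({"trait": trait, "model": model, "H2": vd.H2, **{
            f"sigma2_{k}": v for k, v in vd.components.items()}})
        for cond in table["treatment"].unique():
            red = quantgen.fit_variance_components(
                table[table["treatment"] == cond],
                "sexed_reduced" if model.startswith("sexed") else "reduced")
            summary_out[trait][f"reduced_{cond}"] = red.to_dict()
            print(f"  {cond} only: H2 = {red.H2:.3f}")
        if model == "full":
            summ = quantgen.line_summaries(table)
            print(f"  sensitivity: mean {summ['sensitivity'].mean():+.3f}, range "
                  f"[{summ['sensitivity'].min():.3f}, {summ['sensitivity'].max():.3f}], "
                  f"{int(summ['excluded'].sum())} lines excluded")

    import pandas as pd

    pd.DataFrame(rows).to_csv(args.results / "heritability.tsv", sep="\t", index=False)
    with open(args.results / "variance_components.json", "w") as fh:
        json.dump(summary_out, fh, indent=1, sort_keys=True)
    print(f"-> {args.results}/heritability.tsv, variance_components.json")


if __name__ == "__main__":
    main()
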