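#!/usr/bin/env python
"""Line-mean GWAS for viability on each medium and for ethanol sensitivity.

Filters variants at MAF >= 0.05, regresses line means on minor-allele
counts, takes hits at the nominal (1e-5) and relaxed (5e-5) thresholds,
annotates them against the gene models (+/-1 kb), and writes the candidate
gene union that seeds the network stage.
"""

import argparse
from pathlib import Path

from ethodev import gwa, io, quantgen
from ethodev.pipeline import _field_series


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    panel_dir = args.results / "panel"
    out = args.results / "assoc"
    out.mkdir(parents=True, exist_ok=True)

    geno = gwa.maf_filter(io.read_genotypes(panel_dir / "genotypes.vcf"), 0.05)
    flt = geno.variants.attrs["maf_filter"]
    print(f"MAF filter: kept {flt['kept']} / dropped {flt['dropped']} variants")
    genes = io.read_gene_models(panel_dir / "gene_models.bed")
    summ = quantgen.line_summaries(io.read_phenotypes(panel_dir / "phenotypes.tsv"))

    truth_causal = set()
    truth_file = panel_dir / "truth.json"
    if truth_file.exists():
        import json
        truth_causal = set(json.loads(truth_file.read_text())["causal_variants"])

    union = set()
    for fld in ("regular", "ethanol", "sensitivity"):
        rec = gwa.associate(geno, _field_series(summ, fld), phenotype=f"viability_{fld}")
        rec.to_csv(out / f"assoc_viability_{fld}.tsv", sep="\t", index=False)
        for tag, alpha in (("primary", 1e-5), ("relaxed", 5e-5)):
            hits = gwa.annotate_variants(gwa.threshold_hits(rec, alpha), genes, 1000)
            hits.to_csv(out / f"hits_viability_{fld}_{tag}.tsv", sep="\t", index=False)
            ng = hits.attrs["n_distinct_genes"]
            recov = len(set(hits["id"]) & truth_causal)
            print(f"viability_{fld} @ p<{alpha:g}: {len(hits)} variants in/near {ng} genes"
                  f" ({recov} planted causal among hits)")
            if tag == "relaxed":
                union.update(gwa.distinct_genes(hits))
    io.write_candidates(out / "candidate_genes.txt", union)
    print(f"candidate union across phenotypes: {len(union)} genes -> {out}/candidate_genes.txt")


if __name__ == "__main__":
    main()
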