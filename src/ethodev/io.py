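"""Readers and writers for the pipeline's plain-text formats.

Phenotypes and line means travel as TSV; genotypes as either a simple TSV
matrix (rows = variants, columns = lines) or a minimal VCF with homozygous
genotypes; gene models as BED (0-based half-open) or GFF3 (converted on
read); interaction networks as two-column edge lists, with GraphML export
for viewers.  Every writer here round-trips through its reader.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError, SchemaError
from .gwa import GeneModelSet, GenotypeMatrix

# -- phenotypes --------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    from .quantgen import validate_replicate_table

    df = pd.read_csv(path, sep="\t")
    return validate_replicate_table(df)


def write_phenotypes(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


# -- genotypes: TSV matrix ---------------------------------------------------

def write_genotype_tsv(path, geno: GenotypeMatrix) -> None:
    df = geno.variants[["id", "chrom", "pos", "ref", "alt"]].copy()
    calls = pd.DataFrame(geno.calls, columns=geno.lines)
    pd.concat([df, calls], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA",
                                          float_format="%g")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    meta_cols = ["id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"genotype TSV missing columns: {missing}")
    lines = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        variants=df[meta_cols].copy(),
        calls=df[lines].to_numpy(dtype=float),
        lines=lines,
    )


# -- genotypes: VCF ----------------------------------------------------------

def write_vcf(path, geno: GenotypeMatrix) -> None:
    """Minimal VCF 4.2 with homozygous GT calls (0/0, 1/1 or ./.)."""
    geno = geno.sorted()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(geno.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.lines) + "\n")
        code = {0.0: "0/0", 2.0: "1/1"}
        for i, rec in enumerate(geno.variants.itertuples()):
            gts = "\t".join(
                "./." if np.isnan(c) else code[c] for c in geno.calls[i]
            )
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.ref}\t{rec.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read homozygous biallelic calls from a VCF via cyvcf2.

    Heterozygous calls are rejected (inbred panels are homozygous by
    construction); multi-allelic records raise an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise DataError(f"multi-allelic record at {rec.CHROM}:{rec.POS}")
        gt = rec.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        if (gt == 1).any():
            raise DataError(f"heterozygous call at {rec.CHROM}:{rec.POS}")
        calls = np.where(gt == 0, 0.0, np.where(gt == 3, 2.0, np.nan))
        ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(calls)
    variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss,
                             "ref": refs, "alt": alts})
    return GenotypeMatrix(variants=variants,
                          calls=np.array(rows) if rows else np.empty((0, len(lines))),
                          lines=lines)


def read_genotypes(path) -> GenotypeMatrix:
    """Dispatch on extension: .vcf via cyvcf2, anything else as TSV matrix."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    return read_genotype_tsv(path)


# -- gene models -------------------------------------------------------------

def write_bed(path, genes: GeneModelSet) -> None:
    df = genes.genes
    bed = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": df["id"], "score": 0,
        "strand": df.get("strand", pd.Series(["+"] * len(df))),
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> GeneModelSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise SchemaError("BED gene models need >=4 columns (chrom start end name)")
    genes = pd.DataFrame({
        "id": df[3], "chrom": df[0].astype(str),
        "start": df[1].astype(int), "end": df[2].astype(int),
        "strand": df[5] if df.shape[1] > 5 else "+",
    })
    return GeneModelSet(genes=genes[["id", "chrom", "start", "end", "strand"]])


def read_gff3(path, feature: str = "gene") -> GeneModelSet:
    """Extract gene intervals from GFF3; 1-based closed input -> 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"])
    df = df[df["type"] == feature]
    if df.empty:
        raise SchemaError(f"no {feature!r} features in GFF3")

    def get_id(attrs: str) -> str:
        for part in attrs.split(";"):
            if part.startswith("ID="):
                return part[3:]
        raise SchemaError(f"GFF3 attribute column without ID=: {attrs!r}")

    genes = pd.DataFrame({
        "id": df["attributes"].map(get_id),
        "chrom": df["chrom"].astype(str),
        "start": df["start"].astype(int) - 1,
        "end": df["end"].astype(int),
        "strand": df["strand"],
    })
    return GeneModelSet(genes=genes.reset_index(drop=True))


def read_gene_models(path) -> GeneModelSet:
    if str(path).endswith((".gff", ".gff3")):
        return read_gff3(path)
    return read_bed(path)


# -- interaction network -----------------------------------------------------

def write_edge_list(path, graph: nx.Graph) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path) -> nx.Graph:
    """Two-column TSV (optional provenance column); collapsed to an undirected
    simple graph: duplicate and reversed records merge, self-loops drop."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise SchemaError("edge list needs two gene-id columns")
    g = nx.Graph()
    a, b = df.columns[:2]
    for u, v in zip(df[a].astype(str), df[b].astype(str)):
        if u != v:
            g.add_edge(u, v)
    return g


def write_graphml(path, graph: nx.Graph) -> None:
    nx.write_graphml(graph, str(path))


def read_candidates(path) -> list[str]:
    ids = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [i for i in ids if i and not i.startswith("#")]


def write_candidates(path, ids) -> None:
    Path(path).write_text("\n".join(sorted(set(ids))) + "\n")
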