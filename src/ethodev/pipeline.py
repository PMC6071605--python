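"""End-to-end driver: variance partitioning -> line-mean GWAS -> subnetwork.

``run_pipeline`` chains the analytic stages on files already on disk,
writing every intermediate table plus a JSON manifest of counts at each
filtering step.  All randomness (the subnetwork randomization test) flows
from the single configured seed, so a rerun with the same config and seed
is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import gwa, io, network, quantgen
from .errors import ConfigError

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    ``phenotypes`` maps trait name -> replicate-level TSV.  ``alpha`` is the
    primary nominal association threshold, ``alpha_relaxed`` the threshold
    whose in-or-near genes seed the network stage (candidate lists are
    unioned over traits and phenotype fields).
    """

    phenotypes: dict[str, str]
    genotypes: str
    gene_models: str
    network: str
    out_dir: str
    covariates: str | None = None
    maf_threshold: float = gwa.DEFAULT_MAF
    alpha: float = gwa.DEFAULT_ALPHA
    alpha_relaxed: float = gwa.RELAXED_ALPHA
    annotation_window: int = gwa.DEFAULT_WINDOW
    n_randomizations: int = 1000
    null_model: str = "uniform_nodes"
    min_degree: int = 3
    min_class_lines: int = gwa.MIN_CLASS_LINES
    min_lines: int = 20
    seed: int = 0
    fields: tuple = ("regular", "ethanol", "sensitivity")

    def __post_init__(self):
        if not 0 <= self.maf_threshold <= 0.5:
            raise ConfigError("maf_threshold must be in [0, 0.5]")
        for a in (self.alpha, self.alpha_relaxed):
            if not 0 < a < 1:
                raise ConfigError("alpha levels must be in (0, 1)")
        if self.annotation_window < 0 or self.n_randomizations < 1:
            raise ConfigError("annotation_window >= 0 and n_randomizations >= 1 required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "fields" in raw:
            raw["fields"] = tuple(raw["fields"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(asdict(self), sort_keys=True)


def _field_series(summary: pd.DataFrame, fld: str,
                  treatments=quantgen.TREATMENTS) -> pd.Series:
    base, alt = treatments
    col = {"regular": f"mean_{base}", "ethanol": f"mean_{alt}",
           "sensitivity": "sensitivity"}.get(fld, fld)
    return summary.set_index("line")[col]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }

    # --- stage 1: quantitative genetics ------------------------------------
    summaries: dict[str, pd.DataFrame] = {}
    vc_out: dict[str, dict] = {}
    for trait, path in config.phenotypes.items():
        table = io.read_phenotypes(path)
        sexed = table["sex"].nunique() > 1
        full = quantgen.fit_variance_components(
            table, "sexed_full" if sexed else "full")
        vc_out[trait] = {"full": full.to_dict()}
        for cond in table["treatment"].unique():
            sub = table[table["treatment"] == cond]
            red = quantgen.fit_variance_components(
                sub, "sexed_reduced" if sexed else "reduced")
            vc_out[trait][f"reduced_{cond}"] = red.to_dict()
        summ = quantgen.line_summaries(table)
        summaries[trait] = summ
        summ.to_csv(out / f"line_summary_{trait}.tsv", sep="\t", index=False)
        manifest["stages"][f"quantgen_{trait}"] = {
            "n_lines": int(summ.shape[0]),
            "n_excluded": int(summ["excluded"].sum()),
            "H2_full": full.H2,
        }
    with open(out / "variance_components.json", "w") as fh:
        json.dump(vc_out, fh, indent=1, sort_keys=True)
    quantgen.write_line_means_table(out / "line_means.tsv", summaries)

    # --- stage 2: association ----------------------------------------------
    geno = io.read_genotypes(config.genotypes)
    genes = io.read_gene_models(config.gene_models)
    geno_f = gwa.maf_filter(geno, config.maf_threshold)
    manifest["stages"]["maf_filter"] = geno_f.variants.attrs["maf_filter"]
    covar = None
    if config.covariates:
        covar = pd.read_csv(config.covariates, sep="\t", index_col=0)

    candidate_union: set[str] = set()
    assoc_counts = {}
    for trait, summ in summaries.items():
        for fld in config.fields:
            y = _field_series(summ, fld)
            records = gwa.associate(
                geno_f, y, phenotype=f"{trait}_{fld}", covariates=covar,
                min_class_lines=config.min_class_lines, min_lines=config.min_lines,
            )
            records.to_csv(out / f"assoc_{trait}_{fld}.tsv", sep="\t", index=False)
            entry = {"n_tested": int((records["flag"] != "degenerate").sum())}
            for tag, a in (("primary", config.alpha), ("relaxed", config.alpha_relaxed)):
                hits = gwa.threshold_hits(records, a)
                hits = gwa.annotate_variants(hits, genes, config.annotation_window)
                hits.to_csv(out / f"hits_{trait}_{fld}_{tag}.tsv", sep="\t", index=False)
                hit_genes = gwa.distinct_genes(hits)
                entry[tag] = {"alpha": a, "n_hits": int(len(hits)),
                              "n_genes": len(hit_genes)}
                if tag == "relaxed":
                    candidate_union.update(hit_genes)
            assoc_counts[f"{trait}_{fld}"] = entry
    manifest["stages"]["association"] = assoc_counts
    io.write_candidates(out / "candidate_genes.txt", candidate_union)
    manifest["stages"]["candidates"] = {"n_genes": len(candidate_union)}

    # --- stage 3: network ----------------------------------------------------
    global_graph = io.read_edge_list(config.network)
    if candidate_union:
        result = network.randomization_test(
            global_graph, candidate_union,
            n_randomizations=config.n_randomizations,
            null_model=config.null_model, seed=config.seed,
        )
        io.write_edge_list(out / "subnetwork_edges.tsv", result.graph)
        result.node_table().to_csv(out / "subnetwork_nodes.tsv", sep="\t", index=False)
        io.write_graphml(out / "subnetwork.graphml", result.graph)
        filtered = network.degree_filter(result, config.min_degree)
        io.write_edge_list(out / "subnetwork_filtered_edges.tsv", filtered)
        perm = {k: v for k, v in result.permutation.items() if k != "null_sizes"}
        with open(out / "permutation.json", "w") as fh:
            json.dump(result.permutation, fh, indent=1, sort_keys=True)
        hubs = network.hub_ranking(result) if result.graph.number_of_nodes() else None
        if hubs is not None:
            hubs.to_csv(out / "hub_ranking.tsv", sep="\t", index=False)
        manifest["stages"]["network"] = {
            "n_global_nodes": global_graph.number_of_nodes(),
            "n_global_edges": global_graph.number_of_edges(),
            "n_candidates_matched": len(result.candidates),
            "n_candidates_unmatched": len(result.unmatched),
            "n_interconnected": result.graph.number_of_nodes(),
            "n_candidate_in_subnetwork": len(result.candidate_in_graph),
            "n_recruited": len(result.recruited),
            "largest_cluster_size": result.largest_cluster_size,
            "n_nodes_degree_filtered": filtered.number_of_nodes(),
            "permutation": perm,
        }
    else:
        manifest["stages"]["network"] = {"skipped": "no candidate genes"}

    _check_manifest(manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _check_manifest(manifest: dict) -> None:
    """Internal consistency of stage counts (hits <= tested, matched <= candidates)."""
    st = manifest["stages"]
    for key, entry in st.get("association", {}).items():
        for tag in ("primary", "relaxed"):
            assert entry[tag]["n_hits"] <= entry["n_tested"], (key, tag)
    net = st.get("network", {})
    if "n_candidates_matched" in net:
        assert net["n_candidates_matched"] <= st["candidates"]["n_genes"]
        assert net["n_candidate_in_subnetwork"] + net["n_recruited"] \
            == net["n_interconnected"]
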