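"""Synthetic inbred-line panels: phenotypes, genotypes, gene models, networks.

The generator emulates the data layout of a fully inbred reference panel
phenotyped on two rearing media: ~200 lines, five replicate vials per line
and condition (twenty per sex and condition for the sexed locomotion assay),
biallelic homozygous genotypes with a configurable minor-allele-frequency
spectrum, gene models tiled over a small genome, and a sparse degree-
heterogeneous gene-gene interaction network with an embedded connected
cluster of interacting genes.  Replicate phenotypes follow the factorial
mixed model

    Y = mu + T + L + LxT + e     (optionally + S + LxS + LxTxS when sexed)

with every random term drawn as an independent zero-mean normal at its
configured variance.  All draws flow from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .quantgen import REPLICATE_COLUMNS, TREATMENTS

CHROM_ARMS = ("2L", "2R", "3L", "3R", "X")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic panel; defaults emulate the viability assay.

    Variances are in squared phenotype units.  ``treatment_effect`` is the
    ethanol-minus-regular shift of the grand mean (applied as +/- half around
    ``grand_mean``), so the two condition means are grand_mean -/+ effect/2.
    """

    n_lines: int = 200
    n_replicates: int = 5
    treatments: tuple[str, str] = TREATMENTS
    with_sex: bool = False
    grand_mean: float = 0.36
    treatment_effect: float = -0.32
    sex_effect: float = 0.0
    sigma2_L: float = 0.009
    sigma2_LT: float = 0.0085
    sigma2_LS: float = 0.0
    sigma2_LTS: float = 0.0
    sigma2_eps: float = 0.0149
    # genotypes
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    maf_mode: str = "sampling"  # or "balanced": exact carrier counts
    n_causal: int = 5
    causal_effect: float = 0.12  # phenotype units per minor allele
    causal_on: str = "interaction"  # "mean" | "interaction": which term carries it
    # gene models / genome
    n_genes: int = 1000
    genome_length: int = 100_000_000
    gene_length: int = 5000
    # interaction network
    network_n_nodes: int = 1000
    network_n_edges: int = 1200
    embedded_cluster_size: int = 20
    #: clip phenotype draws to [0, 1] (latent-normal viability); default off so
    #: the ANOVA variance components stay exactly the configured ones
    truncate_unit_interval: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma2_L", "sigma2_LT", "sigma2_LS", "sigma2_LTS", "sigma2_eps"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be a finite non-negative variance, got {v}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_causal > self.n_variants:
            raise ConfigError("n_causal cannot exceed n_variants")
        if self.embedded_cluster_size > self.network_n_nodes:
            raise ConfigError("embedded_cluster_size cannot exceed network_n_nodes")
        if self.network_n_nodes > self.n_genes:
            raise ConfigError("network nodes are gene ids; need network_n_nodes <= n_genes")
        if len(self.treatments) != 2:
            raise ConfigError("exactly two treatments expected")
        if self.n_lines < 1 or self.n_replicates < 1:
            raise ConfigError("n_lines and n_replicates must be >= 1")

    def line_ids(self) -> list[str]:
        return [f"line_{i:03d}" for i in range(1, self.n_lines + 1)]

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]


def viability_config(**overrides) -> SimulationConfig:
    """Egg-to-adult viability study conditions: proportion scale, 52%/20% condition means."""
    return SimulationConfig(**overrides)


def development_time_config(**overrides) -> SimulationConfig:
    """Mean-eclosion-day study conditions: 9.3 d regular, 9.9 d on ethanol, H2 ~ 0.3."""
    base = dict(
        grand_mean=9.6, treatment_effect=0.6,
        sigma2_L=0.06, sigma2_LT=0.04, sigma2_eps=0.2333,
        causal_effect=0.35,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def locomotion_config(**overrides) -> SimulationConfig:
    """Sexed startle-response study conditions: 39 lines, 20 replicates/sex/condition, H2 ~ 0.64."""
    base = dict(
        n_lines=39, n_replicates=20, with_sex=True,
        grand_mean=25.0, treatment_effect=-5.0, sex_effect=0.0,
        sigma2_L=30.0, sigma2_LT=10.0, sigma2_LS=5.0, sigma2_LTS=5.0,
        sigma2_eps=28.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    line_shift: dict[str, float] | None = None,
    line_treatment_shift: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Draw a balanced replicate-level phenotype table under the factorial model.

    ``line_shift`` / ``line_treatment_shift`` add a fixed per-line offset to
    the line effect / to the second-treatment line effect; the panel
    orchestrator uses them to couple phenotypes to causal genotypes.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lines = config.line_ids()
    base, alt = config.treatments
    sexes = ("F", "M") if config.with_sex else ("NA",)
    b, n = config.n_lines, config.n_replicates

    L = rng.normal(0.0, np.sqrt(config.sigma2_L), size=b)
    LT = {t: rng.normal(0.0, np.sqrt(config.sigma2_LT), size=b) for t in config.treatments}
    LS = {s: rng.normal(0.0, np.sqrt(config.sigma2_LS), size=b) for s in sexes}
    LTS = {(t, s): rng.normal(0.0, np.sqrt(config.sigma2_LTS), size=b)
           for t in config.treatments for s in sexes}
    if line_shift:
        L = L + np.array([line_shift.get(l, 0.0) for l in lines])
    if line_treatment_shift:
        LT[alt] = LT[alt] + np.array([line_treatment_shift.get(l, 0.0) for l in lines])

    rows = []
    for ti, t in enumerate(config.treatments):
        t_eff = (-0.5 if ti == 0 else 0.5) * config.treatment_effect
        for si, s in enumerate(sexes):
            s_eff = 0.0 if not config.with_sex else (-0.5 if si == 0 else 0.5) * config.sex_effect
            mu_cell = config.grand_mean + t_eff + s_eff
            eps = rng.normal(0.0, np.sqrt(config.sigma2_eps), size=(b, n))
            cell_line = mu_cell + L + LT[t] + LS[s] + LTS[(t, s)]
            vals = cell_line[:, None] + eps
            if config.truncate_unit_interval:
                vals = np.clip(vals, 0.0, 1.0)
            for li, line in enumerate(lines):
                for r in range(n):
                    rows.append((line, t, s, r + 1, vals[li, r]))
    table = pd.DataFrame(rows, columns=REPLICATE_COLUMNS)
    table.attrs["truth"] = {
        "line_effects": dict(zip(lines, L.tolist())),
        "config": asdict(config),
    }
    return table


def simulate_viability_counts(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_eggs: int = 50,
    error: str = "binomial",
) -> pd.DataFrame:
    """Raw egg-to-adult counts: surviving adults out of ``n_eggs`` per vial.

    The latent survival probability per replicate follows the factorial
    model (clipped to [0, 1]); ``error='binomial'`` then draws the adult
    count binomially, ``'rounded'`` just rounds the latent expectation —
    the two supported viability error distributions.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    latent = simulate_phenotypes(replace(config, truncate_unit_interval=True), rng)
    out = latent[["line", "treatment", "replicate"]].copy()
    p = latent["value"].to_numpy()
    if error == "binomial":
        out["n_adults"] = rng.binomial(n_eggs, p)
    elif error == "rounded":
        out["n_adults"] = np.rint(p * n_eggs).astype(int)
    else:
        raise ConfigError(f"unknown viability error model {error!r}")
    out["n_eggs"] = n_eggs
    return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Biallelic homozygous genotype matrix (calls 0/2) for fully inbred lines.

    Per-variant MAF is uniform on ``maf_range``.  ``maf_mode='sampling'``
    draws carriers Bernoulli(maf); ``'balanced'`` assigns exactly
    round(maf * n_lines) minor-allele carriers.  Variants get sorted
    positions on five chromosome arms spanning ``genome_length``.
    """
    from .gwa import GenotypeMatrix

    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    lo, hi = config.maf_range
    m, b = config.n_variants, config.n_lines
    mafs = rng.uniform(lo, hi, size=m)
    if config.maf_mode == "balanced":
        calls = np.zeros((m, b))
        for j in range(m):
            k = int(round(mafs[j] * b))
            idx = rng.choice(b, size=k, replace=False)
            calls[j, idx] = 2.0
    elif config.maf_mode == "sampling":
        calls = 2.0 * (rng.random((m, b)) < mafs[:, None])
    else:
        raise ConfigError(f"unknown maf_mode {config.maf_mode!r}")

    arm_len = config.genome_length // len(CHROM_ARMS)
    per_arm = np.full(len(CHROM_ARMS), m // len(CHROM_ARMS))
    per_arm[: m % len(CHROM_ARMS)] += 1
    chroms, positions = [], []
    for arm, k in zip(CHROM_ARMS, per_arm):
        pos = np.sort(rng.choice(arm_len - 1, size=k, replace=False)) + 1  # 1-based
        chroms.extend([arm] * k)
        positions.extend(pos.tolist())
    variants = pd.DataFrame({
        "id": [f"{c}_{p}" for c, p in zip(chroms, positions)],
        "chrom": chroms,
        "pos": positions,
        "ref": "A",
        "alt": "T",
    })
    return GenotypeMatrix(variants=variants, calls=calls, lines=config.line_ids())


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def simulate_gene_models(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Non-overlapping gene intervals tiled uniformly over the chromosome arms."""
    from .gwa import GeneModelSet

    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    arm_len = config.genome_length // len(CHROM_ARMS)
    per_arm = np.full(len(CHROM_ARMS), config.n_genes // len(CHROM_ARMS))
    per_arm[: config.n_genes % len(CHROM_ARMS)] += 1
    ids = config.gene_ids()
    rows, k = [], 0
    for arm, ng in zip(CHROM_ARMS, per_arm):
        if ng == 0:
            continue
        slot = arm_len // ng
        if slot <= config.gene_length:
            raise ConfigError("genome too short for requested non-overlapping genes")
        for i in range(ng):
            start = i * slot + int(rng.integers(0, slot - config.gene_length))
            rows.append((ids[k], arm, start, start + config.gene_length,
                         "+" if rng.random() < 0.5 else "-"))
            k += 1
    genes = pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand"])
    return GeneModelSet(genes=genes)


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def simulate_network(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[nx.Graph, list[str]]:
    """Degree-heterogeneous random background graph with an embedded connected cluster.

    Background edges follow a configuration-model-style draw: endpoint
    probabilities proportional to heavy-tailed node weights (Pareto), with
    self-loops and duplicates rejected, yielding the hub-dominated degree
    distributions of curated interaction networks.  ``embedded_cluster_size``
    nodes additionally receive a random spanning tree plus extra in-cluster
    edges, guaranteeing a connected planted module.  Returns the graph and
    the planted node ids.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    nodes = config.gene_ids()[: config.network_n_nodes]
    nn = len(nodes)
    max_edges = nn * (nn - 1) // 2
    if config.network_n_edges > max_edges:
        raise ConfigError("requested edges exceed simple-graph maximum")

    g = nx.Graph()
    g.add_nodes_from(nodes)

    # planted module: spanning tree + ~50% extra in-cluster edges
    cluster_idx = rng.choice(nn, size=config.embedded_cluster_size, replace=False)
    cluster = [nodes[i] for i in sorted(cluster_idx)]
    order = list(rng.permutation(config.embedded_cluster_size))
    for i in range(1, len(order)):
        j = order[int(rng.integers(0, i))]
        g.add_edge(cluster[order[i]], cluster[j])
    # densify the module while the edge budget allows (connectivity already holds)
    extra = config.embedded_cluster_size // 2
    for _ in range(extra * 4):
        if extra <= 0 or g.number_of_edges() >= config.network_n_edges:
            break
        u, v = rng.choice(config.embedded_cluster_size, size=2, replace=False)
        if not g.has_edge(cluster[u], cluster[v]):
            g.add_edge(cluster[u], cluster[v])
            extra -= 1

    # heavy-tailed but finite-variance endpoint weights: hubs emerge without a
    # mega-hub that would let random gene sets coalesce into giant clusters
    w = rng.pareto(3.5, size=nn) + 1.0
    p = w / w.sum()
    target = config.network_n_edges
    guard = 0
    while g.number_of_edges() < target and guard < 50 * target:
        u, v = rng.choice(nn, size=2, p=p)
        guard += 1
        if u == v:
            continue
        a_, b_ = nodes[u], nodes[v]
        if not g.has_edge(a_, b_):
            g.add_edge(a_, b_)
    return g, cluster


# ---------------------------------------------------------------------------
# full panel
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPanel:
    """A coherent synthetic study: phenotypes, genotypes, gene models, network, truth."""

    phenotypes: pd.DataFrame
    genotypes: "object"
    gene_models: "object"
    network: nx.Graph
    truth: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        from pathlib import Path
        from . import io as edio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
        edio.write_genotype_tsv(outdir / "genotypes.tsv", self.genotypes)
        edio.write_vcf(outdir / "genotypes.vcf", self.genotypes)
        edio.write_bed(outdir / "gene_models.bed", self.gene_models)
        edio.write_edge_list(outdir / "network.tsv", self.network)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def simulate_panel(config: SimulationConfig) -> SyntheticPanel:
    """Generate a full coherent panel.

    Causal variants are placed inside genes of the planted network module and
    coupled to the phenotype: with ``causal_on='interaction'`` each minor
    allele shifts the line's ethanol-condition effect by ``causal_effect``
    (so per-line sensitivity carries the signal); with ``'mean'`` the shift
    applies to the line effect in both conditions.
    """
    rng = np.random.default_rng(config.seed)
    geno = simulate_genotypes(config, np.random.default_rng(rng.integers(2**31)))
    genes = simulate_gene_models(config, np.random.default_rng(rng.integers(2**31)))
    net, cluster = simulate_network(config, np.random.default_rng(rng.integers(2**31)))
    crng = np.random.default_rng(rng.integers(2**31))

    # relocate n_causal variants into the bodies of distinct planted-module genes
    causal_ids: list[str] = []
    if config.n_causal > 0:
        host_genes = list(crng.choice(cluster, size=min(config.n_causal, len(cluster)),
                                      replace=False))
        gm = genes.genes.set_index("id")
        cand = list(crng.choice(config.n_variants, size=config.n_causal, replace=False))
        for vi, gid in zip(cand, host_genes * (config.n_causal // len(host_genes) + 1)):
            row = gm.loc[gid]
            pos = int(crng.integers(row["start"], row["end"])) + 1  # 1-based inside body
            geno.variants.loc[vi, ["chrom", "pos"]] = [row["chrom"], pos]
            geno.variants.loc[vi, "id"] = f"{row['chrom']}_{pos}"
            causal_ids.append(str(geno.variants.loc[vi, "id"]))
        geno = geno.sorted()

    beta = {}
    if causal_ids:
        idx = {v: i for i, v in enumerate(geno.variants["id"])}
        carriers = geno.calls[[idx[v] for v in causal_ids], :]
        shift = config.causal_effect * carriers.sum(axis=0)
        shift = shift - shift.mean()  # keep the grand mean on target
        beta = dict(zip(config.line_ids(), shift.tolist()))

    prng = np.random.default_rng(rng.integers(2**31))
    if config.causal_on == "interaction":
        pheno = simulate_phenotypes(config, prng, line_treatment_shift=beta)
    else:
        pheno = simulate_phenotypes(config, prng, line_shift=beta)

    truth = {
        "causal_variants": sorted(causal_ids),
        "embedded_cluster": list(cluster),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    return SyntheticPanel(phenotypes=pheno, genotypes=geno, gene_models=genes,
                          network=net, truth=truth)


def config_from_yaml(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("treatments", "maf_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    try:
        return SimulationConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
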