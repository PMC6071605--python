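# Methods

## Study design emulated by the generator

The synthetic panels mimic a reference panel of fully inbred, fully
sequenced lines phenotyped under two rearing conditions:

- **Viability** (egg-to-adult survival, proportion scale): 200 lines × 2
  media (regular, 10% ethanol) × 5 replicate vials of 50 eggs. Defaults put
  the condition means at 0.52 (regular) and 0.20 (ethanol) — grand mean
  0.36, treatment effect −0.32 applied as ±half around the grand mean — with
  σ²_L = 0.009, σ²_L×T = 0.0085, σ²_ε = 0.0149, i.e. a true H² of 0.54 and a
  cross-condition line-mean correlation of σ²_L/(σ²_L+σ²_L×T+σ²_ε/5) ≈ 0.44.
- **Development time** (mean eclosion day): same design; means 9.3 d
  (regular) and 9.9 d (ethanol), σ²_L = 0.06, σ²_L×T = 0.04, σ²_ε = 0.2333
  (H² = 0.30). Mean sensitivity 0.6 d with a per-line spread of ≈ ±1.2 d.
- **Locomotor reactivity** (sexed, 0–60 s startle score): 39 lines × 2
  sexes × 2 media × 20 replicates; σ²_L = 30, σ²_L×T = 10, σ²_L×S = 5,
  σ²_L×T×S = 5, σ²_ε = 28, giving H² = 0.64 under the four-component
  genetic variance.

Every random term is an independent zero-mean normal draw; lines are
unrelated (no kinship correlation — relatedness enters the association
stage only as an optional covariate matrix). Viability is generated on an
untruncated normal scale by default so that the ANOVA recovers exactly the
configured components; a `truncate_unit_interval` flag and a raw-count
helper (`simulate_viability_counts`, binomial or rounded out of 50 eggs)
provide the bounded-scale variants. The error distribution of real
viability data is not modelled beyond these two options.

Genotypes are strictly homozygous biallelic calls (0/2 minor-allele
counts), per-variant MAF uniform on (0.05, 0.5] either by Bernoulli
sampling or with exact carrier counts ("balanced" mode); variants carry
sorted positions on five chromosome arms. No linkage disequilibrium,
inversions, or infection status are simulated — null association p-values
are exactly exchangeable, which is what the calibration tests rely on, and
which real panels with LD structure will not satisfy.

The interaction network is a degree-heterogeneous random background
(endpoint weights Pareto(3.5)+1, default 1,200 edges on 1,000 gene nodes)
with a planted connected module: a random spanning tree over
`embedded_cluster_size` genes plus ~size/2 extra in-module edges. The
weight tail is deliberately finite-variance: with a heavier tail a single
mega-hub is recruited by almost any random gene set under the one-bridge
rule, the null largest-cluster distribution inflates to ~100 genes, and no
module of realistic size is detectable. Real curated interaction networks
are hubbier than this background; on such networks the degree-matched null
(below) is the more honest reference. In the full panel, causal variants
are relocated into bodies of distinct planted-module genes and (by
default) shift each carrier line's ethanol-condition effect by 0.12 per
minor allele — so the planted signal surfaces in the ethanol and
sensitivity GWAS and the hit genes lie inside the planted module. This
coupling adds real genotype-driven interaction variance on top of the
configured σ²_L×T, so the coupled panel's fitted H² exceeds the pure
variance-component calibration (≈0.75 vs. 0.54 at the defaults);
parameter-recovery checks therefore use the uncoupled phenotype generator
(`n_causal` effectively 0).

## Variance partitioning

`fit_variance_components` treats treatment (and sex) as fixed, line and all
line interactions as random. Two routes:

- **EMS/ANOVA (closed form)** on exactly balanced designs, solving the
  unrestricted-model expected mean squares; for the unsexed model
  E[MS_E]=σ²ε, E[MS_LT]=σ²ε+nσ²LT, E[MS_L]=σ²ε+nσ²LT+anσ²L (a media, b
  lines, n replicates), with the analogous five-equation system for the
  sexed model. On balanced data with interior solutions this *is* the REML
  estimate.
- **REML (statsmodels MixedLM)** with a variance-components formulation
  (random intercept per line plus per-treatment, per-sex and
  per-cell line effects), used for near-balanced tables. BFGS with a tight
  gradient tolerance; the two routes agree to ~1e-9 on balanced toys and
  to <1e-4 on balanced simulated panels.

The default `method="auto"` picks EMS exactly when the table is balanced.
Negative component solutions are kept in `raw_components` but truncated to
zero before H², so H² ∈ [0, 1] and is invariant under positive affine
transforms of the phenotype. Term significance uses the balanced F-tests
(L and L×T against their EMS denominators; the sexed line term has no exact
denominator and uses a Satterthwaite quasi-F, reported as approximate; all
F p-values are NaN when the denominator mean square is zero). For
unbalanced tables fitted by REML no exact F exists and p-values are
omitted.

Per-condition ("reduced") models drop the treatment factor; lines missing a
condition are excluded from sensitivity and full-model fits with a logged
reason (mirroring the exclusion of lines inviable on one medium) but remain
usable in the reduced model of the condition they have.

## Association

Minor allele frequency is computed over non-missing lines; the filter keeps
MAF ≥ threshold (inclusive, default 0.05). Each variant is fit by ordinary
least squares, line_mean ~ intercept + allele_count [+ covariates], the
covariate matrix being the generic stand-in for infection/inversion/
relatedness adjustments of panel-specific pipelines (a full kinship random
effect is out of scope and off by default). Two-sided p comes from the t
distribution with n−2−q degrees of freedom. Variants whose smaller
genotype class holds fewer than 4 lines (configurable) are flagged
`degenerate` with p = 1 rather than dropped, keeping record counts stable;
p-values that underflow are clamped to the smallest positive double and
flagged. The no-covariate, no-missingness path is fully vectorised and
matches per-variant `scipy.stats.linregress` to 1e-10; thresholding is
strict (p < α) and annotation uses an interval tree over gene bodies
extended ±window (default 1 kb), distances measured in bases from the
nearest body base, boundary inclusive.

Coordinates are 0-based half-open internally and in BED; VCF I/O is
1-based (verified by round-trip tests through cyvcf2).

## Subnetwork statistics

Bridge recruitment requires ≥2 *distinct* candidate neighbours — a
non-candidate touching one candidate creates no candidate-to-candidate
path, so admitting it would pad clusters without evidence of candidate
interconnection. The extracted graph contains only nodes incident to
retained edges; isolated candidates drop out but still count toward the
matched-candidate size used for null draws, keeping observed and null
comparable. Cluster size is measured in genes (nodes), and "exceeds" is
strict, so the literal empirical p can be 0/n; the add-one corrected
(count+1)/(n+1) is always reported alongside and is the valid (super-
uniform) quantity under exchangeability. The default null draws candidate
sets uniformly from the global nodes, matching the randomization described
for this analysis; a degree-matched null (log2-degree bins) is offered
because hubby networks inflate null clusters, but it is a documented
deviation, not the default. The display-oriented degree filter (default
≥3 interactions) is a single pass — no iterative re-pruning — so surviving
nodes may fall below the cutoff afterwards; hub degrees are therefore
reported both before and after filtering. Hub ranking breaks degree ties
lexicographically by gene id.

## Pipeline and determinism

`run_pipeline` chains quantgen → association (three phenotype fields per
trait, both α levels) → candidate-gene union at the relaxed α →
subnetwork extraction and randomization, writing every table and an audit
manifest whose counts are internally checked (hits ≤ tested; candidate +
recruited = interconnected). The manifest carries no timestamps and all
JSON is key-sorted, so identical configs and seeds reproduce byte-identical
outputs; all randomness flows from the single configured seed.

## Problem sizes used in tests and the acceptance script

Variance recovery uses 100 panels per true H² at the full study design
(200×2×5); association checks use 1,000 variants against the per-variant
oracle and 10,000 variants for null uniformity; subnetwork extraction is
verified against exhaustive candidate-pair enumeration over all candidate
subsets of a seeded family of ≤8-node graphs, and randomization exactness
against the enumerable C(6,3) candidate sets of a 6-node graph.
Planted-module power uses the default 1,000-node network with a 20-gene
module plus 40 decoy candidates at 1,000 randomizations. These sizes make
the whole suite run in well under a minute while keeping Monte-Carlo error
comfortably inside the asserted tolerances.

## Known limitations

- Combined-condition and per-condition H² coincide under this generator
  (variance components are condition-invariant); real data with
  condition-dependent error variances will not behave this way.
- REML p-values for variance terms on unbalanced data are not provided
  (no exact tests exist; likelihood-ratio machinery was judged out of
  scope).
- The edge-list format cannot represent isolated network nodes, so a
  written-and-reread graph loses them; null draws then sample connected
  nodes only.
- No LD, no multiple-testing correction (the analysis uses nominal
  thresholds by design), and no GO/ortholog downstream analyses.
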