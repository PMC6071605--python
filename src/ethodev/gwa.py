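"""Single-marker association of line means with homozygous biallelic variants.

Inbred panels are associated at the line level: each variant's minor-allele
count (0 or 2 in fully homozygous lines) is regressed on the per-line
phenotype mean, optionally with fixed covariates (the generic stand-in for
infection status, inversion karyotypes or relatedness axes).  Variants are
pre-filtered on minor allele frequency, hits are taken at nominal p-value
thresholds, and passing variants are annotated with the gene models they
fall in or near.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ConfigError, DataError, SchemaError

#: smallest positive subnormal double; p-values underflowing to 0 are clamped here
MIN_P = 5e-324

DEFAULT_MAF = 0.05
DEFAULT_ALPHA = 1e-5
RELAXED_ALPHA = 5e-5
DEFAULT_WINDOW = 1000
MIN_CLASS_LINES = 4


@dataclass
class GenotypeMatrix:
    """Homozygous biallelic calls for inbred lines.

    ``calls`` is (n_variants, n_lines) with values 0.0 / 2.0 (minor-allele
    count) and NaN for missing; ``variants`` has columns id, chrom, pos
    (1-based), ref, alt.
    """

    variants: pd.DataFrame
    calls: np.ndarray
    lines: list[str]

    def __post_init__(self):
        if self.calls.shape != (len(self.variants), len(self.lines)):
            raise SchemaError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.lines)} lines"
            )
        ok = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 2)
        if not ok.all():
            raise DataError("calls must be 0, 2 or missing (homozygous inbred lines)")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant over non-missing lines."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.calls, axis=1) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            variants=self.variants.loc[mask].reset_index(drop=True),
            calls=self.calls[mask],
            lines=list(self.lines),
        )

    def sorted(self) -> "GenotypeMatrix":
        order = self.variants.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        return GenotypeMatrix(
            variants=self.variants.loc[order].reset_index(drop=True),
            calls=self.calls[order],
            lines=list(self.lines),
        )


@dataclass
class GeneModelSet:
    """Gene intervals: columns id, chrom, start, end (0-based half-open), strand."""

    genes: pd.DataFrame
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        need = ["id", "chrom", "start", "end"]
        missing = [c for c in need if c not in self.genes.columns]
        if missing:
            raise SchemaError(f"gene models missing columns: {missing}")
        if (self.genes["start"] >= self.genes["end"]).any():
            raise DataError("gene intervals need start < end (0-based half-open)")
        if self.genes["id"].duplicated().any():
            raise DataError("gene ids must be unique")

    def trees(self) -> dict[str, IntervalTree]:
        if not self._trees:
            for chrom, grp in self.genes.groupby("chrom"):
                self._trees[chrom] = IntervalTree.from_tuples(
                    (int(r.start), int(r.end), r.id) for r in grp.itertuples()
                )
        return self._trees


def maf_filter(geno: GenotypeMatrix, threshold: float = DEFAULT_MAF) -> GenotypeMatrix:
    """Keep variants with MAF >= threshold (inclusive) among non-missing lines.

    Variants with no non-missing call are always dropped.  The kept/dropped
    counts are stored in ``result.variants.attrs['maf_filter']``.
    """
    if not 0 <= threshold <= 0.5:
        raise ConfigError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    maf = geno.maf()
    keep = ~np.isnan(maf) & (maf >= threshold)
    if threshold > 0:
        keep &= maf > 0
    out = geno.subset(keep)
    out.variants.attrs["maf_filter"] = {
        "threshold": threshold,
        "kept": int(keep.sum()),
        "dropped": int((~keep).sum()),
    }
    return out


def associate(
    geno: GenotypeMatrix,
    line_means: pd.Series,
    phenotype: str = "phenotype",
    covariates: pd.DataFrame | None = None,
    min_class_lines: int = MIN_CLASS_LINES,
    min_lines: int = 20,
) -> pd.DataFrame:
    """Per-variant linear regression of line means on minor-allele count.

    ``line_means`` is indexed by line id.  For each variant the model
    ``mean ~ intercept + allele_count [+ covariates]`` is fit by least
    squares on the lines with both genotype and phenotype; slope, its
    standard error and the two-sided p-value from the t distribution with
    n - 2 - q degrees of freedom are reported.  Variants whose smaller
    genotype class has fewer than ``min_class_lines`` lines (or that are
    constant) are emitted with p = 1 and flag ``degenerate``.
    """
    shared = [l for l in geno.lines if l in line_means.index and pd.notna(line_means.loc[l])]
    if len(shared) < min_lines:
        raise DataError(f"only {len(shared)} lines shared between genotypes and means "
                        f"(minimum {min_lines})")
    col = np.array([geno.lines.index(l) for l in shared])
    G = geno.calls[:, col]
    y_full = line_means.loc[shared].to_numpy(dtype=float)

    q = 0
    C_full = None
    if covariates is not None:
        miss = [l for l in shared if l not in covariates.index]
        if miss:
            raise DataError(f"covariates missing for lines: {miss[:5]}...")
        C_full = covariates.loc[shared].to_numpy(dtype=float)
        q = C_full.shape[1]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(shared)), C_full])) < 1 + q:
            raise DataError("rank-deficient covariate matrix")

    m = geno.n_variants
    slope = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.ones(m)
    nn = np.zeros(m, dtype=int)
    flags = np.array([""] * m, dtype=object)

    any_missing = np.isnan(G).any()
    if C_full is None and not any_missing:
        # fully vectorised simple regression across variants
        n = len(shared)
        nn[:] = n
        x = G
        xm = x.mean(axis=1, keepdims=True)
        ym = y_full.mean()
        xc = x - xm
        yc = y_full - ym
        sxx = (xc ** 2).sum(axis=1)
        degen = _degenerate_mask(x, min_class_lines)
        ok = ~degen & (sxx > 0)
        sxy = xc @ yc
        b = np.where(ok, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        rss = (yc ** 2).sum() - b * sxy
        df = n - 2 - q
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = np.clip(rss, 0, None) / df
            se_ = np.sqrt(s2 / np.where(sxx > 0, sxx, np.nan))
            t = b / se_
            p = 2 * stats.t.sf(np.abs(t), df)
        slope[ok] = b[ok]
        se[ok] = se_[ok]
        pval[ok] = p[ok]
        flags[~ok] = "degenerate"
    else:
        for j in range(m):
            x = G[j]
            mask = ~np.isnan(x)
            n = int(mask.sum())
            nn[j] = n
            xj = x[mask]
            if n < max(3 + q, 2 * min_class_lines) or _degenerate_mask(xj[None, :], min_class_lines)[0]:
                flags[j] = "degenerate"
                continue
            cols = [np.ones(n), xj]
            if C_full is not None:
                cols.extend(C_full[mask].T)
            X = np.column_stack(cols)
            yj = y_full[mask]
            beta, _, rank, _ = np.linalg.lstsq(X, yj, rcond=None)
            if rank < X.shape[1]:
                flags[j] = "degenerate"
                continue
            resid = yj - X @ beta
            df = n - X.shape[1]
            s2 = float(resid @ resid) / df
            xtx_inv = np.linalg.inv(X.T @ X)
            se_j = float(np.sqrt(s2 * xtx_inv[1, 1]))
            slope[j] = beta[1]
            se[j] = se_j
            if se_j > 0:
                pval[j] = 2 * stats.t.sf(abs(beta[1]) / se_j, df)
            else:
                pval[j] = MIN_P
                flags[j] = "underflow"

    under = (pval == 0)
    pval[under] = MIN_P
    flags[under & (flags == "")] = "underflow"

    out = geno.variants[["id", "chrom", "pos"]].copy()
    out["phenotype"] = phenotype
    out["maf"] = geno.maf()
    out["effect"] = slope
    out["se"] = se
    out["p"] = pval
    out["n"] = nn
    out["flag"] = flags
    return out


def _degenerate_mask(x: np.ndarray, min_class: int) -> np.ndarray:
    n0 = (x == 0).sum(axis=1)
    n2 = (x == 2).sum(axis=1)
    return (np.minimum(n0, n2) < min_class)


def threshold_hits(records: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Variants passing the nominal threshold p < alpha (strict), sorted by p."""
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    keep = records[(records["p"] < alpha) & (records["flag"] != "degenerate")]
    return keep.sort_values(["p", "id"], kind="mergesort").reset_index(drop=True)


def annotate_variants(
    records: pd.DataFrame,
    genes: GeneModelSet,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Attach the genes each variant is in or near (within ``window`` bp).

    A variant at 1-based position ``pos`` is *inside* a gene when the
    0-based coordinate pos-1 falls in [start, end); otherwise it is *near*
    when the distance to the interval is <= window.  Variants matching no
    gene are annotated ``intergenic``.  Adds columns ``genes``
    (comma-joined "id:relation:distance") and ``gene_ids``; the distinct
    gene count over the whole record set is stored in
    ``out.attrs['n_distinct_genes']``.
    """
    if window < 0:
        raise ConfigError("annotation window must be >= 0")
    trees = genes.trees()
    known = set(trees)
    ann, ids = [], []
    all_genes: set[str] = set()
    for rec in records.itertuples():
        chrom = rec.chrom
        if chrom not in known:
            ann.append("unknown_chrom")
            ids.append("")
            continue
        p0 = int(rec.pos) - 1
        hits = []
        for iv in trees[chrom].overlap(p0 - window, p0 + window + 1):
            if iv.begin <= p0 < iv.end:
                hits.append((iv.data, "inside", 0))
            else:
                dist = iv.begin - p0 if p0 < iv.begin else p0 - (iv.end - 1)
                if dist <= window:
                    hits.append((iv.data, "near", int(dist)))
        hits.sort(key=lambda h: (h[2], h[0]))
        if hits:
            ann.append(",".join(f"{g}:{rel}:{d}" for g, rel, d in hits))
            ids.append(",".join(g for g, _, _ in hits))
            all_genes.update(g for g, _, _ in hits)
        else:
            ann.append("intergenic")
            ids.append("")
    out = records.copy()
    out["genes"] = ann
    out["gene_ids"] = ids
    out.attrs["n_distinct_genes"] = len(all_genes)
    return out


def distinct_genes(annotated: pd.DataFrame) -> list[str]:
    """Sorted distinct gene ids across an annotated hit set."""
    genes: set[str] = set()
    for s in annotated["gene_ids"]:
        if s:
            genes.update(s.split(","))
    return sorted(genes)
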