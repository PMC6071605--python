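"""Variance partitioning, broad-sense heritability and line-level phenotypes.

Replicate-level phenotypes from an inbred line panel reared under two
conditions are modelled with a mixed-model factorial ANOVA,

    Y = mu + T + L + LxT + e            (unsexed traits)
    Y = mu + T + S + L + TxS + LxS + LxT + LxTxS + e   (sexed traits)

where treatment T (and sex S) are fixed and line L and its interactions are
random.  Broad-sense heritability is the genetic fraction of the phenotypic
variance, H2 = sigma2_G / (sigma2_G + sigma2_e), with sigma2_G summing every
line-bearing component of the fitted model.  Per-line condition means and the
ethanol-minus-regular sensitivity are the inputs of the association stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InsufficientReplicationError, SchemaError

REPLICATE_COLUMNS = ["line", "treatment", "sex", "replicate", "value"]

#: canonical treatment labels; first is the baseline condition
TREATMENTS = ("regular", "ethanol")

MODELS = ("full", "reduced", "sexed_full", "sexed_reduced")

_GENETIC_TERMS = {
    "full": ("L", "LT"),
    "reduced": ("L",),
    "sexed_full": ("L", "LT", "LS", "LTS"),
    "sexed_reduced": ("L", "LS"),
}


def validate_replicate_table(table: pd.DataFrame, sexed: bool = False) -> pd.DataFrame:
    """Check a replicate-level phenotype table and return it with canonical columns.

    Required columns: line, treatment, replicate, value (sex additionally when
    ``sexed``).  Values must be finite and the key (line, treatment, sex,
    replicate) unique.
    """
    missing = [c for c in ("line", "treatment", "replicate", "value") if c not in table.columns]
    if missing:
        raise SchemaError(f"replicate table missing columns: {missing}")
    out = table.copy()
    if "sex" not in out.columns:
        if sexed:
            raise SchemaError("sexed model requested but table has no 'sex' column")
        out["sex"] = "NA"
    if not np.isfinite(out["value"].to_numpy(dtype=float)).all():
        raise DataError("non-finite phenotype values")
    key = ["line", "treatment", "sex", "replicate"]
    if out.duplicated(subset=key).any():
        raise SchemaError("duplicate (line, treatment, sex, replicate) keys")
    return out[REPLICATE_COLUMNS + [c for c in out.columns if c not in REPLICATE_COLUMNS]]


@dataclass
class VarianceDecomposition:
    """REML / ANOVA variance-component estimates and broad-sense heritability.

    ``components`` holds the truncated-at-zero estimates used for H2;
    ``raw_components`` keeps the untruncated solutions for diagnostics.
    """

    model: str
    method: str
    components: dict[str, float]
    raw_components: dict[str, float]
    sigma2_G: float
    sigma2_P: float
    H2: float
    p_values: dict[str, float] = field(default_factory=dict)
    mean_squares: dict[str, float] = field(default_factory=dict)
    design: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "method": self.method,
            "components": self.components,
            "raw_components": self.raw_components,
            "sigma2_G": self.sigma2_G,
            "sigma2_P": self.sigma2_P,
            "H2": self.H2,
            "p_values": self.p_values,
            "mean_squares": self.mean_squares,
            "design": self.design,
        }


def _check_replication(table: pd.DataFrame, factors: list[str]) -> int:
    counts = table.groupby(factors, observed=True)["value"].size()
    if (counts < 2).any():
        raise InsufficientReplicationError(
            "every (line, treatment[, sex]) cell needs >=2 replicates for variance partitioning"
        )
    return int(counts.min())


def _is_balanced(table: pd.DataFrame, factors: list[str]) -> bool:
    counts = table.groupby(factors, observed=True)["value"].size()
    full = 1
    for f in factors:
        full *= table[f].nunique()
    return counts.nunique() == 1 and len(counts) == full


def _finish(model, method, raw, pvals, ms, design) -> VarianceDecomposition:
    comp = {k: max(0.0, v) for k, v in raw.items()}
    s2g = float(sum(comp[t] for t in _GENETIC_TERMS[model]))
    s2p = s2g + comp["e"]
    h2 = s2g / s2p if s2p > 0 else float("nan")
    return VarianceDecomposition(
        model=model, method=method, components=comp, raw_components=raw,
        sigma2_G=s2g, sigma2_P=s2p, H2=h2, p_values=pvals, mean_squares=ms,
        design=design,
    )



def _f_p(ms_num: float, ms_den: float, df1: float, df2: float) -> float:
    """Upper-tail F p-value, NaN when the denominator mean square is 0."""
    if ms_den <= 0 or df2 <= 0:
        return float("nan")
    return float(stats.f.sf(ms_num / ms_den, df1, df2))

# ---------------------------------------------------------------------------
# closed-form ANOVA (expected mean squares) estimators for balanced designs
# ---------------------------------------------------------------------------

def _ems_full(table: pd.DataFrame) -> VarianceDecomposition:
    # a treatments x b lines x n reps; unrestricted mixed model EMS:
    #   E[MS_E]  = s2e
    #   E[MS_LT] = s2e + n s2LT
    #   E[MS_L]  = s2e + n s2LT + a n s2L
    a = table["treatment"].nunique()
    b = table["line"].nunique()
    n = len(table) // (a * b)
    y = table["value"].to_numpy(dtype=float)
    grand = y.mean()
    cell = table.groupby(["treatment", "line"], observed=True)["value"].mean()
    tmean = table.groupby("treatment", observed=True)["value"].mean()
    lmean = table.groupby("line", observed=True)["value"].mean()

    ss_t = n * b * float(((tmean - grand) ** 2).sum())
    ss_l = n * a * float(((lmean - grand) ** 2).sum())
    interaction = cell - tmean.reindex(cell.index.get_level_values(0)).to_numpy() \
        - lmean.reindex(cell.index.get_level_values(1)).to_numpy() + grand
    ss_lt = n * float((interaction ** 2).sum())
    fitted = cell.reindex(pd.MultiIndex.from_frame(table[["treatment", "line"]])).to_numpy()
    ss_e = float(((y - fitted) ** 2).sum())

    df = {"T": a - 1, "L": b - 1, "LT": (a - 1) * (b - 1), "e": a * b * (n - 1)}
    ms = {k: s / df[k] for k, s in zip(("T", "L", "LT", "e"), (ss_t, ss_l, ss_lt, ss_e))}
    raw = {
        "e": ms["e"],
        "LT": (ms["LT"] - ms["e"]) / n,
        "L": (ms["L"] - ms["LT"]) / (a * n),
    }
    pvals = {
        "T": _f_p(ms["T"], ms["LT"], df["T"], df["LT"]),
        "L": _f_p(ms["L"], ms["LT"], df["L"], df["LT"]),
        "LT": _f_p(ms["LT"], ms["e"], df["LT"], df["e"]),
    }
    return _finish("full", "ems", raw, pvals, ms, {"a": a, "b": b, "n": n})


def _ems_reduced(table: pd.DataFrame) -> VarianceDecomposition:
    # one condition: Y = mu + L + e;  E[MS_L] = s2e + n s2L
    b = table["line"].nunique()
    n = len(table) // b
    y = table["value"].to_numpy(dtype=float)
    grand = y.mean()
    lmean = table.groupby("line", observed=True)["value"].mean()
    ss_l = n * float(((lmean - grand) ** 2).sum())
    fitted = lmean.reindex(table["line"]).to_numpy()
    ss_e = float(((y - fitted) ** 2).sum())
    df = {"L": b - 1, "e": b * (n - 1)}
    ms = {"L": ss_l / df["L"], "e": ss_e / df["e"]}
    raw = {"e": ms["e"], "L": (ms["L"] - ms["e"]) / n}
    pvals = {"L": _f_p(ms["L"], ms["e"], df["L"], df["e"])}
    return _finish("reduced", "ems", raw, pvals, ms, {"b": b, "n": n})


def _ems_sexed_full(table: pd.DataFrame) -> VarianceDecomposition:
    # a treatments x s sexes x b lines x n reps, unrestricted EMS:
    #   E[MS_E]   = s2e
    #   E[MS_LTS] = s2e + n s2LTS
    #   E[MS_LS]  = s2e + n s2LTS + a n s2LS
    #   E[MS_LT]  = s2e + n s2LTS + s n s2LT
    #   E[MS_L]   = s2e + n s2LTS + a n s2LS + s n s2LT + a s n s2L
    a = table["treatment"].nunique()
    s = table["sex"].nunique()
    b = table["line"].nunique()
    n = len(table) // (a * s * b)
    y = table["value"].to_numpy(dtype=float)
    grand = y.mean()

    def mean_over(cols):
        return table.groupby(cols, observed=True)["value"].mean()

    m_t, m_s, m_l = mean_over("treatment"), mean_over("sex"), mean_over("line")
    m_tl, m_sl, m_ts = mean_over(["treatment", "line"]), mean_over(["sex", "line"]), mean_over(["treatment", "sex"])
    m_tsl = mean_over(["treatment", "sex", "line"])

    def dev(series, cols):
        # align a grouped-mean series to the full cell index
        idx = m_tsl.index.to_frame(index=False)
        if isinstance(cols, str):
            return series.reindex(idx[cols]).to_numpy()
        return series.reindex(pd.MultiIndex.from_frame(idx[cols])).to_numpy()

    cell = m_tsl.to_numpy()
    tl = dev(m_tl, ["treatment", "line"])
    sl = dev(m_sl, ["sex", "line"])
    ts = dev(m_ts, ["treatment", "sex"])
    t_ = dev(m_t, "treatment")
    s_ = dev(m_s, "sex")
    l_ = dev(m_l, "line")

    ss_l = n * a * s * float(((m_l - grand) ** 2).sum())
    # interaction SS over their own margin index (a x b and s x b cells)
    tl_dev = m_tl.to_numpy() \
        - m_t.reindex(m_tl.index.get_level_values(0)).to_numpy() \
        - m_l.reindex(m_tl.index.get_level_values(1)).to_numpy() + grand
    ss_lt = n * s * float((tl_dev ** 2).sum())
    sl_dev = m_sl.to_numpy() \
        - m_s.reindex(m_sl.index.get_level_values(0)).to_numpy() \
        - m_l.reindex(m_sl.index.get_level_values(1)).to_numpy() + grand
    ss_ls = n * a * float((sl_dev ** 2).sum())
    ss_lts = n * float(((cell - tl - sl - ts + t_ + s_ + l_ - grand) ** 2).sum())
    fitted = m_tsl.reindex(pd.MultiIndex.from_frame(table[["treatment", "sex", "line"]])).to_numpy()
    ss_e = float(((y - fitted) ** 2).sum())
    ss_t = n * s * b * float(((m_t - grand) ** 2).sum())
    ss_s = n * a * b * float(((m_s - grand) ** 2).sum())
    ss_ts = n * b * float(((m_ts.to_numpy()
                            - m_t.reindex(m_ts.index.get_level_values(0)).to_numpy()
                            - m_s.reindex(m_ts.index.get_level_values(1)).to_numpy() + grand) ** 2).sum())

    df = {
        "T": a - 1, "S": s - 1, "TS": (a - 1) * (s - 1),
        "L": b - 1, "LT": (a - 1) * (b - 1), "LS": (s - 1) * (b - 1),
        "LTS": (a - 1) * (s - 1) * (b - 1), "e": a * s * b * (n - 1),
    }
    ss = {"T": ss_t, "S": ss_s, "TS": ss_ts, "L": ss_l, "LT": ss_lt,
          "LS": ss_ls, "LTS": ss_lts, "e": ss_e}
    ms = {k: ss[k] / df[k] for k in ss}
    raw = {
        "e": ms["e"],
        "LTS": (ms["LTS"] - ms["e"]) / n,
        "LS": (ms["LS"] - ms["LTS"]) / (a * n),
        "LT": (ms["LT"] - ms["LTS"]) / (s * n),
        "L": (ms["L"] - ms["LT"] - ms["LS"] + ms["LTS"]) / (a * s * n),
    }
    pvals = {
        "T": _f_p(ms["T"], ms["LT"], df["T"], df["LT"]),
        "S": _f_p(ms["S"], ms["LS"], df["S"], df["LS"]),
        "TS": _f_p(ms["TS"], ms["LTS"], df["TS"], df["LTS"]),
        "LT": _f_p(ms["LT"], ms["LTS"], df["LT"], df["LTS"]),
        "LS": _f_p(ms["LS"], ms["LTS"], df["LS"], df["LTS"]),
        "LTS": _f_p(ms["LTS"], ms["e"], df["LTS"], df["e"]),
    }
    # quasi-F for L (no exact denominator); Satterthwaite df
    denom = ms["LT"] + ms["LS"] - ms["LTS"]
    if denom > 0:
        df_den = denom ** 2 / (
            ms["LT"] ** 2 / df["LT"] + ms["LS"] ** 2 / df["LS"] + ms["LTS"] ** 2 / df["LTS"]
        )
        pvals["L"] = stats.f.sf(ms["L"] / denom, df["L"], df_den)
    else:
        pvals["L"] = float("nan")
    return _finish("sexed_full", "ems", raw, pvals, ms, {"a": a, "s": s, "b": b, "n": n})


def _ems_sexed_reduced(table: pd.DataFrame) -> VarianceDecomposition:
    # one condition: Y = mu + S + L + LS + e
    s = table["sex"].nunique()
    b = table["line"].nunique()
    n = len(table) // (s * b)
    y = table["value"].to_numpy(dtype=float)
    grand = y.mean()
    m_s = table.groupby("sex", observed=True)["value"].mean()
    m_l = table.groupby("line", observed=True)["value"].mean()
    m_sl = table.groupby(["sex", "line"], observed=True)["value"].mean()
    ss_s = n * b * float(((m_s - grand) ** 2).sum())
    ss_l = n * s * float(((m_l - grand) ** 2).sum())
    inter = m_sl - m_s.reindex(m_sl.index.get_level_values(0)).to_numpy() \
        - m_l.reindex(m_sl.index.get_level_values(1)).to_numpy() + grand
    ss_ls = n * float((inter ** 2).sum())
    fitted = m_sl.reindex(pd.MultiIndex.from_frame(table[["sex", "line"]])).to_numpy()
    ss_e = float(((y - fitted) ** 2).sum())
    df = {"S": s - 1, "L": b - 1, "LS": (s - 1) * (b - 1), "e": s * b * (n - 1)}
    ms = {k: v / df[k] for k, v in zip(("S", "L", "LS", "e"), (ss_s, ss_l, ss_ls, ss_e))}
    raw = {"e": ms["e"], "LS": (ms["LS"] - ms["e"]) / n, "L": (ms["L"] - ms["LS"]) / (s * n)}
    pvals = {
        "S": _f_p(ms["S"], ms["LS"], df["S"], df["LS"]),
        "L": _f_p(ms["L"], ms["LS"], df["L"], df["LS"]),
        "LS": _f_p(ms["LS"], ms["e"], df["LS"], df["e"]),
    }
    return _finish("sexed_reduced", "ems", raw, pvals, ms, {"s": s, "b": b, "n": n})


# ---------------------------------------------------------------------------
# REML via statsmodels MixedLM (handles near-balanced tables)
# ---------------------------------------------------------------------------

def _reml_fit(table: pd.DataFrame, model: str) -> VarianceDecomposition:
    import statsmodels.formula.api as smf

    data = table.copy()
    if model == "full":
        md = smf.mixedlm(
            "value ~ C(treatment)", data, groups="line", re_formula="1",
            vc_formula={"LT": "0 + C(treatment)"},
        )
    elif model == "reduced":
        md = smf.mixedlm("value ~ 1", data, groups="line", re_formula="1")
    elif model == "sexed_full":
        md = smf.mixedlm(
            "value ~ C(treatment) * C(sex)", data, groups="line", re_formula="1",
            vc_formula={
                "LT": "0 + C(treatment)",
                "LS": "0 + C(sex)",
                "LTS": "0 + C(treatment):C(sex)",
            },
        )
    elif model == "sexed_reduced":
        md = smf.mixedlm(
            "value ~ C(sex)", data, groups="line", re_formula="1",
            vc_formula={"LS": "0 + C(sex)"},
        )
    else:  # pragma: no cover - guarded upstream
        raise SchemaError(f"unknown model {model!r}")
    try:
        # bfgs with a tight gradient tolerance pins the optimum to ~1e-10
        res = md.fit(reml=True, method="bfgs", gtol=1e-10, maxiter=2000)
    except Exception:
        res = md.fit(reml=True, method="lbfgs", maxiter=2000)

    raw = {"e": float(res.scale), "L": float(res.cov_re.iloc[0, 0])}
    vcomp = {name: float(v) for name, v in zip(md.exog_vc.names, res.vcomp)}
    for term in _GENETIC_TERMS[model]:
        if term == "L":
            continue
        raw[term] = vcomp.get(term, 0.0)

    # term p-values: reuse exact balanced F tests when available
    pvals: dict[str, float] = {}
    factors = ["line", "treatment"] + (["sex"] if model.startswith("sexed") else [])
    if model in ("reduced", "sexed_reduced"):
        factors.remove("treatment")
    if _is_balanced(table, factors):
        ems = fit_variance_components(table, model, method="ems")
        pvals = ems.p_values
    design = {"b": data["line"].nunique(), "rows": len(data)}
    return _finish(model, "reml", raw, pvals, {}, design)


def fit_variance_components(
    table: pd.DataFrame, model: str = "full", method: str = "auto"
) -> VarianceDecomposition:
    """Partition phenotypic variance and compute broad-sense heritability.

    Parameters
    ----------
    table
        Replicate-level phenotype table (line, treatment[, sex], replicate,
        value).  Reduced models expect a single-treatment table.
    model
        ``full`` (T fixed; L, LxT random), ``reduced`` (one condition, L
        random), or the sexed variants with S fixed and LxS, LxTxS random.
    method
        ``auto`` uses the closed-form ANOVA (expected-mean-squares) solution
        on exactly balanced designs — where it coincides with REML — and
        MixedLM REML otherwise; ``ems`` / ``reml`` force a route.

    Negative component solutions are truncated to zero before H2, so
    0 <= H2 <= 1 always holds.
    """
    if model not in MODELS:
        raise SchemaError(f"model must be one of {MODELS}, got {model!r}")
    sexed = model.startswith("sexed")
    table = validate_replicate_table(table, sexed=sexed)
    if sexed and table["sex"].nunique() < 2:
        raise SchemaError("sexed model needs both sexes in the table")
    if model in ("reduced", "sexed_reduced"):
        if table["treatment"].nunique() != 1:
            raise SchemaError("reduced (per-condition) model expects a single-treatment table")
        factors = ["line"] + (["sex"] if sexed else [])
    else:
        if table["treatment"].nunique() < 2:
            raise SchemaError("full model needs both treatments")
        factors = ["line", "treatment"] + (["sex"] if sexed else [])

    _check_replication(table, factors)
    balanced = _is_balanced(table, factors)
    if method == "auto":
        method = "ems" if balanced else "reml"
    if method == "ems":
        if not balanced:
            raise SchemaError("EMS estimator requires an exactly balanced design")
        fn = {
            "full": _ems_full, "reduced": _ems_reduced,
            "sexed_full": _ems_sexed_full, "sexed_reduced": _ems_sexed_reduced,
        }[model]
        return fn(table)
    if method == "reml":
        return _reml_fit(table, model)
    raise SchemaError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# phenotype derivation from raw counts
# ---------------------------------------------------------------------------

def derive_viability(raw_counts: pd.DataFrame) -> pd.DataFrame:
    """Egg-to-adult viability: fraction of surviving adults out of eggs laid.

    ``raw_counts`` columns: line, treatment, replicate, n_adults, n_eggs
    (typically 50 eggs per replicate vial).
    """
    need = ["line", "treatment", "replicate", "n_adults", "n_eggs"]
    missing = [c for c in need if c not in raw_counts.columns]
    if missing:
        raise SchemaError(f"viability counts missing columns: {missing}")
    adults = raw_counts["n_adults"].to_numpy(dtype=float)
    eggs = raw_counts["n_eggs"].to_numpy(dtype=float)
    if (eggs <= 0).any():
        raise DataError("n_eggs must be positive")
    if (adults < 0).any() or (adults > eggs).any():
        raise DataError("n_adults must satisfy 0 <= n_adults <= n_eggs")
    out = raw_counts[["line", "treatment", "replicate"]].copy()
    if "sex" in raw_counts.columns:
        out["sex"] = raw_counts["sex"]
    else:
        out["sex"] = "NA"
    out["value"] = adults / eggs
    out.attrs["phenotype"] = "viability"
    out.attrs["units"] = "proportion"
    return out[REPLICATE_COLUMNS]


def derive_development_time(eclosion_counts: pd.DataFrame) -> pd.DataFrame:
    """Development time: mean eclosion day over all flies in a replicate vial.

    ``eclosion_counts`` columns: line, treatment, replicate, day, n_eclosed
    (one row per scoring day).  Replicates in which no fly ecloses carry no
    mean eclosion day and are dropped (their count is recorded in
    ``out.attrs['dropped_replicates']``).
    """
    need = ["line", "treatment", "replicate", "day", "n_eclosed"]
    missing = [c for c in need if c not in eclosion_counts.columns]
    if missing:
        raise SchemaError(f"eclosion counts missing columns: {missing}")
    if (eclosion_counts["n_eclosed"] < 0).any():
        raise DataError("n_eclosed must be >= 0")

    def mean_day(g: pd.DataFrame) -> float:
        tot = g["n_eclosed"].sum()
        if tot == 0:
            return float("nan")
        return float((g["day"] * g["n_eclosed"]).sum() / tot)

    grouped = (
        eclosion_counts.groupby(["line", "treatment", "replicate"], observed=True)
        .apply(mean_day, include_groups=False)
        .rename("value")
        .reset_index()
    )
    n_dropped = int(grouped["value"].isna().sum())
    grouped = grouped.dropna(subset=["value"]).reset_index(drop=True)
    grouped["sex"] = "NA"
    grouped = grouped[REPLICATE_COLUMNS]
    grouped.attrs["phenotype"] = "development_time"
    grouped.attrs["units"] = "days"
    grouped.attrs["dropped_replicates"] = n_dropped
    return grouped


# ---------------------------------------------------------------------------
# line summaries and cross-condition correlations
# ---------------------------------------------------------------------------

def line_summaries(
    table: pd.DataFrame,
    treatments: tuple[str, str] = TREATMENTS,
) -> pd.DataFrame:
    """Per-line condition means and ethanol sensitivity.

    Sensitivity is the signed difference mean(ethanol) - mean(regular); its
    magnitude is reported alongside.  Lines lacking data in either condition
    (e.g. lines that produced no viable output on one medium) are flagged
    excluded with a reason and carry NaN sensitivity.
    """
    table = validate_replicate_table(table)
    base, alt = treatments
    present = set(table["treatment"].unique())
    if not {base, alt} <= present:
        raise SchemaError(f"table needs both treatments {treatments}, has {sorted(present)}")

    means = table.pivot_table(index="line", columns="treatment", values="value", aggfunc="mean")
    counts = table.pivot_table(index="line", columns="treatment", values="value", aggfunc="size")
    out = pd.DataFrame(index=means.index)
    out[f"mean_{base}"] = means.get(base)
    out[f"mean_{alt}"] = means.get(alt)
    out[f"n_{base}"] = counts.get(base)
    out[f"n_{alt}"] = counts.get(alt)
    out["sensitivity"] = out[f"mean_{alt}"] - out[f"mean_{base}"]
    out["abs_sensitivity"] = out["sensitivity"].abs()

    reasons = []
    for line in out.index:
        miss = [t for t in (base, alt) if pd.isna(out.loc[line, f"mean_{t}"])]
        reasons.append("" if not miss else "missing_" + "+".join(miss))
    out["excluded"] = [bool(r) for r in reasons]
    out["exclude_reason"] = reasons
    out.index.name = "line"
    return out.reset_index()


def cross_condition_correlation(
    values_a: pd.Series, values_b: pd.Series
) -> dict:
    """Pearson correlation over lines present in both series.

    The series must be indexed by line id.  Returns r, the two-sided p-value
    from the t distribution, and the number of shared lines.
    """
    a = values_a.dropna()
    b = values_b.dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise DataError(f"need >=3 shared lines for a correlation, got {len(shared)}")
    r, p = stats.pearsonr(a.loc[shared].to_numpy(), b.loc[shared].to_numpy())
    return {"r": float(r), "p": float(p), "n": int(len(shared))}


# ---------------------------------------------------------------------------
# line-means table I/O (layout of a published per-line supplementary table)
# ---------------------------------------------------------------------------

def write_line_means_table(path, summaries: dict[str, pd.DataFrame],
                           treatments: tuple[str, str] = TREATMENTS) -> None:
    """Write per-line trait means as a wide TSV: line + <trait>_<condition> columns."""
    base, alt = treatments
    wide = None
    for trait, summ in summaries.items():
        cols = summ.set_index("line")[[f"mean_{base}", f"mean_{alt}"]]
        cols.columns = [f"{trait}_{base}", f"{trait}_{alt}"]
        wide = cols if wide is None else wide.join(cols, how="outer")
    wide.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_line_means_table(path, treatments: tuple[str, str] = TREATMENTS) -> dict[str, pd.DataFrame]:
    """Read a wide per-line trait-means TSV and rebuild per-trait summaries.

    Column headers are matched case-insensitively as ``<trait><sep><condition>``
    with separator ``_``, ``-``, ``.`` or space; condition labels must contain
    the configured treatment names (so e.g. "Viability Regular" works).
    Sensitivity is recomputed as ethanol minus regular; rows missing either
    condition are flagged excluded.
    """
    df = pd.read_csv(path, sep="\t")
    line_col = next((c for c in df.columns if c.strip().lower() in ("line", "line_id", "dgrp", "line id")), None)
    if line_col is None:
        raise SchemaError("line-means table needs a 'line' column")
    base, alt = treatments
    traits: dict[str, dict[str, str]] = {}
    for col in df.columns:
        if col == line_col:
            continue
        norm = col.strip().lower().replace("-", "_").replace(".", "_").replace(" ", "_")
        for cond in (base, alt):
            if norm.endswith("_" + cond) or norm.endswith(cond):
                trait = norm[: norm.rfind(cond)].rstrip("_")
                if trait:
                    traits.setdefault(trait, {})[cond] = col
    out: dict[str, pd.DataFrame] = {}
    for trait, cols in traits.items():
        if set(cols) != {base, alt}:
            continue
        summ = pd.DataFrame({"line": df[line_col]})
        summ[f"mean_{base}"] = pd.to_numeric(df[cols[base]], errors="coerce")
        summ[f"mean_{alt}"] = pd.to_numeric(df[cols[alt]], errors="coerce")
        summ["sensitivity"] = summ[f"mean_{alt}"] - summ[f"mean_{base}"]
        summ["abs_sensitivity"] = summ["sensitivity"].abs()
        summ["excluded"] = summ[[f"mean_{base}", f"mean_{alt}"]].isna().any(axis=1)
        summ["exclude_reason"] = np.where(summ["excluded"], "missing_condition", "")
        out[trait] = summ
    if not out:
        raise SchemaError("no <trait>_<condition> column pairs recognised in line-means table")
    return out
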