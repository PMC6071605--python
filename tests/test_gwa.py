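"""MAF filtering, line-mean regression, thresholds, gene annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ethodev import gwa, synthdata
from ethodev.errors import ConfigError, DataError


def _matrix(calls, lines=None, chrom="2L"):
    calls = np.asarray(calls, dtype=float)
    m, b = calls.shape
    lines = lines or [f"l{i}" for i in range(b)]
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)], "chrom": chrom,
        "pos": np.arange(1, m + 1) * 100, "ref": "A", "alt": "T",
    })
    return gwa.GenotypeMatrix(variants=variants, calls=calls, lines=lines)


class TestMafFilter:
    def test_boundary_is_inclusive_at_threshold(self):
        # 200 lines: 9 carriers -> MAF 0.045 (dropped), 10 carriers -> 0.05 (kept)
        calls = np.zeros((2, 200))
        calls[0, :9] = 2
        calls[1, :10] = 2
        kept = gwa.maf_filter(_matrix(calls), 0.05)
        assert kept.variants["id"].tolist() == ["v1"]
        assert kept.variants.attrs["maf_filter"] == {
            "threshold": 0.05, "kept": 1, "dropped": 1}

    def test_monomorphic_dropped_at_any_positive_threshold(self):
        calls = np.zeros((1, 50))
        assert gwa.maf_filter(_matrix(calls), 0.01).n_variants == 0
        calls2 = np.full((1, 50), 2.0)
        assert gwa.maf_filter(_matrix(calls2), 0.01).n_variants == 0

    def test_zero_threshold_keeps_everything_called(self):
        calls = np.zeros((3, 10))
        calls[1, :5] = 2
        calls[2] = np.nan
        kept = gwa.maf_filter(_matrix(calls), 0.0)
        assert kept.variants["id"].tolist() == ["v0", "v1"]

    def test_idempotent(self):
        g = synthdata.simulate_genotypes(synthdata.SimulationConfig(
            n_lines=40, n_variants=300, maf_range=(0.01, 0.5), seed=17))
        once = gwa.maf_filter(g, 0.05)
        twice = gwa.maf_filter(once, 0.05)
        assert np.array_equal(once.calls, twice.calls)

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            gwa.maf_filter(_matrix(np.zeros((1, 4))), 0.6)


class TestAssociate:
    def test_eight_line_worked_fixture_matches_closed_form_ols(self):
        calls = np.array([[0, 0, 0, 0, 2, 2, 2, 2]], dtype=float)
        y = pd.Series([1, 1.2, 0.9, 1.1, 2.0, 2.1, 1.9, 2.2],
                      index=[f"l{i}" for i in range(8)])
        rec = gwa.associate(_matrix(calls), y, min_lines=8)
        lr = stats.linregress(calls[0], y.to_numpy())
        assert rec["effect"].iloc[0] == pytest.approx(lr.slope, abs=1e-10)
        assert rec["se"].iloc[0] == pytest.approx(lr.stderr, abs=1e-10)
        assert rec["p"].iloc[0] == pytest.approx(lr.pvalue, rel=1e-10)
        assert rec["n"].iloc[0] == 8

    def test_noise_free_phenotype_gives_unit_slope_and_underflow_flag(self):
        rng = np.random.default_rng(3)
        calls = 2.0 * (rng.random((1, 40)) < 0.5)
        y = pd.Series(calls[0], index=[f"l{i}" for i in range(40)])
        rec = gwa.associate(_matrix(calls), y)
        assert rec["effect"].iloc[0] == pytest.approx(1.0)
        assert rec["p"].iloc[0] <= 1e-200
        assert rec["flag"].iloc[0] == "underflow"

    def test_constant_genotype_emits_degenerate_record(self):
        calls = np.vstack([np.zeros(30), 2.0 * (np.arange(30) % 2)])
        y = pd.Series(np.random.default_rng(0).normal(size=30),
                      index=[f"l{i}" for i in range(30)])
        rec = gwa.associate(_matrix(calls), y)
        assert rec["flag"].iloc[0] == "degenerate"
        assert rec["p"].iloc[0] == 1.0
        assert rec["flag"].iloc[1] == ""

    def test_min_class_lines_guard(self):
        calls = np.zeros((1, 30))
        calls[0, :3] = 2  # 3 carriers < default 4
        y = pd.Series(np.arange(30, dtype=float), index=[f"l{i}" for i in range(30)])
        rec = gwa.associate(_matrix(calls), y)
        assert rec["flag"].iloc[0] == "degenerate"
        rec2 = gwa.associate(_matrix(calls), y, min_class_lines=3)
        assert rec2["flag"].iloc[0] == ""

    def test_vectorised_path_equals_per_variant_linregress(self, rng):
        g = synthdata.simulate_genotypes(synthdata.SimulationConfig(
            n_lines=100, n_variants=200, seed=23))
        g = gwa.maf_filter(g, 0.05)
        y = pd.Series(rng.normal(size=100), index=g.lines)
        rec = gwa.associate(g, y)
        for j in range(g.n_variants):
            if rec["flag"].iloc[j]:
                continue
            lr = stats.linregress(g.calls[j], y.to_numpy())
            assert rec["effect"].iloc[j] == pytest.approx(lr.slope, abs=1e-10)
            assert rec["p"].iloc[j] == pytest.approx(lr.pvalue, rel=1e-8)

    def test_missing_calls_drop_lines_per_variant(self, rng):
        calls = 2.0 * (rng.random((1, 60)) < 0.4)
        calls[0, :10] = np.nan
        y = pd.Series(rng.normal(size=60), index=[f"l{i}" for i in range(60)])
        rec = gwa.associate(_matrix(calls), y)
        assert rec["n"].iloc[0] == 50
        mask = ~np.isnan(calls[0])
        lr = stats.linregress(calls[0, mask], y.to_numpy()[mask])
        assert rec["effect"].iloc[0] == pytest.approx(lr.slope, abs=1e-10)

    def test_covariate_adjustment_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        n = 80
        lines = [f"l{i}" for i in range(n)]
        calls = 2.0 * (rng.random((5, n)) < 0.3)
        covar = pd.DataFrame({"wolb": rng.random(n), "inv": rng.random(n)}, index=lines)
        y = pd.Series(rng.normal(size=n) + 0.5 * covar["wolb"], index=lines)
        rec = gwa.associate(_matrix(calls), y, covariates=covar)
        for j in range(5):
            if rec["flag"].iloc[j]:
                continue
            X = sm.add_constant(np.column_stack([calls[j], covar.to_numpy()]))
            fit = sm.OLS(y.to_numpy(), X).fit()
            assert rec["effect"].iloc[j] == pytest.approx(fit.params[1], abs=1e-10)
            assert rec["se"].iloc[j] == pytest.approx(fit.bse[1], abs=1e-10)
            assert rec["p"].iloc[j] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_rank_deficient_covariates_rejected(self, rng):
        n = 40
        lines = [f"l{i}" for i in range(n)]
        c = rng.random(n)
        covar = pd.DataFrame({"a": c, "b": 2 * c}, index=lines)
        y = pd.Series(rng.normal(size=n), index=lines)
        with pytest.raises(DataError):
            gwa.associate(_matrix(2.0 * (rng.random((1, n)) < 0.4)), y, covariates=covar)

    def test_causal_variant_detected_in_majority_of_seeds(self):
        """Power: a 1-sigma-per-2-alleles effect at MAF 0.3 across 200 lines."""
        found = 0
        n_seeds = 11
        for seed in range(n_seeds):
            rng = np.random.default_rng(500 + seed)
            n = 200
            calls = 2.0 * (rng.random((50, n)) < 0.3)
            y_arr = rng.normal(size=n)
            y_arr += 0.5 * calls[0] * y_arr.std()  # 1 sigma between genotype classes
            y = pd.Series(y_arr, index=[f"l{i}" for i in range(n)])
            rec = gwa.associate(_matrix(calls), y)
            hits = gwa.threshold_hits(rec, 1e-5)
            if "v0" in set(hits["id"]):
                found += 1
        assert found > n_seeds // 2


class TestThresholdHits:
    def test_boundary_is_strict(self):
        rec = pd.DataFrame({"id": ["a", "b"], "p": [1e-5, 0.9e-5], "flag": ["", ""]})
        out = gwa.threshold_hits(rec, 1e-5)
        assert out["id"].tolist() == ["b"]

    def test_empty_input_gives_empty_output(self):
        rec = pd.DataFrame({"id": [], "p": [], "flag": []})
        assert len(gwa.threshold_hits(rec, 1e-5)) == 0

    def test_matches_brute_force_filter_and_is_sorted(self, rng):
        rec = pd.DataFrame({
            "id": [f"v{i}" for i in range(100)],
            "p": 10 ** rng.uniform(-8, 0, size=100),
            "flag": [""] * 100,
        })
        out = gwa.threshold_hits(rec, 1e-3)
        expect = sorted(rec.loc[rec["p"] < 1e-3, "id"],
                        key=lambda i: rec.set_index("id").loc[i, "p"])
        assert out["id"].tolist() == expect
        assert out["p"].is_monotonic_increasing

    def test_relaxed_threshold_is_superset(self, rng):
        rec = pd.DataFrame({
            "id": [f"v{i}" for i in range(200)],
            "p": 10 ** rng.uniform(-7, 0, size=200),
            "flag": [""] * 200,
        })
        strict = set(gwa.threshold_hits(rec, 1e-5)["id"])
        relaxed = set(gwa.threshold_hits(rec, 5e-5)["id"])
        assert strict <= relaxed


class TestAnnotation:
    @pytest.fixture()
    def genes(self):
        return gwa.GeneModelSet(genes=pd.DataFrame({
            "id": ["gA", "gB", "gC"], "chrom": ["2L", "2L", "3R"],
            "start": [1000, 5000, 100], "end": [2000, 6000, 400],
            "strand": ["+", "-", "+"],
        }))

    def _records(self, rows):
        return pd.DataFrame(rows, columns=["id", "chrom", "pos"])

    def test_variant_inside_gene_body(self, genes):
        out = gwa.annotate_variants(self._records([("v", "2L", 1500)]), genes)
        assert out["genes"].iloc[0] == "gA:inside:0"

    def test_upstream_window_boundary(self, genes):
        # gene gA spans 0-based [1000, 2000); 1-based body is 1001..2000
        near = gwa.annotate_variants(self._records([("v", "2L", 2)]), genes, window=1000)
        assert near["genes"].iloc[0] == "gA:near:999"
        edge = gwa.annotate_variants(self._records([("v", "2L", 1)]), genes, window=1000)
        assert edge["genes"].iloc[0] == "gA:near:1000"
        # downstream: last body base is 1-based 2000, so 3000 sits exactly 1000 away
        out = gwa.annotate_variants(self._records([("v", "2L", 3000)]), genes, window=1000)
        assert out["genes"].iloc[0] == "gA:near:1000"
        out2 = gwa.annotate_variants(self._records([("v", "2L", 3001)]), genes, window=1000)
        assert out2["genes"].iloc[0] == "intergenic"

    def test_hand_laid_out_toy_annotations(self, genes):
        recs = self._records([
            ("v1", "2L", 1001),   # first base of gA
            ("v2", "2L", 4500),   # upstream of gB (first body base 1-based 5001)
            ("v3", "2L", 2500),   # near gA (500 bp right of body)
            ("v4", "3R", 350),    # inside gC
            ("v5", "X", 100),     # unknown chromosome
        ])
        out = gwa.annotate_variants(recs, genes, window=1000)
        assert out["genes"].tolist() == [
            "gA:inside:0", "gB:near:501", "gA:near:500", "gC:inside:0", "unknown_chrom",
        ]
        assert out.attrs["n_distinct_genes"] == 3
        assert gwa.distinct_genes(out) == ["gA", "gB", "gC"]

    def test_variant_near_two_genes_lists_both(self, genes):
        # 2-based gap between gA end (2000) and gB start (5000): midpoint-ish
        recs = self._records([("v", "2L", 2500)])
        out = gwa.annotate_variants(recs, genes, window=4000)
        assert set(out["gene_ids"].iloc[0].split(",")) == {"gA", "gB"}


def test_null_pvalues_uniform_by_ks(rng):
    """Under a global null the per-variant p-values are U(0,1)."""
    g = synthdata.simulate_genotypes(synthdata.SimulationConfig(
        n_lines=150, n_variants=2000, seed=29))
    g = gwa.maf_filter(g, 0.05)
    y = pd.Series(rng.normal(size=150), index=g.lines)
    rec = gwa.associate(g, y)
    ps = rec.loc[rec["flag"] == "", "p"]
    assert stats.kstest(ps, "uniform").pvalue > 0.01
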