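"""Variance partitioning, heritability, derived phenotypes, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ethodev import quantgen, synthdata
from ethodev.errors import DataError, InsufficientReplicationError, SchemaError


class TestVarianceComponents:
    def test_integer_toy_ems_solution(self, toy_balanced_table):
        vd = quantgen.fit_variance_components(toy_balanced_table, "full", method="ems")
        assert vd.components == pytest.approx({"e": 2.0, "LT": 1.0, "L": 2.0})
        assert vd.H2 == pytest.approx(0.6)
        assert vd.sigma2_G == pytest.approx(3.0)
        assert vd.sigma2_P == pytest.approx(5.0)

    def test_reml_agrees_with_ems_on_balanced_toy(self, toy_balanced_table):
        ems = quantgen.fit_variance_components(toy_balanced_table, "full", method="ems")
        reml = quantgen.fit_variance_components(toy_balanced_table, "full", method="reml")
        for k in ems.components:
            assert reml.components[k] == pytest.approx(ems.components[k], abs=1e-6)

    def test_reml_agrees_with_ems_on_balanced_sexed_panel(self):
        t = synthdata.simulate_phenotypes(
            synthdata.locomotion_config(n_lines=25, n_replicates=4, seed=13))
        ems = quantgen.fit_variance_components(t, "sexed_full", method="ems")
        reml = quantgen.fit_variance_components(t, "sexed_full", method="reml")
        for k in ems.components:
            assert reml.components[k] == pytest.approx(ems.components[k], abs=1e-4)

    def test_null_heritability_estimates_near_zero(self):
        h2 = []
        for seed in range(10):
            cfg = synthdata.SimulationConfig(
                n_lines=200, n_replicates=5, sigma2_L=0, sigma2_LT=0,
                sigma2_eps=1.0, grand_mean=5, treatment_effect=1, seed=300 + seed)
            t = synthdata.simulate_phenotypes(cfg)
            h2.append(quantgen.fit_variance_components(t, "full").H2)
        assert np.mean(h2) <= 0.05

    def test_noise_free_distinct_lines_give_h2_of_one(self):
        rows = []
        for li, eff in enumerate([0.0, 1.0, 3.0, 6.0]):
            for t in ("regular", "ethanol"):
                for r in (1, 2):
                    rows.append((f"l{li}", t, "NA", r, 10.0 + eff))
        df = pd.DataFrame(rows, columns=["line", "treatment", "sex", "replicate", "value"])
        assert quantgen.fit_variance_components(df, "full").H2 == pytest.approx(1.0)

    def test_negative_components_truncated_keeping_h2_in_unit_interval(self):
        # pure-noise tiny design frequently drives raw solutions negative
        for seed in range(5):
            cfg = synthdata.SimulationConfig(
                n_lines=6, n_replicates=2, sigma2_L=0, sigma2_LT=0,
                sigma2_eps=1.0, grand_mean=0, treatment_effect=0, seed=seed)
            vd = quantgen.fit_variance_components(synthdata.simulate_phenotypes(cfg), "full")
            assert 0.0 <= vd.H2 <= 1.0
            assert all(v >= 0 for v in vd.components.values())

    def test_reduced_model_requires_single_condition(self, toy_balanced_table):
        with pytest.raises(SchemaError):
            quantgen.fit_variance_components(toy_balanced_table, "reduced")
        sub = toy_balanced_table[toy_balanced_table.treatment == "regular"]
        vd = quantgen.fit_variance_components(sub, "reduced")
        assert set(vd.components) == {"e", "L"}

    def test_sexed_model_without_sex_column_is_schema_error(self, toy_balanced_table):
        with pytest.raises(SchemaError):
            quantgen.fit_variance_components(toy_balanced_table, "sexed_full")

    def test_single_replicate_rejected(self):
        rows = [(f"l{i}", t, "NA", 1, float(i)) for i in range(3)
                for t in ("regular", "ethanol")]
        df = pd.DataFrame(rows, columns=["line", "treatment", "sex", "replicate", "value"])
        with pytest.raises(InsufficientReplicationError):
            quantgen.fit_variance_components(df, "full")

    @given(shift=st.floats(-50, 50), scale=st.floats(0.01, 100))
    def test_h2_invariant_under_positive_affine_transform(self, toy_balanced_table,
                                                          shift, scale):
        t2 = toy_balanced_table.copy()
        t2["value"] = shift + scale * t2["value"]
        vd = quantgen.fit_variance_components(t2, "full")
        assert vd.H2 == pytest.approx(0.6, abs=1e-9)


class TestDerivedPhenotypes:
    def test_viability_is_elementwise_fraction(self):
        raw = pd.DataFrame({
            "line": ["a", "a", "b"], "treatment": ["regular"] * 3,
            "replicate": [1, 2, 1],
            "n_adults": [25, 0, 50], "n_eggs": [50, 50, 50],
        })
        out = quantgen.derive_viability(raw)
        assert out["value"].tolist() == [0.5, 0.0, 1.0]

    def test_viability_vector_matches_elementwise_division(self, rng):
        eggs = rng.integers(10, 60, size=40)
        adults = rng.integers(0, eggs + 1)
        raw = pd.DataFrame({
            "line": [f"l{i}" for i in range(40)], "treatment": "regular",
            "replicate": 1, "n_adults": adults, "n_eggs": eggs,
        })
        assert np.allclose(quantgen.derive_viability(raw)["value"], adults / eggs)

    def test_viability_count_preconditions(self):
        bad = pd.DataFrame({"line": ["a"], "treatment": ["regular"], "replicate": [1],
                            "n_adults": [51], "n_eggs": [50]})
        with pytest.raises(DataError):
            quantgen.derive_viability(bad)
        bad2 = bad.assign(n_adults=1, n_eggs=0)
        with pytest.raises(DataError):
            quantgen.derive_viability(bad2)

    def test_development_time_weighted_mean(self):
        ec = pd.DataFrame({
            "line": ["a"] * 2 + ["b"] * 2, "treatment": "regular",
            "replicate": 1, "day": [9, 11, 9, 9],
            "n_eclosed": [10, 10, 7, 0],
        })
        out = quantgen.derive_development_time(ec)
        vals = out.set_index("line")["value"]
        assert vals["a"] == pytest.approx(10.0)  # symmetric two-day split
        assert vals["b"] == pytest.approx(9.0)   # all flies on day 9

    def test_development_time_equals_per_fly_expansion(self, rng):
        days = np.arange(8, 15)
        counts = rng.integers(0, 20, size=len(days))
        counts[3] += 1  # ensure at least one fly
        ec = pd.DataFrame({"line": "a", "treatment": "regular", "replicate": 1,
                           "day": days, "n_eclosed": counts})
        per_fly = np.repeat(days, counts).mean()
        out = quantgen.derive_development_time(ec)
        assert out["value"].iloc[0] == pytest.approx(per_fly)

    def test_zero_eclosion_replicate_dropped_with_count(self):
        ec = pd.DataFrame({"line": ["a", "b"], "treatment": "regular",
                           "replicate": 1, "day": 9, "n_eclosed": [0, 5]})
        out = quantgen.derive_development_time(ec)
        assert out["line"].tolist() == ["b"]
        assert out.attrs["dropped_replicates"] == 1


class TestLineSummaries:
    def test_known_cell_means_recovered(self):
        rows = [("a", "regular", "NA", 1, 1.0), ("a", "regular", "NA", 2, 3.0),
                ("a", "ethanol", "NA", 1, 6.0), ("a", "ethanol", "NA", 2, 8.0),
                ("b", "regular", "NA", 1, 5.0), ("b", "regular", "NA", 2, 5.0),
                ("b", "ethanol", "NA", 1, 5.0), ("b", "ethanol", "NA", 2, 5.0)]
        df = pd.DataFrame(rows, columns=["line", "treatment", "sex", "replicate", "value"])
        s = quantgen.line_summaries(df).set_index("line")
        assert s.loc["a", "mean_regular"] == 2.0
        assert s.loc["a", "mean_ethanol"] == 7.0
        assert s.loc["a", "sensitivity"] == 5.0
        assert s.loc["b", "sensitivity"] == 0.0
        assert not s["excluded"].any()

    def test_line_missing_one_condition_flagged_excluded(self):
        rows = [("a", "regular", "NA", 1, 1.0), ("a", "regular", "NA", 2, 1.0),
                ("a", "ethanol", "NA", 1, 2.0), ("a", "ethanol", "NA", 2, 2.0),
                ("dead", "regular", "NA", 1, 0.5), ("dead", "regular", "NA", 2, 0.4)]
        df = pd.DataFrame(rows, columns=["line", "treatment", "sex", "replicate", "value"])
        s = quantgen.line_summaries(df).set_index("line")
        assert bool(s.loc["dead", "excluded"])
        assert s.loc["dead", "exclude_reason"] == "missing_ethanol"
        assert np.isnan(s.loc["dead", "sensitivity"])
        assert not bool(s.loc["a", "excluded"])

    def test_mean_sensitivity_tracks_treatment_effect(self):
        cfg = synthdata.SimulationConfig(
            n_lines=150, n_replicates=5, grand_mean=10, treatment_effect=0.7,
            sigma2_L=0.3, sigma2_LT=0.2, sigma2_eps=0.5, seed=21)
        s = quantgen.line_summaries(synthdata.simulate_phenotypes(cfg))
        se = np.sqrt((2 * 0.2 + 2 * 0.5 / 5) / 150)
        assert s["sensitivity"].mean() == pytest.approx(0.7, abs=4 * se)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        x = pd.Series([1.0, 2.0, 5.0, 3.0], index=list("abcd"))
        rec = quantgen.cross_condition_correlation(x, x)
        assert rec["r"] == pytest.approx(1.0)
        assert rec["n"] == 4

    def test_matches_textbook_pearson_formula(self):
        x = pd.Series([1.0, 2.0, 4.0, 3.0, 7.0], index=list("abcde"))
        y = pd.Series([2.0, 1.5, 3.0, 2.0, 6.5], index=list("abcde"))
        xd, yd = x - x.mean(), y - y.mean()
        r_hand = (xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum())
        rec = quantgen.cross_condition_correlation(x, y)
        assert rec["r"] == pytest.approx(float(r_hand), abs=1e-12)
        assert 0 < rec["p"] <= 1

    def test_alignment_ignores_lines_missing_either_field(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        y = pd.Series([2.0, 4.0, 6.0], index=list("abc"))
        assert quantgen.cross_condition_correlation(x, y)["n"] == 3

    def test_too_few_shared_lines_is_error(self):
        x = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(DataError):
            quantgen.cross_condition_correlation(x, x)


class TestLineMeansTable:
    def test_round_trip(self, tmp_path):
        t = synthdata.simulate_phenotypes(synthdata.viability_config(n_lines=12, seed=31))
        summ = {"viability": quantgen.line_summaries(t)}
        path = tmp_path / "line_means.tsv"
        quantgen.write_line_means_table(path, summ)
        back = quantgen.read_line_means_table(path)
        assert set(back) == {"viability"}
        merged = summ["viability"].merge(back["viability"], on="line", suffixes=("", "_rt"))
        assert np.allclose(merged["sensitivity"], merged["sensitivity_rt"])

    def test_header_variants_recognised(self, tmp_path):
        df = pd.DataFrame({
            "Line": ["l1", "l2", "l3"],
            "Viability Regular": [0.5, 0.6, 0.7],
            "Viability Ethanol": [0.2, 0.3, 0.1],
        })
        p = tmp_path / "s1.tsv"
        df.to_csv(p, sep="\t", index=False)
        out = quantgen.read_line_means_table(p)
        assert list(out) == ["viability"]
        assert out["viability"]["sensitivity"].tolist() == pytest.approx([-0.3, -0.3, -0.6])
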