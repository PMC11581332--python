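import numpy as np
import pandas as pd
import pytest

from hrqolseg.association import (
    SeparationWarning,
    aic_retained,
    build_design,
    collinearity_check,
    descriptive_table,
    fit_multinomial,
    forward_select_aic,
    refit_with_msss,
)
from .conftest import simulate_multinomial


def intercept_design(n):
    return pd.DataFrame({"intercept": np.ones(n)})


class TestFitMultinomial:
    def test_intercept_only_reproduces_frequencies(self):
        labels = np.repeat(["low", "normal", "high"], [417, 858, 422])
        fit = fit_multinomial(labels, intercept_design(len(labels)), reference="normal")
        probs = fit.predict_proba(intercept_design(1))
        np.testing.assert_allclose(
            probs[0], [858 / 1697, 422 / 1697, 417 / 1697], atol=1e-9
        )
        rrr = fit.rrr.set_index("category")["RRR"]
        assert rrr["low"] == pytest.approx(417 / 858, abs=1e-9)
        assert rrr["high"] == pytest.approx(422 / 858, abs=1e-9)

    def test_saturated_2x3_matches_hand_computation(self):
        x = np.repeat([0.0, 1.0], [300, 300])
        labels = np.concatenate(
            [np.repeat(["a", "b", "c"], [100, 150, 50]), np.repeat(["a", "b", "c"], [60, 180, 60])]
        )
        X = pd.DataFrame({"intercept": np.ones(600), "x": x})
        fit = fit_multinomial(labels, X, reference="b")
        assert fit.params.loc["x", "a"] == pytest.approx(np.log((60 / 180) / (100 / 150)), abs=1e-8)
        assert fit.params.loc["x", "c"] == pytest.approx(np.log((60 / 180) / (50 / 150)), abs=1e-8)
        assert fit.params.loc["intercept", "a"] == pytest.approx(np.log(100 / 150), abs=1e-8)

    def test_gradient_vanishes_at_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=500)})
        labels = simulate_multinomial(
            {"b": {"intercept": 0.3, "x": 0.8}, "c": {"intercept": -0.2, "x": -0.5}},
            X, ["a", "b", "c"], rng,
        )
        fit = fit_multinomial(labels, X, reference="a")
        codes = pd.Categorical(pd.Series(labels), categories=fit.categories).codes
        model = sm.MNLogit(codes, X.to_numpy())
        grad = model.score(fit.params.to_numpy().ravel(order="F"))
        assert np.max(np.abs(grad)) < 1e-8

    def test_aic_identity(self):
        labels = np.repeat(["low", "normal", "high"], [40, 80, 40])
        fit = fit_multinomial(labels, intercept_design(160), reference="normal")
        assert fit.aic == pytest.approx(2 * fit.params.size - 2 * fit.loglik, abs=1e-10)

    def test_separation_warns_with_covariate_name(self):
        x = np.repeat([0.0, 1.0], [60, 60])
        labels = np.array(["a"] * 30 + ["b"] * 30 + ["b"] * 60)  # 'a' only when x == 0
        X = pd.DataFrame({"intercept": np.ones(120), "sep_flag": x})
        with pytest.warns(SeparationWarning, match="sep_flag"):
            fit_multinomial(labels, X, reference="b")

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(60), "a": np.arange(60.0), "b": 2 * np.arange(60.0)})
        labels = np.tile(["x", "y", "z"], 20)
        with pytest.raises(ValueError, match="rank"):
            fit_multinomial(labels, X, reference="y")


class TestForwardSelection:
    def test_retention_threshold_is_two_or_more(self):
        assert aic_retained(-2.0)
        assert not aic_retained(-1.9)
        assert aic_retained(-5.3)
        assert not aic_retained(0.0)

    def test_informative_candidate_retained_noise_rejected(self):
        rng = np.random.default_rng(7)
        n = 1500
        table = pd.DataFrame(
            {
                "signal": rng.integers(0, 2, n).astype(float),
                "noise": rng.normal(size=n),
            }
        )
        X = pd.DataFrame({"intercept": np.ones(n), "signal": table["signal"]})
        labels = simulate_multinomial(
            {"low": {"intercept": -0.7, "signal": 1.0}, "high": {"intercept": -0.7, "signal": -1.0}},
            X, ["normal", "low", "high"], rng,
        )
        trace, final = forward_select_aic(
            table, labels, base_terms=[], candidates=["signal", "noise"], reference="normal"
        )
        assert "signal" in trace.retained
        assert "noise" not in trace.retained
        steps = {s["candidate"]: s for s in trace.steps}
        assert steps["signal"]["delta_aic"] <= -2
        assert final.aic <= steps["signal"]["aic_before"]

    def test_noise_rejected_in_most_replicates(self):
        rejected = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 600
            table = pd.DataFrame({"noise": rng.normal(size=n)})
            labels = rng.choice(["normal", "low", "high"], size=n, p=[0.5, 0.25, 0.25])
            trace, _ = forward_select_aic(
                table, labels, base_terms=[], candidates=["noise"], reference="normal"
            )
            rejected += "noise" not in trace.retained
        assert rejected >= 0.9 * reps

    def test_msss_never_a_candidate(self):
        rng = np.random.default_rng(3)
        n = 300
        table = pd.DataFrame({"msss": rng.uniform(0, 10, n), "flag": rng.integers(0, 2, n)})
        labels = rng.choice(["normal", "low", "high"], size=n)
        trace, _ = forward_select_aic(
            table, labels, base_terms=[], candidates=["msss", "flag"], reference="normal"
        )
        assert "msss" not in trace.retained
        assert any(s.get("decision") == "excluded" for s in trace.steps)

    def test_aic_non_increasing_over_retained_steps(self, small_cohort):
        _, table, _ = small_cohort
        rng = np.random.default_rng(0)
        labels = np.where(
            table["eq5d_index"] < table["eq5d_index"].quantile(0.25), "low",
            np.where(table["eq5d_index"] > table["eq5d_index"].quantile(0.75), "high", "normal"),
        )
        trace, final = forward_select_aic(
            table, labels, base_terms=["sex"],
            candidates=["symptom_depression", "symptom_fatigue", "disability_benefit"],
            reference="normal",
        )
        aics = [s["aic_after"] for s in trace.steps if s["decision"] == "retained"]
        assert all(a >= b for a, b in zip(aics, aics[1:]))


class TestCollinearity:
    def test_orthogonal_design_unit_vif(self):
        n = 64
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        X = pd.DataFrame({"intercept": np.ones(n), "a": a, "b": b})
        out = collinearity_check(X)
        assert np.allclose(out["gvif"], 1.0, atol=1e-10)
        assert not out["flagged"].any()

    def test_two_predictors_with_known_correlation(self):
        # construct columns with empirical correlation exactly 0.9
        n = 100
        e1 = np.tile([1.0, -1.0], n // 2)
        e2 = np.repeat([1.0, -1.0], n // 2)
        b = 0.9 * e1 + np.sqrt(1 - 0.81) * e2
        X = pd.DataFrame({"intercept": np.ones(n), "a": e1, "b": b})
        out = collinearity_check(X).set_index("term")
        assert out.loc["a", "gvif"] == pytest.approx(1 / (1 - 0.81), abs=1e-9)
        assert out.loc["a", "flagged"]

    def test_duplicated_column_flags_rank_deficiency(self):
        X = pd.DataFrame({"intercept": np.ones(50), "a": np.arange(50.0), "b": np.arange(50.0)})
        with pytest.raises(ValueError, match="rank"):
            collinearity_check(X)

    def test_categorical_term_aggregation(self, small_cohort):
        _, table, _ = small_cohort
        X, term_map = build_design(table, ["sex", "phenotype", "srdss_class"])
        out = collinearity_check(X, term_map)
        assert set(out["term"]) == {"sex", "phenotype", "srdss_class"}
        assert out.set_index("term").loc["phenotype", "df"] == 4


class TestDescriptiveTable:
    def test_median_and_iqr(self):
        table = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        out = descriptive_table(table, ["g"] * 3, ["v"])
        assert out.loc[0, "g"] == "2.0 [1.5; 2.5]"

    def test_percentage_hand_computation(self):
        table = pd.DataFrame({"flag": [1] * 7 + [0] * 13})
        out = descriptive_table(table, ["g"] * 20, ["flag"])
        row = out[out["variable"] == "flag=1"].iloc[0]
        assert row["g"] == "7 (35.0)"

    def test_counts_sum_to_group_sizes(self, small_cohort):
        _, table, _ = small_cohort
        groups = np.where(table["vas"] < 70, "lo", "hi")
        out = descriptive_table(table, groups, ["smoking"])
        for g in ("lo", "hi"):
            total = sum(int(v.split(" ")[0]) for v in out[g])
            assert total == (groups == g).sum()


class TestMsssRefit:
    def test_constant_msss_inestimable(self, small_cohort):
        _, table, _ = small_cohort
        table = table.copy()
        table["msss"] = 5.0
        labels = np.where(table["vas"] < 60, "low", np.where(table["vas"] > 90, "high", "normal"))
        with pytest.raises(ValueError, match="constant"):
            refit_with_msss(table, labels, ["sex"], reference="normal")

    def test_subsample_size_bookkeeping(self, small_cohort):
        _, table, _ = small_cohort
        rng = np.random.default_rng(1)
        table = table.copy()
        table["msss"] = np.where(rng.random(len(table)) < 0.5, rng.uniform(0, 10, len(table)), np.nan)
        labels = np.where(table["vas"] < 60, "low", np.where(table["vas"] > 90, "high", "normal"))
        fit = refit_with_msss(table, labels, ["sex"], reference="normal")
        assert fit.n == int(table["msss"].notna().sum())
        assert "msss" in fit.params.index

    def test_positive_msss_effect_recovered(self):
        detected = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(4000 + seed)
            n = 800
            msss = rng.uniform(0, 10, n)
            X = pd.DataFrame({"intercept": np.ones(n), "msss": msss - 5.0})
            labels = simulate_multinomial(
                {"low": {"intercept": -1.0, "msss": 0.25}, "high": {"intercept": -1.0, "msss": -0.25}},
                X, ["normal", "low", "high"], rng,
            )
            table = pd.DataFrame({"msss": msss, "dummy": np.ones(n)})
            fit = refit_with_msss(table, labels, [], reference="normal")
            rrr = fit.rrr
            row = rrr[(rrr["category"] == "low") & (rrr["covariate"] == "msss")].iloc[0]
            detected += row["RRR"] > 1
        assert detected >= 0.9 * reps
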