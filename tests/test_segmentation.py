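import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrqolseg.segmentation import (
    assign_quartile_bin,
    classify,
    enumeration_quantile_oracle,
    fit_conditional_quantiles,
    fit_quantile,
    label_discordance,
    pinball_loss,
    segment_cohort,
)


class TestPinballLoss:
    @pytest.mark.parametrize(
        "y, yhat, tau, expected",
        [
            ([1.0, 2.0], [1.0, 2.0], 0.5, 0.0),
            ([1.0], [0.0], 0.25, 0.25),
            ([0.0], [1.0], 0.25, 0.75),
            ([1.0, 0.0], [0.0, 1.0], 0.25, 1.0),
        ],
    )
    def test_hand_values(self, y, yhat, tau, expected):
        assert pinball_loss(y, yhat, tau) == pytest.approx(expected)

    def test_invalid_tau(self):
        with pytest.raises(ValueError, match="tau"):
            pinball_loss([1.0], [1.0], 1.5)


class TestFitQuantile:
    def test_constant_outcome_gives_flat_fit(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(8), rng.normal(size=(8, 2))])
        for tau in (0.25, 0.5, 0.75):
            fit = fit_quantile(np.full(8, 7.5), X, tau)
            assert fit.coef == pytest.approx([7.5, 0.0, 0.0], abs=1e-9)
            assert fit.loss == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle_small(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = rng.integers(5, 11)
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = rng.normal(size=n) * 5
            tau = rng.choice([0.25, 0.5, 0.75])
            fit = fit_quantile(y, X, tau)
            _, oracle_loss = enumeration_quantile_oracle(y, X, tau)
            assert fit.loss == pytest.approx(oracle_loss, abs=1e-9)

    def test_matches_statsmodels_quantreg(self):
        # independent library cross-check on a moderate problem
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ [5.0, 1.0, -2.0] + rng.standard_t(df=5, size=n)
        for tau in (0.25, 0.5, 0.75):
            ours = fit_quantile(y, X, tau)
            theirs = sm.QuantReg(y, X).fit(q=tau, p_tol=1e-10)
            loss_theirs = pinball_loss(y, X @ theirs.params, tau)
            assert ours.loss <= loss_theirs + 1e-6
            assert ours.coef == pytest.approx(theirs.params, abs=1e-3)

    def test_on_sample_coverage_bounds(self):
        rng = np.random.default_rng(9)
        n, p = 500, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = X @ [10.0, 2.0, 1.0] + rng.normal(size=n) * 3
        for tau in (0.25, 0.5, 0.75):
            fit = fit_quantile(y, X, tau)
            yhat = fit.predict(X)
            below = int((y < yhat).sum())
            at_or_below = int((y <= yhat).sum())
            assert below <= tau * n
            assert at_or_below >= tau * n - 1e-9

    def test_collinear_design_rejected(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_quantile(np.arange(6.0), X, 0.5)

    def test_missing_values_rejected(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        y = np.arange(6.0)
        y[2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_quantile(y, X, 0.5)


class TestClassification:
    def test_low_normal_high(self):
        assert classify(50.0, 60.0, 90.0) == "low"
        assert classify(70.0, 60.0, 90.0) == "normal"
        assert classify(100.0, 60.0, 96.0) == "high"

    def test_boundary_ties_are_normal(self):
        assert classify(60.0, 60.0, 90.0) == "normal"
        assert classify(90.0, 60.0, 90.0) == "normal"

    @pytest.mark.parametrize(
        "y, expected_bin",
        [(10.0, 1), (25.0, 2), (49.9, 2), (50.0, 3), (75.0, 3), (75.1, 4)],
    )
    def test_bin_boundaries(self, y, expected_bin):
        assert assign_quartile_bin(y, 25.0, 50.0, 75.0) == expected_bin

    @given(
        st.floats(0, 100),
        st.floats(10, 40),
        st.floats(41, 60),
        st.floats(61, 90),
    )
    @settings(max_examples=200, deadline=None)
    def test_bins_partition_and_agree_with_labels(self, y, q25, q50, q75):
        b = assign_quartile_bin(y, q25, q50, q75)
        lab = classify(y, q25, q75)
        assert b in (1, 2, 3, 4)
        assert (b == 1) == (lab == "low")
        assert (b == 4) == (lab == "high")
        assert (b in (2, 3)) == (lab == "normal")


class TestDiscordance:
    def test_quoted_rule_cases(self):
        assert label_discordance(4, 2) == "lower_vas"
        assert label_discordance(2, 3) == "within_expectation"
        assert label_discordance(1, 4) == "higher_vas"

    def test_exhaustive_enumeration(self):
        labels = [label_discordance(e, v) for e in (1, 2, 3, 4) for v in (1, 2, 3, 4)]
        assert labels.count("lower_vas") == 3
        assert labels.count("higher_vas") == 3
        assert labels.count("within_expectation") == 10

    def test_symmetry_under_instrument_swap(self):
        swap = {"lower_vas": "higher_vas", "higher_vas": "lower_vas",
                "within_expectation": "within_expectation"}
        for e in (1, 2, 3, 4):
            for v in (1, 2, 3, 4):
                assert label_discordance(v, e) == swap[label_discordance(e, v)]

    def test_bin_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            label_discordance(0, 2)


class TestSegmentCohort:
    def test_labels_partition_cohort(self, small_cohort):
        _, table, _ = small_cohort
        res = segment_cohort(table)
        for inst in ("eq5d_index", "vas"):
            counts = res.group_counts(inst)
            assert sum(counts.values()) == len(table)
            assert set(counts) <= {"low", "normal", "high"}

    def test_every_participant_gets_one_discordance_label(self, small_cohort):
        _, table, _ = small_cohort
        res = segment_cohort(table)
        eq = res.table[res.table["instrument"] == "eq5d_index"]
        assert eq["discordance"].notna().all()
        assert len(eq) == len(table)

    def test_single_instrument_run(self, small_cohort):
        _, table, _ = small_cohort
        res = segment_cohort(table, instruments=("vas",))
        assert set(res.fits) == {"vas"}

    def test_missing_instrument_column_is_named(self, small_cohort):
        _, table, _ = small_cohort
        with pytest.raises(ValueError, match="vas"):
            segment_cohort(table.drop(columns="vas"))

    def test_point_coverage_on_default_cohort(self, default_cohort):
        # each group's share is within p/n of its nominal mass
        _, table, _ = default_cohort
        res = segment_cohort(table, instruments=("eq5d_index",))
        n = len(table)
        q25_fit, _, q75_fit = res.fits["eq5d_index"]
        assert q25_fit.tau == 0.25 and q75_fit.tau == 0.75
        counts = res.group_counts("eq5d_index")
        assert counts["low"] <= 0.25 * n
        assert counts["high"] <= 0.25 * n + 3  # ties at q75 go to normal
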