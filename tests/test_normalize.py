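"""Ratio, fold-change and summary mathematics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dualluc.core_model import NormalizationConfig, TidyExperiment, ValidationError
from dualluc.normalize import (
    compute_ratios,
    filter_experiment,
    fold_change,
    summarize,
)
from dualluc.simulate import SimulationSpec, default_spec, generate_experiment


def _exp(rows, factors=("condition",)):
    return TidyExperiment(data=pd.DataFrame(rows), factor_names=list(factors))


class TestComputeRatios:
    def test_simple_arithmetic(self):
        exp = _exp([{"well": "A01", "condition": "c",
                     "firefly": 1000.0, "renilla": 500.0}])
        assert compute_ratios(exp).data.loc[0, "ratio"] == 2.0

    def test_zero_firefly_gives_zero_ratio(self):
        exp = _exp([{"well": "A01", "condition": "c",
                     "firefly": 0.0, "renilla": 500.0}])
        assert compute_ratios(exp).data.loc[0, "ratio"] == 0.0

    def test_zero_renilla_errors_naming_wells(self):
        exp = _exp([
            {"well": "A01", "condition": "c", "firefly": 1.0, "renilla": 0.0},
            {"well": "A02", "condition": "c", "firefly": 1.0, "renilla": 2.0},
        ])
        with pytest.raises(ValidationError, match="A01"):
            compute_ratios(exp)
        with pytest.warns(UserWarning, match="A01"):
            dropped = compute_ratios(exp, drop_zero_control=True)
        assert len(dropped) == 1

    def test_absent_renilla_means_identity_normalization(self):
        exp = _exp([{"well": "A01", "condition": "c", "firefly": 123.0}])
        assert compute_ratios(exp).data.loc[0, "ratio"] == 123.0

    def test_ratios_match_elementwise_recomputation(self, full_plate_experiment):
        exp, _ = full_plate_experiment
        got = compute_ratios(exp).data
        for _, row in got.iterrows():  # independent loop oracle
            assert row["ratio"] == pytest.approx(
                row["firefly"] / row["renilla"], rel=1e-15
            )


class TestFilterExperiment:
    def test_exclude_single_well(self, full_plate_experiment):
        exp, _ = full_plate_experiment
        out, report = filter_experiment(exp, exclude_wells=["A01"])
        assert len(out) == len(exp) - 1
        assert report["well:A01"] == 1

    def test_exclude_condition_removes_all_matching_rows(
        self, full_plate_experiment
    ):
        exp, _ = full_plate_experiment
        # oracle: count control rows by scanning
        n_control = int((exp.data["condition"] == "control").sum())
        assert n_control == 24  # 4 drugs x 2 cells x 3 replicates
        out, report = filter_experiment(
            exp, exclude_conditions=["condition=control"]
        )
        assert len(out) == len(exp) - n_control
        assert report["condition:condition=control"] == n_control

    def test_empty_exclusions_are_identity(self, full_plate_experiment):
        exp, _ = full_plate_experiment
        out, report = filter_experiment(exp)
        assert out == exp and report == {}

    def test_unknown_exclusion_warns_not_errors(self, full_plate_experiment):
        exp, _ = full_plate_experiment  # 72 wells: rows A-F, H12 unused
        assert "H12" not in set(exp.data["well"])
        with pytest.warns(UserWarning, match="H12"):
            out, _ = filter_experiment(exp, exclude_wells=["H12"])
        assert len(out) == len(exp)
        with pytest.warns(UserWarning, match="ghost"):
            filter_experiment(exp, exclude_conditions=["condition=ghost"])


class TestFoldChange:
    def test_reference_mean_is_the_denominator(self):
        rows = [
            {"well": f"A0{i}", "condition": "ref", "firefly": 2.0,
             "renilla": 1.0} for i in (1, 2, 3)
        ] + [{"well": "A04", "condition": "x", "firefly": 4.0,
              "renilla": 1.0}]
        exp = compute_ratios(_exp(rows))
        out = fold_change(exp, NormalizationConfig("condition=ref"))
        assert out.data.loc[3, "fold_change"] == pytest.approx(2.0)

    def test_reference_group_self_normalizes_to_one(self, manual_experiment):
        exp = compute_ratios(manual_experiment)
        out = fold_change(exp, NormalizationConfig("condition=control"))
        ref = out.data[out.data["condition"] == "control"]["fold_change"]
        assert ref.mean() == pytest.approx(1.0, rel=1e-12)

    def test_stratified_recovers_per_stratum_effects_exactly(self):
        spec = SimulationSpec(
            factors={"condition": ["ref", "test"],
                     "drug": ["a", "b", "c"]},
            true_fold_change={"test_a": 1.0, "test_b": 2.0, "test_c": 0.5},
            replicates=3,
            transfection_sigma=0.0,
            measurement_sigma=0.0,
            seed=1,
        )
        exp, truth = generate_experiment(spec)
        out = fold_change(
            compute_ratios(exp),
            NormalizationConfig("condition=ref", stratified=True),
        )
        means = out.data.groupby(out.condition_keys())["fold_change"].mean()
        for key, val in truth.items():
            assert means[key] == pytest.approx(val, rel=1e-12)

    def test_stratum_without_reference_rows_errors_with_key(self):
        rows = [
            {"well": "A01", "condition": "ref", "drug": "a",
             "firefly": 1.0, "renilla": 1.0},
            {"well": "A02", "condition": "x", "drug": "b",
             "firefly": 1.0, "renilla": 1.0},
        ]
        exp = compute_ratios(_exp(rows, ("condition", "drug")))
        with pytest.raises(ValidationError, match="'b'"):
            fold_change(
                exp, NormalizationConfig("condition=ref", stratified=True)
            )

    def test_unmatched_reference_lists_available_keys(self, manual_experiment):
        exp = compute_ratios(manual_experiment)
        with pytest.raises(ValidationError, match="geneA"):
            fold_change(exp, NormalizationConfig("nope"))

    def test_zero_reference_mean_errors(self):
        rows = [
            {"well": "A01", "condition": "ref", "firefly": 0.0,
             "renilla": 1.0},
            {"well": "A02", "condition": "x", "firefly": 1.0,
             "renilla": 1.0},
        ]
        exp = compute_ratios(_exp(rows))
        with pytest.raises(ValidationError, match="0"):
            fold_change(exp, NormalizationConfig("condition=ref"))

    def test_geometric_mean_option(self):
        rows = [
            {"well": "A01", "condition": "ref", "firefly": 1.0,
             "renilla": 1.0},
            {"well": "A02", "condition": "ref", "firefly": 4.0,
             "renilla": 1.0},
            {"well": "A03", "condition": "x", "firefly": 6.0,
             "renilla": 1.0},
        ]
        exp = compute_ratios(_exp(rows))
        out = fold_change(
            exp, NormalizationConfig("condition=ref", geometric=True)
        )
        # geometric mean of {1, 4} is 2
        assert out.data.loc[2, "fold_change"] == pytest.approx(3.0)

    def test_requires_ratios_first(self, manual_experiment):
        with pytest.raises(ValidationError, match="ratio"):
            fold_change(
                manual_experiment, NormalizationConfig("condition=control")
            )


class TestInvarianceProperties:
    @pytest.mark.parametrize("c", [0.001, 1.0, 1000.0])
    def test_scale_invariance_of_fold_change(self, full_plate_experiment, c):
        """Rescaling both channels by one gain factor cannot move fold
        changes: the gain cancels in the ratio before any referencing."""
        exp, _ = full_plate_experiment
        cfg = NormalizationConfig("condition=control")
        base = fold_change(compute_ratios(exp), cfg).data["fold_change"]
        scaled_df = exp.data.copy()
        scaled_df[["firefly", "renilla"]] *= c
        scaled = fold_change(
            compute_ratios(exp.replace_data(scaled_df)), cfg
        ).data["fold_change"]
        np.testing.assert_allclose(scaled, base, rtol=1e-12)

    def test_firefly_gain_cancels_through_the_reference(
        self, full_plate_experiment
    ):
        """Multiplying every firefly value by k scales numerator and
        denominator alike, so fold changes are unchanged; scaling only the
        non-reference wells scales their fold changes by exactly k."""
        exp, _ = full_plate_experiment
        cfg = NormalizationConfig("condition=control", stratified=False)
        base = fold_change(compute_ratios(exp), cfg).data["fold_change"]
        k = 7.5
        all_df = exp.data.copy()
        all_df["firefly"] *= k
        got_all = fold_change(
            compute_ratios(exp.replace_data(all_df)), cfg
        ).data["fold_change"]
        np.testing.assert_allclose(got_all, base, rtol=1e-12)

        part_df = exp.data.copy()
        non_ref = part_df["condition"] != "control"
        part_df.loc[non_ref, "firefly"] *= k
        got_part = fold_change(
            compute_ratios(exp.replace_data(part_df)), cfg
        ).data["fold_change"]
        np.testing.assert_allclose(
            got_part[non_ref.to_numpy()], base[non_ref.to_numpy()] * k,
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            got_part[~non_ref.to_numpy()], base[~non_ref.to_numpy()],
            rtol=1e-12,
        )

    def test_mean_fold_change_unbiased_under_shrinking_noise(self):
        """Per-condition mean fold change converges to the true effect as
        the noise scale shrinks."""
        errs = []
        for sigma in (0.2, 0.05, 0.0125):
            est = []
            for seed in range(40):
                spec = SimulationSpec(
                    factors={"condition": ["ref", "x"]},
                    true_fold_change={"x": 2.0},
                    replicates=3,
                    transfection_sigma=0.1,
                    measurement_sigma=sigma,
                    seed=seed,
                )
                exp, _ = generate_experiment(spec)
                out = fold_change(
                    compute_ratios(exp), NormalizationConfig("condition=ref")
                )
                est.append(
                    out.data.loc[out.data["condition"] == "x",
                                 "fold_change"].mean()
                )
            errs.append(abs(np.mean(est) - 2.0))
        assert errs[2] < errs[0]
        assert errs[2] < 0.02


class TestSummarize:
    def test_textbook_values(self):
        rows = [
            {"well": f"A0{i}", "condition": "c", "firefly": float(v),
             "renilla": 1.0}
            for i, v in enumerate([1, 2, 3], start=1)
        ]
        table = summarize(compute_ratios(_exp(rows)), value="ratio")
        r = table.data.iloc[0]
        assert r["n"] == 3
        assert r["mean"] == pytest.approx(2.0)
        assert r["median"] == pytest.approx(2.0)
        assert r["sd"] == pytest.approx(1.0)
        assert r["sem"] == pytest.approx(1 / np.sqrt(3))
        tcrit = stats.t.ppf(0.975, 2)
        assert r["ci95_low"] == pytest.approx(2 - tcrit / np.sqrt(3))
        assert r["ci95_high"] == pytest.approx(2 + tcrit / np.sqrt(3))

    def test_single_observation_leaves_dispersion_unset(self):
        rows = [{"well": "A01", "condition": "c", "firefly": 5.0,
                 "renilla": 1.0}]
        r = summarize(compute_ratios(_exp(rows)), value="ratio").data.iloc[0]
        assert r["n"] == 1 and r["mean"] == 5.0 and r["median"] == 5.0
        assert np.isnan(r["sd"]) and np.isnan(r["sem"])
        assert np.isnan(r["ci95_low"]) and np.isnan(r["ci95_high"])

    def test_every_group_matches_independent_recomputation(
        self, full_plate_experiment
    ):
        exp, _ = full_plate_experiment
        exp = fold_change(
            compute_ratios(exp), NormalizationConfig("condition=control")
        )
        table = summarize(exp).data.set_index("condition")
        assert len(table) == 24
        keys = exp.condition_keys()
        for key in table.index:  # group-by oracle, one group at a time
            vals = exp.data.loc[keys == key, "fold_change"].to_numpy()
            assert table.loc[key, "n"] == len(vals)
            assert table.loc[key, "mean"] == pytest.approx(vals.mean())
            assert table.loc[key, "median"] == pytest.approx(np.median(vals))
            assert table.loc[key, "sd"] == pytest.approx(vals.std(ddof=1))

    def test_auto_value_prefers_fold_change(self, manual_experiment):
        exp = compute_ratios(manual_experiment)
        assert summarize(exp).value == "ratio"
        exp = fold_change(exp, NormalizationConfig("condition=control"))
        assert summarize(exp).value == "fold_change"

    def test_grouping_by_factor_subset(self, full_plate_experiment):
        exp, _ = full_plate_experiment
        exp = compute_ratios(exp)
        table = summarize(exp, value="ratio", by=["condition"])
        assert len(table) == 3
        assert set(table.data["n"]) == {24}
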