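"""Correlation screening, stepwise regression, prediction and validation."""

import numpy as np
import pandas as pd
import pytest

from standcount import count_model as cm


class TestPreselect:
    def _matrix(self, names, r_y, r_pairs):
        m = pd.DataFrame(np.eye(len(names) + 1), index=["y"] + names,
                         columns=["y"] + names)
        for n, r in zip(names, r_y):
            m.loc["y", n] = m.loc[n, "y"] = r
        for (a, b), r in r_pairs.items():
            m.loc[a, b] = m.loc[b, a] = r
        return m

    def test_collinear_pair_keeps_higher_y_correlation(self):
        m = self._matrix(["Fa", "Fb"], [0.9, 0.7], {("Fa", "Fb"): 0.95})
        assert cm.preselect(m) == ["Fa"]

    def test_no_collinearity_keeps_all(self):
        m = self._matrix(["Fa", "Fb", "Fc"], [0.9, 0.7, 0.5],
                         {("Fa", "Fb"): 0.5, ("Fa", "Fc"): 0.3, ("Fb", "Fc"): 0.79})
        assert cm.preselect(m) == ["Fa", "Fb", "Fc"]

    def test_tie_keeps_lower_index(self):
        m = self._matrix(["Fa", "Fb"], [0.7, 0.7], {("Fa", "Fb"): 0.9})
        assert cm.preselect(m) == ["Fa"]

    def test_survivors_on_packaged_matrices(self):
        """Frozen rule output on the packaged field correlation structures.

        Hand application of the rule on the first matrix: the 0.99 pairs
        eliminate F3, F15, F6, F5 (each against a stronger y-correlate);
        F2 falls to F1, F13 to F7, F9 to F1, F10 to F4 (tie), F8 to F7
        (tie); the survivors are mutually below the 0.8 cutoff.
        """
        assert cm.preselect(cm.reference_correlation(1)) == \
            ["F1", "F4", "F7", "F11", "F12", "F14"]
        assert cm.preselect(cm.reference_correlation(2)) == \
            ["F1", "F4", "F8", "F12", "F14"]

    def test_nonfinite_matrix_rejected(self):
        m = self._matrix(["Fa", "Fb"], [0.9, np.nan], {})
        with pytest.raises(ValueError):
            cm.preselect(m)

    def test_screen_always_retains_the_uncorrelated_feature(self):
        """F12 (density) has no collinear partner in the reference
        structure, so the screen retains it on every simulated sample.
        Its collinear peers (e.g. F1/F15 at r = 0.99, F4/F10 at 0.89) are
        statistically interchangeable, so which of them survives varies
        with the sample."""
        for seed in range(5):
            tab = cm.simulate_feature_table(800, stage=1, rng=seed)
            surv = cm.preselect(cm.correlation_matrix(tab))
            assert "F12" in surv


class TestStepwise:
    def test_single_true_predictor_recovered(self, rng):
        df = pd.DataFrame({"F1": rng.normal(0, 1, 200), "F2": rng.normal(0, 1, 200)})
        df["y"] = 3.0 * df["F1"] + rng.normal(0, 0.1, 200)
        model = cm.stepwise_fit(df)
        assert model.features == ["F1"]
        assert 2.9 <= model.coefficients[0] <= 3.1

    def test_constant_response_gives_empty_model(self, rng):
        df = pd.DataFrame({"F1": rng.normal(0, 1, 50)})
        df["y"] = 2.0
        model = cm.stepwise_fit(df)
        assert model.features == []
        assert model.intercept == pytest.approx(2.0)

    def test_irrelevant_noise_gives_empty_model_with_warning(self, rng):
        df = pd.DataFrame({"F1": rng.normal(0, 1, 100)})
        df["y"] = rng.normal(0, 1, 100)
        with pytest.warns(UserWarning, match="no variables"):
            model = cm.stepwise_fit(df)
        assert model.features == []

    def test_equal_entry_removal_levels_rejected(self, rng):
        df = pd.DataFrame({"F1": rng.normal(0, 1, 30), "y": rng.normal(0, 1, 30)})
        with pytest.raises(ValueError, match="p_enter"):
            cm.stepwise_fit(df, p_enter=0.05, p_remove=0.05)

    def test_constant_column_rejected(self, rng):
        df = pd.DataFrame({"F1": np.ones(30), "y": rng.normal(0, 1, 30)})
        with pytest.raises(ValueError, match="constant"):
            cm.stepwise_fit(df)

    def test_too_few_rows_rejected(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (4, 3)), columns=["F1", "F2", "y"])
        with pytest.raises(ValueError, match="need n"):
            cm.stepwise_fit(df)

    def test_recovers_packaged_model_coefficients(self):
        """Stepwise refit on data simulated from the stage-1 model, with
        its own features as candidates, recovers every coefficient within
        3 standard errors (n = 2000)."""
        tab = cm.simulate_feature_table(2000, stage=1, rng=11)
        truth = cm.builtin_model("A")
        model = cm.stepwise_fit(tab, candidates=list(truth.features))
        assert model.features == list(truth.features)
        se = model.stats["stderr"]
        for f, true_c in zip(truth.features, truth.coefficients):
            est = model.coefficients[model.features.index(f)]
            assert abs(est - true_c) <= 3 * se[f]
        assert abs(model.intercept - truth.intercept) <= 3 * se["const"]

    def test_bias_shrinks_with_sample_size(self):
        errs = {}
        for n in (200, 2000):
            tab = cm.simulate_feature_table(n, stage=2, rng=5)
            model = cm.stepwise_fit(tab, candidates=["F4", "F12", "F15"])
            truth = cm.builtin_model("B")
            errs[n] = sum(
                abs(model.coefficients[model.features.index(f)] - c)
                for f, c in zip(truth.features, truth.coefficients)
                if f in model.features)
        assert errs[2000] <= errs[200] + 0.05

    def test_r2_equals_independent_sse_sst(self, rng):
        df = pd.DataFrame({"F1": rng.normal(0, 1, 150), "F2": rng.normal(0, 1, 150)})
        df["y"] = 1.5 * df["F1"] - 0.5 * df["F2"] + rng.normal(0, 0.3, 150)
        model = cm.stepwise_fit(df)
        yhat = model.predict(df)
        sse = float(np.sum((df["y"] - yhat) ** 2))
        sst = float(np.sum((df["y"] - df["y"].mean()) ** 2))
        assert model.stats["r2"] == pytest.approx(1 - sse / sst, abs=1e-9)


class TestPrediction:
    def test_packaged_model_hand_values(self):
        A = cm.builtin_model("A")
        df = pd.DataFrame({"F4": [2.0], "F12": [1.0], "F15": [100.0]})
        assert cm.predict_counts(A, df)[0] == pytest.approx(3.040, abs=1e-9)

        B = cm.builtin_model("B")
        zero = pd.DataFrame({"F4": [0.0], "F12": [0.0], "F15": [0.0]})
        assert cm.predict_counts(B, zero)[0] == pytest.approx(1.498)

    def test_plot_sum_rounding(self):
        model = cm.CountModel(["F4"], [1.0], 0.0)
        df = pd.DataFrame({"F4": [720.6]})
        assert cm.predict_plot_sum(model, df) == 721

    def test_round_half_away_from_zero(self):
        assert cm.round_half_away(5.5) == 6
        assert cm.round_half_away(-5.5) == -6
        assert cm.round_half_away(2.4) == 2

    def test_missing_feature_column(self):
        A = cm.builtin_model("A")
        with pytest.raises(KeyError, match="F15"):
            A.predict(pd.DataFrame({"F4": [1.0], "F12": [1.0]}))

    def test_negative_flooring_only_when_requested(self):
        model = cm.CountModel(["F4"], [1.0], 0.0)
        df = pd.DataFrame({"F4": [-2.0, 3.0]})
        assert cm.predict_plot_sum(model, df) == 1
        assert cm.predict_plot_sum(model, df, floor_negative=True) == 3

    def test_model_json_round_trip(self, tmp_path):
        A = cm.builtin_model("A")
        A.to_json(tmp_path / "a.json")
        back = cm.CountModel.from_json(tmp_path / "a.json")
        assert back.features == A.features
        assert back.coefficients == pytest.approx(A.coefficients)
        assert back.intercept == pytest.approx(A.intercept)

    def test_unknown_builtin(self):
        with pytest.raises(KeyError):
            cm.builtin_model("builtin:C")


class TestValidation:
    def test_reported_plot_errors(self):
        """Relative plot errors reproduce the published validation table."""
        v = cm.validation_metrics([147], [177])
        assert round(v.es_percent[0], 2) == 20.41
        v = cm.validation_metrics([431], [425])
        assert round(v.es_percent[0], 2) == -1.39

    def test_reported_mae_for_both_models(self):
        a = cm.validation_metrics([694, 147, 319, 431], [721, 177, 362, 425])
        assert round(a.mae_percent, 2) == 9.79
        b = cm.validation_metrics([846, 255, 459, 440], [859, 281, 442, 418])
        assert round(b.mae_percent, 2) == 5.11

    def test_exact_match_is_zero_error(self):
        v = cm.validation_metrics([100, 250], [100, 250])
        assert v.es_percent == [0.0, 0.0]
        assert v.mae_percent == 0.0

    def test_zero_measured_rejected(self):
        with pytest.raises(ValueError):
            cm.validation_metrics([0], [5])


def test_split_train_validation(rng):
    table = pd.DataFrame({
        "plot": np.repeat(np.arange(1, 10), 40),
        "device": np.repeat(["a", "b", "c"], 120),
        "F4": rng.normal(size=360),
    })
    train, subsets = cm.split_train_validation(table, seed=4)
    assert set(subsets) == {"device:a", "device:b", "device:c", "random"}
    held = {s["plot"].iloc[0] for k, s in subsets.items() if k != "random"}
    assert len(held) == 3
    assert not held & set(train["plot"].unique())
    n_rest = 360 - 3 * 40
    assert len(subsets["random"]) == round(0.15 * n_rest)
    assert len(train) + len(subsets["random"]) == n_rest
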