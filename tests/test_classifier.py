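import numpy as np
import pandas as pd
import pytest

from drivercall import (
    FeatureTable,
    FixtureSpec,
    ModelSpec,
    TrainedModel,
    categorize,
    confidence,
    inverse_frequency_weights,
    load_model,
    make_feature_table,
    predict,
    save_model,
    score,
    train,
)
from drivercall.selection import feature_auc


def fitted_model(seed=0, n_drivers=40, n_passengers=160, effect_size=2.5, **kw):
    table, labels = make_feature_table(
        FixtureSpec(
            n_drivers=n_drivers,
            n_passengers=n_passengers,
            n_features=3,
            n_informative=2,
            effect_size=effect_size,
            seed=seed,
            **kw,
        )
    )
    model = train(table, labels, table.feature_names, ModelSpec(seed=seed))
    return model, table, labels


def threshold_model(driver_scores, passenger_scores):
    """A TrainedModel shell around explicit training-score lists."""
    d = np.sort(np.asarray(driver_scores, dtype=float))
    p = np.sort(np.asarray(passenger_scores, dtype=float))
    return TrainedModel(
        spec=ModelSpec(),
        selected_features=("f",),
        pipeline=None,
        q90_passenger=float(np.percentile(p, 90)),
        q10_driver=float(np.percentile(d, 10)),
        driver_scores=d,
        passenger_scores=p,
    )


class TestWeights:
    def test_balanced_classes_equal_weights(self):
        w = inverse_frequency_weights([0] * 10 + [1] * 10)
        assert w[0] == w[1] == 1.0

    def test_imbalanced_ratio_matches_formula(self):
        # inverse-frequency: ratio of weights equals inverse ratio of counts
        w = inverse_frequency_weights([1] * 1768 + [0] * 8075)
        assert w[1] / w[0] == pytest.approx(8075 / 1768)
        assert w[1] / w[0] == pytest.approx(4.567, abs=5e-4)

    def test_mean_weight_over_samples_is_one(self):
        y = [1] * 30 + [0] * 70
        w = inverse_frequency_weights(y)
        assert np.mean([w[c] for c in y]) == pytest.approx(1.0)


class TestTrain:
    def test_separable_data_training_auc_one(self):
        model, table, labels = fitted_model(effect_size=6.0)
        s = score(model, table)
        assert feature_auc(s[labels == 1], s[labels == 0]) == 1.0

    def test_single_class_rejected(self):
        table, labels = make_feature_table(
            FixtureSpec(
                n_drivers=10, n_passengers=10, n_features=2, n_informative=1, seed=1
            )
        )
        with pytest.raises(ValueError):
            train(table, pd.Series(1, index=labels.index), table.feature_names)

    def test_percentiles_computed_from_training_scores(self):
        model, table, labels = fitted_model()
        s = score(model, table)
        assert model.q90_passenger == pytest.approx(
            np.percentile(s[labels == 0], 90)
        )
        assert model.q10_driver == pytest.approx(np.percentile(s[labels == 1], 10))


class TestScore:
    def test_rescoring_training_set_reproduces_scores(self):
        model, table, labels = fitted_model()
        s1 = score(model, table)
        s2 = score(model, table)
        pd.testing.assert_series_equal(s1, s2)

    def test_invariant_to_extra_columns(self):
        model, table, _ = fitted_model()
        augmented = FeatureTable(
            table.values.assign(extra=np.arange(len(table.values), dtype=float))
        )
        pd.testing.assert_series_equal(score(model, table), score(model, augmented))

    def test_missing_selected_feature_named(self):
        model, table, _ = fitted_model()
        shrunk = FeatureTable(table.values[["F001"]])
        with pytest.raises(KeyError, match="F002"):
            score(model, shrunk)

    def test_duplicate_rows_identical_scores(self):
        model, table, _ = fitted_model()
        dup = FeatureTable(
            pd.concat([table.values.iloc[[0]], table.values.iloc[[0]]]).set_axis(
                ["a", "b"]
            )
        )
        s = score(model, dup)
        assert s["a"] == s["b"]


class TestCategorize:
    def test_above_passenger_q90_is_driver(self):
        m = threshold_model(range(100, 200), range(100))
        assert categorize(m, m.q90_passenger + 1e-9) == "driver"

    def test_exactly_at_q90_falls_through(self):
        m = threshold_model(range(100, 200), range(100))
        # not a driver at equality; also >= q10_driver so it is a no-call
        assert categorize(m, m.q90_passenger) != "driver"

    def test_gap_between_classes_driver_precedence(self):
        m = threshold_model(range(200, 300), range(100))
        mid = (m.q90_passenger + m.q10_driver) / 2
        assert m.q90_passenger < mid < m.q10_driver
        assert categorize(m, mid) == "driver"  # both rules fire; driver precedence

    def test_below_both_thresholds_is_passenger(self):
        m = threshold_model(range(100, 200), range(100))
        low = min(m.q10_driver, m.q90_passenger) - 1.0
        assert categorize(m, low) == "passenger"

    def test_no_call_band(self):
        # overlapping classes: q10_driver < q90_passenger leaves a no-call band
        m = threshold_model(range(50, 150), range(100))
        assert m.q10_driver < m.q90_passenger
        mid = (m.q10_driver + m.q90_passenger) / 2
        assert categorize(m, mid) == "no-call"


class TestConfidence:
    def test_worked_example_0_05(self):
        m = threshold_model(np.arange(1, 101), np.arange(-100, 0))
        q = 95.5  # exceeds 95 of the 100 training drivers
        assert categorize(m, q) == "driver"
        assert confidence(m, q, "driver") == 0.05

    def test_above_all_training_drivers_is_zero(self):
        m = threshold_model(np.arange(1, 101), np.arange(-100, 0))
        assert confidence(m, 1000.0, "driver") == 0.0

    def test_passenger_median_odd_n(self):
        n = 101
        m = threshold_model(np.arange(1000, 1100), np.arange(n, dtype=float))
        med = float(np.median(np.arange(n)))
        assert confidence(m, med, "passenger") == pytest.approx((n - 1) / (2 * n))

    def test_ties_not_more_extreme(self):
        m = threshold_model([1.0, 2.0, 2.0, 3.0], [0.0])
        assert confidence(m, 2.0, "driver") == pytest.approx(1 / 4)

    def test_no_call_is_null(self):
        m = threshold_model(range(100, 200), range(100))
        assert confidence(m, 50.0, "no-call") is None

    def test_training_driver_confidences_near_uniform(self):
        model, table, labels = fitted_model()
        s = score(model, table)
        confs = np.sort(
            [confidence(model, float(v), "driver") for v in s[labels == 1]]
        )
        n = len(confs)
        # ranks of distinct scores give confidences {0, 1/n, ..., (n-1)/n}
        expected = np.arange(n) / n
        assert np.max(np.abs(confs - expected)) < 2 / n


class TestPredictAndSerialization:
    def test_predict_calls_consistent(self):
        model, table, labels = fitted_model()
        calls = predict(model, table)
        s = score(model, table)
        for c in calls:
            assert c.category == categorize(model, c.score)
            assert c.score == pytest.approx(float(s[c.mutation_id]))

    def test_save_load_round_trip(self, tmp_path):
        model, table, _ = fitted_model()
        p = tmp_path / "model.joblib"
        save_model(model, p)
        back = load_model(p)
        assert back.selected_features == model.selected_features
        assert back.q90_passenger == model.q90_passenger
        np.testing.assert_array_equal(back.driver_scores, model.driver_scores)
        pd.testing.assert_series_equal(score(back, table), score(model, table))

    def test_confidence_reproducible_without_retraining(self, tmp_path):
        model, table, labels = fitted_model()
        p = tmp_path / "model.joblib"
        save_model(model, p)
        back = load_model(p)
        s = score(model, table)
        for v in s.iloc[:10]:
            cat = categorize(model, float(v))
            assert confidence(back, float(v), cat) == confidence(model, float(v), cat)
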