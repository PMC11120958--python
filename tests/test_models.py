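import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfsynergy.expression import make_lagged_dataset
from tfsynergy.models import (FittedModel, ModelConfig, derive_seed,
                              ensemble_predict, feature_importance_ranking,
                              fit_regressor, rmse)
from tfsynergy.synthetic import generate_timeseries

from conftest import planted_pair_config


class TestRmse:
    def test_identity_is_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed(self):
        # sqrt((9 + 16) / 2)
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(3.5355, abs=1e-4)

    def test_single_pair_reduces_to_absolute_error(self):
        assert rmse([1.0], [-1.5]) == pytest.approx(2.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0, 2.0], [1.0])


class TestFitRegressor:
    def test_ridge_near_closed_form_on_noise_free_target(self, quick_model):
        series, _ = generate_timeseries(planted_pair_config(2, noise_sd=0.0))
        data = make_lagged_dataset(series)
        cfg = ModelConfig(ridge_alpha=1e-8, seed=0)
        model = fit_regressor(data, ["TF001", "TF002"], "G001", kind="ridge",
                              config=cfg)
        assert model.test_rmse(data) <= 1e-3

    def test_forest_on_pure_noise_matches_intercept_baseline(self):
        """Uninformative drivers: forest should do no better (and not much
        worse) than predicting the training mean."""
        ratios = []
        for seed in range(10):
            series, _ = generate_timeseries(planted_pair_config(
                seed, n_tfs=6, noise_sd=1.0, coefficients=(0.0, 0.0)))
            data = make_lagged_dataset(series)
            model = fit_regressor(data, data.tf_ids, "G001",
                                  config=ModelConfig(n_trees=60, seed=seed))
            test_y = data.Y.loc[data.test_index, "G001"].to_numpy()
            mean = data.Y.loc[data.train_index, "G001"].mean()
            baseline = rmse(np.full_like(test_y, mean), test_y)
            ratios.append(model.test_rmse(data) / baseline)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)

    def test_deterministic_given_seed(self, planted_dataset, quick_model):
        data, _ = planted_dataset
        m1 = fit_regressor(data, data.tf_ids, "G001", config=quick_model)
        m2 = fit_regressor(data, data.tf_ids, "G001", config=quick_model)
        pd.testing.assert_series_equal(m1.predict(data.X.loc[data.test_index]),
                                       m2.predict(data.X.loc[data.test_index]))
        pd.testing.assert_series_equal(m1.train_error_vector, m2.train_error_vector)

    def test_forest_importances_sum_to_one(self, planted_dataset, quick_model):
        data, _ = planted_dataset
        model = fit_regressor(data, data.tf_ids, "G001", config=quick_model)
        assert model.importance.sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_features_rejected(self, planted_dataset):
        data, _ = planted_dataset
        with pytest.raises(ValueError, match="empty"):
            fit_regressor(data, [], "G001")

    def test_sole_self_feature_rejected(self, planted_dataset):
        data, _ = planted_dataset
        with pytest.raises(ValueError, match="own sole predictor"):
            fit_regressor(data, ["TF001"], "TF001")

    def test_target_dropped_from_its_own_features(self, planted_dataset, quick_model):
        data, _ = planted_dataset
        model = fit_regressor(data, ["TF001", "TF002"], "TF001",
                              config=quick_model)
        assert model.feature_ids == ["TF002"]

    def test_train_errors_are_out_of_bag_by_default(self, planted_dataset):
        """OOB errors must exceed in-sample errors on average for a forest."""
        data, _ = planted_dataset
        oob = fit_regressor(data, data.tf_ids, "G001",
                            config=ModelConfig(n_trees=60, seed=1))
        ins = fit_regressor(data, data.tf_ids, "G001",
                            config=ModelConfig(n_trees=60, seed=1,
                                               error_mode="insample"))
        assert oob.train_error_vector.mean() > ins.train_error_vector.mean()

    def test_descriptor_roundtrip(self, planted_dataset, quick_model, tmp_path):
        data, _ = planted_dataset
        model = fit_regressor(data, data.tf_ids, "G001", config=quick_model)
        model.save(tmp_path / "m.json")
        desc = json.loads((tmp_path / "m.json").read_text())
        refit = fit_regressor(data, desc["feature_ids"], desc["target_id"],
                              kind=desc["model_kind"],
                              config=ModelConfig(**desc["config"]))
        pd.testing.assert_series_equal(model.train_error_vector,
                                       refit.train_error_vector)


class TestImportanceRanking:
    def _model(self, importances):
        return FittedModel(model_kind="forest", feature_ids=list(importances),
                           target_id="G", importance=pd.Series(importances),
                           train_error_vector=pd.Series(dtype=float), seed=0,
                           config=ModelConfig())

    def test_descending_order(self):
        assert feature_importance_ranking(
            self._model({"A": 0.5, "B": 0.3, "C": 0.2})) == ["A", "B", "C"]

    def test_tie_breaks_by_id(self):
        assert feature_importance_ranking(
            self._model({"B": 0.5, "A": 0.5})) == ["A", "B"]

    def test_ranking_is_permutation_of_features(self, planted_dataset, quick_model):
        data, _ = planted_dataset
        model = fit_regressor(data, data.tf_ids, "G001", config=quick_model)
        assert sorted(feature_importance_ranking(model)) == sorted(model.feature_ids)

    def test_ridge_ranking_matches_hand_coefficients(self):
        series, _ = generate_timeseries(planted_pair_config(
            4, noise_sd=0.0, coefficients=(0.4, -1.1)))
        data = make_lagged_dataset(series)
        model = fit_regressor(data, ["TF001", "TF002"], "G001", kind="ridge",
                              config=ModelConfig(ridge_alpha=1e-8, seed=0))
        assert feature_importance_ranking(model) == ["TF002", "TF001"]


class TestEnsemble:
    def _const_model(self, value, index):
        class _Const:
            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(len(X), self.v)

        return FittedModel(model_kind="forest", feature_ids=["TF001"],
                           target_id="G", importance=pd.Series({"TF001": 1.0}),
                           train_error_vector=pd.Series(dtype=float), seed=0,
                           config=ModelConfig(), estimator=_Const(value))

    def test_mean_of_members(self):
        X = pd.DataFrame({"TF001": [0.0, 1.0]}, index=["p0", "p1"])
        out = ensemble_predict([self._const_model(1.0, X.index),
                                self._const_model(3.0, X.index)], X)
        np.testing.assert_allclose(out, [2.0, 2.0])

    def test_single_member_identity(self):
        X = pd.DataFrame({"TF001": [0.5]}, index=["p0"])
        out = ensemble_predict([self._const_model(1.25, X.index)], X)
        np.testing.assert_allclose(out, [1.25])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ensemble_predict([], pd.DataFrame())

    def test_mixed_targets_rejected(self):
        a = self._const_model(1.0, None)
        b = self._const_model(1.0, None)
        b.target_id = "OTHER"
        X = pd.DataFrame({"TF001": [0.0]}, index=["p0"])
        with pytest.raises(ValueError, match="target"):
            ensemble_predict([a, b], X)

    @given(data=st.data())
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_ensemble_rmse_never_exceeds_max_member(self, data):
        """Averaging convexity: the ensemble error is bounded by the worst
        member and by the mean of member errors (triangle inequality)."""
        n = data.draw(st.integers(min_value=2, max_value=12))
        k = data.draw(st.integers(min_value=1, max_value=5))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        truth = rng.normal(size=n)
        preds = rng.normal(size=(k, n))
        ens = preds.mean(axis=0)
        member = [rmse(p, truth) for p in preds]
        assert rmse(ens, truth) <= max(member) + 1e-12
        assert rmse(ens, truth) <= np.mean(member) + 1e-12


def test_derive_seed_is_stable_and_in_range():
    a = derive_seed(42, "G001", "rf_all")
    assert a == derive_seed(42, "G001", "rf_all")
    assert a != derive_seed(42, "G001", "rf_gs")
    assert 0 <= a < 2**31
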