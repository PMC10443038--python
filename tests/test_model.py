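"""Gradient-boosted titer model: recovery, determinism, attribution, selection."""

import numpy as np
import pandas as pd
import pytest

import sigpepkit as sk
from sigpepkit.model import cross_validate

from conftest import MODEL_SEED, NOISE_SD


def single_feature_dataset(n=200, noise=0.0, seed=5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "signal": rng.uniform(0, 1, n),
        "distractor": rng.uniform(0, 1, n),
    })
    y = X["signal"].to_numpy() + rng.normal(0, noise, n)
    return X, y


class TestFit:
    def test_constant_targets_predicted_exactly(self):
        X, _ = single_feature_dataset(50)
        est = sk.TiterRegressor(random_state=0).fit(X, np.full(50, 0.42))
        assert np.allclose(est.predict(X), 0.42, atol=1e-6)

    def test_noiseless_single_feature_recovered(self):
        X, y = single_feature_dataset(200)
        est = sk.TiterRegressor(random_state=0).fit(X, y)
        assert est.test_r2_ >= 0.95

    def test_same_seed_identical_predictions(self):
        X, y = single_feature_dataset(200, noise=0.02)
        a = sk.TiterRegressor(random_state=1).fit(X, y).predict(X)
        b = sk.TiterRegressor(random_state=1).fit(X, y).predict(X)
        assert np.array_equal(a, b)

    def test_length_mismatch_rejected(self):
        X, y = single_feature_dataset(50)
        with pytest.raises(ValueError, match="length mismatch"):
            sk.TiterRegressor().fit(X, y[:-1])

    def test_split_memberships_recorded(self):
        X, y = single_feature_dataset(100)
        est = sk.TiterRegressor(random_state=0).fit(X, y)
        assert len(est.train_index_) == 90 and len(est.test_index_) == 10
        assert set(est.train_index_).isdisjoint(est.test_index_)


class TestCrossValidate:
    def test_noiseless_single_feature_low_mae(self):
        X, y = single_feature_dataset(200)
        mae_mean, _ = cross_validate(X, y, sk.TiterRegressor(random_state=0))
        assert mae_mean <= 0.05

    def test_permuted_targets_no_better_than_mean_predictor(self):
        X, y = single_feature_dataset(200, noise=0.0)
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        mae_mean, _ = cross_validate(X, y_perm, sk.TiterRegressor(random_state=0))
        baseline = np.mean(np.abs(y_perm - y_perm.mean()))
        assert mae_mean >= 0.8 * baseline

    def test_reproducible(self):
        X, y = single_feature_dataset(100, noise=0.05)
        est = sk.TiterRegressor(random_state=2)
        assert cross_validate(X, y, est) == cross_validate(X, y, est)

    def test_too_few_rows_rejected(self):
        X, y = single_feature_dataset(4)
        with pytest.raises(ValueError, match="too few rows"):
            cross_validate(X, y, cv_splits=5)


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self, trained_model, scaled_recovery):
        X, _, _ = scaled_recovery
        preds = trained_model.predict(X)
        again = trained_model.predict(X)
        assert np.array_equal(preds, again)

    def test_single_row(self, trained_model, scaled_recovery):
        X, _, _ = scaled_recovery
        assert trained_model.predict(X.iloc[[0]]).shape == (1,)

    def test_row_order_invariance(self, trained_model, scaled_recovery):
        X, _, _ = scaled_recovery
        perm = np.random.default_rng(0).permutation(len(X))
        assert np.array_equal(trained_model.predict(X.iloc[perm]), trained_model.predict(X)[perm])

    def test_missing_column_rejected(self, trained_model, scaled_recovery):
        X, _, _ = scaled_recovery
        with pytest.raises(ValueError, match="schema mismatch"):
            trained_model.predict(X.drop(columns=["pi"]))


class TestAttribution:
    def test_local_accuracy_on_every_row(self, trained_model, scaled_recovery):
        X, _, _ = scaled_recovery
        attr = trained_model.attribute(X.iloc[:50])
        reconstructed = attr.sum(axis=1).to_numpy()
        assert np.allclose(reconstructed, trained_model.predict(X.iloc[:50]), atol=1e-4)

    def test_unused_feature_gets_zero_attribution(self):
        X, y = single_feature_dataset(200)
        X["dead"] = 1.0  # constant: no tree can split on it
        est = sk.TiterRegressor(random_state=0).fit(X, y)
        attr = est.attribute(X)
        assert np.all(attr["dead"].to_numpy() == 0.0)

    def test_monotone_single_feature_sign_tracks_deviation(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"x": rng.uniform(0, 1, 300)})
        est = sk.TiterRegressor(random_state=0).fit(X, X["x"].to_numpy())
        attr = est.attribute(X)
        low, high = X["x"] < 0.2, X["x"] > 0.8
        assert (attr.loc[low.to_numpy(), "x"] < 0).all()
        assert (attr.loc[high.to_numpy(), "x"] > 0).all()


class TestSerialization:
    def test_round_trip_bit_identical(self, trained_model, scaled_recovery, tmp_path):
        X, _, _ = scaled_recovery
        before = trained_model.predict(X)
        trained_model.save(tmp_path / "bundle")
        loaded = sk.TiterRegressor.load(tmp_path / "bundle")
        assert np.array_equal(loaded.predict(X), before)
        assert loaded.feature_names_ == trained_model.feature_names_
        assert loaded.test_r2_ == trained_model.test_r2_


class TestRecovery:
    def test_parameter_recovery_under_study_conditions(self, scaled_recovery):
        """Known linear feature signal at sigma=0.05, n=200: CV MAE and held-out R^2."""
        X, y, _ = scaled_recovery
        est = sk.TiterRegressor(random_state=MODEL_SEED).fit(X, y)
        assert est.test_r2_ >= 0.8
        mae_mean, mae_sd = cross_validate(X, y, sk.TiterRegressor(random_state=MODEL_SEED))
        assert 0.7 * NOISE_SD * np.sqrt(2 / np.pi) <= mae_mean <= 2 * NOISE_SD
        assert mae_sd > 0


class TestSelectCandidates:
    def test_top_three_of_hundred(self):
        preds = {f"a{i}": float(i) for i in range(1, 101)}
        panel = sk.select_candidates(preds, percentile=95, k=3)
        assert panel.ids == ("a100", "a99", "a98")
        assert not panel.short_pool

    def test_all_equal_takes_lexicographic_first(self):
        preds = {pid: 1.0 for pid in ["d", "b", "c", "a"]}
        panel = sk.select_candidates(preds, percentile=50, k=2)
        assert panel.ids == ("a", "b")

    def test_short_pool_flagged(self):
        preds = {f"x{i}": float(i) for i in range(10)}
        panel = sk.select_candidates(preds, percentile=95, k=3)
        assert panel.short_pool and len(panel.ids) < 3

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sk.select_candidates({"a": 1.0}, percentile=100, k=3)
        with pytest.raises(ValueError):
            sk.select_candidates({"a": 1.0}, percentile=95, k=0)
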