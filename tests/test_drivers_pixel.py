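import numpy as np
import pandas as pd
import pytest

from urbanveg.drivers_pixel import (
    build_groups,
    contribution_significance,
    contribution_table,
    contributions,
    fit_rf,
    partial_dependence,
    predict_target,
    saabas_decomposition,
)


class TestBuildGroups:
    def make_table(self, rows):
        cols = ["Crop", "Deciduous Forest", "Evergreen Forest", "Grass",
                "Mixed Forest", "Shrub", "Wetland"]
        df = pd.DataFrame(rows)
        for c in cols:
            df[c] = df.get(c, 0.0)
        return df

    def test_dominant_assignment(self):
        tab = self.make_table([{"city": "a", "Shrub": 0.6, "Grass": 0.2}])
        assert build_groups(tab) == {"Shrub": ["a"]}

    def test_crop_dominant_excluded(self):
        tab = self.make_table([{"city": "a", "Crop": 0.55, "Grass": 0.3}])
        assert build_groups(tab) == {}

    def test_tie_breaks_canonical_order(self):
        tab = self.make_table([{"city": "a", "Grass": 0.4, "Shrub": 0.4}])
        assert build_groups(tab) == {"Grass": ["a"]}  # Grass precedes Shrub


def make_signal_data(rng, n=400, p=5):
    X = rng.uniform(0, 1, (n, p))
    return X


class TestFitRf:
    def test_threshold_signal_classified(self, rng):
        X = make_signal_data(rng)
        y = (X[:, 2] > 0.5).astype(int)
        forest, oob = fit_rf(X, y, "sign", seed=0, n_estimators=100)
        assert oob > 0.95

    def test_noise_regression_oob_near_zero(self, rng):
        X = make_signal_data(rng)
        y = rng.normal(0, 1, len(X))
        forest, oob = fit_rf(X, y, "magnitude", seed=0, n_estimators=100)
        assert oob <= 0.1

    def test_deterministic_given_seed(self, rng):
        X = make_signal_data(rng)
        y = X[:, 0] + rng.normal(0, 0.1, len(X))
        f1, _ = fit_rf(X, y, "magnitude", seed=3, n_estimators=50)
        f2, _ = fit_rf(X, y, "magnitude", seed=3, n_estimators=50)
        assert np.array_equal(f1.predict(X), f2.predict(X))

    def test_single_class_rejected(self, rng):
        X = make_signal_data(rng)
        with pytest.raises(ValueError, match="both classes"):
            fit_rf(X, np.ones(len(X), dtype=int), "sign")

    def test_too_few_rows_rejected(self, rng):
        X = make_signal_data(rng, n=50)
        with pytest.raises(ValueError, match="rows"):
            fit_rf(X, np.zeros(50), "magnitude")


class TestContributions:
    def test_additivity_exact(self, rng):
        X = make_signal_data(rng, n=250)
        y = X[:, 0] + 0.5 * X[:, 1] ** 2 + rng.normal(0, 0.05, 250)
        forest, _ = fit_rf(X, y, "magnitude", seed=1, n_estimators=60)
        bias, contrib = saabas_decomposition(forest, X[:40])
        pred = predict_target(forest, X[:40])
        assert np.allclose(bias + contrib.sum(axis=1), pred, atol=1e-9)

    def test_baseline_differencing_additivity(self, rng):
        X = make_signal_data(rng, n=250)
        y = X[:, 0] + rng.normal(0, 0.05, 250)
        forest, _ = fit_rf(X, y, "magnitude", seed=1, n_estimators=60)
        baseline = X.mean(axis=0)
        c = contributions(forest, X[:30], baseline)
        expected = predict_target(forest, X[:30]) - predict_target(forest, baseline[None, :])[0]
        assert np.allclose(c.sum(axis=1), expected, atol=1e-9)

    def test_single_feature_forest(self, rng):
        X = rng.uniform(0, 1, (250, 1))
        y = 2 * X[:, 0] + rng.normal(0, 0.02, 250)
        forest, _ = fit_rf(X, y, "magnitude", seed=0, n_estimators=60)
        baseline = np.array([0.5])
        c = contributions(forest, X[:20], baseline)
        expected = predict_target(forest, X[:20]) - predict_target(forest, baseline[None, :])[0]
        assert np.allclose(c[:, 0], expected, atol=1e-9)

    def test_row_equal_to_baseline_zero(self, rng):
        X = make_signal_data(rng, n=250)
        y = X[:, 0] + rng.normal(0, 0.05, 250)
        forest, _ = fit_rf(X, y, "magnitude", seed=1, n_estimators=40)
        c = contributions(forest, X[[5]], X[5])
        assert np.allclose(c, 0.0, atol=1e-12)

    def test_known_driver_ranked_first(self, rng):
        X = make_signal_data(rng, n=400)
        y = 3 * X[:, 3] + rng.normal(0, 0.1, 400)
        forest, _ = fit_rf(X, y, "magnitude", seed=2, n_estimators=100)
        tab = contribution_table(forest, X, [f"f{j}" for j in range(5)], np.zeros(5))
        assert tab.iloc[0]["predictor"] == "f3"


class TestContributionSignificance:
    def test_monotone_contribution_significant(self, rng):
        x = rng.uniform(0, 1, 100)
        flag, p = contribution_significance(x, 0.5 * x + rng.normal(0, 0.01, 100))
        assert flag and p <= 0.05

    def test_shuffled_null_not_significant(self, rng):
        x = rng.uniform(0, 1, 1000)
        c = rng.permutation(0.5 * x)
        flag, p = contribution_significance(x, c)
        assert not flag

    def test_too_few_rows_missing(self):
        flag, p = contribution_significance(np.arange(5.0), np.arange(5.0))
        assert not flag and np.isnan(p)

    def test_constant_contribution(self, rng):
        flag, p = contribution_significance(rng.uniform(0, 1, 50), np.zeros(50))
        assert not flag and np.isnan(p)


class TestPartialDependence:
    def test_identity_signal(self, rng):
        X = rng.uniform(0, 1, (400, 1))
        y = X[:, 0]
        forest, _ = fit_rf(X, y, "magnitude", seed=0, n_estimators=80)
        curve = partial_dependence(forest, X, 0, grid=20)
        assert np.corrcoef(curve["value"], curve["prediction"])[0, 1] > 0.99
        # near-identity in the interior of the range
        inner = curve.iloc[3:-3]
        assert np.allclose(inner["prediction"], inner["value"], atol=0.1)

    def test_irrelevant_feature_flat(self, rng):
        X = rng.uniform(0, 1, (600, 5))
        y = 2 * X[:, 0] + rng.normal(0, 0.05, 600)
        forest, _ = fit_rf(X, y, "magnitude", seed=0, n_estimators=200)
        for j in (1, 2, 3, 4):
            curve = partial_dependence(forest, X, j, grid=20)
            rng_ = curve["prediction"].max() - curve["prediction"].min()
            assert rng_ < 0.1 * y.std()

    def test_single_point_grid(self, rng):
        X = rng.uniform(0, 1, (300, 2))
        y = X[:, 0]
        forest, _ = fit_rf(X, y, "magnitude", seed=0, n_estimators=40)
        curve = partial_dependence(forest, X, 0, grid=1)
        assert len(curve) == 1
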