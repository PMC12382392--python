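"""Train/test splitting, the five-metric suite, model fits, and SVR relevance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nitroscan import regression
from nitroscan.regression import (
    ModelConfig, compute_metrics, fit_predict, relevance, split_table,
)


def _table(n=84, n_features=5, seed=0, target="DW"):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    df["plant_id"] = [f"P{i}" for i in range(n)]
    df["dose_ppm"] = np.repeat(np.arange(1, 8.0), int(np.ceil(n / 7)))[:n]
    df[target] = X[:, 0] + 0.1 * rng.normal(size=n)
    return df


class TestSplit:
    def test_84_rows_give_59_train_25_test(self):
        train, test = split_table(_table(84), fraction=0.7, seed=0)
        assert (len(train), len(test)) == (59, 25)
        assert set(train.index).isdisjoint(test.index)
        assert len(train) + len(test) == 84

    def test_same_seed_reproduces_partition(self):
        t = _table(50)
        a = split_table(t, 0.7, seed=3)
        b = split_table(t, 0.7, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_stratification_balances_dose_groups(self):
        t = _table(84)
        train, test = split_table(t, 0.7, seed=1, stratify_by="dose_ppm")
        # every dose group appears in both partitions
        assert set(train["dose_ppm"]) == set(t["dose_ppm"])
        assert set(test["dose_ppm"]) == set(t["dose_ppm"])

    def test_degenerate_fractions_rejected(self):
        t = _table(20)
        with pytest.raises(ValueError):
            split_table(t, 1.0)   # empty test partition
        with pytest.raises(ValueError):
            split_table(t, 0.0)   # empty train partition


class TestMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.me, m.mae, m.rmse, m.rrmse) == (0.0, 0.0, 0.0, 0.0)
        assert m.r2 == 1.0

    def test_hand_computed_case(self):
        # obs=[1,2,3], pred=[2,2,2]: errors (1,0,-1)
        m = compute_metrics([1, 2, 3], [2, 2, 2])
        assert m.me == pytest.approx(0.0)
        assert m.mae == pytest.approx(2 / 3)
        assert m.rmse == pytest.approx(np.sqrt(2 / 3))
        assert m.rrmse == pytest.approx(np.sqrt(2 / 3) / 2)
        assert m.r2 == pytest.approx(0.0)

    def test_zero_mean_observations_make_rrmse_missing(self):
        m = compute_metrics([-1.0, 1.0], [0.0, 0.0])
        assert np.isnan(m.rrmse)

    @given(
        arrays(float, 12, elements=st.floats(-50, 50)),
        arrays(float, 12, elements=st.floats(-50, 50)),
    )
    @settings(deadline=None, max_examples=100)
    def test_metric_identities(self, obs, pred):
        m = compute_metrics(obs, pred)
        err = pred - obs
        assert m.mae <= m.rmse + 1e-9
        assert abs(m.me) <= m.rmse + 1e-9
        assert m.rmse <= np.max(np.abs(err)) + 1e-9
        # population decomposition RMSE² = ME² + var(err)
        assert m.rmse**2 == pytest.approx(m.me**2 + np.var(err), abs=1e-6)


class TestFitPredict:
    @pytest.mark.parametrize("model", ["SVR", "RF", "Lasso"])
    def test_models_learn_a_linear_signal(self, model):
        t = _table(84, seed={"SVR": 1, "RF": 2, "Lasso": 3}[model])
        train, test = split_table(t, 0.7, seed=0)
        result = fit_predict(train, test, "DW", ModelConfig(model=model, seed=0),
                             features=("f0", "f1", "f2", "f3", "f4"))
        assert result.metrics.r2 > 0.5

    def test_noiseless_structural_biomass_closed_loop(self):
        # with geometry jitter off, canopy height/volume are noiseless
        # functions of DW, so structural models recover biomass near-exactly
        from nitroscan import pipeline
        from nitroscan.synthetic import ExperimentConfig, generate_experiment

        plants = generate_experiment(ExperimentConfig(seed=5, geometry_jitter=0.0))
        traits = pd.DataFrame(
            [{"plant_id": p.plant_id, "dose_ppm": p.dose_ppm, "DW": p.traits.DW}
             for p in plants])
        structural_df = pipeline.extract_structural_features(plants, seed=5)
        table = traits.merge(structural_df, on="plant_id")
        train, test = split_table(table, 0.7, seed=0)
        for model in ("RF", "SVR"):
            r = fit_predict(train, test, "DW", ModelConfig(model=model, seed=0),
                            features=regression.STRUCTURAL_FEATURES)
            assert r.metrics.r2 >= 0.95, model

    def test_standardization_uses_train_statistics_only(self):
        t = _table(60, seed=2)
        train, test = split_table(t, 0.7, seed=0)
        shifted = test.copy()
        shifted[["f0", "f1", "f2", "f3", "f4"]] += 100.0
        cfg = ModelConfig(model="SVR", seed=0)
        feats = ("f0", "f1", "f2", "f3", "f4")
        m1 = fit_predict(train, test, "DW", cfg, features=feats).model
        m2 = fit_predict(train, shifted, "DW", cfg, features=feats).model
        np.testing.assert_allclose(m1.coef_, m2.coef_)  # fit saw train only

    def test_zero_variance_target_rejected(self):
        t = _table(30)
        t["DW"] = 5.0
        train, test = split_table(t, 0.7, seed=0)
        with pytest.raises(ValueError, match="zero-variance"):
            fit_predict(train, test, "DW", ModelConfig(model="RF"))


class TestRelevance:
    def test_planted_feature_gets_top_weight(self):
        rng = np.random.default_rng(9)
        n = 84
        df = pd.DataFrame(rng.normal(size=(n, 8)), columns=[f"f{i}" for i in range(8)])
        df["DW"] = 3.0 * df["f2"] + 0.1 * rng.normal(size=n)
        w = relevance(df, "DW", ModelConfig(model="SVR", seed=0), iterations=10,
                      features=tuple(f"f{i}" for i in range(8)))
        assert w.idxmax() == "f2"
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_informative_column_shares_weight(self):
        rng = np.random.default_rng(4)
        n = 84
        df = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"f{i}" for i in range(5)])
        df["DW"] = 2.0 * df["f0"] + 0.05 * rng.normal(size=n)
        single = relevance(df, "DW", ModelConfig(model="SVR", seed=0), iterations=5,
                           features=("f0", "f1", "f2", "f3", "f4"))
        dup = df.copy()
        dup["f0_copy"] = dup["f0"]
        shared = relevance(dup, "DW", ModelConfig(model="SVR", seed=0), iterations=5,
                           features=("f0", "f0_copy", "f1", "f2", "f3", "f4"))
        combined = shared["f0"] + shared["f0_copy"]
        assert combined == pytest.approx(single["f0"], abs=0.1)
        assert shared.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_iteration_equals_one_fit(self):
        df = _table(40, seed=6)
        feats = ("f0", "f1", "f2", "f3", "f4")
        cfg = ModelConfig(model="SVR", seed=13)
        w1 = relevance(df, "DW", cfg, iterations=1, features=feats)
        # reproduce the single internal fit independently
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVR
        seed = int(np.random.SeedSequence(13).generate_state(1)[0] % (2**31))
        train, _ = split_table(df, 0.7, seed=seed)
        X = StandardScaler().fit_transform(train[list(feats)])
        svr = SVR(kernel="linear", C=10.0, epsilon=0.1).fit(X, train["DW"])
        w_manual = np.abs(np.ravel(svr.coef_))
        w_manual /= w_manual.sum()
        np.testing.assert_allclose(w1.to_numpy(), w_manual, atol=1e-12)

    def test_nonlinear_kernel_unsupported(self):
        df = _table(30)
        with pytest.raises(ValueError, match="linear"):
            relevance(df, "DW", ModelConfig(model="SVR", svr_kernel="rbf"))
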