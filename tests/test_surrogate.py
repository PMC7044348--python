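"""Surrogate regressors: the numpy NN, sklearn backends, tuning, persistence."""

import numpy as np
import pandas as pd
import pytest

from gradvolt.dataset import FEATURE_COLUMNS
from gradvolt.surrogate import (ALGORITHMS, RegressorSpec, SurrogateError,
                                VoltageSurrogate, VoltageSurrogateResults,
                                default_nn_spec, train_regressor,
                                tune_hyperparameters)


def make_table(n=200, seed=0, target=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 10))
    if target is None:
        target = 0.5 + 0.3 * X[:, 0] + 0.2 * np.abs(X[:, 1])
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df["v_total_V"] = target
    return df


@pytest.fixture(scope="module")
def quick_spec():
    # few epochs keep the unit tests fast; the architecture is the default
    return default_nn_spec(seed=3, epochs=30)


class TestNeuralNetwork:
    def test_parameter_count_of_default_architecture(self, quick_spec):
        res, _ = train_regressor(quick_spec, make_table())
        # 10·25+25 + 25·120+120 + 120·1+1
        assert res.n_parameters == 3516

    def test_training_reduces_loss(self, quick_spec):
        _, hist = train_regressor(quick_spec, make_table())
        assert len(hist) == 30
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert np.isfinite(hist.train_loss).all()

    def test_bitwise_reproducible(self, quick_spec):
        df = make_table()
        probe = make_table(50, seed=9)
        r1, _ = train_regressor(quick_spec, df)
        r2, _ = train_regressor(quick_spec, df)
        np.testing.assert_array_equal(r1.predict(probe), r2.predict(probe))

    def test_constant_target_is_fit(self):
        c = 0.7
        df = make_table(120, target=np.full(120, c))
        res, _ = train_regressor(default_nn_spec(seed=0), df)  # full 300 epochs
        assert np.abs(res.predict(df) - c).max() < abs(c) * 1e-2 + 1e-3

    def test_validation_history_recorded(self, quick_spec):
        df, val = make_table(150), make_table(40, seed=5)
        _, hist = train_regressor(quick_spec, df, validation_rows=val)
        assert len(hist.val_loss) == len(hist.train_loss) == 30

    def test_standardization_does_not_leak(self, quick_spec):
        # shifting held-out rows' features must not change the trained model
        df = make_table()
        probe = make_table(30, seed=7)
        shifted = probe.copy()
        r1, _ = train_regressor(quick_spec, df, validation_rows=probe)
        r2, _ = train_regressor(quick_spec, df,
                                validation_rows=shifted.assign(
                                    height=shifted["height"] + 100.0))
        np.testing.assert_array_equal(r1.predict(probe), r2.predict(probe))


class TestPredict:
    def test_vectorized_batch(self, quick_spec):
        res, _ = train_regressor(quick_spec, make_table())
        batch = make_table(10_000, seed=1)
        out = res.predict(batch)
        assert out.shape == (10_000,) and np.isfinite(out).all()

    def test_empty_input(self, quick_spec):
        res, _ = train_regressor(quick_spec, make_table())
        assert res.predict(make_table(200).iloc[:0]).shape == (0,)

    def test_permutation_equivariance(self, quick_spec):
        res, _ = train_regressor(quick_spec, make_table())
        probe = make_table(50, seed=2)
        perm = np.random.default_rng(0).permutation(50)
        np.testing.assert_allclose(res.predict(probe.iloc[perm]),
                                   res.predict(probe)[perm],
                                   rtol=0, atol=1e-12)

    def test_wrong_feature_count_rejected(self, quick_spec):
        res, _ = train_regressor(quick_spec, make_table())
        with pytest.raises(SurrogateError):
            res.predict(np.zeros((5, 7)))


class TestModelValidation:
    def test_too_few_rows_rejected(self, quick_spec):
        with pytest.raises(SurrogateError):
            train_regressor(quick_spec, make_table(20))

    def test_non_finite_rejected(self, quick_spec):
        df = make_table()
        df.loc[3, "height"] = np.nan
        with pytest.raises(SurrogateError):
            train_regressor(quick_spec, df)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(SurrogateError):
            RegressorSpec("MLP")


class TestSklearnBackends:
    @pytest.mark.parametrize("algo", [a for a in ALGORITHMS if a != "NN"])
    def test_same_interface_and_determinism(self, algo):
        df = make_table(150)
        probe = make_table(30, seed=4)
        spec = RegressorSpec(algo, (), seed=1)
        r1, h1 = train_regressor(spec, df)
        r2, _ = train_regressor(spec, df)
        assert len(h1) == 0  # no epoch history for non-NN models
        np.testing.assert_array_equal(r1.predict(probe), r2.predict(probe))


class TestTuning:
    def test_single_point_grid(self):
        df = make_table(120)
        spec = tune_hyperparameters("RF", {"n_estimators": [50]}, df, k=3)
        assert dict(spec.hyperparameters) == {"n_estimators": 50}

    def test_tie_break_prefers_first(self):
        df = make_table(120)
        grid = [{"C": 1.0}, {"C": 1.0}]  # duplicated best point
        spec = tune_hyperparameters("SVMLIN", grid, df, k=3)
        assert spec == tune_hyperparameters("SVMLIN", [{"C": 1.0}], df, k=3)

    def test_selects_better_hyperparameter(self):
        df = make_table(200)
        spec = tune_hyperparameters("RF",
                                    {"n_estimators": [2, 100]}, df, k=3)
        assert dict(spec.hyperparameters)["n_estimators"] == 100

    def test_invalid_folds_rejected(self):
        df = make_table(60)
        with pytest.raises(SurrogateError):
            tune_hyperparameters("RF", {"n_estimators": [10]}, df, k=1)
        with pytest.raises(SurrogateError):
            tune_hyperparameters("RF", {"n_estimators": [10]}, df, k=100)


class TestPersistence:
    def test_roundtrip(self, tmp_path, quick_spec):
        res, _ = train_regressor(quick_spec, make_table())
        res.uncertainty = (55.7, 179.5)
        path = tmp_path / "model.joblib"
        res.save(path)
        back = VoltageSurrogateResults.load(path)
        probe = make_table(20, seed=6)
        np.testing.assert_array_equal(back.predict(probe), res.predict(probe))
        assert back.uncertainty == (55.7, 179.5)
        assert back.spec == res.spec

    def test_summary_mentions_key_facts(self, quick_spec):
        res, _ = train_regressor(quick_spec, make_table())
        text = res.summary()
        assert "NN" in text and "3516" in text


class TestModelObject:
    def test_from_dataframe_equivalent_to_arrays(self, quick_spec):
        df = make_table()
        m1 = VoltageSurrogate.from_dataframe(df, quick_spec)
        m2 = VoltageSurrogate(df["v_total_V"].to_numpy(), df, quick_spec)
        np.testing.assert_array_equal(m1.exog, m2.exog)
        r1, r2 = m1.fit(), m2.fit()
        probe = make_table(10, seed=8)
        np.testing.assert_array_equal(r1.predict(probe), r2.predict(probe))
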