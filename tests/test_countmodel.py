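"""The plants-per-object network, importance ranking and RFE."""

import numpy as np
import pandas as pd
import pytest

from wheatdensity.countmodel import (
    CountModel,
    evaluate,
    feature_importance,
    predict_counts,
    recursive_feature_elimination,
    select_architecture,
    train_network,
)
from wheatdensity.errors import SchemaError, WheatDensityError


def _frame(X):
    return pd.DataFrame(X, columns=[f"F{j + 1}" for j in range(X.shape[1])])


def _toy_model(w1, b1, w2, b2, m):
    return CountModel(
        k_n=len(b1),
        input_weights=np.asarray(w1, float),
        input_biases=np.asarray(b1, float),
        output_weights=np.asarray(w2, float),
        output_bias=float(b2),
        feature_subset=[f"F{j + 1}" for j in range(m)],
        norm_mean=np.zeros(m),
        norm_sd=np.ones(m),
    )


class TestTrainNetwork:
    def test_constant_target_learned_exactly(self, rng):
        X = _frame(rng.normal(size=(200, 4)))
        model = train_network(X, np.ones(200), k_n=2, seed=0)
        pred = predict_counts(model, X)
        assert np.abs(pred - 1.0).max() < 0.01

    def test_linear_rule_high_r2_held_out(self, rng):
        X = rng.uniform(50, 500, size=(600, 3))
        y = X[:, 0] / 100.0
        model = train_network(_frame(X[:500]), y[:500], k_n=2, seed=1)
        rep = evaluate(model, _frame(X[500:]), y[500:])
        assert rep.r2 > 0.99

    def test_deterministic_given_seed(self, rng):
        X = _frame(rng.normal(size=(150, 5)))
        y = rng.poisson(1.5, 150).astype(float)
        m1 = train_network(X, y, k_n=3, seed=42)
        m2 = train_network(X, y, k_n=3, seed=42)
        assert m1.to_json() == m2.to_json()

    def test_zero_variance_feature_dropped_with_warning(self, rng):
        X = _frame(np.column_stack([rng.normal(size=100), np.full(100, 7.0)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            model = train_network(X, rng.normal(size=100), k_n=1, seed=0)
        assert model.feature_subset == ["F1"]

    def test_empty_data_raises(self):
        with pytest.raises(WheatDensityError):
            train_network(_frame(np.empty((0, 3))), np.empty(0))

    def test_parameter_recovery_of_known_tanh_network(self, rng):
        # data generated by a 2-node tanh network + N(0, 0.2) noise:
        # held-out RMSE should approach the noise floor
        W1 = np.array([[1.0, -0.5, 0.3], [-0.7, 0.8, 0.2]])
        b1 = np.array([0.1, -0.2])
        w2 = np.array([1.5, -1.0])
        X = rng.normal(size=(600, 3))
        y = np.tanh(X @ W1.T + b1) @ w2 + 2.0 + rng.normal(0, 0.2, 600)
        model = train_network(_frame(X[:500]), y[:500], k_n=2, seed=3)
        rep = evaluate(model, _frame(X[500:]), y[500:])
        assert rep.rmse < 1.5 * 0.2


class TestPredict:
    def test_negative_raw_output_clipped_to_zero(self):
        model = _toy_model([[1.0]], [0.0], [0.0], -5.0, 1)
        assert predict_counts(model, _frame(np.zeros((3, 1)))).tolist() \
            == [0.0, 0.0, 0.0]

    def test_zero_input_closed_form(self):
        model = _toy_model([[0.5, -0.2]], [0.3], [2.0], 0.7, 2)
        want = 0.7 + 2.0 * np.tanh(0.3)
        got = model.raw_predict(_frame(np.zeros((1, 2))))
        assert got[0] == pytest.approx(want, abs=1e-12)

    def test_missing_feature_column_raises(self):
        model = _toy_model([[1.0, 1.0]], [0.0], [1.0], 0.0, 2)
        with pytest.raises(SchemaError):
            predict_counts(model, pd.DataFrame({"F1": [1.0]}))

    def test_near_interpolating_model_reproduces_training_label(self, rng):
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(float) + 1.0
        model = train_network(_frame(X), y, k_n=6, seed=0)
        pred = predict_counts(model, _frame(X))
        # generously parameterized net on separable data: near interpolation
        assert np.median(np.abs(pred - y)) < 0.1

    def test_json_roundtrip(self, rng):
        X = _frame(rng.normal(size=(80, 3)))
        y = rng.poisson(1.0, 80).astype(float)
        model = train_network(X, y, k_n=2, seed=9)
        back = CountModel.from_json(model.to_json())
        np.testing.assert_array_equal(
            predict_counts(model, X), predict_counts(back, X)
        )


class TestEvaluate:
    def test_perfect_predictions(self):
        model = _toy_model([[0.0]], [0.0], [0.0], 2.0, 1)
        rep = evaluate(model, _frame(np.zeros((5, 1))), np.full(5, 2.0))
        assert rep.rmse == 0.0 and rep.bias == 0.0

    def test_constant_offset_gives_equal_bias_and_rmse(self):
        model = _toy_model([[0.0]], [0.0], [0.0], 2.5, 1)
        rep = evaluate(model, _frame(np.zeros((8, 1))), np.full(8, 2.0))
        assert rep.bias == pytest.approx(0.5)
        assert rep.rmse == pytest.approx(0.5)

    def test_matches_independent_recomputation(self, rng):
        X = _frame(rng.normal(size=(100, 2)))
        y = rng.poisson(1.2, 100).astype(float)
        model = train_network(X, y, k_n=2, seed=5)
        rep = evaluate(model, X, y)
        pred = predict_counts(model, X)
        assert rep.rmse == pytest.approx(np.sqrt(np.mean((pred - y) ** 2)))
        assert rep.bias == pytest.approx(np.mean(pred - y))
        ss = np.sum((y - y.mean()) ** 2)
        assert rep.r2 == pytest.approx(1 - np.sum((pred - y) ** 2) / ss)


class TestImportance:
    def test_single_node_closed_form_ranking(self):
        model = _toy_model([[2.0, 0.0, 1.0]], [0.0], [1.0], 0.0, 3)
        ranking = feature_importance(model)
        assert [f for f, _ in ranking] == ["F1", "F3", "F2"]
        assert [v for _, v in ranking] == [2.0, 1.0, 0.0]

    def test_target_feature_outranks_noise(self, rng):
        wins = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = np.column_stack([r.normal(size=300), r.normal(size=300)])
            y = X[:, 0].copy()
            model = train_network(_frame(X), y, k_n=2, seed=seed)
            if feature_importance(model)[0][0] == "F1":
                wins += 1
        assert wins >= 4


class TestArchitectureSearch:
    def test_linear_target_prefers_small_network(self, rng):
        X = _frame(rng.uniform(0, 10, size=(300, 2)))
        y = 0.5 * X["F1"].to_numpy() + rng.normal(0, 0.05, 300)
        k = select_architecture(X, y, k_range=range(1, 6), reps=3, seed=0)
        assert k <= 3

    def test_tie_breaks_toward_smaller_k(self, monkeypatch):
        import wheatdensity.countmodel as cm

        monkeypatch.setattr(cm, "_cv_rmse", lambda *a, **k: 1.0)
        X = _frame(np.random.default_rng(0).normal(size=(50, 2)))
        assert cm.select_architecture(X, np.zeros(50), k_range=range(1, 11)) == 1


class TestRfe:
    def test_informative_features_survive_noise_features(self, rng):
        n = 700
        info = rng.uniform(0, 10, size=(n, 4))
        noise = rng.normal(size=(n, 9))
        # every informative weight well above the noise floor
        y = info @ np.array([0.5, 0.4, 0.3, 0.2]) + rng.normal(0, 0.2, n)
        X = _frame(np.column_stack([info, noise]))
        trace, model = recursive_feature_elimination(X, y, k_n=2, reps=3,
                                                     seed=0)
        informative = {"F1", "F2", "F3", "F4"}
        chosen = set(trace.chosen_features)
        assert trace.chosen_n <= 5
        assert len(chosen - informative) <= 1

    def test_identical_copies_collapse_to_one_feature(self, rng):
        base = rng.uniform(0, 5, 400)
        X = _frame(np.tile(base[:, None], (1, 6)))
        y = base * 0.8 + rng.normal(0, 0.1, 400)
        trace, _ = recursive_feature_elimination(X, y, k_n=1, reps=3, seed=1)
        assert trace.chosen_n == 1

    def test_trace_structure_and_tolerance_rule(self, rng):
        X = _frame(rng.normal(size=(200, 5)))
        y = X["F1"].to_numpy() + rng.normal(0, 0.2, 200)
        trace, _ = recursive_feature_elimination(X, y, k_n=1, reps=2, seed=2)
        sizes = [n for n, _, _ in trace.records]
        assert sizes == list(range(5, 0, -1))
        rmses = {n: r for n, _, r in trace.records}
        assert trace.rmse_best == min(rmses.values())
        qualifying = [n for n in rmses if rmses[n] < 1.02 * trace.rmse_best]
        assert trace.chosen_n == min(qualifying)

    def test_deterministic_given_seed(self, rng):
        X = _frame(rng.normal(size=(150, 4)))
        y = rng.poisson(1.0, 150).astype(float)
        t1, m1 = recursive_feature_elimination(X, y, k_n=1, reps=2, seed=7)
        t2, m2 = recursive_feature_elimination(X, y, k_n=1, reps=2, seed=7)
        assert t1.to_json() == t2.to_json()
        assert m1.to_json() == m2.to_json()
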