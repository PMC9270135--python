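"""Unit and property tests for the backpropagation network."""

import math

import numpy as np
import pytest

from melasma_gabp.bp import (
    NetworkConfig,
    NetworkWeights,
    Normalizer,
    TrainingDivergedError,
    backprop_step,
    evaluate,
    fit_normalizer,
    forward,
    global_error,
    hidden_size,
    load_model,
    save_model,
    sigmoid,
    train,
    _gradients,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_weights(m, H, l, rng, scale=0.5):
    return NetworkWeights(
        rng.uniform(-scale, scale, (m + 1, H)),
        rng.uniform(-scale, scale, (H + 1, l)),
    )


class TestSigmoid:
    def test_symmetry_point(self):
        assert sigmoid(0.0) == 0.5

    def test_complementarity(self, rng):
        x = rng.normal(0, 5, 100)
        np.testing.assert_allclose(sigmoid(x) + sigmoid(-x), 1.0, atol=1e-12)

    def test_saturation(self):
        assert sigmoid(50.0) == pytest.approx(1.0, abs=1e-9)
        assert sigmoid(500.0) == pytest.approx(1.0)
        assert sigmoid(-500.0) == pytest.approx(0.0, abs=1e-200)
        assert math.isfinite(sigmoid(-750.0))  # no overflow warning path


class TestForward:
    def test_zero_weights_give_half_everywhere(self, rng):
        w = NetworkWeights(np.zeros((6, 10)), np.zeros((11, 1)))
        _, O = forward(w, rng.uniform(0, 1, (7, 5)))
        np.testing.assert_array_equal(O, 0.5)

    def test_hand_computed_1_1_1_network(self):
        # unit weights, zero biases, x=0: hidden f(0)=0.5, output f(0.5)
        w = NetworkWeights(np.array([[0.0], [1.0]]), np.array([[0.0], [1.0]]))
        y, O = forward(w, np.array([0.0]))
        assert y[0] == 0.5
        assert O[0] == pytest.approx(1 / (1 + math.exp(-0.5)))
        assert O[0] == pytest.approx(0.62246, abs=1e-5)

    def test_outputs_always_in_open_unit_interval(self, rng):
        for _ in range(20):
            w = random_weights(3, 4, 2, rng, scale=5.0)
            _, O = forward(w, rng.normal(0, 3, (50, 3)))
            assert np.all(O > 0) and np.all(O < 1)

    def test_dimension_mismatch_rejected(self, rng):
        w = random_weights(5, 10, 1, rng)
        with pytest.raises(ValueError, match="features"):
            forward(w, np.zeros(4))

    def test_inconsistent_weight_shapes_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            NetworkWeights(np.zeros((6, 10)), np.zeros((10, 1)))


class TestGlobalError:
    def test_perfect_fit_is_zero(self):
        w = NetworkWeights(np.zeros((2, 2)), np.zeros((3, 1)))
        X = np.array([[0.3], [0.7]])
        _, O = forward(w, X)
        assert global_error(w, (X, O[:, 0])) == 0.0

    def test_hand_computed_single_sample(self):
        # output f(0)=0.5 everywhere with zero weights
        w = NetworkWeights(np.zeros((2, 2)), np.zeros((3, 2)))
        X = np.array([[0.0]])
        B = np.array([[1.0, 0.0]])
        assert global_error(w, (X, B)) == pytest.approx(0.25)  # 0.5*(0.25+0.25)

    def test_single_output_extreme(self):
        # b=1, O=0.5 with zero weights gives 0.5*(0.5)^2; scale check vs b=1,O=0
        w = NetworkWeights(np.zeros((2, 2)), np.zeros((3, 1)))
        assert global_error(w, (np.array([[0.0]]), np.array([1.0]))) == pytest.approx(
            0.125
        )

    def test_empty_dataset_rejected(self):
        w = NetworkWeights(np.zeros((2, 2)), np.zeros((3, 1)))
        with pytest.raises(ValueError, match="non-empty"):
            global_error(w, (np.empty((0, 1)), np.empty(0)))

    def test_mean_aggregation_over_samples(self, rng):
        w = random_weights(2, 3, 1, rng)
        X = rng.uniform(0, 1, (4, 2))
        B = rng.uniform(0, 1, 4)
        per_sample = [global_error(w, (X[i : i + 1], B[i : i + 1])) for i in range(4)]
        assert global_error(w, (X, B)) == pytest.approx(np.mean(per_sample))


class TestBackprop:
    def test_gradient_matches_finite_differences(self, rng):
        """Analytic gradients vs central differences on random 3-4-2 nets."""
        for _ in range(3):
            w = random_weights(3, 4, 2, rng)
            X = rng.uniform(0, 1, (5, 3))
            B = rng.uniform(0, 1, (5, 2))
            dV, dW = _gradients(w, X, B)
            eps = 1e-5
            for mat, grad in ((w.V, dV), (w.W, dW)):
                it = np.nditer(mat, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = mat[idx]
                    mat[idx] = orig + eps
                    e_plus = global_error(w, (X, B))
                    mat[idx] = orig - eps
                    e_minus = global_error(w, (X, B))
                    mat[idx] = orig
                    numeric = (e_plus - e_minus) / (2 * eps)
                    denom = max(abs(numeric), abs(grad[idx]), 1e-8)
                    assert abs(numeric - grad[idx]) / denom < 1e-6

    def test_zero_gradient_at_perfect_fit(self):
        # targets set to the model's own outputs: update is a no-op
        w = NetworkWeights(np.full((3, 2), 0.1), np.full((3, 1), 0.2))
        X = np.array([[0.1, 0.9], [0.4, 0.2]])
        _, O = forward(w, X)
        updated = backprop_step(w, (X, O), 0.2)
        np.testing.assert_array_equal(updated.V, w.V)
        np.testing.assert_array_equal(updated.W, w.W)

    def test_one_step_reduces_error_at_default_rate(self, rng):
        w = random_weights(2, 3, 1, rng)
        X = np.array([[0.2, 0.8]])
        B = np.array([0.9])
        before = global_error(w, (X, B))
        after = global_error(backprop_step(w, (X, B), 0.2), (X, B))
        assert after < before

    def test_small_step_never_increases_error(self, rng):
        for _ in range(100):
            w = random_weights(3, 4, 2, rng, scale=1.0)
            X = rng.uniform(0, 1, (6, 3))
            B = rng.uniform(0, 1, (6, 2))
            before = global_error(w, (X, B))
            after = global_error(backprop_step(w, (X, B), 1e-3), (X, B))
            assert after <= before + 1e-15

    def test_online_mode_differs_but_descends(self, rng):
        w = random_weights(2, 3, 1, rng)
        X = rng.uniform(0, 1, (8, 2))
        B = rng.uniform(0, 1, 8)
        batch = backprop_step(w, (X, B), 0.2, mode="batch")
        online = backprop_step(w, (X, B), 0.2, mode="online")
        assert not np.array_equal(batch.V, online.V)
        assert global_error(online, (X, B)) < global_error(w, (X, B))

    def test_invalid_learning_rate_rejected(self, rng):
        w = random_weights(2, 3, 1, rng)
        with pytest.raises(ValueError, match="learning_rate"):
            backprop_step(w, (np.zeros((1, 2)), np.zeros(1)), 1.5)


class TestNormalizer:
    def test_endpoints_and_midpoint(self):
        X = np.array([[0.0, 10.0], [4.0, 30.0]])
        norm = fit_normalizer(X)
        np.testing.assert_allclose(norm.transform(np.array([0.0, 10.0])), [0, 0])
        np.testing.assert_allclose(norm.transform(np.array([4.0, 30.0])), [1, 1])
        np.testing.assert_allclose(norm.transform(np.array([2.0, 20.0])), [0.5, 0.5])

    def test_round_trip_identity(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-50, 50, (100, 4))
        norm = fit_normalizer(X)
        back = norm.inverse_transform(norm.transform(X))
        np.testing.assert_allclose(back, X, atol=1e-12)

    def test_degenerate_feature_maps_to_half(self):
        X = np.array([[1.0, 3.0], [1.0, 5.0]])
        norm = fit_normalizer(X)
        assert norm.degenerate.tolist() == [True, False]
        np.testing.assert_allclose(norm.transform(X)[:, 0], 0.5)

    def test_unfit_normalizer_rejected(self):
        with pytest.raises(RuntimeError, match="before fit"):
            Normalizer().transform(np.zeros((2, 2)))

    def test_single_sample_fit_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_normalizer(np.zeros((1, 3)))


class TestHiddenSize:
    @pytest.mark.parametrize("m, n, a, expected", [(5, 1, 4, 10), (5, 4, 1, 10), (1, 1, 1, 3)])
    def test_linear_rule(self, m, n, a, expected):
        assert hidden_size(m, n, a) == expected

    def test_sqrt_variant(self):
        assert hidden_size(5, 4, 1, rule="sqrt") == 4  # round(sqrt(9)) + 1

    @pytest.mark.parametrize("a", [0, 11])
    def test_constant_out_of_range_rejected(self, a):
        with pytest.raises(ValueError, match="constant"):
            hidden_size(5, 1, a)

    def test_default_config_width_is_ten(self):
        assert NetworkConfig().hidden == 10  # 5 inputs + 1 output + a=4


class TestTrain:
    def toy_dataset(self):
        # noiseless, linearly representable in the features
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        B = np.array([0.9, 0.6, 0.4, 0.1])
        return X, B

    def test_huge_error_goal_stops_immediately(self):
        X, B = self.toy_dataset()
        cfg = NetworkConfig(n_input=2, n_hidden=3, error_goal=1e6, seed=0)
        result = train(cfg, (X, B))
        assert result.epochs_run == 1
        assert result.converged

    def test_converges_on_separable_toy_set(self):
        X, B = self.toy_dataset()
        cfg = NetworkConfig(
            n_input=2, n_hidden=4, learning_rate=0.2, max_epochs=1000,
            error_goal=0.001, seed=3,
        )
        result = train(cfg, (X, B), mode="online")
        assert result.converged
        assert result.error_history[-1] < 0.001
        assert result.epochs_run <= 1000

    def test_deterministic_given_seed(self):
        X, B = self.toy_dataset()
        cfg = NetworkConfig(n_input=2, n_hidden=3, max_epochs=50, seed=11)
        r1 = train(cfg, (X, B))
        r2 = train(cfg, (X, B))
        assert r1.error_history == r2.error_history  # bitwise identical
        np.testing.assert_array_equal(r1.final_weights.V, r2.final_weights.V)

    def test_history_matches_epochs_and_goal_flag(self):
        X, B = self.toy_dataset()
        cfg = NetworkConfig(n_input=2, n_hidden=3, max_epochs=25, error_goal=1e-9, seed=0)
        result = train(cfg, (X, B))
        assert result.epochs_run == len(result.error_history) == 25
        assert not result.converged

    def test_divergence_reported_with_epoch(self):
        # a non-finite target makes the global error NaN on the first epoch
        X = np.array([[0.5], [0.25]])
        B = np.array([0.5, np.nan])
        cfg = NetworkConfig(n_input=1, n_hidden=2, max_epochs=5, seed=0)
        with pytest.raises(TrainingDivergedError) as excinfo:
            train(cfg, (X, B))
        assert excinfo.value.epoch == 0

    def test_dataset_config_mismatch_rejected(self):
        cfg = NetworkConfig(n_input=3, n_hidden=2)
        with pytest.raises(ValueError, match="does not"):
            train(cfg, (np.zeros((4, 2)), np.zeros(4)))


class TestEvaluate:
    def test_exact_model_has_zero_error(self):
        w = NetworkWeights(np.zeros((3, 2)), np.zeros((3, 1)))
        X = np.array([[0.1, 0.2], [0.3, 0.4]])
        _, O = forward(w, X)
        report = evaluate(w, None, (X, O[:, 0]))
        assert report.mean_abs_error == 0.0

    def test_mean_of_row_errors(self):
        rows_exp = np.array([0.2, 0.4])
        w = NetworkWeights(np.zeros((2, 1)), np.zeros((2, 1)))  # outputs 0.5
        report = evaluate(w, None, (np.array([[0.0], [0.0]]), rows_exp))
        np.testing.assert_allclose(report.rows["abs_error"], [0.3, 0.1])
        assert report.mean_abs_error == pytest.approx(0.2)
        assert report.mean_abs_error == pytest.approx(report.rows["abs_error"].mean())

    def test_row_count_and_ids(self):
        w = NetworkWeights(np.zeros((2, 1)), np.zeros((2, 1)))
        X = np.zeros((5, 1))
        report = evaluate(w, None, (X, np.full(5, 0.5)), sample_ids=[7, 8, 9, 10, 11])
        assert len(report.rows) == 5
        assert report.rows["sample"].tolist() == [7, 8, 9, 10, 11]

    def test_empty_test_set_rejected(self):
        w = NetworkWeights(np.zeros((2, 1)), np.zeros((2, 1)))
        with pytest.raises(ValueError, match="non-empty"):
            evaluate(w, None, (np.empty((0, 1)), np.empty(0)))


def test_model_json_round_trip(tmp_path, rng):
    w = random_weights(5, 10, 1, rng)
    norm = fit_normalizer(rng.uniform(1, 4, (20, 5)))
    path = tmp_path / "model.json"
    save_model(path, w, norm)
    w2, norm2 = load_model(path)
    np.testing.assert_array_equal(w.V, w2.V)
    np.testing.assert_array_equal(w.W, w2.W)
    np.testing.assert_array_equal(norm.minimum, norm2.minimum)
    np.testing.assert_array_equal(norm.maximum, norm2.maximum)
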