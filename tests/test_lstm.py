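import numpy as np
import pytest

from gwpred import (
    LSTM_PRESETS,
    LstmConfig,
    LstmParameters,
    lstm_cell_step,
    lstm_preset,
    predict_lstm,
    simulate_genotypes,
    simulate_trait,
    train_lstm,
)
from gwpred.lstm import TrainedLstm, loss_and_gradients


def zero_params(H, F):
    return LstmParameters(
        np.zeros((4 * H, F)), np.zeros((4 * H, H)), np.zeros(4 * H), np.zeros(H), 0.0
    )


def random_params(H, F, seed=0, scale=0.4):
    rng = np.random.default_rng(seed)
    return LstmParameters(
        rng.normal(0, scale, (4 * H, F)),
        rng.normal(0, scale, (4 * H, H)),
        rng.normal(0, 0.2, 4 * H),
        rng.normal(0, scale, H),
        0.3,
    )


class TestCellStep:
    def test_zero_weights_tanh_hand_values(self):
        p = zero_params(3, 2)
        c = np.array([1.0, -2.0, 0.5])
        h, C = lstm_cell_step(p, np.zeros(2), np.zeros(3), c, "tanh")
        np.testing.assert_allclose(C, 0.5 * c)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c))

    def test_zero_weights_relu_hand_values(self):
        p = zero_params(3, 2)
        h, C = lstm_cell_step(p, np.zeros(2), np.zeros(3), np.ones(3), "relu")
        np.testing.assert_allclose(C, 0.5)
        np.testing.assert_allclose(h, 0.25)

    def test_gate_and_state_ranges(self):
        p = random_params(4, 5, seed=1, scale=2.0)
        rng = np.random.default_rng(2)
        h, C = np.zeros(4), np.zeros(4)
        for _ in range(20):
            h, C = lstm_cell_step(p, rng.normal(0, 3, 5), h, C, "tanh")
            assert np.all(np.abs(h) <= 1.0)  # |o*tanh(C)| <= 1
        assert np.all(np.isfinite(C))

    def test_dimension_mismatch_rejected(self):
        p = zero_params(3, 2)
        with pytest.raises(ValueError, match="dimension"):
            lstm_cell_step(p, np.zeros(5), np.zeros(3), np.zeros(3))

    def test_bad_parameter_shapes_rejected(self):
        with pytest.raises(ValueError):
            LstmParameters(np.zeros((13, 2)), np.zeros((13, 3)), np.zeros(13), np.zeros(3), 0.0)


class TestGradients:
    @pytest.mark.parametrize("act", ["tanh", "relu"])
    def test_analytic_matches_central_finite_differences(self, act):
        params = random_params(3, 4, seed=3)
        rng = np.random.default_rng(4)
        Xseq = rng.normal(0, 1, (4, 2, 4))
        y = rng.normal(0, 1, 4)
        _, grads = loss_and_gradients(params, Xseq, y, act)
        eps = 1e-6
        for fld in ("W", "R", "b", "w_out"):
            arr = getattr(params, fld)
            garr = np.atleast_1d(getattr(grads, fld))
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                old = arr[ix]
                arr[ix] = old + eps
                lp, _ = loss_and_gradients(params, Xseq, y, act)
                arr[ix] = old - eps
                lm, _ = loss_and_gradients(params, Xseq, y, act)
                arr[ix] = old
                fd = (lp - lm) / (2 * eps)
                an = garr[ix]
                # 1e-8 absolute floor: near-zero entries are dominated by
                # finite-difference roundoff, not by gradient error
                assert abs(fd - an) < 1e-5 * max(abs(fd), abs(an)) + 1e-8, (
                    f"{fld}{ix}: fd={fd}, analytic={an}"
                )


class TestPresets:
    def test_grid_matches_activation_by_minibatch(self):
        assert LSTM_PRESETS == {
            "lstm1": ("relu", 0.1),
            "lstm2": ("tanh", 0.1),
            "lstm3": ("relu", 0.5),
            "lstm4": ("tanh", 0.5),
            "lstm5": ("relu", 1.0),
            "lstm6": ("tanh", 1.0),
        }

    def test_preset_builds_config(self):
        cfg = lstm_preset("lstm5", epochs=7)
        assert cfg.state_activation == "relu"
        assert cfg.minibatch_fraction == 1.0
        assert cfg.epochs == 7

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            lstm_preset("lstm7")


@pytest.fixture(scope="module")
def tiny_training_problem():
    G = simulate_genotypes(200, 100, seed=30)
    y, truth = simulate_trait(G, n_qtl=5, h2a=1.0, seed=31)
    return G.dosage, y.value


class TestTraining:
    def test_seeded_loss_trace_bitwise_identical(self, tiny_training_problem):
        X, y = tiny_training_problem
        cfg = LstmConfig(hidden_units=8, epochs=5, chunk_size=50, seed=7)
        a = train_lstm(X, y, cfg)
        b = train_lstm(X, y, cfg)
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)

    def test_fits_noiseless_linear_trait(self, tiny_training_problem):
        X, y = tiny_training_problem
        cfg = LstmConfig(epochs=200, minibatch_fraction=0.5, chunk_size=50, seed=0)
        net = train_lstm(X, y, cfg)
        mse = np.mean((predict_lstm(net, X) - y) ** 2)
        assert mse < 0.1 * y.var()

    def test_update_step_count_decreases_with_minibatch_fraction(self, tiny_training_problem):
        X, y = tiny_training_problem
        steps = {}
        for frac in (0.1, 0.5, 1.0):
            cfg = LstmConfig(hidden_units=4, epochs=3, chunk_size=50, minibatch_fraction=frac, seed=0)
            steps[frac] = train_lstm(X, y, cfg).n_update_steps
        assert steps[0.1] > steps[0.5] > steps[1.0]

    def test_relu_identity_initialization(self):
        from gwpred.lstm import _init_params

        cfg = LstmConfig(hidden_units=5, state_activation="relu", chunk_size=10)
        p = _init_params(cfg, 10, np.random.default_rng(0))
        H = 5
        np.testing.assert_array_equal(p.R[2 * H : 3 * H, :], np.eye(H))
        np.testing.assert_array_equal(p.b, 0.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LstmConfig(minibatch_fraction=0.0)
        with pytest.raises(ValueError):
            LstmConfig(state_activation="sigmoid")


class TestPredict:
    def make_net(self, H=4, p=20, chunk=10):
        cfg = LstmConfig(hidden_units=H, chunk_size=chunk)
        return TrainedLstm(
            config=cfg,
            params=zero_params(H, chunk),
            n_markers=p,
            x_mean=np.zeros(p),
            x_std=np.ones(p),
            y_mean=0.0,
            y_std=1.0,
        )

    def test_zero_parameters_predict_output_bias(self):
        net = self.make_net()
        net.params.b_out = 1.25
        pred = predict_lstm(net, np.random.default_rng(0).normal(0, 1, (6, 20)))
        np.testing.assert_allclose(pred, 1.25)

    def test_duplicated_rows_identical_predictions(self, tiny_training_problem):
        X, y = tiny_training_problem
        net = train_lstm(X, y, LstmConfig(hidden_units=4, epochs=3, chunk_size=50, seed=0))
        pred = predict_lstm(net, np.vstack([X[:1], X[:1]]))
        assert pred[0] == pytest.approx(pred[1])

    def test_marker_count_mismatch_rejected(self):
        net = self.make_net()
        with pytest.raises(ValueError, match="markers"):
            predict_lstm(net, np.zeros((2, 19)))

    def test_prediction_invariant_to_minibatch_fraction(self, tiny_training_problem):
        X, y = tiny_training_problem
        net = train_lstm(X, y, LstmConfig(hidden_units=4, epochs=3, chunk_size=50, seed=0))
        base = predict_lstm(net, X[:5])
        net.config.minibatch_fraction = 0.1  # inference must ignore it
        np.testing.assert_array_equal(predict_lstm(net, X[:5]), base)
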