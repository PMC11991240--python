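"""Architecture contract, training mechanics and utilities of the regressor."""

import numpy as np
import pytest

from imugait import cnn as C
from imugait.errors import ConfigError, ShapeError, TrainingError
from imugait.synthetic import simulate_cohort


def small_config(**kw):
    defaults = dict(sequence_length=32, epochs=2, seed=0, batch_size=4)
    defaults.update(kw)
    return C.CnnConfig(**defaults)


class TestArchitecture:
    def test_eleven_convolutions_and_mirrored_filters(self):
        model = C.build_model(small_config())
        assert model.config.n_conv_layers == 11
        assert len(model.conv_layers) == 11
        enc, dec = model.encoder_decoder_filters()
        assert enc == [128, 256, 512, 1024]
        assert dec == enc[::-1][1:] + [64]
        assert dec == [512, 256, 128, 64]

    def test_parameter_count_closed_form(self):
        model = C.build_model(small_config())
        pairs = model.config.filter_sizes()
        expected = sum(c_out * c_in * 41 + c_out for c_in, c_out in pairs)
        # every hidden convolution carries a batch-norm gain and shift
        expected += sum(2 * c_out for _, c_out in pairs[:-1])
        assert model.n_params == expected

    def test_default_window_shape_is_preserved(self):
        model = C.build_model(C.CnnConfig())
        x = np.zeros((1, 1392, 6), dtype=np.float32)
        assert model.forward(x).shape == (1, 1392, 3)

    def test_any_multiple_of_16_preserved(self):
        model = C.build_model(small_config(sequence_length=48))
        x = np.zeros((2, 48, 6), dtype=np.float32)
        assert model.forward(x).shape == (2, 48, 3)

    def test_indivisible_length_rejected(self):
        with pytest.raises(ConfigError, match="divisible"):
            C.CnnConfig(sequence_length=1000)

    def test_broken_filter_ladder_rejected(self):
        with pytest.raises(ConfigError, match="double"):
            C.CnnConfig(max_filters=512)


class TestGradients:
    def test_conv_gradients_match_finite_differences(self, rng):
        """Backprop through one convolution agrees with numerical derivatives."""
        x = rng.normal(size=(2, 8, 3)).astype(np.float32)
        W = rng.normal(0, 0.3, size=(4, 3, 5)).astype(np.float32)
        b = rng.normal(size=4).astype(np.float32)
        S = C._im2col(x, 5).copy()
        y = C._conv_forward(S, W, b, 2, 8).copy()
        dy = rng.normal(size=y.shape).astype(np.float32)
        # the backward pass consumes its patch-matrix argument
        dx, dW, db = C._conv_backward(S.copy(), x.shape, W, dy, C._BufferPool())
        dx, dW = dx.copy(), dW.copy()
        eps = 1e-2
        for idx in [(0, 3, 1), (1, 0, 2)]:
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fp = (C._conv_forward(C._im2col(xp, 5), W, b, 2, 8) * dy).sum()
            fm = (C._conv_forward(C._im2col(xm, 5), W, b, 2, 8) * dy).sum()
            assert dx[idx] == pytest.approx((fp - fm) / (2 * eps), rel=2e-2, abs=1e-3)
        for idx in [(0, 0, 0), (3, 2, 4)]:
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            fp = (C._conv_forward(S, Wp, b, 2, 8) * dy).sum()
            fm = (C._conv_forward(S, Wm, b, 2, 8) * dy).sum()
            assert dW[idx] == pytest.approx((fp - fm) / (2 * eps), rel=2e-2, abs=1e-3)


@pytest.fixture(scope="module")
def tiny_dataset():
    sessions = simulate_cohort(12, seed=21, accel_bias=0.0)
    return C.make_dataset(sessions, side="right", length=32)


class TestTraining:
    def test_loss_decreases_and_is_deterministic(self, tiny_dataset):
        reports = []
        for _ in range(2):
            model = C.build_model(small_config(learning_rate=3e-4))
            reports.append(C.train(model, tiny_dataset, split=0.25, epochs=2, seed=3))
        a, b = reports
        assert a.train_loss == b.train_loss  # bit-identical loss curves
        assert a.val_loss == b.val_loss
        assert a.train_loss[-1] < a.train_loss[0]

    def test_empty_dataset_rejected(self):
        model = C.build_model(small_config())
        with pytest.raises(TrainingError):
            C.train(model, (np.zeros((1, 6, 32)), np.zeros((1, 3, 32))), epochs=1)

    def test_wrong_window_length_rejected(self, tiny_dataset):
        model = C.build_model(small_config(sequence_length=48))
        with pytest.raises(ShapeError):
            C.train(model, tiny_dataset, epochs=1)


class TestPredict:
    def test_untrained_model_zero_input_finite(self):
        model = C.build_model(small_config())
        traj = C.predict(model, np.zeros((6, 32)))
        assert np.isfinite(traj.xyz).all()
        assert len(traj) == 32

    def test_short_window_padded_and_cropped_back(self):
        model = C.build_model(small_config())
        traj = C.predict(model, np.zeros((6, 20)))
        assert len(traj) == 20

    def test_wrong_channel_count_rejected(self):
        model = C.build_model(small_config())
        with pytest.raises(ShapeError):
            C.predict(model, np.zeros((5, 32)))

    def test_checkpoint_round_trip(self, tmp_path, tiny_dataset):
        model = C.build_model(small_config(learning_rate=3e-4))
        C.train(model, tiny_dataset, split=0.25, epochs=1, seed=3)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = C.CnnModel.load(path)
        x = tiny_dataset[0][0]
        a = C.predict(model, x)
        b = C.predict(loaded, x)
        np.testing.assert_array_equal(a.xyz, b.xyz)


class TestSmoother:
    def test_constant_series_unchanged(self):
        x = np.full(100, 3.7)
        np.testing.assert_allclose(C.smooth(x), x, atol=1e-12)

    def test_unit_impulse_becomes_plateau(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = C.smooth(x, halfwidth=10)
        np.testing.assert_allclose(out[40:61], 1.0 / 21.0, atol=1e-12)
        assert out[39] == 0.0 and out[61] == 0.0

    def test_white_noise_variance_reduced(self, rng):
        x = rng.normal(size=200_000)
        out = C.smooth(x, halfwidth=10)
        ratio = out[50:-50].std() / x.std()
        assert ratio == pytest.approx(1.0 / np.sqrt(21.0), rel=0.02)


class TestRmse:
    def test_identical_inputs_zero(self, rng):
        a = rng.normal(size=(50, 3))
        assert C.rmse(a, a.copy()) == 0.0

    def test_constant_offset_closed_form(self):
        a = np.zeros((100, 3))
        b = a.copy()
        b[:, 0] += 0.01
        assert C.rmse(a, b) == pytest.approx(0.01 / np.sqrt(3), abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        a, b = rng.normal(size=(20, 3)), rng.normal(size=(20, 3))
        acc = 0.0
        count = 0
        for i in range(20):
            for j in range(3):
                acc += (a[i, j] - b[i, j]) ** 2
                count += 1
        assert C.rmse(a, b) == pytest.approx(np.sqrt(acc / count), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            C.rmse(np.zeros((5, 3)), np.zeros((6, 3)))
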