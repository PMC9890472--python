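"""Backward TRF decoder: lagged design, ridge training, reconstruction, scoring."""

import numpy as np
import pytest

from popout.decoding import (lag_design, lagged_gram, reconstruct_envelope,
                             score_reconstruction, train_decoder)
from popout.exceptions import AlignmentError, ConfigurationError, StructuralError
from popout.preprocessing import EEGEpoch
from popout.utils import pearson_r


def _epoch(data, fs=100.0):
    return EEGEpoch(data=np.asarray(data, float), fs=fs, t0=0.0,
                    channels=tuple(f"ch{i}" for i in range(len(data))))


class TestLagDesign:
    def test_column_count(self, rng):
        X = lag_design(rng.standard_normal((64, 500)), fs=100.0)
        assert X.shape == (500, 64 * 31)

    def test_zero_lag_identity(self, rng):
        data = rng.standard_normal((3, 40))
        X = lag_design(data, lags_ms=np.array([0.0]), fs=100.0)
        np.testing.assert_array_equal(X, data.T)

    def test_hand_shift(self):
        data = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        X = lag_design(data, lags_ms=np.array([0.0, 10.0]), fs=100.0)
        np.testing.assert_array_equal(X[:, 0], [1, 2, 3, 4, 5])
        np.testing.assert_array_equal(X[:, 1], [2, 3, 4, 5, 0])

    def test_non_integer_lag_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            lag_design(rng.standard_normal((1, 10)), lags_ms=np.array([0.0, 7.0]),
                       fs=100.0)

    @pytest.mark.parametrize("C,T,L", [(2, 37, 4), (5, 120, 31)])
    def test_lagged_gram_matches_dense(self, rng, C, T, L):
        data = rng.standard_normal((C, T))
        y = rng.standard_normal(T)
        D = lag_design(data, lags_ms=np.arange(L) * 10.0, fs=100.0)
        for a, b in [(0, T), (5, T // 2)]:
            XtX, Xty = lagged_gram(data, y, np.arange(L), (a, b))
            np.testing.assert_allclose(XtX, D[a:b].T @ D[a:b], atol=1e-10)
            np.testing.assert_allclose(Xty, D[a:b].T @ y[a:b], atol=1e-10)


class TestTraining:
    def test_identity_mapping(self, rng):
        y = rng.standard_normal(600)
        data = np.zeros((4, 600))
        data[1] = y
        data += 1e-8 * rng.standard_normal(data.shape)  # avoid constant channels
        model = train_decoder(data, y, lambda_grid=(1e-8,))
        assert model.training_r >= 0.999
        w = np.abs(model.weights)
        assert np.unravel_index(np.argmax(w), w.shape) == (1, 0)

    def test_matches_normal_equations(self, rng):
        data = rng.standard_normal((3, 200))
        y = rng.standard_normal(200)
        lam = 5.0
        model = train_decoder(data, y, lambda_grid=(lam,))
        Z = (data - data.mean(1, keepdims=True)) / data.std(1, keepdims=True)
        yz = (y - y.mean()) / y.std()
        X = lag_design(Z, fs=100.0)
        w = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ yz)
        rel = np.abs(model.weights.ravel() - w).max() / np.abs(w).max()
        assert rel < 1e-8

    def test_cv_selects_reasonable_lambda(self, rng):
        # strong signal + noise: CV should not pick the degenerate extremes
        y = np.convolve(rng.standard_normal(2000), np.hanning(20), "same")
        data = np.stack([np.roll(y, -3) + 0.5 * rng.standard_normal(2000)
                         for _ in range(3)])
        model = train_decoder(data, y, lambda_grid=(1e-6, 1e0, 1e6), n_folds=4)
        assert model.lambda_ in (1e-6, 1e0, 1e6)
        assert len(model.cv_summary) == 3
        held_out = model.cv_summary[model.lambda_]["mean_r"]
        assert held_out == max(v["mean_r"] for v in model.cv_summary.values())

    def test_degenerate_inputs(self, rng):
        with pytest.raises(ConfigurationError):
            train_decoder(rng.standard_normal((2, 100)), np.ones(100),
                          lambda_grid=(1.0,))
        bad = rng.standard_normal((2, 100))
        bad[0, 0] = np.nan
        with pytest.raises(ConfigurationError):
            train_decoder(bad, rng.standard_normal(100), lambda_grid=(1.0,))
        with pytest.raises(AlignmentError):
            train_decoder(rng.standard_normal((2, 100)),
                          rng.standard_normal(50), lambda_grid=(1.0,))


class TestReconstruction:
    def _model(self, rng):
        data = rng.standard_normal((3, 400))
        y = data[0] * 0.5 + 0.1 * rng.standard_normal(400)
        return train_decoder(data, y, lambda_grid=(1.0,)), data, y

    def test_zero_eeg_gives_constant_output(self, rng):
        model, data, y = self._model(rng)
        zero = _epoch(np.zeros((3, 100)))
        est = reconstruct_envelope(model, zero)
        # constant wherever all lags see data (the trailing 300 ms loses
        # zero-padded terms)
        assert np.ptp(est[:-31]) < 1e-9

    def test_training_fit_reproduced(self, rng):
        model, data, y = self._model(rng)
        est = reconstruct_envelope(model, _epoch(data))
        assert abs(pearson_r(est, y) - model.training_r) < 1e-12

    def test_channel_mismatch(self, rng):
        model, data, y = self._model(rng)
        other = EEGEpoch(data=np.zeros((3, 50)), fs=100.0, t0=0.0,
                         channels=("x", "y", "z"))
        with pytest.raises(StructuralError):
            reconstruct_envelope(model, other)


class TestScoring:
    def test_perfect_and_inverted(self, rng):
        env = rng.standard_normal(1050)
        scores = score_reconstruction(env, env)
        assert [s.iteration for s in scores] == [1, 2, 3]
        assert all(abs(s.r - 1.0) < 1e-12 for s in scores)
        neg = score_reconstruction(-env, env)
        assert all(abs(s.r + 1.0) < 1e-12 for s in neg)

    def test_window_boundaries(self, rng):
        env = rng.standard_normal(1050)
        est = env.copy()
        est[350:700] = rng.standard_normal(350)  # corrupt iteration 2 only
        scores = score_reconstruction(est, env)
        assert scores[0].r > 0.999 and scores[2].r > 0.999
        assert abs(scores[1].r) < 0.5

    def test_constant_segment_warns_nan(self, rng):
        env = rng.standard_normal(700)
        est = est = np.concatenate([np.ones(350), rng.standard_normal(350)])
        with pytest.warns(UserWarning):
            scores = score_reconstruction(est, env)
        assert np.isnan(scores[0].r)
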