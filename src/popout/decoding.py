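"""Backward (stimulus-reconstruction) temporal-response-function decoder.

A ridge-regularized linear map from multichannel, lagged EEG to the 2-8 Hz
auditory envelope.  The envelope at time t is predicted from EEG at
t .. t+300 ms (lags 0..300 ms in 10 ms steps, i.e. one 100 Hz sample per
lag).  Predictors and target are z-scored on training statistics; the ridge
penalty is selected by contiguous-segment k-fold cross-validation maximizing
mean held-out Pearson r.

The normal equations are assembled by a lag-correlation routine
(`lagged_gram`) that is algebraically identical to forming the dense
zero-padded lagged design and computing X'X / X'y, but runs in
O(C^2 L T) instead of O((CL)^2 T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .exceptions import AlignmentError, ConfigurationError, StructuralError
from .preprocessing import EEGEpoch
from .utils import pearson_r

LAGS_MS = np.arange(0, 301, 10)      # 31 lags
DEFAULT_LAMBDA_GRID = tuple(10.0 ** np.arange(-6, 7))


def lag_design(eeg: EEGEpoch | np.ndarray, lags_ms=LAGS_MS,
               fs: float | None = None) -> np.ndarray:
    """Dense lagged design matrix (sample x (channel*lag)).

    Column (c, l) holds channel c advanced by lag l (zero-padded at the end):
    the envelope at sample t is predicted from EEG at t + l.  Columns are
    ordered channel-major (all lags of channel 0, then channel 1, ...).
    """
    if isinstance(eeg, EEGEpoch):
        data, fs = eeg.data, eeg.fs
    else:
        data = np.asarray(eeg, float)
        if fs is None:
            raise ConfigurationError("fs required when passing a bare array")
    lag_samp = np.asarray(lags_ms, float) * fs / 1000.0
    if np.any(np.abs(lag_samp - np.round(lag_samp)) > 1e-9):
        raise ConfigurationError(
            "lags must be integer multiples of the sample period")
    lags = np.round(lag_samp).astype(int)
    C, T = data.shape
    X = np.zeros((T, C * len(lags)))
    for c in range(C):
        for j, l in enumerate(lags):
            if l < T:
                X[: T - l, c * len(lags) + j] = data[c, l:]
    return X


def lagged_gram(data: np.ndarray, y: np.ndarray, lags: np.ndarray,
                row_range: tuple[int, int] | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """X'X and X'y of the zero-padded lagged design, without materializing X.

    ``data`` is channels x samples (already standardized), ``y`` the target,
    ``lags`` integer sample lags 0..L-1 with unit step.  ``row_range``
    restricts the sum to design rows [a, b), which is what the contiguous
    cross-validation folds use.  Exact up to floating-point reassociation.
    """
    C, T = data.shape
    L = len(lags)
    if not np.array_equal(lags, np.arange(L)):
        raise ConfigurationError("lagged_gram requires unit-step lags 0..L-1")
    a, b = row_range if row_range is not None else (0, T)
    Xp = np.concatenate([data, np.zeros((C, L + 1))], axis=1)  # zero-padded
    XtX = np.empty((C * L, C * L))
    for d in range(L):
        # blocks[l1] = sum_{t=a}^{b-1} x[:, t+l1] x[:, t+l1+d]'  (zero-padded)
        block = Xp[:, a:b + 0] @ Xp[:, a + d:b + d].T
        for l1 in range(L - d):
            l2 = l1 + d
            if l1 > 0:
                s_head = a + l1 - 1
                s_tail = b + l1 - 1
                block = (block
                         - np.outer(Xp[:, s_head], Xp[:, s_head + d])
                         + np.outer(Xp[:, s_tail], Xp[:, s_tail + d]))
            rows = slice(l1, C * L, L)
            cols = slice(l2, C * L, L)
            XtX[rows, cols] = block
            if d > 0:
                XtX[cols, rows] = block.T
    Xty = np.empty(C * L)
    for l in range(L):
        Xty[l::L] = Xp[:, a + l:b + l] @ y[a:b]
    return XtX, Xty


@dataclass
class DecoderModel:
    """Ridge decoder weights (channel x lag) with its training context."""
    weights: np.ndarray                 # (n_channels, n_lags), standardized space
    intercept: float
    lags_ms: np.ndarray
    lambda_: float
    channels: tuple[str, ...]
    channel_means: np.ndarray
    channel_stds: np.ndarray
    env_mean: float
    env_std: float
    cv_summary: dict = field(default_factory=dict)
    training_r: float = float("nan")

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ConfigurationError("ridge penalty must be nonnegative")
        if not np.all(np.isfinite(self.weights)):
            raise StructuralError("decoder weights must be finite")


@dataclass
class ReconstructionScore:
    trial_index: int
    presentation: int
    iteration: int          # 1..3
    r: float


def _standardize(data: np.ndarray, y: np.ndarray):
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ConfigurationError("constant EEG channel in training data")
    muy, sdy = float(y.mean()), float(y.std())
    if sdy == 0:
        raise ConfigurationError("constant training envelope")
    return (data - mu) / sd, (y - muy) / sdy, mu.ravel(), sd.ravel(), muy, sdy


def _solve(XtX: np.ndarray, Xty: np.ndarray, lam: float) -> np.ndarray:
    A = XtX + lam * np.eye(XtX.shape[0])
    try:
        return linalg.cho_solve(linalg.cho_factor(A, lower=True), Xty)
    except linalg.LinAlgError:
        return linalg.solve(A, Xty, assume_a="sym")


def train_decoder(training_eeg: EEGEpoch | np.ndarray,
                  training_envelope, lambda_grid=DEFAULT_LAMBDA_GRID,
                  n_folds: int = 8, lags_ms=LAGS_MS) -> DecoderModel:
    """Fit the backward model on time-aligned clear-speech training data.

    With more than one candidate in ``lambda_grid``, the penalty is chosen by
    contiguous-segment k-fold cross-validation (held-out Pearson r averaged
    over folds); the final solve uses all training samples.
    """
    if isinstance(training_eeg, EEGEpoch):
        data, fs, channels = (training_eeg.data, training_eeg.fs,
                              training_eeg.channels)
    else:
        data = np.asarray(training_eeg, float)
        fs, channels = 100.0, tuple(f"ch{i}" for i in range(data.shape[0]))
    y = np.asarray(getattr(training_envelope, "samples", training_envelope),
                   float)
    if not (np.all(np.isfinite(data)) and np.all(np.isfinite(y))):
        raise ConfigurationError("non-finite values in training data")
    n = min(data.shape[1], len(y))
    if abs(data.shape[1] - len(y)) > 1:
        raise AlignmentError(
            f"EEG ({data.shape[1]}) and envelope ({len(y)}) lengths differ by "
            "more than one sample")
    data, y = data[:, :n], y[:n]
    Z, yz, mu, sd, muy, sdy = _standardize(data, y)

    lag_samp = np.round(np.asarray(lags_ms, float) * fs / 1000.0).astype(int)
    L = len(lag_samp)
    C = data.shape[0]

    lambda_grid = [float(l) for l in np.atleast_1d(lambda_grid)]
    cv_summary: dict = {}
    if len(lambda_grid) == 1:
        best_lam = lambda_grid[0]
        XtX, Xty = lagged_gram(Z, yz, lag_samp)
    else:
        bounds = np.linspace(0, n, n_folds + 1).astype(int)
        grams = [lagged_gram(Z, yz, lag_samp, (bounds[k], bounds[k + 1]))
                 for k in range(n_folds)]
        XtX = np.sum([g[0] for g in grams], axis=0)
        Xty = np.sum([g[1] for g in grams], axis=0)
        mean_r = []
        for lam in lambda_grid:
            rs = []
            for k in range(n_folds):
                a, b = bounds[k], bounds[k + 1]
                w = _solve(XtX - grams[k][0], Xty - grams[k][1], lam)
                Xk = lag_design(Z[:, a:b], lags_ms=np.asarray(lags_ms), fs=fs)
                # rows near the fold end lack the out-of-fold continuation;
                # that boundary effect is shared by all lambdas
                pred = Xk @ w
                rs.append(pearson_r(pred, yz[a:b]))
            mean_r.append(float(np.nanmean(rs)))
            cv_summary[lam] = {"fold_r": rs, "mean_r": mean_r[-1]}
        best_lam = lambda_grid[int(np.argmax(mean_r))]

    w = _solve(XtX, Xty, best_lam)
    weights = w.reshape(C, L)
    pred = _predict_standardized(Z, weights, lag_samp)
    training_r = pearson_r(pred, yz)
    return DecoderModel(weights=weights, intercept=muy, lags_ms=np.asarray(lags_ms),
                        lambda_=best_lam, channels=tuple(channels),
                        channel_means=mu, channel_stds=sd, env_mean=muy,
                        env_std=sdy, cv_summary=cv_summary,
                        training_r=training_r)


def _predict_standardized(Z: np.ndarray, weights: np.ndarray,
                          lags: np.ndarray) -> np.ndarray:
    """Prediction sum_c sum_l w[c,l] * Z[c, t+l] via shifted accumulation."""
    C, T = Z.shape
    out = np.zeros(T)
    for j, l in enumerate(lags):
        if l < T:
            out[: T - l] += weights[:, j] @ Z[:, l:]
    return out


def reconstruct_envelope(model: DecoderModel, eeg: EEGEpoch) -> np.ndarray:
    """Apply the trained decoder to a preprocessed (100 Hz) test epoch."""
    if tuple(eeg.channels) != tuple(model.channels):
        raise StructuralError("test epoch channels do not match the decoder")
    lag_samp = np.round(model.lags_ms * eeg.fs / 1000.0).astype(int)
    Z = (eeg.data - model.channel_means[:, None]) / model.channel_stds[:, None]
    pred = _predict_standardized(Z, model.weights, lag_samp)
    return pred * model.env_std + model.env_mean


def score_reconstruction(estimate: np.ndarray, true_envelope,
                         iteration_length: float = 3.5, fs: float = 100.0,
                         trial_index: int = 0, presentation: int = 1
                         ) -> list[ReconstructionScore]:
    """Pearson r per 3.5 s iteration window (the headline analysis uses iteration 1)."""
    true = np.asarray(getattr(true_envelope, "samples", true_envelope), float)
    est = np.asarray(estimate, float)
    n = min(len(est), len(true))
    est, true = est[:n], true[:n]
    n_iter = int(round(n / (iteration_length * fs)))
    win = int(round(iteration_length * fs))
    scores = []
    for it in range(n_iter):
        a, b = it * win, min((it + 1) * win, n)
        r = pearson_r(est[a:b], true[a:b])
        if np.isnan(r):
            warnings.warn(f"constant segment in iteration {it + 1}; r undefined")
        scores.append(ReconstructionScore(trial_index=trial_index,
                                          presentation=presentation,
                                          iteration=it + 1, r=r))
    return scores
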