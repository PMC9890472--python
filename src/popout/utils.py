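"""Shared numerical helpers: seeding, FIR band-pass filtering, resampling."""

from __future__ import annotations

import hashlib
from functools import lru_cache

import numpy as np
from scipy import signal


def rng_for(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator on an independent named substream of ``seed``.

    The master seed is combined with the (stringified) names through SHA-256,
    so each (seed, names) pair maps to a stable, platform-independent stream
    and changing the draws of one stage never perturbs another stage's.
    """
    key = "/".join(str(n) for n in names)
    digest = hashlib.sha256(f"{seed}:{key}".encode()).digest()
    entropy = int.from_bytes(digest[:16], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy))


@lru_cache(maxsize=32)
def fir_bandpass(lo_hz: float, hi_hz: float, fs: float,
                 transition_hz: float = 1.0) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass kernel with ~``transition_hz`` transition width."""
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length -> exactly linear phase
    return signal.firwin(numtaps, [lo_hz, hi_hz], pass_zero=False, fs=fs)


@lru_cache(maxsize=32)
def _squared_kernel(key: tuple) -> np.ndarray:
    h = np.asarray(key)
    return np.convolve(h, h)


def filt_twopass_fir(x: np.ndarray, h: np.ndarray, axis: int = -1) -> np.ndarray:
    """Two-pass (forward-backward) zero-phase FIR filtering with reflection padding.

    Equivalent to filtfilt with the kernel ``h`` but computed with FFT
    convolution, which is what makes long speech/EEG epochs affordable.
    """
    return _fir_passes(x, h, axis, n_passes=2)


def filt_onepass_fir(x: np.ndarray, h: np.ndarray, axis: int = -1) -> np.ndarray:
    """One-pass zero-phase FIR filtering (symmetric kernel, delay-compensated)."""
    return _fir_passes(x, h, axis, n_passes=1)


def _fir_passes(x: np.ndarray, h: np.ndarray, axis: int, n_passes: int) -> np.ndarray:
    x = np.asarray(x, float)
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    pad = min(len(h), n - 1)
    if pad > 0:
        left = 2 * x[..., :1] - x[..., pad:0:-1]
        right = 2 * x[..., -1:] - x[..., -2:-pad - 2:-1]
        xp = np.concatenate([left, x, right], axis=-1)
    else:
        xp = x
    if n_passes == 2:
        # forward-backward with a symmetric kernel equals one pass with h*h
        h = _squared_kernel(tuple(h))
        n_passes = 1
    for _ in range(n_passes):
        xp = signal.oaconvolve(xp, np.broadcast_to(h, xp.shape[:-1] + h.shape),
                               mode="same", axes=-1)
    y = xp[..., pad:pad + n] if pad > 0 else xp
    return np.moveaxis(y, -1, axis)


def resample_to(x: np.ndarray, fs_in: float, fs_out: float, axis: int = -1) -> np.ndarray:
    """Polyphase anti-aliased resampling between two rational rates."""
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    if frac.numerator == frac.denominator:
        return np.asarray(x, float)
    return signal.resample_poly(x, frac.numerator, frac.denominator, axis=axis)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two 1-D sequences; NaN for constant inputs."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))
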