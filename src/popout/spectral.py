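"""Time-frequency power, band-averaged log power, and induced oscillatory profiles.

Power is estimated with a sliding 1 s Hanning taper at 1 Hz resolution
(1-30 Hz) every 100 ms, scaled so that a unit-amplitude sinusoid at a bin
center yields power 1 (amplitude-squared units).  Band power averages the
window [0.5, 3.0] s (first sentence iteration, onset/offset trimmed) before
the log10 transform.  Induced (non-phase-locked) profiles use the intertrial
variance method: band-pass, subtract the cell-evoked mean, square, log10,
trial-average, 500 ms moving-average smooth, and downsample to 10 Hz, with
no baseline scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import BoundaryError, ConfigurationError
from .preprocessing import EEGEpoch
from .utils import fir_bandpass, filt_onepass_fir

FREQS = np.arange(1.0, 31.0)          # 1..30 Hz, 1 Hz increments
TAPER_S = 1.0
STEP_S = 0.1
BANDS = {"delta": (1.0, 3.0), "theta": (4.0, 9.0),
         "alpha": (10.0, 15.0), "beta": (16.0, 30.0)}
ANALYSIS_WINDOW = (0.5, 3.0)          # s, first iteration minus onset/offset
INDUCED_FS = 10.0
LOG_FLOOR = 1e-20


@dataclass
class TFR:
    """Channel x frequency x time power array."""
    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    taper: str = "hanning-1s"

    def __post_init__(self) -> None:
        if np.any(self.power < 0) or not np.all(np.isfinite(self.power)):
            raise ConfigurationError("power must be finite and nonnegative")


def tf_decompose(epoch: EEGEpoch, freqs: np.ndarray = FREQS,
                 taper_s: float = TAPER_S, step_s: float = STEP_S,
                 tmin: float | None = None, tmax: float | None = None) -> TFR:
    """Short-time Hanning-taper power at each frequency bin and 100 ms step."""
    fs = epoch.fs
    win = int(round(taper_s * fs))
    step = int(round(step_s * fs))
    half = taper_s / 2
    t_lo = epoch.t0 + half if tmin is None else tmin
    t_hi = epoch.t0 + epoch.n_samples / fs - half if tmax is None else tmax
    centers = np.arange(np.ceil(t_lo / step_s) * step_s, t_hi + 1e-9, step_s)
    if len(centers) == 0:
        raise BoundaryError("epoch too short for one taper window")
    taper = np.hanning(win)
    scale = 2.0 / taper.sum()
    starts = np.round((centers - half - epoch.t0) * fs).astype(int)
    if starts[0] < 0 or starts[-1] + win > epoch.n_samples:
        raise BoundaryError("requested time bins exceed the epoch (need half a "
                            "taper of padding each side)")
    idx = starts[:, None] + np.arange(win)[None, :]
    segs = epoch.data[:, idx]                          # (C, n_t, win)
    # tapered DFT evaluated only at the requested bins (1 Hz spacing for a
    # 1 s window makes these exact FFT bins)
    tt = np.arange(win) / fs
    W = taper[None, :] * np.exp(-2j * np.pi * np.asarray(freqs)[:, None] * tt)
    spec = segs @ W.T                                  # (C, n_t, F)
    power = np.abs(spec * scale) ** 2
    return TFR(power=np.transpose(power, (0, 2, 1)), freqs=np.asarray(freqs),
               times=centers, fs=fs)


def band_average(tfr: TFR, band: tuple[float, float],
                 window: tuple[float, float] = ANALYSIS_WINDOW,
                 channels=None) -> pd.DataFrame:
    """Mean power over a band and time window, log10-transformed, per channel."""
    fsel = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    tsel = (tfr.times >= window[0] - 1e-9) & (tfr.times <= window[1] + 1e-9)
    if not fsel.any() or not tsel.any():
        raise ConfigurationError("empty frequency band or time window")
    mean = tfr.power[:, fsel][:, :, tsel].mean(axis=(1, 2))
    out = pd.DataFrame({
        "channel": list(channels) if channels is not None
        else list(range(tfr.power.shape[0])),
        "log10_power": np.log10(np.maximum(mean, LOG_FLOOR)),
    })
    out.attrs["band"] = band
    out.attrs["window"] = window
    return out


@dataclass
class InducedProfile:
    """Trial-averaged log10 induced power (channel x time) at 10 Hz resolution."""
    data: np.ndarray
    times: np.ndarray
    band: tuple[float, float]
    n_trials: int


def induced_profile(epochs: list[EEGEpoch], band: tuple[float, float],
                    smooth_s: float = 0.5, out_fs: float = INDUCED_FS
                    ) -> InducedProfile:
    """Induced (non-phase-locked) band power profile for one condition cell.

    The evoked waveform (cell mean) is subtracted per trial before squaring,
    so any trial-constant component cancels; no prestimulus baseline scaling
    is applied.
    """
    if len(epochs) < 2:
        raise ConfigurationError(
            "induced power needs >= 2 epochs per cell (evoked subtraction is "
            "degenerate for a singleton)")
    fs = epochs[0].fs
    stack = np.stack([e.data for e in epochs])         # (n, C, T)
    h = fir_bandpass(band[0], band[1], fs, transition_hz=max(1.0, band[0] / 3))
    stack = filt_onepass_fir(stack, h, axis=2)         # 1-pass zero-phase FIR
    stack -= stack.mean(axis=0, keepdims=True)         # remove evoked response
    logpow = np.log10(stack ** 2 + LOG_FLOOR).mean(axis=0)   # (C, T)
    w = int(round(smooth_s * fs))
    kernel = np.ones(w) / w
    sm = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"),
                             1, logpow)
    dec = int(round(fs / out_fs))
    sm = sm[:, ::dec]
    times = epochs[0].times[::dec]
    return InducedProfile(data=sm, times=times, band=band, n_trials=len(epochs))
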