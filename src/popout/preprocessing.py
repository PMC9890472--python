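"""Deterministic EEG conditioning: epoching, filtering, interpolation, referencing.

All operations are linear and preserve channel order and count, so they can
be composed freely; `prepare_for_decoding` chains the decoder-specific steps
(common-average reference, 2-8 Hz two-pass FIR, resampling to 100 Hz, and
trimming to the stimulus span).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .exceptions import BoundaryError, ConfigurationError, StructuralError
from .layout import ChannelLayout
from .utils import fir_bandpass, filt_twopass_fir, resample_to

HP_HZ = 1.0
LP_HZ = 125.0
NOTCH_HZ = (50.0, 100.0)
DECODE_BAND = (2.0, 8.0)
DECODE_FS = 100.0


@dataclass
class EEGEpoch:
    """Channel x sample EEG segment with its time axis relative to stimulus onset."""
    data: np.ndarray
    fs: float
    t0: float                      # time of first sample, s
    channels: tuple[str, ...]
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.shape[0] != len(self.channels):
            raise StructuralError("data rows must match channel names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


def epoch_eeg(continuous: np.ndarray, fs: float, onsets, channels,
              window: tuple[float, float] = (-5.0, 15.0),
              infos: list[dict] | None = None) -> list[EEGEpoch]:
    """Cut per-trial epochs out of a continuous recording and demean them."""
    continuous = np.asarray(continuous, float)
    n_total = continuous.shape[1]
    epochs = []
    n_samp = int(round((window[1] - window[0]) * fs))
    for k, onset in enumerate(onsets):
        i0 = int(round((onset + window[0]) * fs))
        if i0 < 0 or i0 + n_samp > n_total:
            raise BoundaryError(
                f"trial {k}: window {window} around onset {onset:.2f} s falls "
                "outside the recording")
        seg = continuous[:, i0:i0 + n_samp].copy()
        seg -= seg.mean(axis=1, keepdims=True)
        epochs.append(EEGEpoch(data=seg, fs=fs, t0=window[0],
                               channels=tuple(channels),
                               info=dict(infos[k]) if infos else {"trial": k}))
    return epochs


def _dft_notch(data: np.ndarray, fs: float, freqs) -> np.ndarray:
    """Remove line components by least-squares projection onto sin/cos pairs."""
    n = data.shape[1]
    t = np.arange(n) / fs
    basis = []
    for f in freqs:
        basis += [np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)]
    B = np.stack(basis, axis=1)                      # (n, 2*len(freqs))
    coef, *_ = np.linalg.lstsq(B, data.T, rcond=None)
    return data - (B @ coef).T


def dft_notch(epoch: EEGEpoch, freqs=NOTCH_HZ) -> EEGEpoch:
    """Discrete-Fourier-transform notch: project out the line-frequency
    sin/cos components over the whole epoch (exact for stationary tones)."""
    return replace(epoch, data=_dft_notch(epoch.data, epoch.fs, freqs))


def filter_eeg(epoch: EEGEpoch, hp_hz: float = HP_HZ, lp_hz: float = LP_HZ,
               notch_hz=NOTCH_HZ) -> EEGEpoch:
    """Two-pass 4th-order Butterworth band-pass plus DFT notch at line frequencies."""
    if epoch.fs <= 2 * lp_hz:
        raise ConfigurationError(
            f"sampling rate {epoch.fs} Hz too low for a {lp_hz} Hz low-pass")
    sos_hp = signal.butter(4, hp_hz, btype="highpass", fs=epoch.fs, output="sos")
    sos_lp = signal.butter(4, lp_hz, btype="lowpass", fs=epoch.fs, output="sos")
    out = signal.sosfiltfilt(sos_hp, epoch.data, axis=1)
    out = signal.sosfiltfilt(sos_lp, out, axis=1)
    if notch_hz:
        out = _dft_notch(out, epoch.fs, notch_hz)
    return replace(epoch, data=out)


def interpolate_bad_channels(epoch: EEGEpoch, bad_channels,
                             layout: ChannelLayout,
                             radius: float = 0.040) -> EEGEpoch:
    """Replace bad channels by the inverse-distance-weighted mean of good neighbors."""
    bad = list(bad_channels)
    if not bad:
        return epoch
    d = layout.distance_matrix()
    names = list(epoch.channels)
    bad_idx = [names.index(b) for b in bad]
    good = np.ones(len(names), bool)
    good[bad_idx] = False
    out = epoch.data.copy()
    for bi in bad_idx:
        nbr = np.where((d[bi] < radius) & (d[bi] > 0) & good)[0]
        if len(nbr) < 2:
            raise StructuralError(
                f"channel {names[bi]!r} has fewer than 2 good neighbors within "
                f"{radius * 1000:.0f} mm; cannot interpolate")
        w = 1.0 / d[bi, nbr]
        out[bi] = (w @ epoch.data[nbr]) / w.sum()
    return replace(epoch, data=out)


def rereference(epoch: EEGEpoch, scheme: str = "common_average",
                mastoids=("TP9", "TP10")) -> EEGEpoch:
    """Subtract the common average or the mean of the two mastoid channels."""
    if scheme == "common_average":
        ref = epoch.data.mean(axis=0, keepdims=True)
    elif scheme == "linked_mastoids":
        try:
            idx = [epoch.channels.index(m) for m in mastoids]
        except ValueError as e:
            raise StructuralError(f"mastoid channel missing: {e}") from None
        ref = epoch.data[idx].mean(axis=0, keepdims=True)
    else:
        raise ConfigurationError(f"unknown reference scheme {scheme!r}")
    return replace(epoch, data=epoch.data - ref)


def prepare_for_decoding(epoch: EEGEpoch, stimulus_duration: float,
                         band: tuple[float, float] = DECODE_BAND,
                         fs_out: float = DECODE_FS) -> EEGEpoch:
    """Common average -> 2-8 Hz two-pass FIR -> 100 Hz -> trim to the stimulus span."""
    if epoch.t0 > 0 or epoch.t0 + epoch.n_samples / epoch.fs < stimulus_duration:
        raise BoundaryError(
            f"epoch [{epoch.t0:.2f}, {epoch.t0 + epoch.n_samples / epoch.fs:.2f}] s "
            f"does not cover the stimulus [0, {stimulus_duration:.2f}] s")
    ref = rereference(epoch, "common_average")
    h = fir_bandpass(band[0], band[1], epoch.fs)
    filt = filt_twopass_fir(ref.data, h, axis=1)
    res = resample_to(filt, epoch.fs, fs_out, axis=1)
    i0 = int(round((0.0 - epoch.t0) * fs_out))
    n_stim = int(round(stimulus_duration * fs_out))
    if i0 + n_stim > res.shape[1]:
        n_stim = res.shape[1] - i0
    return EEGEpoch(data=res[:, i0:i0 + n_stim], fs=fs_out, t0=0.0,
                    channels=epoch.channels, info=dict(epoch.info))
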