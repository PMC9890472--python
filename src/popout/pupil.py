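"""Pupil preprocessing: blink handling, filtering, eye averaging, epoching.

Blinks are interruptions (NaN runs) of each eye's signal up to 5 s; longer
runs are dropouts that are never interpolated.  Each blink is bridged by the
line joining the medians of the flanking 100 ms windows.  The corrected
signal is low-passed below 6 Hz (two-pass 4th-order Butterworth), the eyes
averaged, and [-1, 11] s epochs around the two presentation onsets are
baseline-corrected with the mean of the 1st presentation's [-1, 0] s window.
Pupil size is kept in arbitrary units throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import BoundaryError
from .synthetic import PupilTrace

MAX_BLINK_S = 5.0
FLANK_S = 0.1
LOWPASS_HZ = 6.0
EPOCH_WINDOW = (-1.0, 11.0)
BASELINE_WINDOW = (-1.0, 0.0)


@dataclass
class BlinkAnnotation:
    onset: float        # seconds (first missing sample)
    offset: float       # seconds (first valid sample after the gap)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PupilEpoch:
    samples: np.ndarray
    fs: float
    t0: float = EPOCH_WINDOW[0]
    presentation: int = 1
    trial_index: int | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


def detect_blinks(eye: np.ndarray, fs: float,
                  max_blink_s: float = MAX_BLINK_S
                  ) -> tuple[list[BlinkAnnotation], list[BlinkAnnotation]]:
    """Maximal NaN runs <= ``max_blink_s`` become blinks; longer ones dropouts."""
    missing = ~np.isfinite(np.asarray(eye, float))
    if not missing.any():
        return [], []
    padded = np.concatenate([[False], missing, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.where(edges == 1)[0]
    ends = np.where(edges == -1)[0]
    blinks, dropouts = [], []
    for s, e in zip(starts, ends):
        ann = BlinkAnnotation(onset=s / fs, offset=e / fs)
        (blinks if ann.duration <= max_blink_s else dropouts).append(ann)
    return blinks, dropouts


def _flank_median(eye: np.ndarray, fs: float, lo: int, hi: int,
                  direction: int) -> float:
    """Median of the valid samples in [lo, hi); widen outward if all missing."""
    n = len(eye)
    width = hi - lo
    while 0 <= lo and hi <= n:
        seg = eye[max(lo, 0):hi]
        valid = seg[np.isfinite(seg)]
        if len(valid):
            return float(np.median(valid))
        warnings.warn("no valid samples in blink flank window; widening search")
        lo += direction * width
        hi += direction * width
    return float("nan")


def interpolate_blinks(eye: np.ndarray, fs: float,
                       blinks: list[BlinkAnnotation],
                       flank_s: float = FLANK_S) -> np.ndarray:
    """Bridge each blink with the line joining the flanking-window medians.

    The line is anchored at the flank-window centers (where the median of a
    smoothly varying signal lives), so linear trends are restored exactly
    across the gap.
    """
    out = np.asarray(eye, float).copy()
    w = int(round(flank_s * fs))
    for ann in blinks:
        i0 = int(round(ann.onset * fs))
        i1 = int(round(ann.offset * fs))
        m_pre = _flank_median(out, fs, i0 - w, i0, direction=-1)
        m_post = _flank_median(out, fs, i1, i1 + w, direction=+1)
        if np.isnan(m_pre):
            m_pre = m_post
        if np.isnan(m_post):
            m_post = m_pre
        a = i0 - (w + 1) / 2.0      # pre-window center (sample index)
        b = i1 + (w - 1) / 2.0      # post-window center
        idx = np.arange(i0, i1)
        out[i0:i1] = m_pre + (m_post - m_pre) * (idx - a) / (b - a)
    return out


def filter_and_average(trace: PupilTrace,
                       lowpass_hz: float = LOWPASS_HZ) -> np.ndarray:
    """Per-eye 6 Hz two-pass Butterworth low-pass, then the mean of the eyes."""
    sos = signal.butter(4, lowpass_hz, btype="low", fs=trace.fs, output="sos")
    eyes = []
    for eye in (trace.left, trace.right):
        if eye is None or not np.isfinite(eye).any():
            warnings.warn("one eye absent; using the other only")
            continue
        if not np.isfinite(eye).all():
            raise BoundaryError("eyes must be gap-free before filtering "
                                "(run interpolate_blinks first)")
        eyes.append(signal.sosfiltfilt(sos, eye))
    if not eyes:
        raise BoundaryError("no usable eye signal")
    return np.mean(eyes, axis=0)


def preprocess_trace(trace: PupilTrace) -> tuple[np.ndarray, list[BlinkAnnotation]]:
    """Blink-interpolate both eyes, low-pass, and average; returns dropouts too."""
    eyes = []
    all_dropouts = []
    for eye in (trace.left, trace.right):
        blinks, dropouts = detect_blinks(eye, trace.fs)
        all_dropouts.extend(dropouts)
        fixed = interpolate_blinks(eye, trace.fs, blinks)
        eyes.append(fixed)
    clean = PupilTrace(left=eyes[0], right=eyes[1], fs=trace.fs,
                       t0=trace.t0, onset_1=trace.onset_1,
                       onset_2=trace.onset_2, trial_index=trace.trial_index)
    if all_dropouts:
        # dropouts (> 5 s) exclude the trial from analysis; caller decides
        return None, all_dropouts
    return filter_and_average(clean), all_dropouts


def epoch_and_baseline(averaged: np.ndarray, fs: float, onset_1: float,
                       onset_2: float,
                       window: tuple[float, float] = EPOCH_WINDOW,
                       baseline: tuple[float, float] = BASELINE_WINDOW,
                       trial_index: int | None = None
                       ) -> tuple[PupilEpoch, PupilEpoch]:
    """Two [-1, 11] s epochs, both corrected by presentation 1's [-1, 0] s mean."""
    n = len(averaged)
    epochs = []
    for pres, onset in ((1, onset_1), (2, onset_2)):
        i0 = int(round((onset + window[0]) * fs))
        i1 = i0 + int(round((window[1] - window[0]) * fs))
        if i0 < 0 or i1 > n:
            raise BoundaryError(
                f"presentation {pres} window {window} not covered by the trace")
        epochs.append(averaged[i0:i1].copy())
    b0 = int(round((onset_1 + baseline[0]) * fs))
    b1 = int(round((onset_1 + baseline[1]) * fs))
    base = float(np.mean(averaged[b0:b1]))
    return tuple(PupilEpoch(samples=e - base, fs=fs, t0=window[0],
                            presentation=p, trial_index=trial_index)
                 for p, e in zip((1, 2), epochs))
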