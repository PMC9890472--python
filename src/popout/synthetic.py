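"""Synthetic study generator: stimuli, design, forward-model EEG, pupil, ratings.

This module emulates, at desk scale, a pop-out experiment in which listeners
hear degraded "sentences" twice, with written information (correct P+,
incorrect P-, or none P0) shown between the two presentations:

* a pool of parametric sentence pairs (formant tracks + syllabic envelope),
  partitioned into 5 lists;
* clear, sine-wave (SWS) and 7-band noise-vocoded (NVS) renderings;
* a 6-block x 16-trial per-participant design (2 stimulus types x 3 prior
  conditions, 16 trials per cell) with Latin-square list rotation;
* 64-channel, 500 Hz EEG built from a known envelope-tracking kernel plus
  condition-gated theta/alpha oscillations, an onset transient, and 1/f noise;
* two-eye 300 Hz pupil traces with blink dropouts; and
* ordinal 1-4 clarity ratings from a latent threshold model.

Every injected effect is parameterized by :class:`ConditionEffects`, so the
downstream analyses have a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .exceptions import (AlignmentError, ConfigurationError, StructuralError,
                         SynthesisError)
from .layout import ChannelLayout
from .utils import resample_to, rng_for

LISTS = ("A", "B", "C", "D", "E")
PRIORS = ("P+", "P-", "P0")
STIMULUS_TYPES = ("SWS", "NVS")
SENTENCE_DURATION = 3.5     # seconds per iteration
N_ITERATIONS = 3
DEFAULT_AUDIO_FS = 22050.0
EEG_FS = 500.0
PUPIL_FS = 300.0
EPOCH_SPAN = (-5.0, 15.0)   # seconds around stimulus onset
TRF_LAGS_MS = np.arange(0, 301, 10)  # 0..300 ms in 10 ms steps (31 lags)

# Formant centers (Hz) loosely covering a male vowel space; trajectories
# wander around these.
_FORMANT_CENTERS = (500.0, 1500.0, 2500.0)
_F0 = 110.0  # glottal source fundamental, Hz


# --------------------------------------------------------------------------
# sentence specifications
# --------------------------------------------------------------------------

@dataclass
class SentenceSpec:
    """Parametric description of one synthetic sentence (a single 3.5 s iteration)."""
    sentence_id: int
    pair_id: int
    list_id: str
    formant_freqs: np.ndarray   # (n_formants, n_ctrl) Hz
    formant_amps: np.ndarray    # (n_formants, n_ctrl) linear amplitude
    syllable_envelope: np.ndarray  # (n_ctrl,) nonnegative
    ctrl_rate: float = 100.0    # control-track sampling rate, Hz
    duration: float = SENTENCE_DURATION

    def __post_init__(self) -> None:
        if np.any(self.formant_freqs <= 90.0) or np.any(self.formant_freqs >= 8000.0):
            raise StructuralError("formant frequencies must stay within (90, 8000) Hz")
        if np.any(self.syllable_envelope < 0):
            raise StructuralError("syllable envelope must be nonnegative")


@dataclass
class AudioStimulus:
    """A sampled waveform with its variant tag and sentence identity."""
    samples: np.ndarray
    fs: float
    variant: str                # clear | SWS | NVS
    sentence_id: int
    n_iterations: int = N_ITERATIONS

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


def _smooth_track(rng: np.random.Generator, n: int, scale: float,
                  smooth_pts: int) -> np.ndarray:
    """Low-pass-filtered Gaussian walk used for formant/amplitude trajectories."""
    x = rng.standard_normal(n)
    w = np.hanning(smooth_pts)
    x = np.convolve(x, w / w.sum(), mode="same")
    sd = x.std()
    return x / sd * scale if sd > 0 else x


def _syllable_envelope(rng: np.random.Generator, n: int, ctrl_rate: float) -> np.ndarray:
    """Sum of smooth syllabic bumps with dominant energy in the 2-8 Hz range."""
    t = np.arange(n) / ctrl_rate
    env = np.zeros(n)
    pos = rng.uniform(0.05, 0.15)
    while pos < t[-1]:
        width = rng.uniform(0.05, 0.11)     # bump sd: ~3-5 Hz syllable rate
        amp = rng.uniform(0.6, 1.0)
        env += amp * np.exp(-0.5 * ((t - pos) / width) ** 2)
        pos += rng.uniform(0.17, 0.33)      # inter-syllable interval
    return env


def build_stimulus_pool(n_pairs: int, seed: int) -> list[SentenceSpec]:
    """Generate ``2 * n_pairs`` sentence specs in 5 equal lists.

    Pair mates share the base trajectories up to bounded jitter (<=10 %
    formant scaling and resampled syllable timing), which emulates pairs of
    sentences with similar but not identical structure.
    """
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    if n_pairs % len(LISTS) != 0:
        raise ConfigurationError(
            f"n_pairs={n_pairs} must be divisible by {len(LISTS)} so the pool "
            "partitions into 5 equal lists")
    ctrl_rate = 100.0
    n_ctrl = int(SENTENCE_DURATION * ctrl_rate)
    pairs_per_list = n_pairs // len(LISTS)
    pool: list[SentenceSpec] = []
    for pair in range(n_pairs):
        rng = rng_for(seed, "pool", pair)
        base_f = np.stack([
            c * np.exp(_smooth_track(rng, n_ctrl, 0.12, 60))
            for c in _FORMANT_CENTERS])
        base_a = np.stack([
            np.exp(_smooth_track(rng, n_ctrl, 0.3, 60)) * (1.0 / (j + 1))
            for j in range(len(_FORMANT_CENTERS))])
        base_env = _syllable_envelope(rng, n_ctrl, ctrl_rate)
        list_id = LISTS[pair // pairs_per_list]
        for member in range(2):
            if member == 0:
                f, a, env = base_f, base_a, base_env
            else:
                jitter = np.exp(rng.uniform(-0.1, 0.1, size=(base_f.shape[0], 1)))
                f = np.clip(base_f * jitter, 100.0, 7800.0)
                a = base_a * np.exp(_smooth_track(rng, n_ctrl, 0.1, 60))
                # resampled syllable timing: small smooth time warp
                warp = np.cumsum(1 + _smooth_track(rng, n_ctrl, 0.08, 80))
                warp = (warp - warp[0]) / (warp[-1] - warp[0]) * (n_ctrl - 1)
                env = np.interp(warp, np.arange(n_ctrl), base_env)
            pool.append(SentenceSpec(
                sentence_id=2 * pair + member, pair_id=pair, list_id=list_id,
                formant_freqs=f, formant_amps=a, syllable_envelope=env,
                ctrl_rate=ctrl_rate))
    return pool


# --------------------------------------------------------------------------
# audio synthesis
# --------------------------------------------------------------------------

def _upsample_ctrl(track: np.ndarray, ctrl_rate: float, fs: float, n_out: int) -> np.ndarray:
    t_ctrl = np.arange(track.shape[-1]) / ctrl_rate
    t_out = np.arange(n_out) / fs
    return np.interp(t_out, t_ctrl, track)


def synthesize_clear(spec: SentenceSpec, fs: float = DEFAULT_AUDIO_FS) -> AudioStimulus:
    """Harmonic source shaped by the spec's formant resonances.

    A glottal pulse train (harmonics of ``_F0``) is weighted per harmonic by
    Gaussian resonance profiles that follow the formant tracks, then
    amplitude-modulated by the syllable envelope.  One 3.5 s iteration is
    synthesized and concatenated 3 times.
    """
    if fs < 16000:
        raise ConfigurationError("audio sampling rate must be >= 16 kHz")
    if np.any(spec.formant_freqs >= fs / 2):
        raise SynthesisError("formant track exceeds Nyquist frequency")
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    freqs = np.stack([_upsample_ctrl(f, spec.ctrl_rate, fs, n)
                      for f in spec.formant_freqs])
    amps = np.stack([_upsample_ctrl(a, spec.ctrl_rate, fs, n)
                     for a in spec.formant_amps])
    env = _upsample_ctrl(spec.syllable_envelope, spec.ctrl_rate, fs, n)
    x = np.zeros(n)
    n_harm = int((fs / 2 - 200.0) // _F0)
    bw = 120.0  # resonance half-width, Hz
    for k in range(1, n_harm + 1):
        fk = k * _F0
        weight = (amps * np.exp(-0.5 * ((fk - freqs) / bw) ** 2)).sum(axis=0)
        if np.max(weight) < 1e-4:
            continue
        x += weight * np.cos(2 * np.pi * fk * t + 0.7 * k)
    x *= env
    x = np.tile(x, N_ITERATIONS)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak * 0.5
    return AudioStimulus(samples=x, fs=fs, variant="clear",
                         sentence_id=spec.sentence_id)


def sine_wave_synthesize(spec: SentenceSpec, fs: float = DEFAULT_AUDIO_FS) -> AudioStimulus:
    """Sine-wave speech: one sinusoid per formant, following the known tracks.

    The sinusoid amplitudes follow the formant amplitude tracks driven by a
    smoothed, compressively flattened version of the syllable envelope,
    emulating the sluggish frame-wise amplitude estimation of formant-based
    resynthesis; this is what degrades the fine temporal-envelope structure
    of the source while preserving its spectral trajectories.
    """
    if spec.formant_freqs.shape[0] < 2:
        raise ConfigurationError("sine-wave synthesis needs >= 2 formant tracks")
    if fs < 16000:
        raise ConfigurationError("audio sampling rate must be >= 16 kHz")
    if np.any(spec.formant_freqs >= fs / 2):
        raise SynthesisError("formant track exceeds Nyquist frequency")
    n = int(round(spec.duration * fs))
    env = _upsample_ctrl(spec.syllable_envelope, spec.ctrl_rate, fs, n)
    # ~150 ms tracker smoothing (sinusoid amplitudes cannot follow fast
    # syllabic onsets) plus a voicing floor: attenuates the 4-8 Hz
    # modulation content while keeping the slow trend
    w = int(0.15 * fs)
    env = np.convolve(env, np.ones(w) / w, mode="same")
    env = 0.3 * env.max() + 0.7 * env if env.max() > 0 else env
    x = np.zeros(n)
    for f_track, a_track in zip(spec.formant_freqs, spec.formant_amps):
        f = _upsample_ctrl(f_track, spec.ctrl_rate, fs, n)
        a = _upsample_ctrl(a_track, spec.ctrl_rate, fs, n)
        phase = 2 * np.pi * np.cumsum(f) / fs
        x += a * np.cos(phase)
    x *= env
    x = np.tile(x, N_ITERATIONS)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak * 0.5
    return AudioStimulus(samples=x, fs=fs, variant="SWS",
                         sentence_id=spec.sentence_id)


def noise_vocode(clear: AudioStimulus, n_bands: int = 7, seed: int = 0,
                 band_range: tuple[float, float] = (100.0, 8000.0),
                 env_cutoff_hz: float = 30.0) -> AudioStimulus:
    """Noise-vocoded speech: band envelopes of ``clear`` modulate band noise.

    The signal is split into ``n_bands`` logarithmically spaced bands
    (4th-order Butterworth); each band's envelope (half-wave rectification +
    ``env_cutoff_hz`` low-pass) multiplies white noise limited to the same
    band, the modulated bands are RMS-matched to the source band and summed.
    """
    if clear.variant != "clear":
        raise ConfigurationError("noise_vocode expects a clear-speech stimulus")
    if n_bands < 2:
        raise ConfigurationError("n_bands must be >= 2")
    x = np.asarray(clear.samples, float)
    fs = clear.fs
    hi = min(band_range[1], 0.45 * fs)
    edges = np.geomspace(band_range[0], hi, n_bands + 1)
    rng = rng_for(seed, "vocoder", clear.sentence_id)
    noise = rng.standard_normal(len(x))
    smooth = signal.butter(2, env_cutoff_hz, btype="low", fs=fs, output="sos")
    out = np.zeros_like(x)
    for b in range(n_bands):
        sos = signal.butter(4, edges[b:b + 2], btype="bandpass", fs=fs, output="sos")
        band = signal.sosfilt(sos, x)
        env = signal.sosfilt(smooth, np.maximum(band, 0.0))
        env = np.maximum(env, 0.0)
        carrier = signal.sosfilt(sos, noise)
        mod = env * carrier
        rms_src = np.sqrt(np.mean(band ** 2))
        rms_mod = np.sqrt(np.mean(mod ** 2))
        if rms_mod > 0 and rms_src > 0:
            mod *= rms_src / rms_mod
        out += mod
    return AudioStimulus(samples=out, fs=fs, variant="NVS",
                         sentence_id=clear.sentence_id,
                         n_iterations=clear.n_iterations)


def equalize_amplitude(stimuli: list[AudioStimulus],
                       target_rms: float = 0.05) -> list[AudioStimulus]:
    """Rescale every stimulus to a common RMS."""
    out = []
    for s in stimuli:
        rms = s.rms()
        if rms == 0:
            raise ConfigurationError(
                f"stimulus {s.sentence_id} ({s.variant}) is silent; gain undefined")
        out.append(replace(s, samples=s.samples * (target_rms / rms)))
    return out


# --------------------------------------------------------------------------
# experimental design
# --------------------------------------------------------------------------

@dataclass
class TrialRecord:
    trial_index: int            # 1..96
    block: int                  # 1..6
    stimulus_type: str          # SWS | NVS
    prior: str                  # P+ | P- | P0
    sentence_id: int
    displayed_sentence_id: int | None = None
    clarity_1: int | None = None
    clarity_2: int | None = None


#: the four informative list roles; the fifth list is split across P0 cells
_INFORMATIVE_ROLES = (("NVS", "P-"), ("NVS", "P+"), ("SWS", "P-"), ("SWS", "P+"))


def assign_conditions(pool: list[SentenceSpec], participant_index: int,
                      seed: int) -> list[TrialRecord]:
    """Build one participant's 96-trial design with Latin-square list rotation.

    Lists rotate through the condition roles with ``participant_index`` so
    that across any 5 consecutive participants every list serves every role
    exactly once.  Which pair member is heard, and the trial order within the
    6 blocks, are seeded draws shared across participants only through
    ``seed``.
    """
    by_list: dict[str, dict[int, list[SentenceSpec]]] = {l: {} for l in LISTS}
    for spec in pool:
        by_list.setdefault(spec.list_id, {}).setdefault(spec.pair_id, []).append(spec)
    n_pairs_per_list = {l: len(p) for l, p in by_list.items()}
    if set(by_list) != set(LISTS) or len(set(n_pairs_per_list.values())) != 1:
        raise StructuralError("pool must contain 5 complete lists of equal size")
    if any(len(members) != 2 for pairs in by_list.values()
           for members in pairs.values()):
        raise StructuralError("every pair_id must have exactly 2 sentences")
    pairs_per_list = next(iter(n_pairs_per_list.values()))
    trials_per_cell = pairs_per_list  # 16 at full scale

    rot = participant_index % len(LISTS)
    rotated = LISTS[rot:] + LISTS[:rot]
    role_of_list = dict(zip(rotated, _INFORMATIVE_ROLES + (("P0", "P0"),)))

    rng = rng_for(seed, "design", participant_index)
    records: list[TrialRecord] = []
    for list_id, role in role_of_list.items():
        pairs = by_list[list_id]
        pair_ids = sorted(pairs)
        if role == ("P0", "P0"):
            # split the list across SWS-P0 and NVS-P0: one member each
            for pid in pair_ids:
                a, b = pairs[pid]
                flip = rng.integers(2)
                sws, nvs = (a, b) if flip == 0 else (b, a)
                records.append(TrialRecord(0, 0, "SWS", "P0", sws.sentence_id))
                records.append(TrialRecord(0, 0, "NVS", "P0", nvs.sentence_id))
        else:
            stim_type, prior = role
            for pid in pair_ids:
                a, b = pairs[pid]
                flip = rng.integers(2)
                heard, other = (a, b) if flip == 0 else (b, a)
                displayed = (heard.sentence_id if prior == "P+"
                             else other.sentence_id)
                records.append(TrialRecord(0, 0, stim_type, prior,
                                           heard.sentence_id,
                                           displayed_sentence_id=displayed))
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    trials_per_block = max(1, len(records) // 6)
    for i, rec in enumerate(records):
        rec.trial_index = i + 1
        rec.block = i // trials_per_block + 1
    return records


def design_to_frame(design: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in design])


# --------------------------------------------------------------------------
# condition effects and the forward model
# --------------------------------------------------------------------------

def _gain_map(value: float = 1.0) -> dict[tuple[str, int], float]:
    return {(p, pres): value for p in PRIORS for pres in (1, 2)}


@dataclass
class ConditionEffects:
    """Injectable ground-truth effects, keyed by (prior, presentation).

    All gains are multiplicative (> 0); rating shifts act on the latent
    clarity scale of the 2nd presentation.  The neutral configuration (all
    gains 1, shifts 0) makes the three prior conditions exchangeable.
    """
    tracking_gain: dict[tuple[str, int], float] = field(default_factory=_gain_map)
    theta_gain: dict[tuple[str, int], float] = field(default_factory=_gain_map)
    alpha_gain: dict[tuple[str, int], float] = field(default_factory=_gain_map)
    pupil_gain: dict[str, float] = field(
        default_factory=lambda: {p: 1.0 for p in PRIORS})
    rating_shift: dict[str, float] = field(
        default_factory=lambda: {p: 0.0 for p in PRIORS})

    def __post_init__(self) -> None:
        for m in (self.tracking_gain, self.theta_gain, self.alpha_gain,
                  self.pupil_gain):
            if any(v <= 0 for v in m.values()):
                raise ConfigurationError("all gains must be > 0")

    @classmethod
    def neutral(cls) -> "ConditionEffects":
        return cls()

    @classmethod
    def paper_like(cls) -> "ConditionEffects":
        """Effects qualitatively matching the reported pop-out findings:

        better envelope tracking and lower theta power for correct priors on
        the 2nd presentation; higher alpha power and pupil dilation whenever
        any written sentence was shown (P+ and P-).
        """
        eff = cls()
        eff.tracking_gain[("P+", 2)] = 1.5
        eff.theta_gain[("P+", 2)] = 0.67
        eff.alpha_gain[("P+", 2)] = 1.5
        eff.alpha_gain[("P-", 2)] = 1.5
        eff.pupil_gain["P+"] = 1.5
        eff.pupil_gain["P-"] = 1.5
        eff.rating_shift["P+"] = 2.0
        return eff


@dataclass
class ForwardTRF:
    """Ground-truth envelope-to-EEG kernel over channels x lags (0..300 ms)."""
    kernel: np.ndarray          # (n_channels, n_lags)
    lags_ms: np.ndarray = field(default_factory=lambda: TRF_LAGS_MS.copy())
    topography: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.kernel)):
            raise StructuralError("TRF kernel must be finite")
        norm = np.linalg.norm(self.kernel)
        if norm > 0:
            self.kernel = self.kernel / norm


def _topography(layout: ChannelLayout, peak_channel: str, width_m: float = 0.05
                ) -> np.ndarray:
    p0 = layout.positions[layout.index(peak_channel)]
    d = np.linalg.norm(layout.positions - p0, axis=1)
    return np.exp(-0.5 * (d / width_m) ** 2)


def make_forward_trf(layout: ChannelLayout) -> ForwardTRF:
    """Smooth positive-then-negative temporal kernel with fronto-central focus."""
    tau = TRF_LAGS_MS / 1000.0
    temporal = (np.exp(-0.5 * ((tau - 0.08) / 0.035) ** 2)
                - 0.8 * np.exp(-0.5 * ((tau - 0.19) / 0.05) ** 2))
    topo = _topography(layout, "FCz")
    return ForwardTRF(kernel=np.outer(topo, temporal), topography=topo)


@dataclass
class NoiseParams:
    """Amplitude settings of the simulated EEG constituents (arbitrary units).

    Defaults were chosen once so that single-trial reconstruction scores land
    in the 0.05-0.3 range typical of speech-tracking EEG studies.
    """
    tracking_scale: float = 0.03    # envelope-tracking component
    osc_scale: float = 1.0          # theta/alpha oscillations
    background_scale: float = 1.0   # 1/f noise
    evoked_amp: float = 1.0         # onset transient
    noise_multiplier: float = 1.0   # scales everything except envelope tracking


_THETA_BAND = (4.0, 9.0)
_ALPHA_BAND = (10.0, 15.0)


def _one_over_f_noise(rng: np.random.Generator, n_sources: int, n: int,
                      fs: float) -> np.ndarray:
    """1/f-power noise time courses, unit RMS each."""
    import scipy.fft as sfft

    freqs = sfft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal((n_sources, len(freqs)))
            + 1j * rng.standard_normal((n_sources, len(freqs)))) * shape
    x = sfft.irfft(spec, n=n, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


_N_NOISE_SOURCES = 16


def _background_noise(rng: np.random.Generator, layout: ChannelLayout, n: int,
                      fs: float) -> np.ndarray:
    """Spatially correlated 1/f background plus a little sensor noise.

    A small number of smooth random scalp patterns mix independent 1/f time
    courses, mimicking the volume-conducted, low-rank spatial structure of
    real EEG background activity (spatially white noise would be
    unrealistically easy for a multichannel decoder to cancel).
    """
    C = layout.n_channels
    centers = rng.integers(0, C, size=_N_NOISE_SOURCES)
    widths = rng.uniform(0.03, 0.08, size=_N_NOISE_SOURCES)
    d = np.linalg.norm(layout.positions[:, None, :]
                       - layout.positions[None, centers, :], axis=-1)
    B = np.exp(-0.5 * (d / widths[None, :]) ** 2)       # (C, K)
    B *= rng.choice([-1.0, 1.0], size=_N_NOISE_SOURCES)[None, :]
    S = _one_over_f_noise(rng, _N_NOISE_SOURCES, n, fs)
    x = B @ S
    rms = np.sqrt(np.mean(x ** 2))
    if rms > 0:
        x /= rms
    x += 0.5 * rng.standard_normal((C, n))
    return x


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + int(fs)))[int(fs):]
    sd = x.std()
    return x / sd if sd > 0 else x


def _onset_transient(t: np.ndarray) -> np.ndarray:
    """Fixed biphasic onset response over ~0.5 s (identical across trials)."""
    w = (np.exp(-0.5 * ((t - 0.1) / 0.03) ** 2)
         - 0.6 * np.exp(-0.5 * ((t - 0.25) / 0.06) ** 2))
    w[t < 0] = 0.0
    return w


def simulate_trial_eeg(envelope, trf: ForwardTRF, effects: ConditionEffects,
                       trial: TrialRecord, presentation: int,
                       layout: ChannelLayout,
                       noise_params: NoiseParams | None = None,
                       seed: int = 0,
                       epoch_span: tuple[float, float] = EPOCH_SPAN,
                       fs: float = EEG_FS):
    """Forward-model EEG epoch for one trial and presentation.

    The envelope-tracking component is the lagged kernel applied to the
    100 Hz auditory envelope (upsampled to ``fs``); theta and alpha
    oscillations are band-limited noise with fixed topographies; the onset
    transient is identical across trials; 1/f noise is the background.
    Gains are read from ``effects`` for the trial's prior and presentation.
    """
    from .preprocessing import EEGEpoch  # local import to avoid a cycle

    npar = noise_params or NoiseParams()
    env = np.asarray(envelope.samples, float)
    env_fs = envelope.fs
    dur = len(env) / env_fs
    if epoch_span[0] > 0 or epoch_span[1] < dur:
        raise AlignmentError(
            f"epoch span {epoch_span} does not cover the stimulus [0, {dur:.2f}] s")
    n = int(round((epoch_span[1] - epoch_span[0]) * fs))
    t = epoch_span[0] + np.arange(n) / fs
    C = layout.n_channels
    key = (trial.prior, presentation)

    rng = rng_for(seed, "eeg", trial.trial_index, presentation)
    data = np.zeros((C, n))

    # envelope tracking: EEG(c, t) = sum_tau k(c, tau) env(t - tau)
    g_track = effects.tracking_gain[key]
    if g_track != 0 and npar.tracking_scale != 0:
        env_z = (env - env.mean())
        sd = env_z.std()
        if sd > 0:
            env_z /= sd
        lag_step = env_fs * (TRF_LAGS_MS[1] - TRF_LAGS_MS[0]) / 1000.0
        if abs(lag_step - 1.0) > 1e-9:
            raise AlignmentError("envelope must be sampled at 100 Hz (one sample per 10 ms lag)")
        tracked = signal.fftconvolve(trf.kernel, env_z[None, :],
                                     mode="full", axes=1)[:, :len(env)]
        rms = np.sqrt(np.mean(tracked ** 2))
        if rms > 0:
            tracked /= rms
        tracked = resample_to(tracked, env_fs, fs, axis=1)
        i0 = int(round((0.0 - epoch_span[0]) * fs))
        seg = tracked[:, : min(tracked.shape[1], n - i0)]
        data[:, i0:i0 + seg.shape[1]] += npar.tracking_scale * g_track * seg

    mult = npar.noise_multiplier
    if npar.osc_scale != 0 and mult != 0:
        theta_topo = _topography(layout, "Fz")
        alpha_topo = _topography(layout, "POz")
        theta = _band_noise(rng, n, fs, _THETA_BAND)
        alpha = _band_noise(rng, n, fs, _ALPHA_BAND)
        data += (npar.osc_scale * mult * effects.theta_gain[key]
                 * np.outer(theta_topo, theta))
        data += (npar.osc_scale * mult * effects.alpha_gain[key]
                 * np.outer(alpha_topo, alpha))
    if npar.background_scale != 0 and mult != 0:
        data += npar.background_scale * mult * _background_noise(rng, layout, n, fs)
    if npar.evoked_amp != 0 and mult != 0:
        data += npar.evoked_amp * mult * np.outer(_topography(layout, "Cz"),
                                                  _onset_transient(t))

    return EEGEpoch(data=data, fs=fs, t0=epoch_span[0], channels=layout.names,
                    info={"trial_index": trial.trial_index,
                          "presentation": presentation,
                          "stimulus_type": trial.stimulus_type,
                          "prior": trial.prior,
                          "sentence_id": trial.sentence_id})


# --------------------------------------------------------------------------
# pupil and ratings
# --------------------------------------------------------------------------

@dataclass
class PupilTrace:
    """Two-eye pupil recording (arbitrary units) with NaN blink gaps."""
    left: np.ndarray
    right: np.ndarray
    fs: float = PUPIL_FS
    t0: float = 0.0
    onset_1: float = 2.0        # seconds of presentation onsets in trace time
    onset_2: float = 18.5
    trial_index: int | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.left)) / self.fs


def _dilation_response(t: np.ndarray, onset: float, amp: float) -> np.ndarray:
    """Gamma-shaped event-related dilation (peak ~2.5 s after onset)."""
    tt = np.maximum(t - onset, 0.0)
    return amp * stats.gamma.pdf(tt, a=3.0, scale=0.9) * 2.2


def simulate_pupil(trial: TrialRecord, effects: ConditionEffects, seed: int = 0,
                   fs: float = PUPIL_FS, blink_rate_hz: float = 0.25,
                   insert_blinks: bool = True) -> PupilTrace:
    """Two-eye pupil trace spanning both presentations of one trial.

    Baseline + slow drift + gamma-shaped dilation after each presentation
    onset (the 2nd scaled by the prior's ``pupil_gain``) + measurement noise;
    blinks are NaN gaps of 0.1-0.4 s inserted independently per eye.
    """
    rng = rng_for(seed, "pupil", trial.trial_index)
    onset_1, onset_2 = 2.0, 18.5
    dur = onset_2 + 11.5
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    drift_f = rng.uniform(0.005, 0.015)
    base = 3000.0 + 12.0 * np.sin(2 * np.pi * drift_f * t + rng.uniform(0, 2 * np.pi))
    gain = effects.pupil_gain[trial.prior]
    common = (base
              + _dilation_response(t, onset_1, 60.0)
              + _dilation_response(t, onset_2, 60.0 * gain)
              + 8.0 * _smooth_track(rng, n, 1.0, int(fs)))
    eyes = []
    for eye in range(2):
        x = common + 4.0 * rng.standard_normal(n)
        if insert_blinks:
            pos = rng.exponential(1 / blink_rate_hz)
            while pos < dur:
                width = rng.uniform(0.1, 0.4)
                i0, i1 = int(pos * fs), min(int((pos + width) * fs), n)
                x[i0:i1] = np.nan
                pos += width + rng.exponential(1 / blink_rate_hz)
        eyes.append(x)
    return PupilTrace(left=eyes[0], right=eyes[1], fs=fs,
                      onset_1=onset_1, onset_2=onset_2,
                      trial_index=trial.trial_index)


_RATING_THRESHOLDS = (-1.0, 0.5, 2.0)
_RATING_BASE = {"SWS": 0.3, "NVS": 0.0}


def simulate_ratings(design: list[TrialRecord], effects: ConditionEffects,
                     seed: int = 0) -> list[TrialRecord]:
    """Fill clarity_1/clarity_2 from a latent Gaussian threshold model."""
    rng = rng_for(seed, "ratings")
    out = []
    for trial in design:
        base = _RATING_BASE[trial.stimulus_type]
        lat1 = base + rng.standard_normal()
        lat2 = base + effects.rating_shift[trial.prior] + rng.standard_normal()
        c1 = int(np.searchsorted(_RATING_THRESHOLDS, lat1) + 1)
        c2 = int(np.searchsorted(_RATING_THRESHOLDS, lat2) + 1)
        out.append(replace(trial, clarity_1=c1, clarity_2=c2))
    return out


# --------------------------------------------------------------------------
# whole-session assembly
# --------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Scale knobs for one simulated session."""
    n_pairs: int = 80
    training_duration: float = 120.0
    audio_fs: float = DEFAULT_AUDIO_FS
    epoch_span: tuple[float, float] = EPOCH_SPAN
    n_trials: int | None = None     # subset (balanced across cells) if set
    noise: NoiseParams = field(default_factory=NoiseParams)
    simulate_pupil_traces: bool = True


@dataclass
class SessionData:
    participant_index: int
    design: list[TrialRecord]
    training_eeg: np.ndarray            # (64, samples) at 500 Hz
    training_envelope: object           # AuditoryEnvelope at 100 Hz
    training_audio: AudioStimulus
    trial_epochs: dict                  # (trial_index, presentation) -> EEGEpoch
    trial_envelopes: dict               # sentence_id -> AuditoryEnvelope
    pupil: dict                         # trial_index -> PupilTrace
    layout: ChannelLayout = None
    trf: ForwardTRF = None
    seed: int = 0
    config: SessionConfig = None


def make_training_stimulus(duration: float, seed: int,
                           fs: float = DEFAULT_AUDIO_FS) -> AudioStimulus:
    """Continuous clear-speech-like narrative emulating an audiobook segment."""
    n_chunks = int(np.ceil(duration / SENTENCE_DURATION))
    rng = rng_for(seed, "training-stim")
    ctrl_rate = 100.0
    n_ctrl = int(SENTENCE_DURATION * ctrl_rate)
    pieces = []
    for c in range(n_chunks):
        sub = rng_for(seed, "training-stim", c)
        freqs = np.stack([f * np.exp(_smooth_track(sub, n_ctrl, 0.12, 60))
                          for f in _FORMANT_CENTERS])
        amps = np.stack([np.exp(_smooth_track(sub, n_ctrl, 0.3, 60)) / (j + 1)
                         for j in range(len(_FORMANT_CENTERS))])
        env = _syllable_envelope(sub, n_ctrl, ctrl_rate)
        spec = SentenceSpec(sentence_id=-1 - c, pair_id=-1, list_id="A",
                            formant_freqs=freqs, formant_amps=amps,
                            syllable_envelope=env, ctrl_rate=ctrl_rate)
        chunk = synthesize_clear(spec, fs)
        n_one = int(round(SENTENCE_DURATION * fs))
        pieces.append(chunk.samples[:n_one])
    x = np.concatenate(pieces)[: int(round(duration * fs))]
    return AudioStimulus(samples=x, fs=fs, variant="clear", sentence_id=-1,
                         n_iterations=1)


def simulate_training_eeg(envelope, trf: ForwardTRF, layout: ChannelLayout,
                          noise: NoiseParams, seed: int,
                          fs: float = EEG_FS) -> np.ndarray:
    """Continuous training EEG: tracking gain 1, no condition effects."""
    dummy = TrialRecord(trial_index=0, block=0, stimulus_type="SWS",
                        prior="P0", sentence_id=-1)
    dur = len(envelope.samples) / envelope.fs
    epoch = simulate_trial_eeg(envelope, trf, ConditionEffects.neutral(), dummy,
                               presentation=1, layout=layout, noise_params=noise,
                               seed=seed, epoch_span=(0.0, dur), fs=fs)
    return epoch.data


def _subset_design(design: list[TrialRecord], n_trials: int) -> list[TrialRecord]:
    """Balanced subset: equal trials per stimulus_type x prior cell, in order."""
    per_cell = max(1, n_trials // 6)
    taken: dict[tuple[str, str], int] = {}
    subset = []
    for tr in design:
        cell = (tr.stimulus_type, tr.prior)
        if taken.get(cell, 0) < per_cell:
            taken[cell] = taken.get(cell, 0) + 1
            subset.append(tr)
    return subset


def simulate_session(pool: list[SentenceSpec], participant_index: int,
                     effects: ConditionEffects, seed: int,
                     config: SessionConfig | None = None) -> SessionData:
    """Generate one participant's full session (training, trials, pupil, ratings)."""
    from . import auditory  # deferred: auditory imports AudioStimulus from here

    cfg = config or SessionConfig()
    layout = ChannelLayout.load_default()
    trf = make_forward_trf(layout)

    design = assign_conditions(pool, participant_index, seed)
    design = simulate_ratings(design, effects,
                              seed=seed * 1000 + participant_index)
    if cfg.n_trials is not None:
        design = _subset_design(design, cfg.n_trials)

    specs = {s.sentence_id: s for s in pool}
    trial_envelopes = {}
    trial_epochs = {}
    pupil = {}
    part_seed = seed * 1000 + participant_index

    training_audio = make_training_stimulus(cfg.training_duration, seed,
                                            cfg.audio_fs)
    training_env = auditory.extract_envelope(training_audio)
    training_eeg = simulate_training_eeg(training_env, trf, layout, cfg.noise,
                                         seed=part_seed)

    for trial in design:
        sid = trial.sentence_id
        if sid not in trial_envelopes:
            spec = specs[sid]
            clear = synthesize_clear(spec, cfg.audio_fs)
            if trial.stimulus_type == "NVS":
                stim = noise_vocode(clear, seed=seed)
            else:
                stim = sine_wave_synthesize(spec, cfg.audio_fs)
            stim = equalize_amplitude([stim])[0]
            trial_envelopes[sid] = auditory.extract_envelope(stim)
        env = trial_envelopes[sid]
        for presentation in (1, 2):
            trial_epochs[(trial.trial_index, presentation)] = simulate_trial_eeg(
                env, trf, effects, trial, presentation, layout,
                noise_params=cfg.noise, seed=part_seed,
                epoch_span=cfg.epoch_span)
        if cfg.simulate_pupil_traces:
            pupil[trial.trial_index] = simulate_pupil(
                trial, effects, seed=part_seed)

    return SessionData(participant_index=participant_index, design=design,
                       training_eeg=training_eeg,
                       training_envelope=training_env,
                       training_audio=training_audio,
                       trial_epochs=trial_epochs,
                       trial_envelopes=trial_envelopes,
                       pupil=pupil, layout=layout, trf=trf, seed=seed,
                       config=cfg)
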