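# Methods

This note documents the models, parameter choices, and numerical decisions
behind the `popout` pipeline, and states what the synthetic-data generator
does and does not emulate.

## The synthetic study

The generator reproduces the structure of a two-presentation degraded-speech
experiment. A pool of `n_pairs` (default 80) sentence pairs is partitioned
into 5 lists; each participant completes 6 blocks of 16 trials — 16 trials
in each stimulus-type (SWS/NVS) x prior (P+/P-/P0) cell. Four lists feed the
informative-prior cells (one pair member heard, the other serving as the
incorrect written sentence in P-), and the fifth list is split across the
two P0 cells, so 64 informative and 32 neutral trials use each sentence at
most once. List-to-role assignment rotates with the participant index as a
5 x 5 Latin square.

### Sentences and audio

"Sentences" are parametric: three formant tracks (smooth log-normal
excursions around 500/1500/2500 Hz), per-formant amplitude tracks, and a
nonnegative syllable envelope built from Gaussian bumps at 3-5 Hz — the
modulation range that carries syllabic rhythm. Pair mates share the base
trajectories up to bounded jitter (<= 10% formant scaling, smoothly warped
syllable timing), which preserves the "similar but not identical" pair
structure the P- condition requires without any language assets. Each 3.5 s
iteration is synthesized and concatenated three times (10.5 s total, exact
by construction, so no time-stretching is needed).

* Clear speech: harmonics of a 110 Hz glottal source weighted by Gaussian
  resonance profiles that follow the formant tracks, modulated by the
  syllable envelope.
* NVS: 7 logarithmically spaced bands spanning 100-8000 Hz (4th-order
  Butterworth); per-band envelope = half-wave rectification + 30 Hz
  low-pass; each envelope modulates band-limited white noise, RMS-matched
  per band and summed. Band edges and the 30 Hz cutoff are package choices
  (the band count and log spacing are the defining constraints).
* SWS: one sinusoid per formant following the known tracks. Sinusoid
  amplitudes are driven by a 150 ms-smoothed, floor-limited version of the
  syllable envelope, emulating the sluggish frame-wise amplitude estimation
  of formant-based resynthesis. This is what makes SWS degrade the 2-8 Hz
  temporal envelope (clear-SWS envelope correlation ~0.9) while NVS
  preserves it (~0.95), matching the complementary-degradation logic of the
  design.
* Degraded stimuli are RMS-equalized (default target 0.05).

### EEG forward model

Trial EEG (64 channels, 500 Hz, epochs [-5, +15] s by default) is the sum
of:

1. an envelope-tracking component: a ground-truth kernel over lags
   0..300 ms (10 ms steps) with a smooth positive-then-negative temporal
   profile and a fronto-central topography, convolved with the stimulus'
   2-8 Hz envelope, unit-RMS normalized, scaled by `tracking_scale` x
   `tracking_gain(prior, presentation)`;
2. theta (4-9 Hz) and alpha (10-15 Hz) band-limited noise with fixed
   fronto-central and parieto-occipital topographies, scaled by the
   corresponding condition gains — non-phase-locked by construction, so the
   induced-power analysis has something real to estimate;
3. a fixed biphasic onset transient (identical across trials and
   conditions), so evoked-subtraction has a nontrivial component to remove;
4. background noise: 16 smooth random scalp patterns mixing independent 1/f
   time courses, plus white sensor noise. The low-rank spatially correlated
   part mimics volume conduction; the white part sets the decoder's noise
   floor. Spatially white noise alone would be unrealistically easy for a
   64-channel decoder to cancel.

`tracking_scale` defaults to 0.03, calibrated once so that single-trial
reconstruction scores land in the 0.05-0.3 range typical of published
speech-tracking EEG (noiseless trials reconstruct near r ~ 1; the packaged
"paper-like" effect raises `tracking_gain` to 1.5 for P+ on the 2nd
presentation). The `noise_multiplier` scales every constituent except the
tracking component and is the axis of the noise-robustness checks.

All randomness derives from a master seed through SHA-256-keyed named
substreams (`utils.rng_for`), so each stage's draws are independent and
changing one stage never perturbs another.

### Pupil and ratings

Pupil traces (two eyes, 300 Hz) span both presentations: a 3000 a.u.
baseline, a slow drift (12 a.u., 0.005-0.015 Hz), gamma-shaped dilation
responses after each presentation onset (peak ~2.5 s; the 2nd scaled by the
prior's `pupil_gain`), smooth measurement noise, and NaN blink gaps of
0.1-0.4 s inserted independently per eye. The drift amplitude was set so
that baseline-to-presentation-2 drift stays small relative to the
event-related dilation, as in practice. Clarity ratings come from a latent
Gaussian (base depending on stimulus type, plus `rating_shift(prior)` on
the 2nd presentation) cut at fixed thresholds into 1..4.

### What the generator does not emulate

Real language content and intelligibility, ocular/cardiac artifacts (ICA is
out of scope), electrode drift and impedance changes, between-participant
anatomical variability (all participants share the layout and forward
kernel; they differ in noise realizations), reaction times, and the
original audiobook narrative (a configurable-length synthetic "clear
speech" stream stands in). Passing tests therefore demonstrate that the
analysis machinery is correct and calibrated — not that it would produce
identical numbers on the human recordings.

## Analysis pipeline

**Envelope extraction (STEP).** Resample to 22.05 kHz; 2nd-order
Butterworth band-pass 450-8500 Hz (outer/middle ear); 128 gammatone filters
(4th order, ERB-spaced 50-8000 Hz, FIR kernels covering the envelope
decay); per band half-wave rectification and a 100 Hz 2nd-order Butterworth
low-pass; square-root compression and log10 (floor 1e-6) for the
cochleagram. The summed-band envelope is taken before compression (keeping
it linear in sound amplitude), resampled to 100 Hz and band-passed 2-8 Hz
with a two-pass windowed-sinc FIR (~1 Hz transition). For efficiency the
per-band smoothing runs at 3150 Hz after a 7-sample box-car (flat to 0.02%
below 100 Hz), and band envelopes are stored at 450 Hz — both are exact in
the passband by construction.

**EEG preprocessing.** Epoching with per-channel demeaning; two-pass
4th-order Butterworth 1-125 Hz; DFT notch at 50/100 Hz implemented as
least-squares projection onto the line-frequency sin/cos pair (exact for
stationary tones); inverse-distance-weighted interpolation of bad channels
over the 40 mm neighbor graph; common-average or linked-mastoid (TP9/TP10)
re-referencing. Decoder preparation: common average -> 2-8 Hz two-pass FIR
-> resample to 100 Hz -> trim to the stimulus span (truncation to the
shorter of EEG/envelope reconciles any off-by-one).

**Decoder.** Backward model from lagged EEG (0..300 ms, 31 lags, one
sample per lag at 100 Hz; the envelope at t is predicted from EEG at
t..t+300 ms) to the envelope. Predictors and target are z-scored on
training statistics; ridge normal equations are assembled by a
lag-correlation routine that is algebraically identical to forming the
dense zero-padded design (verified to 1e-12) but ~30x cheaper; the penalty
is selected on a log grid by 8-fold contiguous-segment cross-validation
maximizing held-out Pearson r (a single-element grid skips CV). Scores are
Pearson r per exact 3.5 s iteration third; the headline analysis consumes
iteration 1 of each presentation.

**Spectral analysis.** Sliding 1 s Hanning windows every 100 ms, 1-30 Hz
in 1 Hz bins, computed as a tapered DFT at exactly those bins (identical to
FFT-bin selection for a 1 s window); scaling is such that a unit-amplitude
sinusoid at a bin center yields power 1. Band power averages [0.5, 3.0] s
(first iteration, onset/offset trimmed) before log10. Induced profiles:
1-pass zero-phase FIR band-pass, subtract the cell-mean evoked waveform,
square, log10 (floor 1e-20), average across trials, 500 ms moving average,
downsample to 10 Hz, no baseline scaling.

**Cluster statistics.** Paired t per (channel, bin); threshold at the
two-tailed alpha=0.025 t quantile; positive and negative clusters formed
separately over bin adjacency plus the 40 mm spatial graph, a sample being
clusterable only with >= 2 supra-threshold spatial neighbors in the same
bin (single-pass pruning); cluster mass = summed t; null = maximum absolute
mass over random within-participant sign flips of the paired differences
(all permutation t-maps come from one matrix product since sums of squares
are flip-invariant); add-one Monte Carlo p, so the smallest attainable p is
1/(n_perm+1). Constant nonzero differences map to a large finite t
(1e12) rather than infinity so masses stay finite. The 1-D variant drops
the spatial dimension and the neighbor rule.

**Pupillometry.** NaN runs <= 5 s are blinks; longer runs are dropouts
that exclude the trial (never interpolated). Blinks are bridged by the line
through the medians of the flanking 100 ms windows, anchored at the window
centers — this restores linear trends exactly and keeps the median's
robustness to flank outliers; empty flanks widen outward with a warning.
Then 6 Hz two-pass 4th-order Butterworth low-pass per eye, eye averaging,
[-1, 11] s epochs around each presentation onset, both corrected by the
mean of presentation 1's [-1, 0] s window. Dilation curves are downsampled
to 10 Hz for the 1-D cluster tests (the 6 Hz low-pass leaves nothing
above that resolution).

## Recovery harnesses and problem sizes

`popout.validation` runs the pipeline end to end at desk scale and is what
the reproduction script calls. Sizes were chosen once as the smallest at
which the statistics are meaningful:

* trials simulate the first 3.5 s iteration plus 0.3 s so the decoder's
  lags stay supplied over the scored window (at full scale iteration 1 sits
  inside the 10.5 s stimulus), with a [-2.0, +5.6] s epoch giving the
  band-pass filters real context around the scored span;
* the training narrative is 60 s (the full-study default is configurable);
* EEG recovery runs use 19 participants with 4-6 trials per cell; pupil
  runs use 17 participants with the full 16 trials per cell (pupil
  simulation is cheap);
* the noise-robustness curve pairs noise scales by common random numbers
  (each trial reuses one noise realization across scales) and trains a
  matched decoder per scale, so the monotone degradation is measured
  without between-scale sampling noise;
* the paired pop-out contrast uses an exact sign-flip permutation test
  (4999 flips): unlike the plain t-test it keeps its size when
  participant-level difference variances differ, which they do because
  decoder quality varies across simulated participants;
* cluster-test calibration: 200 null simulations at 8 participants, 16
  spatially contiguous channels (nearest the vertex, so the 40 mm graph
  keeps realistic degrees), 30 bins, 500 permutations.

## Known limitations

* The forward model is rank-1 per component and shared across participants;
  between-participant topographic variability is not modelled.
* The STEP front end fixes gammatone order/spacing and the ear filter at
  standard values; these were not fitted to any data.
* Vocoder band edges, envelope-smoothing cutoffs, and FIR transition widths
  are package defaults, stated in the module constants, not inferences
  about any particular original implementation.
* The cluster "min 2 neighbors" rule uses single-pass pruning; iterative
  re-pruning would be marginally more conservative.
* Mixed-effects modelling of ratings/scores is intentionally out of scope;
  the exported tidy tables are designed to feed external statistical
  environments.
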