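# popout

A synthetic-study pipeline for investigating how prior written information
changes neurophysiological responses to degraded speech ("pop-out": the
abrupt gain in subjective clarity of a noise-vocoded or sine-wave sentence
once the listener knows its content).

The package is aimed at researchers who want a fully controlled, desk-scale
replica of such an experiment: every stage of the analysis — stimulus
synthesis, peripheral auditory modelling, EEG preprocessing, backward
temporal-response-function (TRF) decoding, spectral analysis with
cluster-based permutation statistics, and pupillometry — runs against
simulated data whose condition effects are injected, and therefore known
exactly. That makes the pipeline testable end to end: an effect the
generator injects must come out of the statistics with the right sign and
calibrated error rates.

## What it implements

**Design.** 80 sentence pairs in 5 lists; per participant, 6 blocks x 16
trials crossing stimulus type (sine-wave speech SWS / 7-band noise-vocoded
speech NVS) with prior condition (correct P+, incorrect P-, none P0), 16
trials per cell, Latin-square list rotation. Each trial presents the same
degraded sentence twice, with the written prior shown in between, and
collects 1-4 clarity ratings after each presentation.

**Stimulus reconstruction.** The 2-8 Hz auditory envelope is extracted with
a spectro-temporal excitation pattern (STEP) front end: outer/middle-ear
band-pass, 128 ERB-spaced gammatone filters, half-wave rectification,
100 Hz low-pass, summed and resampled to 100 Hz. A backward model

```
s(t) = sum_c sum_tau  w(c, tau) * r_c(t + tau) + b,    tau = 0..300 ms
```

maps lagged multichannel EEG `r` to the envelope `s`; the weights are the
ridge solution `w = (X'X + lambda I)^-1 X'y` trained on an independent
clear-speech narrative and evaluated per trial by the Pearson correlation
between reconstructed and true envelope over each 3.5 s sentence iteration.

**Spectral analysis.** Sliding Hanning-taper power (1-30 Hz, 1 s taper,
100 ms steps), band-averaged log10 power (delta 1-3, theta 4-9, alpha
10-15, beta 16-30 Hz), and induced (non-phase-locked) profiles via the
intertrial-variance method. Condition contrasts use nonparametric
cluster-based permutation tests (paired t maps, |t| threshold at
alpha=0.025 two-tailed, spatial adjacency within 40 mm and a minimum of 2
supra-threshold neighbors, max-sum-t null over 1000 sign-flip
permutations).

**Pupillometry.** Blink detection (signal interruptions up to 5 s),
linear interpolation between flanking 100 ms medians, 6 Hz low-pass, eye
averaging, [-1, 11] s epochs baselined to the pre-first-presentation
second, and 1-D cluster permutation tests on the dilation time courses.

## Worked example

```python
import numpy as np
from popout import (build_stimulus_pool, synthesize_clear, noise_vocode,
                    extract_envelope)
from popout.utils import pearson_r

pool = build_stimulus_pool(n_pairs=5, seed=1)     # 10 sentences, 5 lists
clear = synthesize_clear(pool[0])                  # 10.5 s clear rendering
nvs = noise_vocode(clear, n_bands=7, seed=1)       # 7-band noise vocoding
e_clear = extract_envelope(clear)                  # 2-8 Hz envelope, 100 Hz
e_nvs = extract_envelope(nvs)
print(len(e_clear.samples), pearson_r(e_clear.samples, e_nvs.samples))
```

prints

```
1050 0.953...
```

1050 samples is the 10.5 s stimulus at the 100 Hz envelope rate, and ~0.95
is the 2-8 Hz envelope correlation between the clear sentence and its
noise-vocoded version — vocoding preserves the temporal (syllabic) cues
while destroying spectral detail, which is exactly what makes NVS
intelligible after a correct prior.

A full synthetic study runs through the pipeline API:

```python
from popout import RunConfig, run_pipeline, summarize_conditions
bundle = run_pipeline(RunConfig.smoke(seed=1))   # 3 participants, 12 trials
print(summarize_conditions(bundle))
```

which reports per-cell mean reconstruction scores (single-trial r typically
0.05-0.3 at the packaged noise level) with paired differences against P0.
The same stages are exposed as a CLI (`popout simulate`, `popout envelope`,
`popout decode`, `popout spectra`, `popout pupil`, `popout all`, ...).

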