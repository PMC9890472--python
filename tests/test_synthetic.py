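"""Stimulus pool, design counterbalancing, audio synthesis, and simulators."""

import numpy as np
import pytest

from popout.exceptions import (AlignmentError, ConfigurationError,
                               StructuralError)
from popout.synthetic import (LISTS, AudioStimulus, ConditionEffects,
                              NoiseParams, SentenceSpec, TrialRecord,
                              assign_conditions, build_stimulus_pool,
                              equalize_amplitude, noise_vocode, simulate_pupil,
                              simulate_ratings, simulate_trial_eeg,
                              sine_wave_synthesize, synthesize_clear)
from popout.auditory import AuditoryEnvelope
from popout.utils import pearson_r


def _const_spec(freqs=(500.0, 1500.0, 2500.0), env_value=1.0):
    n = 350
    return SentenceSpec(
        sentence_id=0, pair_id=0, list_id="A",
        formant_freqs=np.tile(np.array(freqs)[:, None], (1, n)),
        formant_amps=np.ones((len(freqs), n)),
        syllable_envelope=np.full(n, env_value))


class TestStimulusPool:
    def test_full_pool_structure(self):
        pool = build_stimulus_pool(80, seed=0)
        assert len(pool) == 160
        per_list = {}
        for s in pool:
            per_list.setdefault(s.list_id, set()).add(s.pair_id)
        assert set(per_list) == set(LISTS)
        assert all(len(p) == 16 for p in per_list.values())
        pair_sizes = {}
        for s in pool:
            pair_sizes[s.pair_id] = pair_sizes.get(s.pair_id, 0) + 1
        assert set(pair_sizes.values()) == {2}

    def test_seeded_determinism(self):
        a = build_stimulus_pool(5, seed=42)
        b = build_stimulus_pool(5, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.formant_freqs, y.formant_freqs)
            np.testing.assert_array_equal(x.syllable_envelope, y.syllable_envelope)

    def test_pair_members_more_similar_than_nonpairs(self, small_pool):
        def corr(a, b):
            return pearson_r(a.formant_freqs.ravel(), b.formant_freqs.ravel())
        within = [corr(small_pool[2 * k], small_pool[2 * k + 1]) for k in range(5)]
        across = [corr(small_pool[0], small_pool[2 * k]) for k in range(1, 5)]
        assert min(within) > max(across)

    def test_divisibility_error(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            build_stimulus_pool(7, seed=0)


class TestDesign:
    @pytest.mark.parametrize("participant", [0, 3, 11])
    def test_design_counts(self, small_pool, participant):
        pool = build_stimulus_pool(80, seed=1)
        design = assign_conditions(pool, participant, seed=1)
        assert len(design) == 96
        cells = {}
        for t in design:
            cells[(t.stimulus_type, t.prior)] = cells.get(
                (t.stimulus_type, t.prior), 0) + 1
        assert all(v == 16 for v in cells.values()) and len(cells) == 6
        informative = [t for t in design if t.prior != "P0"]
        assert len(informative) == 64
        sids = [t.sentence_id for t in design]
        assert len(set(sids)) == len(sids)
        assert {t.block for t in design} == set(range(1, 7))

    def test_incongruent_prior_shows_pair_mate(self):
        pool = build_stimulus_pool(80, seed=1)
        spec_by_id = {s.sentence_id: s for s in pool}
        for t in assign_conditions(pool, 2, seed=1):
            if t.prior == "P-":
                assert t.displayed_sentence_id != t.sentence_id
                assert (spec_by_id[t.displayed_sentence_id].pair_id
                        == spec_by_id[t.sentence_id].pair_id)
            elif t.prior == "P+":
                assert t.displayed_sentence_id == t.sentence_id
            else:
                assert t.displayed_sentence_id is None

    def test_latin_square_rotation(self):
        pool = build_stimulus_pool(80, seed=1)
        spec_by_id = {s.sentence_id: s for s in pool}
        roles = np.empty((5, 5), dtype=object)
        for p in range(5):
            for t in assign_conditions(pool, p, seed=1):
                lst = LISTS.index(spec_by_id[t.sentence_id].list_id)
                role = ("P0" if t.prior == "P0"
                        else f"{t.stimulus_type}:{t.prior}")
                roles[p, lst] = role
        for col in range(5):
            assert len(set(roles[:, col])) == 5  # each list serves each role once

    def test_malformed_pool(self, small_pool):
        with pytest.raises(StructuralError):
            assign_conditions(small_pool[:-1], 0, seed=0)


class TestAudioSynthesis:
    def test_clear_length_and_variant(self):
        stim = synthesize_clear(_const_spec(), fs=22050)
        assert len(stim.samples) == 231525  # 3 x 3.5 s x 22050
        assert stim.variant == "clear"

    def test_zero_envelope_silent(self):
        stim = synthesize_clear(_const_spec(env_value=0.0))
        assert np.allclose(stim.samples, 0.0)

    def test_spectral_ridges_track_formants(self):
        import scipy.fft as sfft
        stim = synthesize_clear(_const_spec(freqs=(600.0, 2200.0)))
        x = stim.samples[: 22050]
        spec = np.abs(sfft.rfft(x * np.hanning(len(x))))
        f = sfft.rfftfreq(len(x), 1 / 22050)
        for target in (600.0, 2200.0):
            sel = (f > target - 300) & (f < target + 300)
            peak = f[sel][np.argmax(spec[sel])]
            # energy ridge within one source harmonic of the formant
            assert abs(peak - target) < 120.0

    def test_sampling_rate_floor(self):
        # spec-level formant bounds (< 8 kHz) already guarantee Nyquist
        # safety at the minimum legal rate; lower rates are rejected
        with pytest.raises(ConfigurationError):
            synthesize_clear(_const_spec(), fs=8000)

    def test_sws_peaks_only_at_formants(self):
        import scipy.fft as sfft
        stim = sine_wave_synthesize(_const_spec())
        x = stim.samples[: 22050 * 2]
        spec = np.abs(sfft.rfft(x * np.hanning(len(x))))
        f = sfft.rfftfreq(len(x), 1 / 22050)
        strong = f[spec > 0.02 * spec.max()]
        for fr in strong:
            assert min(abs(fr - c) for c in (500, 1500, 2500)) < 30
        # clear version carries source harmonics between formants; SWS not
        clear = synthesize_clear(_const_spec())
        sel = (f > 800) & (f < 1200)
        cspec = np.abs(sfft.rfft(clear.samples[: 22050 * 2]
                                 * np.hanning(len(x))))
        assert cspec[sel].max() / cspec.max() > 10 * spec[sel].max() / spec.max()

    def test_sws_zero_amplitude_silent(self):
        spec = _const_spec()
        spec.formant_amps[:] = 0.0
        assert np.allclose(sine_wave_synthesize(spec).samples, 0.0)

    def test_sws_needs_two_tracks(self):
        spec = _const_spec(freqs=(500.0,))
        with pytest.raises(ConfigurationError):
            sine_wave_synthesize(spec)


class TestVocoder:
    def test_requires_clear_and_two_bands(self):
        stim = synthesize_clear(_const_spec())
        with pytest.raises(ConfigurationError):
            noise_vocode(stim, n_bands=1)
        sws = sine_wave_synthesize(_const_spec())
        with pytest.raises(ConfigurationError):
            noise_vocode(sws)

    def test_silent_input_silent_output(self):
        stim = synthesize_clear(_const_spec(env_value=0.0))
        out = noise_vocode(stim, 7)
        assert np.allclose(out.samples, 0.0)
        assert out.variant == "NVS"
        assert len(out.samples) == len(stim.samples)


class TestEqualize:
    def test_exact_target(self):
        a = AudioStimulus(np.sin(np.arange(1000)) * 0.1, 22050, "NVS", 0)
        b = AudioStimulus(np.sin(np.arange(1000)) * 0.2, 22050, "SWS", 1)
        out = equalize_amplitude([a, b], target_rms=0.1)
        for s in out:
            assert abs(s.rms() - 0.1) < 1e-12
        assert pearson_r(out[0].samples, a.samples) > 0.999999

    def test_pool_rms_ratio(self, small_pool):
        stims = [sine_wave_synthesize(s) for s in small_pool[:6]]
        out = equalize_amplitude(stims)
        rms = [s.rms() for s in out]
        assert max(rms) / min(rms) < 1 + 1e-6

    def test_silent_error(self):
        silent = AudioStimulus(np.zeros(100), 22050, "NVS", 0)
        with pytest.raises(ConfigurationError):
            equalize_amplitude([silent])


class TestTrialEEG:
    def _env(self, n=380):
        rng = np.random.default_rng(0)
        return AuditoryEnvelope(samples=rng.standard_normal(n), fs=100.0)

    def test_zero_scales_zero_epoch(self, layout, trf):
        quiet = NoiseParams(tracking_scale=0, osc_scale=0, background_scale=0,
                            evoked_amp=0)
        ep = simulate_trial_eeg(self._env(), trf, ConditionEffects.neutral(),
                                TrialRecord(1, 1, "SWS", "P0", 0), 1, layout,
                                quiet, seed=0, epoch_span=(-1.0, 5.0))
        assert np.allclose(ep.data, 0.0)

    def test_default_epoch_shape(self, layout, trf):
        env = AuditoryEnvelope(samples=np.random.default_rng(0).standard_normal(1050),
                               fs=100.0)
        ep = simulate_trial_eeg(env, trf, ConditionEffects.neutral(),
                                TrialRecord(1, 1, "SWS", "P0", 0), 1, layout,
                                seed=0)
        assert ep.data.shape == (64, 10000)  # 64 channels x 20 s x 500 Hz
        assert ep.fs == 500.0 and ep.t0 == -5.0

    def test_span_must_cover_stimulus(self, layout, trf):
        with pytest.raises(AlignmentError):
            simulate_trial_eeg(self._env(), trf, ConditionEffects.neutral(),
                               TrialRecord(1, 1, "SWS", "P0", 0), 1, layout,
                               seed=0, epoch_span=(-1.0, 2.0))

    def test_determinism(self, layout, trf):
        args = (self._env(), trf, ConditionEffects.paper_like(),
                TrialRecord(3, 1, "NVS", "P+", 5), 2, layout)
        a = simulate_trial_eeg(*args, seed=9, epoch_span=(-1.0, 5.0))
        b = simulate_trial_eeg(*args, seed=9, epoch_span=(-1.0, 5.0))
        np.testing.assert_array_equal(a.data, b.data)


class TestPupilAndRatings:
    def test_pupil_blink_toggle_and_determinism(self):
        trial = TrialRecord(1, 1, "SWS", "P+", 0)
        eff = ConditionEffects.paper_like()
        tr = simulate_pupil(trial, eff, seed=4)
        assert np.isnan(tr.left).any() and np.isnan(tr.right).any()
        clean = simulate_pupil(trial, eff, seed=4, insert_blinks=False)
        assert not np.isnan(clean.left).any()
        again = simulate_pupil(trial, eff, seed=4)
        np.testing.assert_array_equal(tr.left, again.left)

    def test_gains_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            ConditionEffects(pupil_gain={"P+": 0.0, "P-": 1.0, "P0": 1.0})

    def test_ratings_range_and_shift(self):
        pool = build_stimulus_pool(80, seed=2)
        eff = ConditionEffects.neutral()
        eff.rating_shift["P+"] = 2.0
        n_higher = 0
        n_parts = 40
        for p in range(n_parts):
            design = assign_conditions(pool, p, seed=2)
            design = simulate_ratings(design, eff, seed=p)
            vals = {pr: [] for pr in ("P+", "P-", "P0")}
            for t in design:
                assert t.clarity_1 in (1, 2, 3, 4)
                assert t.clarity_2 in (1, 2, 3, 4)
                vals[t.prior].append(t.clarity_2)
            if (np.mean(vals["P+"]) > np.mean(vals["P0"])
                    and np.mean(vals["P+"]) > np.mean(vals["P-"])):
                n_higher += 1
        assert n_higher >= 0.99 * n_parts - 1  # allow one MC miss

    def test_neutral_ratings_exchangeable(self):
        pool = build_stimulus_pool(80, seed=3)
        means = {pr: [] for pr in ("P+", "P-", "P0")}
        for p in range(30):
            design = simulate_ratings(assign_conditions(pool, p, seed=3),
                                      ConditionEffects.neutral(), seed=p)
            for pr in means:
                means[pr].append(np.mean([t.clarity_2 for t in design
                                          if t.prior == pr]))
        grand = [np.mean(means[pr]) for pr in means]
        assert max(grand) - min(grand) < 0.25
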