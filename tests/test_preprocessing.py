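"""EEG conditioning: epoching, filtering, interpolation, referencing, decimation."""

import numpy as np
import pytest

from popout.exceptions import (BoundaryError, ConfigurationError,
                               StructuralError)
from popout.preprocessing import (EEGEpoch, dft_notch, epoch_eeg, filter_eeg,
                                  interpolate_bad_channels,
                                  prepare_for_decoding, rereference)

FS = 500.0


def _epoch(data, t0=-5.0, names=None):
    names = names or tuple(f"ch{i}" for i in range(data.shape[0]))
    return EEGEpoch(data=np.asarray(data, float), fs=FS, t0=t0, channels=names)


class TestEpoching:
    def test_sample_count_and_centering(self, rng):
        cont = rng.standard_normal((4, int(FS * 60))) + 3.0
        epochs = epoch_eeg(cont, FS, onsets=[10.0, 30.0], channels=list("abcd"))
        assert len(epochs) == 2
        for ep in epochs:
            assert ep.data.shape == (4, 10000)  # 20 s x 500 Hz
            np.testing.assert_allclose(ep.data.mean(axis=1), 0.0, atol=1e-10)

    def test_boundary_error_names_trial(self, rng):
        cont = rng.standard_normal((2, int(FS * 30)))
        with pytest.raises(BoundaryError, match="trial 1"):
            epoch_eeg(cont, FS, onsets=[10.0, 29.0], channels=["a", "b"])


class TestFiltering:
    def test_dc_removed(self):
        ep = _epoch(np.full((2, 8000), 5.0))
        out = filter_eeg(ep)
        assert np.abs(out.data.mean()) < 5e-3

    def test_line_noise_notched(self):
        t = np.arange(8000) / FS
        line = (np.sin(2 * np.pi * 50 * t + 0.3)
                + 0.5 * np.sin(2 * np.pi * 100 * t))
        out = dft_notch(_epoch(line[None, :]))
        assert out.data.std() < 0.01 * line.std()
        # and the full filter chain keeps the residual small away from edges
        full = filter_eeg(_epoch(line[None, :]))
        assert full.data[0, 1000:-1000].std() < 0.01 * line.std()

    def test_passband_gain(self):
        t = np.arange(8000) / FS
        ep = _epoch(np.sin(2 * np.pi * 10 * t)[None, :])
        out = filter_eeg(ep)
        mid = slice(2000, 6000)
        assert abs(np.abs(out.data[0, mid]).max() - 1.0) < 0.05

    def test_low_rate_rejected(self):
        ep = EEGEpoch(data=np.zeros((1, 100)), fs=200.0, t0=0.0,
                      channels=("a",))
        with pytest.raises(ConfigurationError):
            filter_eeg(ep)

    def test_linearity(self, rng):
        a = _epoch(rng.standard_normal((3, 6000)))
        b = _epoch(rng.standard_normal((3, 6000)))
        summed = _epoch(a.data + b.data)
        lhs = filter_eeg(summed).data
        rhs = filter_eeg(a).data + filter_eeg(b).data
        assert np.max(np.abs(lhs - rhs)) < 1e-9 * np.max(np.abs(lhs))


class TestInterpolation:
    def test_weighted_mean_oracle(self, layout, rng):
        data = rng.standard_normal((layout.n_channels, 100))
        ep = _epoch(data, names=layout.names)
        bad = "Cz"
        out = interpolate_bad_channels(ep, [bad], layout)
        d = layout.distance_matrix()
        bi = layout.index(bad)
        nbr = np.where((d[bi] < 0.040) & (d[bi] > 0))[0]
        w = 1.0 / d[bi, nbr]
        expected = (w @ data[nbr]) / w.sum()
        np.testing.assert_allclose(out.data[bi], expected, rtol=1e-12)
        good = [i for i in range(layout.n_channels) if i != bi]
        np.testing.assert_array_equal(out.data[good], data[good])

    def test_identical_neighbors(self, layout):
        data = np.tile(np.sin(np.arange(50)), (layout.n_channels, 1))
        ep = _epoch(data.copy(), names=layout.names)
        ep.data[layout.index("Cz")] = 99.0
        out = interpolate_bad_channels(ep, ["Cz"], layout)
        np.testing.assert_allclose(out.data[layout.index("Cz")],
                                   np.sin(np.arange(50)), atol=1e-12)

    def test_no_bad_channels_identity(self, layout, rng):
        ep = _epoch(rng.standard_normal((layout.n_channels, 10)),
                    names=layout.names)
        out = interpolate_bad_channels(ep, [], layout)
        np.testing.assert_array_equal(out.data, ep.data)

    def test_isolated_channel_error(self, layout, rng):
        ep = _epoch(rng.standard_normal((layout.n_channels, 10)),
                    names=layout.names)
        with pytest.raises(StructuralError, match="TP9"):
            interpolate_bad_channels(ep, ["TP9"], layout)  # mastoid: <2 neighbors


class TestRereference:
    def test_common_average_zero_mean_and_idempotent(self, rng):
        ep = _epoch(rng.standard_normal((8, 300)))
        out = rereference(ep, "common_average")
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12
        twice = rereference(out, "common_average")
        np.testing.assert_allclose(twice.data, out.data, atol=1e-12)

    def test_linked_mastoids(self, rng):
        names = ("a", "TP9", "TP10", "d")
        data = rng.standard_normal((4, 100))
        data[1] = data[2]  # identical mastoid signal s
        ep = _epoch(data, names=names)
        out = rereference(ep, "linked_mastoids")
        np.testing.assert_allclose(out.data, data - data[1], atol=1e-12)

    def test_missing_mastoid(self, rng):
        ep = _epoch(rng.standard_normal((2, 10)), names=("a", "b"))
        with pytest.raises(StructuralError):
            rereference(ep, "linked_mastoids")
        with pytest.raises(ConfigurationError):
            rereference(ep, "bipolar")


class TestPrepareForDecoding:
    def test_output_length(self, rng):
        ep = _epoch(rng.standard_normal((4, 10000)))  # [-5, 15] s
        out = prepare_for_decoding(ep, stimulus_duration=10.5)
        assert out.fs == 100.0
        assert abs(out.n_samples - 1050) <= 1
        assert out.t0 == 0.0

    def test_zero_in_zero_out(self):
        ep = _epoch(np.zeros((3, 10000)))
        out = prepare_for_decoding(ep, 10.5)
        assert np.allclose(out.data, 0.0)

    def test_band_selectivity(self):
        t = np.arange(10000) / FS
        sig = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 1 * t)
        data = np.stack([sig, -sig])  # zero common average must be avoided
        data = np.stack([sig, 0.1 * sig])
        ep = _epoch(data)
        out = prepare_for_decoding(ep, 10.5)
        x = out.data[0, 200:-200]
        import scipy.fft as sfft
        spec = np.abs(sfft.rfft(x))
        f = sfft.rfftfreq(len(x), 1 / 100)
        a5 = spec[np.argmin(np.abs(f - 5))]
        a1 = spec[np.argmin(np.abs(f - 1))]
        assert 20 * np.log10(a5 / a1) >= 20.0

    def test_epoch_must_cover_stimulus(self, rng):
        ep = _epoch(rng.standard_normal((2, 2000)), t0=0.0)  # 4 s
        with pytest.raises(BoundaryError):
            prepare_for_decoding(ep, 10.5)
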