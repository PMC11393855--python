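import numpy as np
import pytest

from snoreforge.audio import AudioClip, FrameSet, frame_signal
from snoreforge.features.spectral import (spectral_shape_features, ltas_features,
                                          tonality_features, autoregressive_features)
from snoreforge.features._lpc import lpc_coefficients, line_spectral_frequencies

from conftest import sine_clip, noise_clip


def get(names, values, key):
    return values[names.index(key)]


def naive_centroid_spread(frame, rate):
    """Double-loop oracle for spectral centroid and spread of one frame."""
    mag = np.abs(np.fft.rfft(frame))
    freqs = np.fft.rfftfreq(frame.size, d=1.0 / rate)
    p = mag**2
    total = p.sum()
    cent = sum(f * pi for f, pi in zip(freqs, p)) / total
    spread = np.sqrt(sum(((f - cent) ** 2) * pi for f, pi in zip(freqs, p)) / total)
    return cent, spread


class TestSpectralShape:
    def test_pure_tone_centroid_and_flatness(self):
        clip = sine_clip(1000.0)
        fs = frame_signal(clip)
        names, values = spectral_shape_features(fs)
        bin_hz = clip.rate / fs.frame_length
        assert get(names, values, "freq.centroid.mean") == pytest.approx(1000.0, abs=2 * bin_hz)
        assert get(names, values, "freq.flatness.mean") < 0.1

    def test_white_noise_is_spectrally_flat(self):
        flats = []
        for seed in range(10):
            fs = frame_signal(noise_clip(seed=seed))
            names, values = spectral_shape_features(fs)
            flats.append(get(names, values, "freq.flatness.mean"))
        assert np.mean(flats) > 0.5

    def test_identical_frames_have_zero_flux(self):
        frame = np.sin(2 * np.pi * 3 * np.arange(400) / 400)
        frames = FrameSet(frames=np.tile(frame, (5, 1)), frame_length=400, hop=160,
                          window_name="rect", rate=16000, raw_frames=np.tile(frame, (5, 1)))
        names, values = spectral_shape_features(frames)
        assert get(names, values, "freq.flux.mean") == 0.0

    def test_descriptor_invariants(self):
        fs = frame_signal(noise_clip(seed=3))
        names, values = spectral_shape_features(fs)
        assert 0.0 < get(names, values, "freq.flatness.mean") <= 1.0
        assert 0.0 <= get(names, values, "freq.entropy.mean") <= 1.0
        assert get(names, values, "freq.rolloff.mean") <= 8000.0
        assert get(names, values, "freq.crest.mean") >= 1.0

    def test_centroid_spread_match_naive_oracle(self, rng):
        frames = rng.normal(size=(20, 128))
        fs = FrameSet(frames=frames, frame_length=128, hop=64, window_name="rect",
                      rate=16000, raw_frames=frames)
        names, values = spectral_shape_features(fs)
        cents, spreads = zip(*(naive_centroid_spread(f, 16000) for f in frames))
        assert get(names, values, "freq.centroid.mean") == pytest.approx(np.mean(cents), abs=1e-9)
        assert get(names, values, "freq.spread.mean") == pytest.approx(np.mean(spreads), abs=1e-9)

    def test_all_zero_frames_stay_finite(self):
        frames = np.zeros((4, 64))
        fs = FrameSet(frames=frames, frame_length=64, hop=32, window_name="rect",
                      rate=16000, raw_frames=frames)
        names, values = spectral_shape_features(fs)
        assert np.all(np.isfinite(values))


class TestLtas:
    def _frames_with_rms(self, rms_series, n=16):
        rows = np.array([[r] * n for r in rms_series], dtype=float)
        return FrameSet(frames=rows, frame_length=n, hop=n, window_name="rect",
                        rate=16000, raw_frames=rows)

    def test_hand_series(self):
        names, values = ltas_features(self._frames_with_rms([1, 2, 3, 4]))
        assert values[names.index("freq.ltas_range")] == pytest.approx(3.0)
        assert values[names.index("freq.ltas_ppv")] == pytest.approx(1.0)

    def test_constant_tone_has_flat_statistics(self):
        names, values = ltas_features(self._frames_with_rms([0.5] * 8))
        assert values[names.index("freq.ltas_range")] == pytest.approx(0.0, abs=1e-12)
        assert values[names.index("freq.ltas_skew")] == 0.0
        assert values[names.index("freq.ltas_kurt")] == 0.0

    def test_amplitude_modulation_raises_range(self):
        t = np.arange(16000) / 16000
        plain = sine_clip(200.0)
        mod = AudioClip(samples=plain.samples * (0.6 + 0.4 * np.sin(2 * np.pi * 3 * t)),
                        rate=16000)
        _, v_plain = ltas_features(frame_signal(plain))
        names, v_mod = ltas_features(frame_signal(mod))
        i = names.index("freq.ltas_range")
        assert v_mod[i] > v_plain[i]

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            ltas_features(self._frames_with_rms([1, 2, 3]))


class TestTonality:
    def test_stationary_200hz_tone(self):
        clip = sine_clip(200.0)
        names, values = tonality_features(clip, frame_signal(clip))
        f0 = get(names, values, "freq.f0.mean")
        assert f0 == pytest.approx(200.0, rel=0.05)
        assert get(names, values, "freq.jitter") < 0.01

    def test_noise_lowers_hnr(self, rng):
        clean = sine_clip(300.0)
        noisy = AudioClip(samples=np.clip(clean.samples + 0.5 * rng.standard_normal(16000), -1, 1),
                          rate=16000)
        names, v_clean = tonality_features(clean, frame_signal(clean))
        _, v_noisy = tonality_features(noisy, frame_signal(noisy))
        i = names.index("freq.hnr")
        assert v_noisy[i] < v_clean[i]

    def test_peak_frequency_of_440hz_line(self):
        clip = sine_clip(440.0)
        names, values = tonality_features(clip, frame_signal(clip))
        assert get(names, values, "freq.peak_freq") == pytest.approx(440.0, abs=1.5)

    def test_unvoiced_clip_gets_sentinels(self):
        clip = AudioClip(samples=np.zeros(8000) + 1e-8, rate=16000)
        names, values = tonality_features(clip, frame_signal(clip))
        assert get(names, values, "freq.f0.mean") == 0.0
        assert get(names, values, "freq.hnr") == 0.0


class TestAutoregressive:
    def test_ar2_process_recovery(self):
        g = np.random.default_rng(7)
        x = np.zeros(4000)
        e = g.standard_normal(4000)
        for n in range(2, 4000):
            x[n] = 1.0 * x[n - 1] - 0.5 * x[n - 2] + e[n]
        a = lpc_coefficients(x, 2)
        assert a[0] == pytest.approx(-1.0, abs=0.1)
        assert a[1] == pytest.approx(0.5, abs=0.1)

    def test_white_noise_has_near_zero_coefficients(self):
        g = np.random.default_rng(11)
        a = lpc_coefficients(g.standard_normal(4000), 4)
        assert np.all(np.abs(a) < 0.1)

    @staticmethod
    def _stable_lpc(reflections):
        """Step-up recursion: reflection coefficients in (-1, 1) give a
        guaranteed minimum-phase error filter."""
        a = np.array([])
        for k in reflections:
            a = np.concatenate([a + k * a[::-1], [k]]) if a.size else np.array([k])
        return a

    def test_lsf_strictly_increasing_in_unit_interval(self, rng):
        for _ in range(20):
            order = int(rng.integers(4, 13))
            a = self._stable_lpc(rng.uniform(-0.9, 0.9, size=order))
            lsf = line_spectral_frequencies(a)
            assert lsf.size == order
            assert np.all(np.diff(lsf) > 0)
            assert np.all((lsf > 0) & (lsf < np.pi))

    def test_clip_level_vector_shape(self, tone_frames):
        names, values = autoregressive_features(tone_frames, order=12)
        assert len(names) == 24
        assert np.all(np.isfinite(values))

    def test_order_must_fit_frame(self, tone_frames):
        with pytest.raises(ValueError):
            autoregressive_features(tone_frames, order=tone_frames.frame_length)
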