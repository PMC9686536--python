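"""Audio I/O, high-pass filter design/application, windowing and framing."""

import numpy as np
import pytest
from scipy.io import wavfile

from chickcall.errors import EmptyInputError, FormatError, ParameterError
from chickcall.preprocess import (
    AudioClip,
    WindowSpec,
    apply_filter,
    design_highpass,
    frame_signal,
    make_window,
    minus3db_frequency,
    n_frames_for,
    read_wav,
    write_wav,
)

FS = 48_000


def sine(freq, duration_s=1.0, fs=FS, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return AudioClip(amp * np.sin(2 * np.pi * freq * t), sample_rate=fs)


class TestReadWriteWav:
    def test_constant_int16_scales_to_half(self, tmp_path):
        path = tmp_path / "const.wav"
        wavfile.write(path, FS, np.full(1000, 16384, dtype=np.int16))
        clip = read_wav(path)
        assert np.allclose(clip.samples, 0.5)
        assert clip.sample_rate == FS

    def test_silence_preserves_length_and_rate(self, tmp_path):
        path = tmp_path / "silence.wav"
        wavfile.write(path, FS, np.zeros(FS, dtype=np.int16))
        clip = read_wav(path)
        assert len(clip) == FS
        assert np.all(clip.samples == 0)

    def test_roundtrip_within_quantization(self, tmp_path, clean_recording):
        clip, _ = clean_recording
        path = tmp_path / "rt.wav"
        write_wav(path, clip)
        back = read_wav(path)
        assert len(back) == len(clip)
        assert np.max(np.abs(back.samples - clip.samples)) <= 1.0 / 2**15

    def test_unreadable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "not_audio.wav"
        bad.write_bytes(b"definitely not RIFF")
        with pytest.raises(FormatError):
            read_wav(bad)


class TestFilterDesign:
    def test_minus3db_at_cutoff(self, highpass):
        assert highpass.magnitude_db(1500.0) == pytest.approx(-3.0, abs=0.1)

    def test_dc_fully_rejected(self, highpass):
        assert highpass.magnitude_db(1e-6) < -200

    def test_stopband_attenuation_matches_butterworth_form(self, highpass):
        # analytic high-pass magnitude: 1/sqrt(1 + (fc/f)^(2N))
        analytic = 20 * np.log10(1.0 / np.sqrt(1.0 + (1500.0 / 500.0) ** 8))
        assert highpass.magnitude_db(500.0) <= -38.0
        assert highpass.magnitude_db(500.0) == pytest.approx(analytic, abs=0.2)

    def test_halfpower_frequency_located_at_cutoff(self, highpass):
        assert minus3db_frequency(highpass) == pytest.approx(1500.0, abs=1.0)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            design_highpass(30_000, 4, FS)

    @pytest.mark.parametrize("order", [2, 4, 6])
    def test_magnitude_monotone_below_nyquist(self, order):
        spec = design_highpass(1500.0, order, FS)
        freqs = np.linspace(10, FS / 2 - 10, 2000)
        _, mag = spec.frequency_response(freqs)
        assert np.all(np.diff(mag) > -1e-9)


class TestApplyFilter:
    def test_zero_in_zero_out(self, highpass):
        out = apply_filter(AudioClip(np.zeros(4096)), highpass)
        assert np.all(out.samples == 0)

    def test_stopband_sine_strongly_attenuated(self, highpass):
        out = apply_filter(sine(500.0), highpass)
        steady = out.samples[FS // 2 :]
        assert np.max(np.abs(steady)) <= 0.02

    def test_passband_sine_preserved(self, highpass):
        out = apply_filter(sine(5000.0), highpass)
        steady = out.samples[FS // 2 :]
        assert np.max(np.abs(steady)) >= 0.99

    def test_linearity(self, highpass):
        rng = np.random.default_rng(0)
        a = rng.normal(size=8192)
        b = rng.normal(size=8192)
        fa = apply_filter(AudioClip(a), highpass).samples
        fb = apply_filter(AudioClip(b), highpass).samples
        fab = apply_filter(AudioClip(a + b), highpass).samples
        assert np.max(np.abs(fab - (fa + fb))) < 1e-9

    def test_sample_rate_mismatch_rejected(self, highpass):
        with pytest.raises(ParameterError):
            apply_filter(AudioClip(np.zeros(100), sample_rate=44_100), highpass)


class TestWindows:
    def test_edge_values(self):
        assert make_window(WindowSpec(kind="hamming"))[0] == pytest.approx(0.08)
        assert make_window(WindowSpec(kind="hanning"))[0] == pytest.approx(0.0)

    def test_hann_peak_at_half_window(self):
        w = make_window(WindowSpec(1024, 128, "hanning"))
        assert w[512] == pytest.approx(1.0)

    def test_hann_symmetry(self):
        w = make_window(WindowSpec(1024, 128, "hanning"))
        assert np.max(np.abs(w[1:] - w[1:][::-1])) < 1e-12

    def test_window_duration_at_48k(self):
        spec = WindowSpec.for_sample_rate(FS)
        assert spec.length_samples == 1024
        assert spec.hop_samples == 128
        assert spec.length_samples / FS * 1000 == pytest.approx(21.3, abs=0.05)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError):
            WindowSpec(kind="blackman")


class TestFraming:
    @pytest.mark.parametrize(
        "n_samples,expected",
        [(4800, 30), (1024, 1), (16800, 124)],
    )
    def test_frame_counts(self, n_samples, expected, window):
        clip = AudioClip(np.zeros(n_samples))
        fm = frame_signal(clip, window)
        assert fm.n_frames == expected

    def test_frame_count_formula_exhaustive(self, window):
        signal = np.zeros(20_000)
        for length in range(1024, 20_001, 1):
            expected = (length - 1024) // 128 + 1
            assert n_frames_for(length, window) == expected
        # spot-check the formula against actual slicing on a spread of lengths
        for length in range(1024, 20_001, 97):
            fm = frame_signal(AudioClip(signal[:length]), window)
            assert fm.n_frames == (length - 1024) // 128 + 1

    def test_windowed_equals_raw_times_window(self, window, detected_call):
        fm = frame_signal(detected_call, window)
        w = make_window(window)
        assert np.allclose(fm.windowed_frames, fm.raw_frames * w)

    def test_frames_follow_hop_layout(self, window):
        x = np.arange(5000, dtype=float)
        fm = frame_signal(AudioClip(x / 5000), window)
        assert np.allclose(fm.raw_frames[3] * 5000, np.arange(3 * 128, 3 * 128 + 1024))

    def test_too_short_clip_rejected(self, window):
        with pytest.raises(EmptyInputError):
            frame_signal(AudioClip(np.zeros(1000)), window)
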