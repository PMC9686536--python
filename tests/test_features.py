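"""Feature computation against independent brute-force oracles."""

import numpy as np
import pytest

from chickcall.errors import ParameterError, ShapeError
from chickcall.features import (
    CEPSTRUM_KEEP,
    FEATURE_DIMS,
    FeatureMatrix,
    build_mel_bank,
    cepstrogram,
    cepstrum_transform,
    energy_spectrum,
    featurize,
    logfbank_mfcc,
    mel_of_hz,
    pad_to_fixed,
    spectrogram,
    to_db,
)
from chickcall.preprocess import AudioClip, WindowSpec, make_window

FS = 48_000


def brute_force_dft_modulus(frame):
    """Direct-summation one-sided DFT modulus (the defining formula)."""
    n = len(frame)
    bins = n // 2 + 1
    out = np.empty(bins)
    for b in range(bins):
        w = -2j * np.pi * b * np.arange(n) / n
        out[b] = np.abs(np.sum(frame * np.exp(w)))
    return out


def brute_force_cosine_transform(vec):
    """Double-loop evaluation of C(n) = 2/N sum_k v[k] cos(pi n (k+0.5)/N)."""
    n = len(vec)
    out = np.zeros(n)
    for c in range(n):
        acc = 0.0
        for k in range(n):
            acc += vec[k] * np.cos(np.pi * c * (k + 0.5) / n)
        out[c] = 2.0 / n * acc
    return out


class TestEnergySpectrum:
    def test_zero_frame(self):
        assert np.all(energy_spectrum(np.zeros(1024)) == 0)

    def test_unit_impulse_is_flat(self):
        frame = np.zeros(1024)
        frame[0] = 1.0
        assert np.allclose(energy_spectrum(frame), 1.0)

    def test_3khz_sine_peaks_at_bin_64(self):
        t = np.arange(1024) / FS
        frame = np.sin(2 * np.pi * 3000 * t) * make_window(WindowSpec())
        assert int(np.argmax(energy_spectrum(frame))) == 64

    def test_matches_direct_dft_definition(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            frame = rng.normal(size=1024)
            fast = energy_spectrum(frame)
            slow = brute_force_dft_modulus(frame)
            assert np.max(np.abs(fast - slow) / np.maximum(np.abs(slow), 1e-12)) < 1e-7

    def test_wrong_shape_rejected(self):
        with pytest.raises(ShapeError):
            energy_spectrum(np.zeros((2, 1024)))


class TestToDb:
    @pytest.mark.parametrize("energy,expected", [(1.0, 0.0), (100.0, 20.0)])
    def test_decade_scaling(self, energy, expected):
        assert to_db(np.array([energy]))[0] == pytest.approx(expected)

    def test_floor_clamps_zero_energy(self):
        assert to_db(np.array([0.0]), floor=1e-10)[0] == pytest.approx(-100.0)

    def test_nonpositive_floor_rejected(self):
        with pytest.raises(ParameterError):
            to_db(np.ones(3), floor=0.0)


class TestCepstrum:
    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            vec = rng.normal(size=97)
            assert np.max(np.abs(cepstrum_transform(vec) - brute_force_cosine_transform(vec))) < 1e-9

    def test_constant_spectrum_has_no_ripple_coefficients(self, detected_call):
        flat = np.full(513, -40.0)
        lo, hi = CEPSTRUM_KEEP
        kept = cepstrum_transform(flat)[lo:hi]
        assert np.max(np.abs(kept)) < 1e-6


class TestMelScale:
    def test_anchor_points(self):
        assert mel_of_hz(0.0) == pytest.approx(0.0)
        assert mel_of_hz(700.0) == pytest.approx(781.17, abs=0.01)

    def test_strictly_increasing(self):
        f = np.linspace(0, 24_000, 1000)
        assert np.all(np.diff(mel_of_hz(f)) > 0)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ParameterError):
            mel_of_hz(-1.0)


class TestMelBank:
    def test_shape_and_unit_peaks(self):
        bank = build_mel_bank()
        assert bank.filters.shape == (26, 513)
        assert np.all(bank.filters >= 0)
        assert np.allclose(bank.filters.max(axis=1), 1.0)

    def test_peak_bins_strictly_ordered(self):
        bank = build_mel_bank()
        peaks = bank.filters.argmax(axis=1)
        assert np.all(np.diff(peaks) > 0)

    def test_centers_equally_spaced_in_mel(self):
        bank = build_mel_bank()
        gaps = np.diff(mel_of_hz(bank.center_hz))
        assert np.max(np.abs(gaps - gaps[0])) < 1e-6

    def test_inconsistent_band_rejected(self):
        with pytest.raises(ParameterError):
            build_mel_bank(low_hz=30_000, high_hz=40_000)


class TestFeatureMatrices:
    @pytest.mark.parametrize("kind", list(FEATURE_DIMS))
    def test_canonical_shapes(self, kind, detected_call):
        feat = featurize(detected_call, kind)
        assert feat.values.shape == (110, FEATURE_DIMS[kind])
        assert np.isfinite(feat.values).all()

    def test_padding_rows_identical(self, detected_call, window):
        from chickcall.preprocess import n_frames_for

        n = n_frames_for(len(detected_call), window)
        assert n < 110
        feat = spectrogram(detected_call, window)
        pad_rows = feat.values[n:]
        assert np.all(pad_rows == pad_rows[0])
        assert np.allclose(pad_rows[0], -100.0)  # dB floor of a silent frame

    def test_spectrogram_tracks_planted_fundamental(self, detected_call, clean_recording, window):
        from chickcall.preprocess import n_frames_for

        _, truth = clean_recording
        f0 = truth.calls[0].fundamental_hz
        n = n_frames_for(len(detected_call), window)
        feat = spectrogram(detected_call, window)
        bin_hz = FS / 1024
        expected_bin = f0 / bin_hz
        argmax = feat.values[2 : n - 2].argmax(axis=1)
        assert np.median(np.abs(argmax - expected_bin)) <= 1.5

    def test_amplitude_scaling_shifts_db_spectrogram(self, detected_call, window):
        from chickcall.preprocess import n_frames_for

        n = n_frames_for(len(detected_call), window)
        base = spectrogram(detected_call, window).values[:n]
        for c in (0.5, 2.0):
            scaled_clip = AudioClip(detected_call.samples * c, detected_call.sample_rate)
            scaled = spectrogram(scaled_clip, window).values[:n]
            # modulus spectrum scales linearly in amplitude: dB shift 10*log10(c)
            mask = base > -95  # away from the floor clamp
            assert np.allclose((scaled - base)[mask], 10 * np.log10(c), atol=1e-6)

    def test_logfbank_exponentiates_back_to_mel_energies(self, detected_call, window):
        from chickcall.preprocess import n_frames_for

        from chickcall.preprocess import frame_signal

        bank = build_mel_bank()
        n = n_frames_for(len(detected_call), window)
        feat = logfbank_mfcc(detected_call, bank, window).values[:n]
        spectra = np.abs(np.fft.rfft(frame_signal(detected_call, window).windowed_frames, axis=1))
        mel_energies = spectra @ bank.filters.T
        recovered = 10.0 ** (feat[:, :26] / 10.0)
        rel = np.abs(recovered - mel_energies) / np.maximum(mel_energies, 1e-12)
        assert np.max(rel) < 1e-6

    def test_mfcc_block_is_cosine_transform_of_logfbank_block(self, detected_call):
        feat = logfbank_mfcc(detected_call).values
        for row in feat[::13]:
            assert np.max(np.abs(row[26:] - brute_force_cosine_transform(row[:26]))) < 1e-9

    def test_cepstrogram_keeps_coefficient_band(self, detected_call, window):
        from chickcall.preprocess import frame_signal, n_frames_for

        n = n_frames_for(len(detected_call), window)
        feat = cepstrogram(detected_call, window).values
        edb = to_db(np.abs(np.fft.rfft(frame_signal(detected_call, window).windowed_frames, axis=1)))
        full = np.stack([brute_force_cosine_transform(row) for row in edb[:3]])
        assert np.max(np.abs(feat[:3] - full[:, 5:165])) < 1e-9

    def test_unknown_kind_rejected(self, detected_call):
        with pytest.raises(ParameterError):
            featurize(detected_call, "chromagram")


class TestPadToFixed:
    def test_identity_at_target(self):
        x = np.random.default_rng(0).normal(size=(110, 4))
        assert np.array_equal(pad_to_fixed(x, 110, 0.0), x)

    def test_pad_row_count(self):
        x = np.zeros((30, 4))
        out = pad_to_fixed(x, 110, -1.0)
        assert out.shape == (110, 4)
        assert np.all(out[30:] == -1.0)

    def test_overlong_input_truncated_with_warning(self, caplog):
        import logging

        x = np.zeros((120, 4))
        with caplog.at_level(logging.WARNING, logger="chickcall.features"):
            out = pad_to_fixed(x, 110, 0.0)
        assert out.shape == (110, 4)
        assert any("truncating" in r.message for r in caplog.records)


def test_feature_matrix_validates_shape():
    with pytest.raises(ShapeError):
        FeatureMatrix(kind="spectrogram", values=np.zeros((110, 100)))
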