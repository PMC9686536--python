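"""Shared fixtures: windows, filters, and small synthetic recordings."""

import numpy as np
import pytest

from chickcall.detect import detect_in_clip, extract_call_audio
from chickcall.preprocess import WindowSpec, design_highpass
from chickcall.synth import CallParams, generate_recording


@pytest.fixture(scope="session")
def window():
    return WindowSpec()  # 1024 samples / hop 128 / Hann


@pytest.fixture(scope="session")
def highpass():
    return design_highpass(1500.0, 4, 48_000)


@pytest.fixture(scope="session")
def clean_recording():
    """One-bird, six-call recording with no noise, plus its ground truth."""
    clip, truth = generate_recording(
        n_chicks=1, calls_per_chick=6, gap_s=0.5, noise_level=0.0, seed=3
    )
    return clip, truth


@pytest.fixture(scope="session")
def detected_call(clean_recording):
    """Audio of the first detected call of the clean recording (denoised)."""
    clip, _ = clean_recording
    segments, filtered = detect_in_clip(clip)
    assert segments, "clean recording must contain detectable calls"
    return extract_call_audio(filtered, segments[0])


@pytest.fixture(scope="session")
def three_chirp_recording():
    """Three 0.2 s chirps separated by >= 0.5 s silence."""
    params = CallParams(duration_range=(0.2, 0.2))
    return generate_recording(
        n_chicks=1, calls_per_chick=3, gap_s=0.6, noise_level=0.0, seed=11, params=params
    )
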