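"""Synthetic chick-call recordings with exact ground truth.

Day-old chick distress calls are short (0.1-0.35 s) harmonic chirps with a
fundamental near 5 kHz and a band of formant energy up to ~16 kHz; recordings
in a sound-isolating box add only low-frequency (<1 kHz) handling noise, and
calls of one chick are highly similar while chicks differ from each other.

The generator reproduces exactly that statistical structure - a per-chick
fundamental offset (identity), an optional per-sex fundamental shift (the
controllable stand-in for the unknown real acoustic sex cue), harmonics, a
formant component, smooth onset/offset envelopes, and additive low-pass
noise - and emits the planted call extents both as sample ranges and as the
frame runs the ZCR detector is expected to report.

Call durations default to [0.1, 0.27] s: within the species' stated range,
and chosen so that every planted call maps inside the detector's 30-110-frame
duration gate under run-length accounting (a frame overlapping a call by only
a millisecond already exceeds the crossing threshold, so a detected run is
about seven frames longer than the call's own frame count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from chickcall.errors import ParameterError
from chickcall.preprocess import AudioClip, WindowSpec, write_wav

DEFAULT_SEX_OFFSET_HZ = 400.0
#: per-sex fundamental offsets of the three synthetic breeds, ordered from
#: most to least sex-separable (mirroring the TC > NC > FC ordering).
DEFAULT_BREED_PROFILES = {"A": 400.0, "B": 250.0, "C": 100.0}


@dataclass
class CallParams:
    """Knobs of one synthetic call family.

    Frequencies in Hz, durations in seconds, amplitudes on the [-1, 1] scale.
    """

    fundamental_hz: float = 5000.0
    formant_hz: float = 16000.0
    duration_range: tuple[float, float] = (0.10, 0.27)
    harmonics: tuple[float, ...] = (0.30, 0.10)  # relative amps of 2f0, 3f0
    formant_level: float = 0.35
    attack_s: float = 0.008
    decay_s: float = 0.015
    vibrato_hz: float = 15.0  # within-call fundamental drift amplitude
    amplitude: float = 0.7
    sex_offset_hz: float = DEFAULT_SEX_OFFSET_HZ  # added to cocks' fundamental
    chick_jitter_hz: float = 150.0  # per-chick identity offset, uniform +-
    sample_rate: int = 48_000

    def __post_init__(self):
        lo, hi = self.duration_range
        if not 0.1 - 1e-9 <= lo <= hi <= 0.35 + 1e-9:
            raise ParameterError("duration_range must lie within [0.1, 0.35] s")
        nyq = self.sample_rate / 2
        top = (self.fundamental_hz + abs(self.sex_offset_hz) + self.chick_jitter_hz
               + self.vibrato_hz) * (1 + len(self.harmonics))
        if self.formant_hz >= nyq or top >= nyq:
            raise ParameterError("call components must stay below Nyquist")


@dataclass
class PlantedCall:
    """Ground truth for one synthesized call."""

    chick_id: str
    sex: str
    fundamental_hz: float
    start_sample: int
    end_sample: int
    start_frame: int  # expected detected run, default detector/window
    end_frame: int


@dataclass
class GroundTruth:
    """Everything the generator knows about a recording."""

    calls: list[PlantedCall]
    sample_rate: int
    noise_level: float = 0.0
    noise_cutoff_hz: float = 1000.0


def _expected_run(
    start_sample: int,
    end_sample: int,
    fundamental_hz: float,
    window: WindowSpec,
    zcr_threshold: float = 10.0,
    sample_rate: int = 48_000,
) -> tuple[int, int]:
    """Frame run the ZCR detector should report for a planted call.

    A frame is active once its overlap with the call supplies more than
    ``zcr_threshold`` crossings, i.e. overlap o with 2*f0*o/fs > threshold.
    """
    o_min = math.ceil((zcr_threshold + 1) * sample_rate / (2.0 * fundamental_hz))
    hop, length = window.hop_samples, window.length_samples
    f_start = max(0, math.ceil((start_sample + o_min - length) / hop))
    f_end_incl = math.floor((end_sample - o_min) / hop)
    return f_start, f_end_incl + 1


def generate_call(
    params: CallParams,
    rng: np.random.Generator,
    sex: str = "hen",
    chick_offset_hz: float = 0.0,
    duration_s: float | None = None,
) -> AudioClip:
    """Synthesize one call: harmonic chirp + formant band, smooth envelope."""
    if sex not in ("cock", "hen"):
        raise ParameterError(f"sex must be 'cock' or 'hen', got {sex!r}")
    fs = params.sample_rate
    if duration_s is None:
        duration_s = rng.uniform(*params.duration_range)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    f0 = params.fundamental_hz + chick_offset_hz
    if sex == "cock":
        f0 += params.sex_offset_hz
    # slow within-call drift, bounded by vibrato_hz
    drift = params.vibrato_hz * rng.uniform(-1.0, 1.0)
    inst_freq = f0 + drift * np.linspace(-1.0, 1.0, n)
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / fs

    wave = np.sin(phase)
    for h, amp in enumerate(params.harmonics, start=2):
        wave += amp * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    formant_f = params.formant_hz + rng.uniform(-300.0, 300.0)
    wave += params.formant_level * np.sin(2.0 * np.pi * formant_f * t + rng.uniform(0, 2 * np.pi))

    env = np.ones(n)
    na = min(n // 2, int(params.attack_s * fs))
    nd = min(n - na, int(params.decay_s * fs))
    if na > 0:
        env[:na] = 0.5 * (1.0 - np.cos(np.pi * np.arange(na) / na))
    if nd > 0:
        env[-nd:] = 0.5 * (1.0 + np.cos(np.pi * np.arange(nd) / nd))
    wave *= env

    peak = params.amplitude * rng.uniform(0.9, 1.0)
    wave *= peak / np.max(np.abs(wave))
    return AudioClip(samples=wave, sample_rate=fs, source_id=f"call_{sex}")


def _lowpass_noise(
    n: int, level: float, cutoff_hz: float, rng: np.random.Generator, fs: int
) -> np.ndarray:
    """Additive handling/movement noise: white noise low-passed below cutoff."""
    if level <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    # steep roll-off keeps the noise genuinely below the cutoff
    sos = sp_signal.butter(10, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    shaped = sp_signal.sosfilt(sos, white)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped * (level / rms)


def generate_recording(
    n_chicks: int = 1,
    calls_per_chick: int = 5,
    gap_s: float = 0.5,
    noise_level: float = 0.0,
    noise_cutoff_hz: float = 1000.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    params: CallParams | None = None,
    source_id: str = "synthetic",
    sexes: list[str] | None = None,
) -> tuple[AudioClip, GroundTruth]:
    """One continuous recording with planted calls and silent gaps.

    Chicks alternate cock/hen unless ``sexes`` names one sex per chick.  Each
    chick keeps a fixed fundamental offset (identity); calls of all chicks are
    interleaved in chick order.
    """
    if n_chicks < 1 or calls_per_chick < 1 or gap_s <= 0:
        raise ParameterError("n_chicks, calls_per_chick and gap_s must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    if params is None:
        params = CallParams()
    if sexes is None:
        sexes = ["cock" if i % 2 == 0 else "hen" for i in range(n_chicks)]
    if len(sexes) != n_chicks:
        raise ParameterError("sexes must name one sex per chick")
    fs = params.sample_rate
    window = WindowSpec()
    offsets = {i: rng.uniform(-params.chick_jitter_hz, params.chick_jitter_hz)
               for i in range(n_chicks)}

    pieces, planted = [], []
    cursor = int(round(gap_s * fs))
    pieces.append(np.zeros(cursor))
    for k in range(calls_per_chick):
        for i in range(n_chicks):
            sex = sexes[i]
            call = generate_call(params, rng, sex=sex, chick_offset_hz=offsets[i])
            start, end = cursor, cursor + len(call)
            f0 = params.fundamental_hz + offsets[i] + (params.sex_offset_hz if sex == "cock" else 0.0)
            fa, fb = _expected_run(start, end, f0, window, sample_rate=fs)
            planted.append(PlantedCall(
                chick_id=f"chick{i:03d}", sex=sex, fundamental_hz=f0,
                start_sample=start, end_sample=end, start_frame=fa, end_frame=fb,
            ))
            pieces.append(call.samples)
            gap = int(round(gap_s * fs * rng.uniform(0.9, 1.3)))
            pieces.append(np.zeros(gap))
            cursor = end + gap
    samples = np.concatenate(pieces)
    samples = samples + _lowpass_noise(len(samples), noise_level, noise_cutoff_hz, rng, fs)
    clip = AudioClip(samples=samples, sample_rate=fs, source_id=source_id)
    truth = GroundTruth(calls=planted, sample_rate=fs,
                        noise_level=noise_level, noise_cutoff_hz=noise_cutoff_hz)
    return clip, truth


@dataclass
class StudyChick:
    """One synthetic bird: identity, labels, its recording and ground truth."""

    chick_id: str
    breed: str
    sex: str
    clip: AudioClip
    truth: GroundTruth
    wav_path: Path | None = None


def generate_study(
    n_chicks_per_sex: int,
    breed_profiles: dict[str, float] | None = None,
    calls_per_chick: int = 45,
    gap_s: float = 0.18,
    noise_level: float = 0.0,
    seed: int | None = None,
    params: CallParams | None = None,
    out_dir=None,
) -> tuple[list[StudyChick], pd.DataFrame]:
    """Per-bird recordings plus a metadata table, mirroring the field protocol.

    ``breed_profiles`` maps a synthetic breed name to its per-sex fundamental
    offset (Hz); the default three breeds are ordered from well-separated to
    barely-separated sexes.  Each bird gets its own recording with at least
    41 detectable calls (default 45).  With ``out_dir`` set, recordings are
    also written as 16-bit/48 kHz WAV files.
    """
    if n_chicks_per_sex < 2:
        raise ParameterError("need at least 2 chicks per sex for leakage-safe splits")
    if breed_profiles is None:
        breed_profiles = dict(DEFAULT_BREED_PROFILES)
    if params is None:
        params = CallParams()
    root = np.random.default_rng(seed)
    chicks: list[StudyChick] = []
    rows = []
    idx = 0
    for breed, offset in breed_profiles.items():
        breed_params = replace(params, sex_offset_hz=float(offset))
        for sex in ("cock", "hen"):
            for _ in range(n_chicks_per_sex):
                chick_id = f"{breed}_{sex}_{idx:03d}"
                rng = np.random.default_rng(root.integers(0, 2**31 - 1))
                clip, truth = generate_recording(
                    n_chicks=1, calls_per_chick=calls_per_chick, gap_s=gap_s,
                    noise_level=noise_level, rng=rng, params=breed_params,
                    source_id=chick_id, sexes=[sex],
                )
                for c in truth.calls:
                    c.chick_id = chick_id
                wav_path = None
                if out_dir is not None:
                    wav_path = Path(out_dir) / f"{chick_id}.wav"
                    wav_path.parent.mkdir(parents=True, exist_ok=True)
                    write_wav(wav_path, clip)
                chicks.append(StudyChick(chick_id, breed, sex, clip, truth, wav_path))
                rows.append({
                    "chick_id": chick_id, "breed": breed, "sex": sex,
                    "wav": str(wav_path) if wav_path else "",
                    "n_calls": len(truth.calls),
                })
                idx += 1
    return chicks, pd.DataFrame(rows)


def truth_to_table(truth: GroundTruth) -> pd.DataFrame:
    return pd.DataFrame([{
        "chick_id": c.chick_id, "sex": c.sex, "fundamental_hz": c.fundamental_hz,
        "start_sample": c.start_sample, "end_sample": c.end_sample,
        "start_frame": c.start_frame, "end_frame": c.end_frame,
    } for c in truth.calls])
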