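"""Audio input, high-pass denoising and short-time framing.

Recordings are mono PCM WAV at 48 kHz / 16-bit (the field protocol).  Handling
and movement noise sits below ~1000 Hz while chick calls live above ~1500 Hz,
so denoising is a causal Butterworth high-pass IIR filter with its -3 dB point
at 1500 Hz.  Short-time analysis uses 1024-sample windows (21.3 ms at 48 kHz)
hopped by 1/8 window, with a periodic Hann taper for spectral work.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from scipy.io import wavfile

from chickcall.errors import EmptyInputError, FormatError, ParameterError

log = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 48_000
WINDOW_MS = 21.3  # nominal analysis-window duration


@dataclass
class AudioClip:
    """A sampled waveform on the [-1, 1] full-scale convention."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    source_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ParameterError(f"sample_rate must be positive, got {self.sample_rate}")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate


@dataclass
class FilterSpec:
    """Designed high-pass IIR filter: y(n) = sum_i a_i y(n-i) + sum_j b_j x(n-j)."""

    cutoff_hz: float
    order: int
    sample_rate: int
    b_coeffs: np.ndarray
    a_coeffs: np.ndarray

    def frequency_response(self, freqs_hz: np.ndarray | None = None, n: int = 8192):
        """Return (freqs_hz, |H|) of the filter's magnitude response."""
        if freqs_hz is None:
            w, h = signal.freqz(self.b_coeffs, self.a_coeffs, worN=n, fs=self.sample_rate)
        else:
            w, h = signal.freqz(
                self.b_coeffs, self.a_coeffs, worN=np.asarray(freqs_hz, dtype=float),
                fs=self.sample_rate,
            )
        return w, np.abs(h)

    def magnitude_db(self, freq_hz: float) -> float:
        """Magnitude response at one frequency, in dB (20*log10|H|)."""
        _, mag = self.frequency_response(np.array([freq_hz]))
        m = float(mag[0])
        return -np.inf if m == 0.0 else 20.0 * np.log10(m)


@dataclass
class WindowSpec:
    """Short-time analysis geometry: window length, hop, and taper kind."""

    length_samples: int = 1024
    hop_samples: int = 128
    kind: str = "hanning"

    def __post_init__(self):
        if self.length_samples < 2:
            raise ParameterError("window length must be >= 2 samples")
        if self.hop_samples < 1:
            raise ParameterError("hop must be >= 1 sample")
        if self.kind not in ("hanning", "hamming", "rectangular"):
            raise ParameterError(f"unknown window kind {self.kind!r}")

    @classmethod
    def for_sample_rate(cls, sample_rate: int, kind: str = "hanning") -> "WindowSpec":
        """Window of ~21.3 ms rounded to a multiple of 8 samples, hop = length/8.

        At 48 kHz this is exactly the canonical 1024-sample window with a
        128-sample hop (21.33 ms).
        """
        length = 8 * max(1, int(round(WINDOW_MS * 1e-3 * sample_rate / 8)))
        return cls(length_samples=length, hop_samples=max(1, length // 8), kind=kind)


@dataclass
class FrameMatrix:
    """Frames laid out row-wise; raw view plus window-tapered view.

    ``raw_frames`` is a read-only strided view into the signal (no copy), so
    full two-minute recordings frame cheaply; the tapered view materializes on
    first access.
    """

    raw_frames: np.ndarray
    spec: WindowSpec
    sample_rate: int
    window: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.window is None:
            self.window = make_window(self.spec)

    @property
    def n_frames(self) -> int:
        return self.raw_frames.shape[0]

    @cached_property
    def windowed_frames(self) -> np.ndarray:
        return self.raw_frames * self.window


def read_wav(path, channel: int = 0) -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip` normalized to [-1, 1].

    Integer PCM is scaled by 2**(bits-1); float WAV is taken as-is.
    Multi-channel files are reduced to ``channel`` with a logged warning.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # chunk warnings from odd encoders
            rate, data = wavfile.read(path)
    except (ValueError, FileNotFoundError, OSError) as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        log.warning("%s has %d channels; using channel %d", path, data.shape[1], channel)
        data = data[:, channel]
    if data.size == 0:
        raise EmptyInputError(f"{path} contains no audio samples")
    if data.dtype == np.int16:
        samples = data / 2.0**15
    elif data.dtype == np.int32:
        samples = data / 2.0**31
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"unsupported WAV sample dtype {data.dtype} in {path}")
    return AudioClip(samples=samples, sample_rate=int(rate), source_id=path.stem)


def write_wav(path, clip: AudioClip) -> None:
    """Write an :class:`AudioClip` as 16-bit PCM WAV (full scale = |1.0|)."""
    scaled = np.round(np.clip(clip.samples, -1.0, 1.0) * 2.0**15)
    pcm = np.clip(scaled, -(2.0**15), 2.0**15 - 1).astype(np.int16)
    wavfile.write(Path(path), clip.sample_rate, pcm)


def design_highpass(
    cutoff_hz: float = 1500.0,
    order: int = 4,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> FilterSpec:
    """Design the Butterworth high-pass denoising filter.

    The Butterworth design places the half-power (-3 dB) point exactly at
    ``cutoff_hz`` for every order, which is the one constraint the recording
    protocol fixes.
    """
    if not 0 < cutoff_hz < sample_rate / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={sample_rate / 2} Hz)"
        )
    if order < 1:
        raise ParameterError("filter order must be >= 1")
    b, a = signal.butter(order, cutoff_hz, btype="highpass", fs=sample_rate)
    return FilterSpec(
        cutoff_hz=float(cutoff_hz), order=int(order), sample_rate=int(sample_rate),
        b_coeffs=np.asarray(b), a_coeffs=np.asarray(a),
    )


def minus3db_frequency(spec: FilterSpec) -> float:
    """Locate the half-power frequency: where |H(f)| crosses 1/sqrt(2).

    Measured from the realized coefficients (not assumed from the design
    request), by bisection on a dense magnitude-response grid.
    """
    from scipy.optimize import brentq

    target = 1.0 / np.sqrt(2.0)

    def gain_minus_target(f):
        _, mag = spec.frequency_response(np.array([f]))
        return float(mag[0]) - target

    nyq = spec.sample_rate / 2.0
    freqs = np.linspace(1.0, nyq - 1.0, 4096)
    _, mags = spec.frequency_response(freqs)
    above = mags >= target
    idx = int(np.argmax(above))  # first grid point at/above half power
    if idx == 0:
        raise ParameterError("magnitude response never crosses -3 dB inside (0, Nyquist)")
    return float(brentq(gain_minus_target, freqs[idx - 1], freqs[idx], xtol=1e-6))


def apply_filter(clip: AudioClip, spec: FilterSpec) -> AudioClip:
    """Run the causal single-pass IIR recursion over the clip.

    Single-pass (not forward-backward): zero-phase filtering would square the
    magnitude response and move the -3 dB point off the designed cutoff.
    """
    if spec.sample_rate != clip.sample_rate:
        raise ParameterError(
            f"filter designed for {spec.sample_rate} Hz, clip is {clip.sample_rate} Hz"
        )
    filtered = signal.lfilter(spec.b_coeffs, spec.a_coeffs, clip.samples)
    return AudioClip(samples=filtered, sample_rate=clip.sample_rate, source_id=clip.source_id)


def make_window(spec: WindowSpec) -> np.ndarray:
    """Evaluate the taper at n = 0..M-1 with divisor M (periodic form).

    Hamming: w(n) = 0.54 - 0.46 cos(2 pi n / M)   -> w(0) = 0.08
    Hann:    w(n) = 0.50 - 0.50 cos(2 pi n / M)   -> w(0) = 0
    """
    m = spec.length_samples
    n = np.arange(m)
    if spec.kind == "hamming":
        return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / m)
    if spec.kind == "hanning":
        return 0.5 - 0.5 * np.cos(2.0 * np.pi * n / m)
    if spec.kind == "rectangular":
        return np.ones(m)
    raise ParameterError(f"unknown window kind {spec.kind!r}")


def n_frames_for(length: int, spec: WindowSpec) -> int:
    """floor((L - M)/hop) + 1 for L >= M, else 0."""
    if length < spec.length_samples:
        return 0
    return (length - spec.length_samples) // spec.hop_samples + 1


def frame_signal(clip: AudioClip, spec: WindowSpec | None = None) -> FrameMatrix:
    """Slice the clip into overlapping frames (trailing remainder dropped)."""
    if spec is None:
        spec = WindowSpec.for_sample_rate(clip.sample_rate)
    n = n_frames_for(len(clip), spec)
    if n == 0:
        raise EmptyInputError(
            f"clip of {len(clip)} samples is shorter than one "
            f"{spec.length_samples}-sample window"
        )
    raw = sliding_window_view(clip.samples, spec.length_samples)[:: spec.hop_samples]
    raw = raw[:n]
    return FrameMatrix(raw_frames=raw, spec=spec, sample_rate=clip.sample_rate)
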