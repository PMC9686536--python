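"""Per-call time-frequency features: spectrogram, cepstrogram, MFCC+Logfbank.

All three features start from the same short-time front end (1024-sample Hann
frames, hop 128).  Per frame:

* energy spectrum  E(n)  = |DFT_1024(y)| on the one-sided 513 bins;
* dB spectrum      EdB(n) = 10 * log10(E(n))   (floored at 1e-10);
* cepstrum         C(n)  = 2/N * sum_k EdB(k) * cos(pi*n*(k+0.5)/N), N = 513
  (the DCT-II of the dB spectrum), of which coefficients [5, 165) are kept
  (160 values);
* Mel energies through a 26-channel triangular filter bank on the Mel scale
  M(f) = 2595 * log10(1 + f/700), log-scaled to the 26-dim Logfbank, whose
  26-coefficient cosine transform (same normalization as the cepstrum, N = 26)
  is the MFCC; Logfbank || MFCC gives the 52-dim combined feature.

Calls vary in length (30-110 frames), so matrices are padded row-wise to a
fixed 110 frames with the feature of a silent frame, yielding the canonical
shapes 110x513, 110x160 and 110x52.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from chickcall.detect import CallSegment
from chickcall.errors import ParameterError, ShapeError
from chickcall.preprocess import AudioClip, WindowSpec, frame_signal

log = logging.getLogger(__name__)

TARGET_FRAMES = 110
DB_FLOOR = 1e-10
CEPSTRUM_KEEP = (5, 165)  # half-open coefficient band -> 160 values
N_MEL_FILTERS = 26

FEATURE_KINDS = ("spectrogram", "cepstrogram", "mfcc_logfbank")
FEATURE_DIMS = {"spectrogram": 513, "cepstrogram": 160, "mfcc_logfbank": 52}


@dataclass
class FeatureMatrix:
    """Fixed-shape (110 x D) representation of one call."""

    kind: str
    values: np.ndarray
    call_ref: CallSegment | None = None

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ParameterError(f"unknown feature kind {self.kind!r}")
        expected = FEATURE_DIMS[self.kind]
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ShapeError(
                f"{self.kind} matrix must be T x {expected}, got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ShapeError(f"{self.kind} matrix contains non-finite entries")


@dataclass
class MelFilterBank:
    """Triangular unit-peak filters equally spaced on the Mel scale.

    ``center_hz`` holds the exact equally-Mel-spaced center frequencies;
    the triangles themselves are laid out on the nearest FFT bins so each
    row peaks at exactly 1.
    """

    n_filters: int
    filters: np.ndarray  # n_filters x n_bins, all >= 0
    low_hz: float
    high_hz: float
    center_hz: np.ndarray


def energy_spectrum(windowed_frame: np.ndarray, n_fft: int | None = None) -> np.ndarray:
    """One-sided DFT modulus of one frame (modulus, not power)."""
    frame = np.asarray(windowed_frame, dtype=np.float64)
    if frame.ndim != 1:
        raise ShapeError(f"expected a 1-D frame, got shape {frame.shape}")
    n = n_fft if n_fft is not None else frame.shape[0]
    if frame.shape[0] != n:
        raise ShapeError(f"frame length {frame.shape[0]} != expected {n}")
    return np.abs(np.fft.rfft(frame, n=n))


def to_db(energy: np.ndarray, floor: float = DB_FLOOR) -> np.ndarray:
    """Linear -> dB scale: 10 * log10(max(E, floor))."""
    if floor <= 0:
        raise ParameterError("dB floor must be positive")
    return 10.0 * np.log10(np.maximum(np.asarray(energy, dtype=np.float64), floor))


@lru_cache(maxsize=8)
def _cosine_basis(n: int) -> np.ndarray:
    """DCT-II basis B[c, k] = cos(pi * c * (k + 0.5) / n), c,k = 0..n-1."""
    c = np.arange(n)[:, None]
    k = np.arange(n)[None, :]
    return np.cos(np.pi * c * (k + 0.5) / n)


def cepstrum_transform(db_spectrum: np.ndarray) -> np.ndarray:
    """Cosine transform of a dB spectrum row (or rows): 2/N * EdB @ B.T."""
    x = np.atleast_2d(np.asarray(db_spectrum, dtype=np.float64))
    n = x.shape[1]
    out = (2.0 / n) * x @ _cosine_basis(n).T
    return out[0] if np.asarray(db_spectrum).ndim == 1 else out


def mel_of_hz(f) -> np.ndarray:
    """Mel scale: M(f) = 2595 * log10(1 + f/700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ParameterError("frequency must be >= 0")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def hz_of_mel(m) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def build_mel_bank(
    n_filters: int = N_MEL_FILTERS,
    low_hz: float = 0.0,
    high_hz: float | None = None,
    sample_rate: int = 48_000,
    n_bins: int = 513,
) -> MelFilterBank:
    """26-channel triangular Mel bank evaluated on the FFT-bin grid.

    Edge/center frequencies are n_filters + 2 points equally spaced in Mel
    between low_hz and high_hz; triangles rise/fall linearly between the
    FFT bins nearest those points, with unit peak.
    """
    nyquist = sample_rate / 2.0
    if high_hz is None:
        high_hz = nyquist
    if n_filters < 1:
        raise ParameterError("need at least one Mel filter")
    if not 0 <= low_hz < high_hz <= nyquist:
        raise ParameterError(
            f"band [{low_hz}, {high_hz}] Hz inconsistent with Nyquist {nyquist} Hz"
        )
    n_fft = 2 * (n_bins - 1)
    mel_points = np.linspace(mel_of_hz(low_hz), mel_of_hz(high_hz), n_filters + 2)
    hz_points = hz_of_mel(mel_points)
    bins = np.floor((n_fft + 1) * hz_points / sample_rate).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    filters = np.zeros((n_filters, n_bins))
    for j in range(n_filters):
        left, center, right = bins[j], bins[j + 1], bins[j + 2]
        if not left < center < right:
            raise ParameterError(
                f"Mel filter {j} degenerates on the FFT grid "
                f"(bins {left}, {center}, {right}); widen the band or reduce n_filters"
            )
        k = np.arange(left, center)
        filters[j, k] = (k - left) / (center - left)
        k = np.arange(center, right + 1)
        filters[j, k] = (right - k) / (right - center)
        filters[j, center] = 1.0
    return MelFilterBank(
        n_filters=n_filters, filters=filters,
        low_hz=float(low_hz), high_hz=float(high_hz),
        center_hz=hz_points[1:-1].copy(),
    )


def _frame_spectra(call: AudioClip, window: WindowSpec | None) -> np.ndarray:
    if window is None:
        window = WindowSpec.for_sample_rate(call.sample_rate)
    frames = frame_signal(call, window)
    return np.abs(np.fft.rfft(frames.windowed_frames, axis=1))


def silence_row(kind: str, bank: MelFilterBank | None = None, n_bins: int = 513) -> np.ndarray:
    """The feature of an all-zero frame - used as the padding row."""
    edb = to_db(np.zeros(n_bins))
    if kind == "spectrogram":
        return edb
    if kind == "cepstrogram":
        lo, hi = CEPSTRUM_KEEP
        return cepstrum_transform(edb)[lo:hi]
    if kind == "mfcc_logfbank":
        n = bank.n_filters if bank is not None else N_MEL_FILTERS
        logfbank = to_db(np.zeros(n))
        return np.concatenate([logfbank, cepstrum_transform(logfbank)])
    raise ParameterError(f"unknown feature kind {kind!r}")


def pad_to_fixed(
    frames_matrix: np.ndarray,
    target_frames: int = TARGET_FRAMES,
    pad_value=None,
) -> np.ndarray:
    """Pad (or, with a warning, truncate) rows to ``target_frames``.

    ``pad_value`` may be a scalar or a row vector; every appended row is
    identical, so the padded region carries no signal.
    """
    x = np.asarray(frames_matrix, dtype=np.float64)
    t, d = x.shape
    if t > target_frames:
        log.warning("truncating %d-frame feature matrix to %d frames", t, target_frames)
        return x[:target_frames].copy()
    if t == target_frames:
        return x.copy()
    if pad_value is None:
        pad_value = x.min()
    row = np.broadcast_to(np.asarray(pad_value, dtype=np.float64), (d,))
    return np.vstack([x, np.tile(row, (target_frames - t, 1))])


def spectrogram(
    call: AudioClip,
    window: WindowSpec | None = None,
    call_ref: CallSegment | None = None,
) -> FeatureMatrix:
    """dB-scale spectrogram of one call, padded to 110 x 513."""
    edb = to_db(_frame_spectra(call, window))
    values = pad_to_fixed(edb, pad_value=silence_row("spectrogram", n_bins=edb.shape[1]))
    return FeatureMatrix(kind="spectrogram", values=values, call_ref=call_ref)


def cepstrogram(
    call: AudioClip,
    window: WindowSpec | None = None,
    call_ref: CallSegment | None = None,
    keep: tuple[int, int] = CEPSTRUM_KEEP,
) -> FeatureMatrix:
    """Cepstrogram of one call: coefficient band [5, 165), padded to 110 x 160."""
    edb = to_db(_frame_spectra(call, window))
    lo, hi = keep
    ceps = cepstrum_transform(edb)[:, lo:hi]
    pad = cepstrum_transform(to_db(np.zeros(edb.shape[1])))[lo:hi]
    values = pad_to_fixed(ceps, pad_value=pad)
    return FeatureMatrix(kind="cepstrogram", values=values, call_ref=call_ref)


def logfbank_mfcc(
    call: AudioClip,
    bank: MelFilterBank | None = None,
    window: WindowSpec | None = None,
    call_ref: CallSegment | None = None,
) -> FeatureMatrix:
    """Combined Logfbank || MFCC feature of one call, padded to 110 x 52."""
    spectra = _frame_spectra(call, window)
    if bank is None:
        bank = build_mel_bank(sample_rate=call.sample_rate, n_bins=spectra.shape[1])
    mfe = spectra @ bank.filters.T
    logfbank = to_db(mfe)
    mfcc = cepstrum_transform(logfbank)
    combined = np.hstack([logfbank, mfcc])
    values = pad_to_fixed(combined, pad_value=silence_row("mfcc_logfbank", bank=bank))
    return FeatureMatrix(kind="mfcc_logfbank", values=values, call_ref=call_ref)


def featurize(
    call: AudioClip,
    kind: str,
    window: WindowSpec | None = None,
    bank: MelFilterBank | None = None,
    call_ref: CallSegment | None = None,
) -> FeatureMatrix:
    """Dispatch on feature kind."""
    if kind == "spectrogram":
        return spectrogram(call, window, call_ref)
    if kind == "cepstrogram":
        return cepstrogram(call, window, call_ref)
    if kind == "mfcc_logfbank":
        return logfbank_mfcc(call, bank, window, call_ref)
    raise ParameterError(f"unknown feature kind {kind!r}")


def save_feature_archive(path, features: list[FeatureMatrix], names: list[str]) -> None:
    """Write features as an .npz (one array per call) + a .manifest.tsv."""
    path = Path(path)
    np.savez_compressed(path, **{n: f.values for n, f in zip(names, features)})
    manifest = pd.DataFrame(
        {"name": names, "kind": [f.kind for f in features],
         "n_frames": [f.values.shape[0] for f in features]}
    )
    manifest.to_csv(path.with_suffix(".manifest.tsv"), sep="\t", index=False)


def load_feature_archive(path) -> dict[str, np.ndarray]:
    with np.load(Path(path)) as z:
        return {k: z[k] for k in z.files}
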