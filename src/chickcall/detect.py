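"""Call endpoint detection by short-time zero-crossing rate (ZCR).

Chick distress calls carry a ~5 kHz fundamental, so frames containing a call
show hundreds of zero crossings while silence shows essentially none; a low
per-frame crossing threshold separates the two.  Candidate runs of
above-threshold frames are then gated by duration: calls last roughly
0.1-0.35 s, which the detector expresses as a 30-110 frame band.

Crossings are "true" crossings: samples with magnitude at or below a small
offset are treated as idle-channel noise and skipped, and a crossing is
counted when the sign of the last significant sample flips.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from chickcall.errors import BoundsError, ParameterError
from chickcall.preprocess import (
    AudioClip,
    FrameMatrix,
    WindowSpec,
    apply_filter,
    design_highpass,
    frame_signal,
)


@dataclass
class DetectorConfig:
    """ZCR endpoint-detector thresholds.

    zcr_threshold : crossings per analysis frame a frame must exceed to count
        as voiced (default 10 - far below the ~213 crossings a full frame of a
        5 kHz call produces, far above silence).
    min_frames / max_frames : duration gate T1/T2 on the detected run length.
    offset : full-scale amplitude below which samples are ignored when
        counting crossings.
    """

    zcr_threshold: float = 10.0
    min_frames: int = 30
    max_frames: int = 110
    offset: float = 0.01

    def __post_init__(self):
        if not 0 < self.min_frames <= self.max_frames:
            raise ParameterError("need 0 < min_frames <= max_frames")
        if self.zcr_threshold < 0 or self.offset < 0:
            raise ParameterError("zcr_threshold and offset must be >= 0")


@dataclass
class CallSegment:
    """One detected call; frame indices are 0-based and half-open."""

    start_frame: int
    end_frame: int
    start_sample: int
    end_sample: int
    source_id: str = ""

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame

    @classmethod
    def from_frames(
        cls, start_frame: int, end_frame: int, spec: WindowSpec, source_id: str = ""
    ) -> "CallSegment":
        """Frame run -> sample extent: the samples its frames cover."""
        start_sample = start_frame * spec.hop_samples
        end_sample = (end_frame - 1) * spec.hop_samples + spec.length_samples
        return cls(start_frame, end_frame, start_sample, end_sample, source_id)


def short_time_zcr(frames: FrameMatrix, offset: float = 0.01) -> np.ndarray:
    """Offset-gated zero-crossing count per frame (on the untapered frames).

    Samples with |s| <= offset are skipped; the count is the number of sign
    flips along each frame's remaining samples.  Vectorized by forward-filling
    the sign of the last significant sample.
    """
    x = frames.raw_frames
    if x.shape[0] == 0:
        return np.zeros(0, dtype=np.int64)
    sign = np.where(x > offset, 1, np.where(x < -offset, -1, 0)).astype(np.int8)
    # forward-fill nonzero signs within each frame
    idx = np.where(sign != 0, np.arange(sign.shape[1])[None, :], 0)
    np.maximum.accumulate(idx, axis=1, out=idx)
    filled = np.take_along_axis(sign, idx, axis=1)
    # a flip shows as a -1 product between consecutive filled signs
    return np.count_nonzero(filled[:, 1:] * filled[:, :-1] == -1, axis=1).astype(np.int64)


def detect_calls(
    zcr_sequence: np.ndarray,
    config: DetectorConfig | None = None,
    window: WindowSpec | None = None,
    source_id: str = "",
) -> list[CallSegment]:
    """Gate maximal above-threshold ZCR runs into call segments.

    A run opens at the first frame strictly above ``zcr_threshold`` and closes
    before the next frame at/below it; runs shorter than T1 frames or longer
    than T2 frames are discarded.
    """
    if config is None:
        config = DetectorConfig()
    if window is None:
        window = WindowSpec()
    z = np.asarray(zcr_sequence)
    active = z > config.zcr_threshold
    if not active.any():
        return []
    padded = np.concatenate(([False], active, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    segments = []
    for s, e in zip(starts, ends):
        dur = e - s
        if config.min_frames <= dur <= config.max_frames:
            segments.append(CallSegment.from_frames(int(s), int(e), window, source_id))
    return segments


def extract_call_audio(clip: AudioClip, segment: CallSegment) -> AudioClip:
    """Cut the segment's sample extent out of the clip."""
    if not (0 <= segment.start_sample < segment.end_sample <= len(clip)):
        raise BoundsError(
            f"segment [{segment.start_sample}, {segment.end_sample}) outside "
            f"clip of {len(clip)} samples"
        )
    sid = segment.source_id or clip.source_id
    return AudioClip(
        samples=clip.samples[segment.start_sample : segment.end_sample].copy(),
        sample_rate=clip.sample_rate,
        source_id=f"{sid}[{segment.start_frame}:{segment.end_frame}]",
    )


def detect_in_clip(
    clip: AudioClip,
    config: DetectorConfig | None = None,
    window: WindowSpec | None = None,
    highpass=True,
) -> tuple[list[CallSegment], AudioClip]:
    """Full front end: high-pass filter, frame, ZCR-detect.

    Returns the detected segments and the filtered clip (features should be
    computed from the same denoised signal the detector saw).
    """
    if config is None:
        config = DetectorConfig()
    if window is None:
        window = WindowSpec.for_sample_rate(clip.sample_rate)
    filtered = apply_filter(clip, design_highpass(sample_rate=clip.sample_rate)) if highpass else clip
    frames = frame_signal(filtered, window)
    zcr = short_time_zcr(frames, offset=config.offset)
    segments = detect_calls(zcr, config, window, source_id=clip.source_id)
    return segments, filtered


def segments_to_table(segments: list[CallSegment]) -> pd.DataFrame:
    """Per-recording segment table in the on-disk column order."""
    return pd.DataFrame(
        [
            {
                "source_id": s.source_id,
                "start_sample": s.start_sample,
                "end_sample": s.end_sample,
                "start_frame": s.start_frame,
                "end_frame": s.end_frame,
                "duration_frames": s.duration_frames,
            }
            for s in segments
        ],
        columns=[
            "source_id", "start_sample", "end_sample",
            "start_frame", "end_frame", "duration_frames",
        ],
    )


def table_to_segments(table: pd.DataFrame) -> list[CallSegment]:
    return [
        CallSegment(
            start_frame=int(r.start_frame),
            end_frame=int(r.end_frame),
            start_sample=int(r.start_sample),
            end_sample=int(r.end_sample),
            source_id=str(r.source_id),
        )
        for r in table.itertuples()
    ]


def write_segment_table(segments: list[CallSegment], path) -> None:
    segments_to_table(segments).to_csv(Path(path), sep="\t", index=False)


def read_segment_table(path) -> list[CallSegment]:
    return table_to_segments(pd.read_csv(Path(path), sep="\t"))
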