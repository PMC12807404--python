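"""Acoustic preprocessing: normalisation, clip segmentation, frame-feature
extraction and two-stage pooling to a story-level acoustic vector.

The pipeline is: resample to 16 kHz mono → zero-mean unit-variance
normalisation → overlapping fixed-length clips (default 15 s with 5 s
overlap) → a pluggable frame-level feature extractor per clip (production
binding: a pretrained self-supervised speech encoder producing
``[seq_len, 1024]`` frames; desk-scale binding: the deterministic extractors
below) → mean over frames within each clip, then an unweighted mean over
clips.  The result is one ``F``-dimensional vector per story.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "Waveform",
    "ClipSet",
    "FrameFeatureExtractor",
    "SinusoidProjectionExtractor",
    "ConstantExtractor",
    "read_wav",
    "write_wav",
    "preprocess_audio",
    "segment_clips",
    "pool_visit_feature",
    "extract_story_acoustic",
    "TARGET_RATE_HZ",
]

TARGET_RATE_HZ = 16_000
MIN_REMAINDER_S = 1.0  # trailing partial clips shorter than this are dropped


@dataclass
class Waveform:
    samples: np.ndarray  # (n,) mono or (n, channels)
    rate_hz: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.rate_hz


@dataclass
class ClipSet:
    clips: list[Waveform]
    clip_len_s: float
    overlap_s: float

    @property
    def seg_num(self) -> int:
        return len(self.clips)


class FrameFeatureExtractor(Protocol):
    """Maps a mono 16 kHz clip to a ``[seq_len, F]`` frame-feature matrix."""

    n_features: int

    def extract(self, clip: Waveform) -> np.ndarray: ...


class SinusoidProjectionExtractor:
    """Deterministic desk-scale frame extractor.

    Frames the signal (25 ms windows, 20 ms hop) and projects each frame onto
    a fixed bank of random sinusoids drawn from a frozen seed — a cheap,
    bit-stable stand-in with the same ``[seq_len, F]`` contract as a
    pretrained speech encoder.
    """

    def __init__(
        self,
        n_features: int = 1024,
        frame_len: int = 400,
        hop: int = 320,
        seed: int = 0,
    ):
        self.n_features = n_features
        self.frame_len = frame_len
        self.hop = hop
        rng = np.random.default_rng(seed)
        phases = rng.uniform(0, 2 * np.pi, n_features)
        freqs = rng.uniform(0.5, 40.0, n_features)
        t = np.arange(frame_len) / frame_len
        self._bank = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
        self._bank /= np.sqrt(frame_len)

    def extract(self, clip: Waveform) -> np.ndarray:
        x = clip.samples
        if x.shape[0] < self.frame_len:  # short clip: single zero-padded frame
            x = np.pad(x, (0, self.frame_len - x.shape[0]))
        n_frames = 1 + (x.shape[0] - self.frame_len) // self.hop
        frames = np.lib.stride_tricks.sliding_window_view(x, self.frame_len)[
            :: self.hop
        ][:n_frames]
        return frames @ self._bank.T  # (seq_len, F)


class ConstantExtractor:
    """Every frame equals a fixed vector; used to test pooling fixed points."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.n_features = self.value.shape[0]

    def extract(self, clip: Waveform) -> np.ndarray:
        n_frames = max(1, int(clip.samples.shape[0] // 320))
        return np.tile(self.value, (n_frames, 1))


# ---------------------------------------------------------------------------
# wav I/O


def read_wav(path: str | Path) -> Waveform:
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return Waveform(samples=data.astype(np.float64), rate_hz=int(rate))


def write_wav(samples: np.ndarray, rate_hz: int, path: str | Path) -> None:
    clipped = np.clip(np.asarray(samples, dtype=np.float64), -1.0, 1.0)
    wavfile.write(path, rate_hz, (clipped * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# operations


def preprocess_audio(raw: Waveform, target_rate_hz: int = TARGET_RATE_HZ) -> Waveform:
    """Mono (channel average) → polyphase resample to 16 kHz → zero-mean,
    unit-variance (population standard deviation) normalisation."""
    x = raw.samples
    if x.ndim == 2:
        x = x.mean(axis=1)
    if x.shape[0] < 2:
        raise ValueError("waveform needs at least 2 samples")
    if raw.rate_hz != target_rate_hz:
        g = np.gcd(raw.rate_hz, target_rate_hz)
        x = resample_poly(x, target_rate_hz // g, raw.rate_hz // g)
    sd = x.std()  # population standard deviation
    if sd == 0:
        raise ValueError("constant signal: zero variance, cannot normalise")
    x = (x - x.mean()) / sd
    return Waveform(samples=x, rate_hz=target_rate_hz)


def segment_clips(
    w: Waveform, clip_len_s: float = 15.0, overlap_s: float = 5.0
) -> ClipSet:
    """Cut overlapping clips starting at 0, hop, 2·hop, … with
    hop = clip_len − overlap.

    A trailing partial clip exists only when samples extend beyond the last
    full clip's end; it is kept if at least 1 s long, otherwise dropped.  An
    input shorter than one clip yields a single clip of the whole signal.
    """
    if overlap_s >= clip_len_s:
        raise ValueError("overlap must be smaller than the clip length")
    if overlap_s < 0:
        raise ValueError("overlap must be non-negative")
    n = w.samples.shape[0]
    if n == 0:
        raise ValueError("empty waveform")
    clip_n = int(round(clip_len_s * w.rate_hz))
    hop_n = int(round((clip_len_s - overlap_s) * w.rate_hz))
    clips: list[np.ndarray] = []
    start = 0
    while start + clip_n <= n:
        clips.append(w.samples[start : start + clip_n])
        start += hop_n
    covered = (start - hop_n + clip_n) if clips else 0
    if n > covered:
        remainder = w.samples[start:n]
        if not clips or remainder.shape[0] >= MIN_REMAINDER_S * w.rate_hz:
            clips.append(remainder)
    return ClipSet(
        clips=[Waveform(c, w.rate_hz) for c in clips],
        clip_len_s=clip_len_s,
        overlap_s=overlap_s,
    )


def pool_visit_feature(clip_features: Sequence[np.ndarray]) -> np.ndarray:
    """Two-stage average pooling: mean over frames within each clip, then an
    unweighted mean over the clip vectors (clips count equally regardless of
    their frame counts)."""
    if len(clip_features) == 0:
        raise ValueError("no clips to pool")
    dims = {np.asarray(cf).shape[1] for cf in clip_features}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature dimensions across clips: {dims}")
    clip_means = np.stack([np.asarray(cf).mean(axis=0) for cf in clip_features])
    return clip_means.mean(axis=0)


def extract_story_acoustic(
    w: Waveform,
    fx: FrameFeatureExtractor,
    clip_len_s: float = 15.0,
    overlap_s: float = 5.0,
) -> np.ndarray:
    """Full story-level acoustic feature: preprocess → segment → per-clip
    frame extraction → two-stage pooling.  Returns a length-F vector."""
    clean = preprocess_audio(w)
    clip_set = segment_clips(clean, clip_len_s=clip_len_s, overlap_s=overlap_s)
    return pool_visit_feature([fx.extract(c) for c in clip_set.clips])
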