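"""Synthetic longitudinal dual-modal cohorts.

The generator emulates the statistical structure the longitudinal model
assumes, at desk scale and with known ground truth:

* subjects with ``V`` visits (default 3) and 1–3 stories per visit;
* visit-level binary labels following a two-state transition chain whose
  default probabilities reproduce the observed cohort proportions
  (50 HC→HC, 10 HC→impaired, 8 impaired→HC, 40 impaired→impaired out of 108
  consecutive-visit pairs; initial impaired fraction 26/54);
* story-level feature vectors built from a per-subject latent base ``b``
  (isotropic normal, sd ``base_sd``) plus a cumulative group-dependent drift
  of magnitude ``drift`` along fixed orthonormal directions ``g_HC`` /
  ``g_MCI`` (one step per visit, direction chosen by the label at that
  visit), a visit-independent class offset ``static_sep`` along a third
  orthonormal direction, and isotropic noise ``noise_sd``;
* template-rendered timed transcripts whose pause counts and utterance
  lengths are group-dependent (impaired: medium/long-pause rates x1.5, mean
  utterance length x0.8), so the linguistic extractor recovers the intended
  features by construction;
* optional deterministic toy audio per story.

Setting ``static_sep = 0`` yields cohorts where *only* the visit-to-visit
trajectory is informative; ``drift = 0`` yields purely static separation;
both zero is the null condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    CognitiveLabel,
    LongitudinalDataset,
    StoryRecord,
    TimedSegment,
    TimedTranscript,
)
from .acoustic import TARGET_RATE_HZ, Waveform

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_toy_audio",
    "generate_toy_transcript",
    "TOPICS",
    "WORD_POOLS",
]

#: topics drawn for synthetic stories (all nouns known to the toy tagger)
TOPICS = ("college", "garden", "wedding", "trip", "school", "market", "summer")

#: word pools keyed by coarse POS class; "other" words are absent from the
#: toy tagger's lexicon on purpose.
WORD_POOLS = {
    "pronoun": ("i", "we", "she", "they"),
    "verb": ("went", "remember", "visited", "talked", "saw", "stayed"),
    "noun": ("garden", "school", "friend", "house", "dog", "family", "day"),
    "adjective": ("happy", "old", "quiet", "warm", "small"),
    "other": ("then", "very", "quite", "slowly", "there"),
}

_POS_PATTERN = ("pronoun", "verb", "adjective", "noun", "other")

# default transition counts between consecutive visits (two-state chain)
_DEFAULT_TRANSITIONS = {
    (0, 0): 50,
    (0, 1): 10,
    (1, 0): 8,
    (1, 1): 40,
}


@dataclass
class SynthConfig:
    n_subjects: int = 60
    visits: int = 3
    stories_per_visit: tuple[int, int] = (1, 3)
    p_impaired_init: float = 26 / 54
    transition_counts: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(_DEFAULT_TRANSITIONS)
    )
    drift: float = 1.0  # per-visit drift magnitude along the group direction
    static_sep: float = 1.0  # visit-independent impaired offset
    noise_sd: float = 0.3  # story-level isotropic noise
    base_sd: float = 1.0  # sd of the per-subject latent base
    feature_dim: int = 32
    with_audio: bool = False
    seed: int = 0

    def transition_probs(self) -> np.ndarray:
        """2x2 row-stochastic matrix P[from, to] from the transition counts."""
        P = np.zeros((2, 2))
        for (a, b), c in self.transition_counts.items():
            if c < 0:
                raise ValueError("transition counts must be non-negative")
            P[a, b] = c
        rows = P.sum(axis=1)
        if np.any(rows <= 0):
            raise ValueError("each originating state needs positive mass")
        return P / rows[:, None]

    def validate(self) -> None:
        if not 0 <= self.p_impaired_init <= 1:
            raise ValueError("p_impaired_init must be a probability")
        if min(self.drift, self.noise_sd, self.base_sd) < 0 or self.static_sep < 0:
            raise ValueError("magnitudes must be non-negative")
        if self.feature_dim < 4:
            raise ValueError("feature_dim must be >= 4 (three orthonormal axes)")
        self.transition_probs()


@dataclass
class GroundTruth:
    labels: np.ndarray  # (n_subjects, visits) of {0, 1}
    base: np.ndarray  # (n_subjects, feature_dim) latent bases
    positions: np.ndarray  # (n_subjects, visits, feature_dim) noise-free means
    g_hc: np.ndarray
    g_impaired: np.ndarray
    static_axis: np.ndarray
    subject_ids: list[str]


def _orthonormal_axes(dim: int, rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(dim, 3)))
    return q.T  # rows orthonormal


def generate_dataset(cfg: SynthConfig) -> tuple[LongitudinalDataset, GroundTruth]:
    """Sample a complete longitudinal cohort; deterministic under cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    P = cfg.transition_probs()
    g_hc, g_imp, static_axis = _orthonormal_axes(cfg.feature_dim, rng)
    drift_dirs = (g_hc, g_imp)

    n, V, dim = cfg.n_subjects, cfg.visits, cfg.feature_dim
    labels = np.zeros((n, V), dtype=int)
    base = rng.normal(0.0, cfg.base_sd, size=(n, dim))
    positions = np.zeros((n, V, dim))
    stories: list[StoryRecord] = []
    subject_ids = [f"s{i + 1:03d}" for i in range(n)]

    for i, sid in enumerate(subject_ids):
        labels[i, 0] = int(rng.random() < cfg.p_impaired_init)
        for k in range(1, V):
            labels[i, k] = int(rng.random() < P[labels[i, k - 1], 1])
        pos = base[i].copy()
        for k in range(V):
            if k > 0:
                pos = pos + cfg.drift * drift_dirs[labels[i, k]]
            positions[i, k] = pos + cfg.static_sep * static_axis * labels[i, k]
            n_stories = int(
                rng.integers(cfg.stories_per_visit[0], cfg.stories_per_visit[1] + 1)
            )
            for m in range(1, n_stories + 1):
                feats = positions[i, k] + rng.normal(0.0, cfg.noise_sd, dim)
                topic = TOPICS[int(rng.integers(len(TOPICS)))]
                transcript = _render_transcript(rng, impaired=bool(labels[i, k]))
                audio = None
                if cfg.with_audio:
                    duration = transcript.segments[-1].end_s + 0.5
                    audio = generate_toy_audio(
                        duration, kind="sine_mix", seed=int(rng.integers(2**31))
                    ).samples
                stories.append(
                    StoryRecord(
                        subject_id=sid,
                        visit_index=k + 1,
                        story_index=m,
                        topic=topic,
                        label=CognitiveLabel(labels[i, k]),
                        audio_ref=audio,
                        transcript=transcript,
                        features=feats,
                    )
                )

    ds = LongitudinalDataset(stories=stories, V=V)
    gt = GroundTruth(
        labels=labels,
        base=base,
        positions=positions,
        g_hc=g_hc,
        g_impaired=g_imp,
        static_axis=static_axis,
        subject_ids=subject_ids,
    )
    return ds, gt


# linguistic profile of the two groups: utterance length and pause mix
_HC_MLU_MEAN = 8.0
_HC_PAUSE_PROBS = {"short": 0.70, "medium": 0.20, "long": 0.10}


def _group_profile(impaired: bool) -> tuple[float, dict[str, float]]:
    if not impaired:
        return _HC_MLU_MEAN, dict(_HC_PAUSE_PROBS)
    probs = {
        "short": 1.0 - 1.5 * (_HC_PAUSE_PROBS["medium"] + _HC_PAUSE_PROBS["long"]),
        "medium": 1.5 * _HC_PAUSE_PROBS["medium"],
        "long": 1.5 * _HC_PAUSE_PROBS["long"],
    }
    return 0.8 * _HC_MLU_MEAN, probs


_GAP_RANGES = {"short": (0.05, 0.45), "medium": (0.6, 1.9), "long": (2.1, 4.0)}


def _render_transcript(rng: np.random.Generator, impaired: bool) -> TimedTranscript:
    mlu_mean, pause_probs = _group_profile(impaired)
    n_segments = int(rng.integers(3, 7))
    words_per_segment = np.maximum(
        1, rng.poisson(mlu_mean, size=n_segments)
    ).tolist()
    cats = list(pause_probs)
    gap_cats = rng.choice(cats, size=n_segments - 1, p=[pause_probs[c] for c in cats])
    gaps = [float(rng.uniform(*_GAP_RANGES[c])) for c in gap_cats]
    return generate_toy_transcript(
        n_segments, gaps, words_per_segment, seed=int(rng.integers(2**31))
    )


def generate_toy_transcript(
    n_segments: int,
    gap_profile,
    words_per_segment,
    seed: int = 0,
) -> TimedTranscript:
    """Transcript with exactly the requested inter-segment gaps and per
    segment word counts, so pause counts and MLU are known by construction."""
    if n_segments < 1:
        raise ValueError("need at least one segment")
    gap_profile = list(gap_profile)
    if len(gap_profile) != n_segments - 1:
        raise ValueError(
            f"expected {n_segments - 1} gaps, got {len(gap_profile)}"
        )
    if isinstance(words_per_segment, int):
        words_per_segment = [words_per_segment] * n_segments
    words_per_segment = list(words_per_segment)
    if len(words_per_segment) != n_segments:
        raise ValueError("words_per_segment length mismatch")
    rng = np.random.default_rng(seed)
    segments = []
    cursor = 0.0
    for idx, n_words in enumerate(words_per_segment):
        if idx > 0:
            cursor += gap_profile[idx - 1]
        words = [
            WORD_POOLS[_POS_PATTERN[j % len(_POS_PATTERN)]][
                int(rng.integers(len(WORD_POOLS[_POS_PATTERN[j % len(_POS_PATTERN)]]))
                )
            ]
            for j in range(n_words)
        ]
        start = cursor
        end = start + 0.35 * n_words
        segments.append(TimedSegment(round(start, 3), round(end, 3), " ".join(words)))
        cursor = end
    return TimedTranscript(tuple(segments))


def generate_toy_audio(
    duration_s: float, kind: str = "sine_mix", seed: int = 0
) -> Waveform:
    """Deterministic 16 kHz mono test signal.

    ``sine_mix`` sums three sinusoids whose frequencies are snapped to an
    integer number of cycles over the requested duration (so the signal mean
    is zero by symmetry); ``noise`` is white Gaussian.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * TARGET_RATE_HZ))
    t = np.arange(n)
    if kind == "sine_mix":
        x = np.zeros(n)
        for _ in range(3):
            f = rng.uniform(80.0, 400.0)
            cycles = max(1, int(round(f * duration_s)))
            phase = rng.uniform(0, 2 * np.pi)
            x += 0.2 * np.sin(2 * np.pi * cycles * t / n + phase)
    elif kind == "noise":
        x = 0.1 * rng.standard_normal(n)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return Waveform(samples=x, rate_hz=TARGET_RATE_HZ)
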