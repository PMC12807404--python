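"""Linguistic features from timestamped transcripts.

From a timed transcript plus its story topic this module derives:

* the 9-dimensional numeric feature vector — mean length of utterance (MLU),
  counts of short/medium/long inter-utterance pauses, and counts of the five
  coarse part-of-speech classes (noun, verb, adjective, pronoun, other); and
* the *enriched transcript*: a topic sentence prepended to the story text,
  pause-marker tokens inserted at inter-segment gaps, and per-token context
  ids (0 = topic span, 1 = story content) consumed by the linguistic encoder.

Pauses follow the clinical taxonomy: short < 0.5 s, medium 0.5–2 s, long
> 2 s, measured between consecutive ASR segments (one segment = one
utterance).  Negative gaps from overlapping ASR segments are clipped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Protocol, Sequence

import numpy as np

from .data import TimedTranscript

__all__ = [
    "PauseCategory",
    "LinguisticFeatures",
    "EnrichedTranscript",
    "PosTagger",
    "RuleTagger",
    "whitespace_tokenize",
    "classify_pause",
    "extract_pause_counts",
    "compute_mlu",
    "count_pos",
    "build_enriched_transcript",
    "extract_linguistic_features",
    "PAUSE_MARKERS",
    "TOPIC_TEMPLATE",
    "POS_CLASSES",
]

SHORT_MAX_S = 0.5  # short pause: gap < 0.5 s (strict)
LONG_MIN_S = 2.0  # long pause: gap > 2 s (strict); boundaries fall to medium

TOPIC_TEMPLATE = "I'm going to share a story of {topic}."

POS_CLASSES = ("noun", "verb", "adjective", "pronoun", "other")


class PauseCategory(Enum):
    SHORT = "short"
    MEDIUM = "medium"
    LONG = "long"


PAUSE_MARKERS = {
    PauseCategory.SHORT: "[PAUSE_S]",
    PauseCategory.MEDIUM: "[PAUSE_M]",
    PauseCategory.LONG: "[PAUSE_L]",
}


@dataclass(frozen=True)
class LinguisticFeatures:
    """The 9 story-level numeric linguistic features, in canonical order."""

    mlu: float
    n_short: int
    n_medium: int
    n_long: int
    n_noun: int
    n_verb: int
    n_adjective: int
    n_pronoun: int
    n_other: int

    FIELD_ORDER = (
        "mlu",
        "n_short",
        "n_medium",
        "n_long",
        "n_noun",
        "n_verb",
        "n_adjective",
        "n_pronoun",
        "n_other",
    )

    def to_vector(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in self.FIELD_ORDER], dtype=np.float64
        )


@dataclass(frozen=True)
class EnrichedTranscript:
    text: str
    context_ids: tuple[int, ...]

    def __post_init__(self):
        ids = self.context_ids
        if any(i not in (0, 1) for i in ids):
            raise ValueError("context ids must be 0 (topic) or 1 (content)")
        if any(a > b for a, b in zip(ids, ids[1:])):
            raise ValueError("context ids must be non-decreasing")


class PosTagger(Protocol):
    """Interface for pluggable part-of-speech taggers: returns one
    (token, coarse class) pair per token, classes from :data:`POS_CLASSES`."""

    def tag(self, text: str) -> list[tuple[str, str]]: ...


def whitespace_tokenize(text: str) -> list[str]:
    return text.split()


class RuleTagger:
    """Deterministic toy tagger backed by a surface-form lexicon.

    Ships for tests and synthetic data; real taggers (e.g. a CKIP-style model
    with a fine-to-coarse mapping table) plug in behind the same interface.
    Unknown tokens fall to "other", so token conservation always holds.
    """

    #: default lexicon; covers the synthetic story templates
    DEFAULT_LEXICON = {
        # pronouns
        **{w: "pronoun" for w in ("i", "you", "he", "she", "we", "they", "it", "me")},
        # nouns
        **{
            w: "noun"
            for w in (
                "story",
                "college",
                "family",
                "garden",
                "school",
                "trip",
                "house",
                "friend",
                "summer",
                "wedding",
                "dog",
                "market",
                "year",
                "day",
            )
        },
        # verbs
        **{
            w: "verb"
            for w in (
                "share",
                "remember",
                "went",
                "was",
                "were",
                "visited",
                "walked",
                "talked",
                "saw",
                "liked",
                "stayed",
                "met",
            )
        },
        # adjectives
        **{
            w: "adjective"
            for w in ("happy", "old", "young", "long", "quiet", "warm", "small", "hard")
        },
    }

    def __init__(self, lexicon: dict[str, str] | None = None):
        self.lexicon = dict(self.DEFAULT_LEXICON if lexicon is None else lexicon)

    def tag(self, text: str) -> list[tuple[str, str]]:
        out = []
        for token in whitespace_tokenize(text):
            cls = self.lexicon.get(token.lower().strip(".,!?"), "other")
            out.append((token, cls))
        return out


# ---------------------------------------------------------------------------
# operations


def classify_pause(gap_s: float) -> PauseCategory:
    """Classify an inter-utterance silence by duration; boundaries 0.5 s and
    2.0 s map to MEDIUM (the short/long definitions are strict)."""
    if gap_s < 0:
        raise ValueError(f"pause duration must be >= 0, got {gap_s}")
    if gap_s < SHORT_MAX_S:
        return PauseCategory.SHORT
    if gap_s > LONG_MIN_S:
        return PauseCategory.LONG
    return PauseCategory.MEDIUM


def _gaps(tr: TimedTranscript) -> list[float]:
    if len(tr) == 0:
        raise ValueError("empty transcript")
    return [
        max(0.0, b.start_s - a.end_s) for a, b in zip(tr.segments, tr.segments[1:])
    ]


def extract_pause_counts(tr: TimedTranscript) -> tuple[int, int, int]:
    """Count (short, medium, long) pauses over the n-1 inter-segment gaps;
    overlapping segments are clipped to a zero gap (counted short)."""
    counts = {c: 0 for c in PauseCategory}
    for gap in _gaps(tr):
        counts[classify_pause(gap)] += 1
    return (
        counts[PauseCategory.SHORT],
        counts[PauseCategory.MEDIUM],
        counts[PauseCategory.LONG],
    )


def compute_mlu(
    tr: TimedTranscript,
    tokenizer: Callable[[str], Sequence[str]] = whitespace_tokenize,
) -> float:
    """Mean length of utterance: average word count per segment (one ASR
    segment = one utterance)."""
    if len(tr) == 0:
        raise ValueError("empty transcript")
    counts = [len(tokenizer(s.text)) for s in tr.segments]
    return float(np.mean(counts))


def count_pos(
    tr: TimedTranscript, tagger: PosTagger
) -> tuple[int, int, int, int, int]:
    """Counts of the five coarse POS classes over the whole story text; the
    counts always sum to the tagger's token total."""
    counts = dict.fromkeys(POS_CLASSES, 0)
    for seg in tr.segments:
        for _, cls in tagger.tag(seg.text):
            counts[cls] += 1
    return tuple(counts[c] for c in POS_CLASSES)  # type: ignore[return-value]


def build_enriched_transcript(
    tr: TimedTranscript,
    topic: str,
    topic_template: str = TOPIC_TEMPLATE,
    tokenizer: Callable[[str], Sequence[str]] = whitespace_tokenize,
) -> EnrichedTranscript:
    """Prepend the topic sentence and weave pause markers into the story text.

    The marker token for each inter-segment gap is chosen by
    :func:`classify_pause`; context ids are 0 over the topic sentence's tokens
    and 1 over everything else (markers included).
    """
    if not topic.strip():
        raise ValueError("topic must be non-empty")
    if len(tr) == 0:
        raise ValueError("empty transcript")
    topic_sentence = topic_template.format(topic=topic)
    parts: list[str] = []
    gaps = _gaps(tr)
    for i, seg in enumerate(tr.segments):
        if i > 0:
            parts.append(PAUSE_MARKERS[classify_pause(gaps[i - 1])])
        parts.append(seg.text)
    content = " ".join(parts)
    text = f"{topic_sentence} {content}"
    n_topic = len(tokenizer(topic_sentence))
    n_total = len(tokenizer(text))
    context_ids = (0,) * n_topic + (1,) * (n_total - n_topic)
    return EnrichedTranscript(text=text, context_ids=context_ids)


def extract_linguistic_features(
    tr: TimedTranscript,
    tagger: PosTagger,
    tokenizer: Callable[[str], Sequence[str]] = whitespace_tokenize,
) -> LinguisticFeatures:
    """Compose MLU, pause counts and POS counts into the 9-vector."""
    n_short, n_medium, n_long = extract_pause_counts(tr)
    n_noun, n_verb, n_adj, n_pron, n_other = count_pos(tr, tagger)
    return LinguisticFeatures(
        mlu=compute_mlu(tr, tokenizer),
        n_short=n_short,
        n_medium=n_medium,
        n_long=n_long,
        n_noun=n_noun,
        n_verb=n_verb,
        n_adjective=n_adj,
        n_pronoun=n_pron,
        n_other=n_other,
    )
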