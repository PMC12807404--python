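"""Domain types and dataset I/O for longitudinal spontaneous-speech cohorts.

A cohort is a set of subjects, each interviewed at up to ``V`` visits (ordinal,
1-based); at every visit the subject narrates one or more free-form stories.
Each story carries an audio recording, a timestamped transcript (the
``segments`` dialect emitted by whisper-style ASR), a topic string, and the
visit-level binary cognitive label (healthy control vs. impaired — MCI for the
autobiographical-memory task, AD for picture-description corpora).

Interchange format: one CSV manifest row per story with columns
``subject_id, visit_index, story_index, topic, label, audio_path,
transcript_path`` (paths relative to the manifest), transcripts as JSON files,
audio as PCM WAV.  Precomputed story-level feature vectors travel in an
optional ``features.csv`` next to the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CognitiveLabel",
    "TimedSegment",
    "TimedTranscript",
    "StoryRecord",
    "LongitudinalDataset",
    "VisitTriplet",
    "ManifestFormatError",
    "ValidationError",
    "load_timed_transcript",
    "write_timed_transcript",
    "load_manifest",
    "write_manifest",
    "write_dataset",
    "validate_longitudinal",
]

MANIFEST_COLUMNS = [
    "subject_id",
    "visit_index",
    "story_index",
    "topic",
    "label",
    "audio_path",
    "transcript_path",
]


class ManifestFormatError(ValueError):
    """The manifest or transcript file does not have the expected layout."""


class ValidationError(ValueError):
    """The data violate a dataset invariant (label consistency, coverage)."""


class CognitiveLabel(IntEnum):
    """Binary visit-level cognitive status; serialised as 0 (HC) / 1 (impaired)."""

    HC = 0
    IMPAIRED = 1

    @classmethod
    def parse(cls, text: str) -> "CognitiveLabel":
        key = str(text).strip().lower()
        if key in {"hc", "healthy", "control", "0"}:
            return cls.HC
        if key in {"mci", "ad", "impaired", "1"}:
            return cls.IMPAIRED
        raise ValueError(f"unknown cognitive label {text!r}")

    def serialize(self) -> str:
        return "HC" if self is CognitiveLabel.HC else "MCI"


@dataclass(frozen=True)
class TimedSegment:
    start_s: float
    end_s: float
    text: str

    def __post_init__(self):
        if self.start_s < 0:
            raise ValidationError(f"segment start {self.start_s} < 0")
        if self.end_s < self.start_s:
            raise ValidationError(
                f"segment end {self.end_s} before start {self.start_s}"
            )
        if not self.text.strip():
            raise ValidationError("segment text empty after whitespace strip")


@dataclass(frozen=True)
class TimedTranscript:
    segments: tuple[TimedSegment, ...]

    def __post_init__(self):
        ordered = tuple(sorted(self.segments, key=lambda s: s.start_s))
        object.__setattr__(self, "segments", ordered)

    def __len__(self) -> int:
        return len(self.segments)

    def to_json_dict(self) -> dict:
        return {
            "segments": [
                {"start": s.start_s, "end": s.end_s, "text": s.text}
                for s in self.segments
            ]
        }


@dataclass
class StoryRecord:
    subject_id: str
    visit_index: int
    story_index: int
    topic: str
    label: CognitiveLabel
    audio_ref: Path | np.ndarray | None = None
    transcript: TimedTranscript | None = None
    features: np.ndarray | None = None

    def key(self) -> tuple[str, int, int]:
        return (self.subject_id, self.visit_index, self.story_index)


@dataclass
class LongitudinalDataset:
    stories: list[StoryRecord]
    V: int = 3

    def __post_init__(self):
        self.stories = sorted(self.stories, key=StoryRecord.key)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.stories:
            seen.setdefault(s.subject_id, None)
        return list(seen)

    def stories_at(self, subject_id: str, visit: int) -> list[StoryRecord]:
        return [
            s
            for s in self.stories
            if s.subject_id == subject_id and s.visit_index == visit
        ]

    def visit_label(self, subject_id: str, visit: int) -> CognitiveLabel:
        stories = self.stories_at(subject_id, visit)
        if not stories:
            raise KeyError(f"no stories for subject {subject_id} visit {visit}")
        return stories[0].label


@dataclass(frozen=True)
class VisitTriplet:
    """Ordered per-subject model input: one story per visit 1..V; the
    prediction target is the label of the last visit."""

    subject_id: str
    stories: tuple[StoryRecord, ...]
    target_label: CognitiveLabel

    def __post_init__(self):
        visits = [s.visit_index for s in self.stories]
        if visits != list(range(1, len(visits) + 1)):
            raise ValidationError(f"triplet visits {visits} not 1..V in order")
        if self.stories[-1].label != self.target_label:
            raise ValidationError("target label must equal the last visit's label")


# ---------------------------------------------------------------------------
# transcripts


def load_timed_transcript(path: str | Path) -> TimedTranscript:
    """Read a whisper-style ``{"segments": [{start, end, text}, ...]}`` JSON
    file; segments are returned sorted by start time."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "segments" not in payload:
        raise ManifestFormatError(f"{path}: missing top-level 'segments' key")
    segments = []
    for raw in payload["segments"]:
        try:
            seg = TimedSegment(float(raw["start"]), float(raw["end"]), str(raw["text"]))
        except KeyError as exc:
            raise ManifestFormatError(f"{path}: segment missing field {exc}") from exc
        segments.append(seg)
    return TimedTranscript(tuple(segments))


def write_timed_transcript(tr: TimedTranscript, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tr.to_json_dict(), fh, ensure_ascii=False, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# manifests


def load_manifest(
    path: str | Path, audio_root: str | Path | None = None
) -> LongitudinalDataset:
    """Load a dataset manifest (CSV, one row per story) and its transcripts.

    Paths in the manifest are resolved relative to ``audio_root`` (default:
    the manifest's directory).  A ``features.csv`` sitting next to the
    manifest, if present, populates per-story feature vectors.
    """
    path = Path(path)
    root = Path(audio_root) if audio_root is not None else path.parent
    df = pd.read_csv(path, dtype={"subject_id": str, "topic": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestFormatError(f"{path}: missing columns {missing}")

    features = _load_features(path.parent / "features.csv")
    stories: list[StoryRecord] = []
    for row in df.itertuples(index=False):
        transcript = None
        if isinstance(row.transcript_path, str) and row.transcript_path:
            transcript = load_timed_transcript(root / row.transcript_path)
        audio_ref = (
            root / row.audio_path
            if isinstance(row.audio_path, str) and row.audio_path
            else None
        )
        key = (str(row.subject_id), int(row.visit_index), int(row.story_index))
        stories.append(
            StoryRecord(
                subject_id=key[0],
                visit_index=key[1],
                story_index=key[2],
                topic=str(row.topic),
                label=CognitiveLabel.parse(row.label),
                audio_ref=audio_ref,
                transcript=transcript,
                features=features.get(key),
            )
        )
    v_max = max(s.visit_index for s in stories)
    ds = LongitudinalDataset(stories=stories, V=v_max)
    _check_label_consistency(ds)
    return ds


def _check_label_consistency(ds: LongitudinalDataset) -> None:
    labels: dict[tuple[str, int], CognitiveLabel] = {}
    for s in ds.stories:
        key = (s.subject_id, s.visit_index)
        if key in labels and labels[key] != s.label:
            raise ValidationError(
                f"inconsistent labels for subject {key[0]} visit {key[1]}"
            )
        labels[key] = s.label


def _load_features(path: Path) -> dict[tuple[str, int, int], np.ndarray]:
    if not path.exists():
        return {}
    df = pd.read_csv(path, dtype={"subject_id": str})
    cols = [c for c in df.columns if c.startswith("f")]
    out = {}
    for row in df.itertuples(index=False):
        key = (str(row.subject_id), int(row.visit_index), int(row.story_index))
        out[key] = np.array([getattr(row, c) for c in cols], dtype=np.float64)
    return out


def write_manifest(ds: LongitudinalDataset, path: str | Path) -> None:
    """Write the canonical manifest: fixed column order, rows sorted by
    (subject, visit, story), floats via ``repr`` — so write→read→write is
    byte-identical."""
    path = Path(path)
    rows = []
    for s in sorted(ds.stories, key=StoryRecord.key):
        rows.append(
            {
                "subject_id": s.subject_id,
                "visit_index": s.visit_index,
                "story_index": s.story_index,
                "topic": s.topic,
                "label": s.label.serialize(),
                "audio_path": _relpath(s.audio_ref, path.parent),
                "transcript_path": f"transcripts/{s.subject_id}_v{s.visit_index}_s{s.story_index}.json",
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def _relpath(audio_ref, root: Path) -> str:
    if isinstance(audio_ref, (str, Path)):
        ref = Path(audio_ref)
        try:
            return ref.relative_to(root).as_posix()
        except ValueError:
            return ref.as_posix()
    return ""


def write_dataset(ds: LongitudinalDataset, outdir: str | Path) -> Path:
    """Materialise a dataset directory: manifest.csv, transcripts/ JSON files,
    wavs/ (for stories holding in-memory waveforms), and features.csv when
    precomputed story features are present.  Returns the manifest path."""
    from .acoustic import write_wav  # local import to avoid a cycle

    outdir = Path(outdir)
    (outdir / "transcripts").mkdir(parents=True, exist_ok=True)
    stories = []
    feature_rows = []
    for s in sorted(ds.stories, key=StoryRecord.key):
        stem = f"{s.subject_id}_v{s.visit_index}_s{s.story_index}"
        audio_ref = s.audio_ref
        if isinstance(audio_ref, np.ndarray):
            (outdir / "wavs").mkdir(exist_ok=True)
            wav_path = outdir / "wavs" / f"{stem}.wav"
            write_wav(audio_ref, 16000, wav_path)
            audio_ref = wav_path
        if s.transcript is not None:
            write_timed_transcript(s.transcript, outdir / "transcripts" / f"{stem}.json")
        if s.features is not None:
            feature_rows.append(
                {
                    "subject_id": s.subject_id,
                    "visit_index": s.visit_index,
                    "story_index": s.story_index,
                    **{f"f{i}": v for i, v in enumerate(s.features)},
                }
            )
        stories.append(replace(s, audio_ref=audio_ref))
    manifest = outdir / "manifest.csv"
    write_manifest(LongitudinalDataset(stories, V=ds.V), manifest)
    if feature_rows:
        pd.DataFrame(feature_rows).to_csv(outdir / "features.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    subject_id: str
    visit_index: int | None
    message: str


def validate_longitudinal(ds: LongitudinalDataset) -> list[Violation]:
    """Report (never raise) longitudinal-completeness and label-consistency
    violations: every subject needs >=1 story at each visit 1..V, and one
    label per (subject, visit)."""
    reports: list[Violation] = []
    labels: dict[tuple[str, int], CognitiveLabel] = {}
    for s in ds.stories:
        key = (s.subject_id, s.visit_index)
        if key in labels and labels[key] != s.label:
            reports.append(
                Violation(s.subject_id, s.visit_index, "inconsistent visit labels")
            )
        labels.setdefault(key, s.label)
    for subject in ds.subjects():
        for visit in range(1, ds.V + 1):
            if not ds.stories_at(subject, visit):
                reports.append(
                    Violation(subject, visit, f"subject {subject} missing visit {visit}")
                )
    return reports
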