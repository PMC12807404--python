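"""Dataset types, manifest and transcript I/O, longitudinal validation."""

import json

import numpy as np
import pytest

from ltam.data import (
    CognitiveLabel,
    LongitudinalDataset,
    ManifestFormatError,
    TimedSegment,
    TimedTranscript,
    ValidationError,
    VisitTriplet,
    load_manifest,
    load_timed_transcript,
    validate_longitudinal,
    write_dataset,
    write_manifest,
)
from ltam.synthetic import SynthConfig, generate_dataset


class TestCognitiveLabel:
    @pytest.mark.parametrize(
        "text,expected",
        [("HC", 0), ("hc", 0), ("MCI", 1), ("AD", 1), ("mci", 1)],
    )
    def test_parse_case_insensitive(self, text, expected):
        assert CognitiveLabel.parse(text) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown cognitive label"):
            CognitiveLabel.parse("severe")


class TestTimedTranscript:
    def test_load_single_segment(self, tmp_path):
        path = tmp_path / "t.json"
        path.write_text(
            json.dumps({"segments": [{"start": 0.0, "end": 2.1, "text": "我想分享"}]}),
            encoding="utf-8",
        )
        tr = load_timed_transcript(path)
        assert len(tr) == 1
        assert tr.segments[0].end_s == pytest.approx(2.1)

    def test_out_of_order_segments_sorted_by_start(self, tmp_path):
        path = tmp_path / "t.json"
        path.write_text(
            json.dumps(
                {
                    "segments": [
                        {"start": 5.0, "end": 6.0, "text": "b"},
                        {"start": 1.0, "end": 2.0, "text": "a"},
                    ]
                }
            )
        )
        tr = load_timed_transcript(path)
        assert [s.text for s in tr.segments] == ["a", "b"]

    def test_empty_transcript_allowed(self, tmp_path):
        path = tmp_path / "t.json"
        path.write_text(json.dumps({"segments": []}))
        assert len(load_timed_transcript(path)) == 0

    def test_missing_segments_key(self, tmp_path):
        path = tmp_path / "t.json"
        path.write_text(json.dumps({"text": "hello"}))
        with pytest.raises(ManifestFormatError, match="segments"):
            load_timed_transcript(path)

    def test_end_before_start_rejected(self, tmp_path):
        path = tmp_path / "t.json"
        path.write_text(
            json.dumps({"segments": [{"start": 3.0, "end": 1.0, "text": "x"}]})
        )
        with pytest.raises(ValidationError):
            load_timed_transcript(path)

    def test_idempotent_under_reserialization(self, tmp_path):
        from ltam.data import write_timed_transcript

        tr = TimedTranscript(
            (TimedSegment(0.0, 1.5, "hello there"), TimedSegment(2.0, 3.0, "again"))
        )
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_timed_transcript(tr, p1)
        tr2 = load_timed_transcript(p1)
        write_timed_transcript(tr2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert tr2 == tr


class TestManifest:
    def test_two_row_manifest_parses(self, tmp_path):
        manifest = tmp_path / "manifest.csv"
        manifest.write_text(
            "subject_id,visit_index,story_index,topic,label,audio_path,transcript_path\n"
            "s1,1,1,garden,HC,,\n"
            "s1,2,1,trip,MCI,,\n"
        )
        ds = load_manifest(manifest)
        assert len(ds.stories) == 2
        assert ds.V == 2
        assert ds.visit_label("s1", 2) == CognitiveLabel.IMPAIRED

    def test_missing_column_is_format_error(self, tmp_path):
        manifest = tmp_path / "manifest.csv"
        manifest.write_text("subject_id,visit_index\ns1,1\n")
        with pytest.raises(ManifestFormatError, match="missing columns"):
            load_manifest(manifest)

    def test_inconsistent_visit_labels_rejected(self, tmp_path):
        manifest = tmp_path / "manifest.csv"
        manifest.write_text(
            "subject_id,visit_index,story_index,topic,label,audio_path,transcript_path\n"
            "s1,2,1,garden,HC,,\n"
            "s1,2,2,trip,MCI,,\n"
        )
        with pytest.raises(ValidationError, match="inconsistent"):
            load_manifest(manifest)

    def test_synthetic_roundtrip(self, tmp_path):
        ds, _ = generate_dataset(SynthConfig(n_subjects=4, seed=7))
        manifest = write_dataset(ds, tmp_path)
        loaded = load_manifest(manifest)
        assert len(loaded.stories) == len(ds.stories)
        for a, b in zip(ds.stories, loaded.stories):
            assert a.key() == b.key()
            assert a.topic == b.topic and a.label == b.label
            assert a.transcript == b.transcript
            np.testing.assert_allclose(a.features, b.features, rtol=1e-12)

    def test_write_read_write_byte_identical(self, tmp_path):
        ds, _ = generate_dataset(SynthConfig(n_subjects=3, seed=11))
        m1 = write_dataset(ds, tmp_path / "a")
        loaded = load_manifest(m1)
        m2 = tmp_path / "b.csv"
        write_manifest(loaded, m2)
        assert m1.read_bytes() == m2.read_bytes()


class TestValidation:
    def test_complete_dataset_clean(self, complete_dataset):
        assert validate_longitudinal(complete_dataset) == []

    def test_missing_visit_reported(self, complete_dataset):
        stories = [s for s in complete_dataset.stories if not (s.subject_id == "s2" and s.visit_index == 3)]
        ds = LongitudinalDataset(stories, V=3)
        reports = validate_longitudinal(ds)
        assert len(reports) == 1
        assert reports[0].subject_id == "s2" and reports[0].visit_index == 3

    @pytest.mark.parametrize("seed", [0, 5, 123])
    def test_synthetic_always_complete(self, seed):
        ds, _ = generate_dataset(SynthConfig(n_subjects=5, seed=seed))
        assert validate_longitudinal(ds) == []


class TestVisitTriplet:
    def test_wrong_visit_order_rejected(self, complete_dataset):
        s = complete_dataset.stories_at("s1", 1)[0]
        s2 = complete_dataset.stories_at("s1", 2)[0]
        s3 = complete_dataset.stories_at("s1", 3)[0]
        with pytest.raises(ValidationError, match="visits"):
            VisitTriplet("s1", (s2, s, s3), s3.label)

    def test_target_must_match_last_visit(self, complete_dataset):
        s1, s2, s3 = (complete_dataset.stories_at("s2", v)[0] for v in (1, 2, 3))
        with pytest.raises(ValidationError, match="target label"):
            VisitTriplet("s2", (s1, s2, s3), CognitiveLabel.HC)
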