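"""Pause taxonomy, MLU, POS counts and the enriched transcript."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltam.data import TimedSegment, TimedTranscript
from ltam.linguistic import (
    PAUSE_MARKERS,
    PauseCategory,
    RuleTagger,
    build_enriched_transcript,
    classify_pause,
    compute_mlu,
    count_pos,
    extract_linguistic_features,
    extract_pause_counts,
    whitespace_tokenize,
)
from ltam.synthetic import generate_toy_transcript


class TestClassifyPause:
    @pytest.mark.parametrize(
        "gap,expected",
        [
            (0.3, PauseCategory.SHORT),
            (2.5, PauseCategory.LONG),
            (0.5, PauseCategory.MEDIUM),  # boundary forced by the strict < 0.5
            (2.0, PauseCategory.MEDIUM),  # boundary forced by the strict > 2
            (0.0, PauseCategory.SHORT),
            (1.0, PauseCategory.MEDIUM),
        ],
    )
    def test_thresholds(self, gap, expected):
        assert classify_pause(gap) is expected

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            classify_pause(-0.1)

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_partition_every_gap_has_exactly_one_category(self, gap):
        assert classify_pause(gap) in PauseCategory


class TestPauseCounts:
    def test_hand_enumeration(self, three_segment_transcript):
        # gaps 0.3 and 2.5 -> (short, medium, long) = (1, 0, 1)
        assert extract_pause_counts(three_segment_transcript) == (1, 0, 1)

    def test_single_segment_has_no_gaps(self):
        tr = TimedTranscript((TimedSegment(0, 1, "hi there"),))
        assert extract_pause_counts(tr) == (0, 0, 0)

    def test_overlap_clipped_to_zero_counts_short(self):
        tr = TimedTranscript(
            (TimedSegment(0.0, 2.0, "a b"), TimedSegment(1.5, 3.0, "c d"))
        )
        assert extract_pause_counts(tr) == (1, 0, 0)

    def test_empty_transcript_rejected(self):
        with pytest.raises(ValueError):
            extract_pause_counts(TimedTranscript(()))

    @given(st.lists(st.floats(min_value=0, max_value=10), min_size=0, max_size=8))
    @settings(max_examples=50, derandomize=True)
    def test_counts_sum_to_gap_count(self, gaps):
        tr = generate_toy_transcript(len(gaps) + 1, gaps, 3, seed=1)
        assert sum(extract_pause_counts(tr)) == len(gaps)


class TestMlu:
    @pytest.mark.parametrize(
        "word_counts,expected", [([3, 5, 4], 4.0), ([7], 7.0), ([1, 1, 1, 1], 1.0)]
    )
    def test_mean_words_per_utterance(self, word_counts, expected):
        tr = generate_toy_transcript(
            len(word_counts), [0.1] * (len(word_counts) - 1), word_counts, seed=0
        )
        assert compute_mlu(tr) == pytest.approx(expected)

    def test_empty_transcript_rejected(self):
        with pytest.raises(ValueError):
            compute_mlu(TimedTranscript(()))


class TestPosCounts:
    def test_toy_tagger_counts(self):
        tr = TimedTranscript((TimedSegment(0, 1, "dog went garden she"),))
        # noun, verb, noun, pronoun -> (2, 1, 0, 1, 0)
        assert count_pos(tr, RuleTagger()) == (2, 1, 0, 1, 0)

    @pytest.mark.parametrize("seed", [0, 3, 9])
    def test_conservation_counts_sum_to_token_total(self, seed):
        tr = generate_toy_transcript(4, [0.2, 1.0, 3.0], [5, 2, 7, 4], seed=seed)
        total_tokens = sum(len(whitespace_tokenize(s.text)) for s in tr.segments)
        assert sum(count_pos(tr, RuleTagger())) == total_tokens


class TestEnrichedTranscript:
    def test_topic_sentence_prefix_and_context_ids(self):
        tr = TimedTranscript((TimedSegment(0, 1, "it was hard"),))
        enr = build_enriched_transcript(tr, "college")
        assert enr.text == "I'm going to share a story of college. it was hard"
        n_topic = len(whitespace_tokenize("I'm going to share a story of college."))
        assert enr.context_ids == (0,) * n_topic + (1, 1, 1)

    def test_long_gap_inserts_long_marker(self):
        tr = TimedTranscript(
            (TimedSegment(0, 1, "first part"), TimedSegment(3.5, 4.0, "second part"))
        )
        enr = build_enriched_transcript(tr, "trip")
        assert PAUSE_MARKERS[PauseCategory.LONG] in enr.text.split()

    def test_empty_topic_rejected(self):
        tr = TimedTranscript((TimedSegment(0, 1, "x y"),))
        with pytest.raises(ValueError):
            build_enriched_transcript(tr, "  ")

    @given(st.integers(1, 5), st.integers(0, 10))
    @settings(max_examples=30, derandomize=True)
    def test_context_ids_non_decreasing(self, n_segments, seed):
        rng = np.random.default_rng(seed)
        gaps = rng.uniform(0, 3, n_segments - 1)
        tr = generate_toy_transcript(n_segments, gaps, 4, seed=seed)
        enr = build_enriched_transcript(tr, "garden")
        assert list(enr.context_ids) == sorted(enr.context_ids)
        assert len(enr.context_ids) == len(whitespace_tokenize(enr.text))


class TestFeatureVector:
    def test_composition_and_arity(self, three_segment_transcript):
        feats = extract_linguistic_features(three_segment_transcript, RuleTagger())
        vec = feats.to_vector()
        assert vec.shape == (9,)
        assert feats.n_short == 1 and feats.n_long == 1 and feats.n_medium == 0
        assert feats.mlu == pytest.approx((3 + 5 + 4) / 3)

    def test_single_segment_composition(self):
        tr = TimedTranscript((TimedSegment(0, 1, "she visited garden"),))
        feats = extract_linguistic_features(tr, RuleTagger())
        assert feats.mlu == 3.0
        assert (feats.n_short, feats.n_medium, feats.n_long) == (0, 0, 0)
        assert (feats.n_noun, feats.n_verb, feats.n_pronoun) == (1, 1, 1)

    def test_field_order_stable(self, three_segment_transcript):
        feats = extract_linguistic_features(three_segment_transcript, RuleTagger())
        expected = np.array(
            [
                feats.mlu,
                feats.n_short,
                feats.n_medium,
                feats.n_long,
                feats.n_noun,
                feats.n_verb,
                feats.n_adjective,
                feats.n_pronoun,
                feats.n_other,
            ]
        )
        np.testing.assert_array_equal(feats.to_vector(), expected)
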