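import numpy as np
import pytest

from ltam.data import (
    CognitiveLabel,
    LongitudinalDataset,
    StoryRecord,
    TimedSegment,
    TimedTranscript,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def three_segment_transcript():
    """Gaps of 0.3 s and 2.5 s -> one short and one long pause."""
    return TimedTranscript(
        (
            TimedSegment(0.0, 1.0, "i went there"),
            TimedSegment(1.3, 2.0, "it was a long day"),
            TimedSegment(4.5, 5.0, "we walked home slowly"),
        )
    )


def make_story(subject, visit, story, label, features=None, transcript=None):
    return StoryRecord(
        subject_id=subject,
        visit_index=visit,
        story_index=story,
        topic="garden",
        label=label,
        transcript=transcript,
        features=features,
    )


@pytest.fixture
def complete_dataset():
    """Two subjects x three visits x one story, with 4-dim features."""
    stories = []
    rng = np.random.default_rng(7)
    for i, subject in enumerate(["s1", "s2"]):
        for v in range(1, 4):
            label = CognitiveLabel.IMPAIRED if (i == 1 and v >= 2) else CognitiveLabel.HC
            stories.append(
                make_story(subject, v, 1, label, features=rng.normal(size=4))
            )
    return LongitudinalDataset(stories, V=3)
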