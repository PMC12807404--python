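"""Alignment and contrastive losses against naive loop oracles, plus their
invariances (scale, rotation, relabeling)."""

import numpy as np
import pytest

from ltam.data import CognitiveLabel
from ltam.losses import (
    EXCLUDED,
    DirectionBatch,
    LossWeights,
    binary_cross_entropy_with_logits,
    encoder_loss,
    group_alignment_loss,
    subject_alignment_loss,
    supcon_loss,
    total_loss,
    transition_code,
)

HC, MCI = CognitiveLabel.HC, CognitiveLabel.IMPAIRED


# ---------------------------------------------------------------------------
# independent naive oracles (pure numpy double loops)


def naive_supcon(z, labels, tau):
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    zn = z / np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)
    n = len(z)
    per_anchor = []
    for i in range(n):
        positives = [p for p in range(n) if p != i and labels[p] == labels[i]]
        if not positives:
            continue
        denom = sum(np.exp(zn[i] @ zn[a] / tau) for a in range(n) if a != i)
        terms = [np.log(np.exp(zn[i] @ zn[p] / tau) / denom) for p in positives]
        per_anchor.append(-np.mean(terms))
    return float(np.mean(per_anchor)) if per_anchor else 0.0


def naive_subject_alignment(directions, subjects, visits, reduction="mean"):
    directions = np.asarray(directions, dtype=float)
    keys = list(zip(subjects, visits))
    total, count = 0.0, 0
    for key in dict.fromkeys(keys):
        idx = [i for i, k in enumerate(keys) if k == key]
        mean = directions[idx].mean(axis=0)
        for i in idx:
            d = directions[i]
            cos = (mean @ d) / max(np.linalg.norm(mean) * np.linalg.norm(d), 1e-12)
            total += 1 - cos
            count += 1
    return total / count if reduction == "mean" else total


# ---------------------------------------------------------------------------


class TestTransitionCode:
    @pytest.mark.parametrize(
        "prev,curr,expected",
        [(HC, HC, 0), (HC, MCI, 1), (MCI, MCI, 2), (MCI, HC, EXCLUDED)],
    )
    def test_mapping(self, prev, curr, expected):
        assert transition_code(prev, curr) == expected


class TestSupCon:
    def test_two_identical_same_label_is_zero(self):
        v = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert supcon_loss(v, [0, 0], 0.07).item() == pytest.approx(0.0, abs=1e-12)

    def test_no_positives_returns_zero_with_warning(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.warns(UserWarning, match="no positive"):
            assert supcon_loss(v, [0, 1], 0.07).item() == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        z = rng.normal(size=(n, 6))
        labels = rng.integers(0, 3, n)
        if len(np.unique(labels)) < 2 or not _has_pos(labels):
            labels[:2] = [0, 0]
        ours = supcon_loss(z, labels, 0.07).item()
        assert ours == pytest.approx(naive_supcon(z, labels, 0.07), abs=1e-6)

    def test_rotation_invariance(self, rng):
        z = rng.normal(size=(6, 4))
        labels = [0, 0, 1, 1, 0, 1]
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        a = supcon_loss(z, labels, 0.1).item()
        b = supcon_loss(z @ Q, labels, 0.1).item()
        assert a == pytest.approx(b, abs=1e-9)

    def test_label_partition_symmetry(self, rng):
        z = rng.normal(size=(6, 4))
        labels = np.array([0, 0, 1, 1, 0, 1])
        a = supcon_loss(z, labels, 0.1).item()
        b = supcon_loss(z, 1 - labels, 0.1).item()
        assert a == pytest.approx(b, abs=1e-12)


def _has_pos(labels):
    labels = np.asarray(labels)
    return any((labels == l).sum() > 1 for l in np.unique(labels))


class TestSubjectAlignment:
    def test_identical_directions_zero(self):
        d = np.tile([1.0, 0.0], (3, 1))
        batch = DirectionBatch(d, ["a"] * 3, [1] * 3, [0] * 3)
        assert subject_alignment_loss(batch).item() == pytest.approx(0.0, abs=1e-7)

    def test_hand_computed_orthogonal_pair(self):
        # one subject, one visit-pair, directions (1,0) and (0,1):
        # mean (0.5, 0.5); each term 1 - cos(45 deg); raw sum 2(1 - sqrt(2)/2)
        d = np.array([[1.0, 0.0], [0.0, 1.0]])
        batch = DirectionBatch(d, ["a", "a"], [1, 1], [0, 0])
        raw = subject_alignment_loss(batch, reduction="sum").item()
        assert raw == pytest.approx(2 * (1 - np.sqrt(2) / 2), abs=1e-9)
        assert raw == pytest.approx(0.58579, abs=1e-5)

    def test_scale_invariance(self, rng):
        d = rng.normal(size=(5, 3))
        subjects = ["a", "a", "b", "b", "b"]
        batch1 = DirectionBatch(d, subjects, [1, 2, 1, 1, 2], [0] * 5)
        batch3 = DirectionBatch(3.0 * d, subjects, [1, 2, 1, 1, 2], [0] * 5)
        assert subject_alignment_loss(batch1).item() == pytest.approx(
            subject_alignment_loss(batch3).item(), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("reduction", ["mean", "sum"])
    def test_matches_naive_oracle(self, seed, reduction):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 16))
        d = rng.normal(size=(n, 4))
        subjects = rng.integers(0, 4, n)
        visits = rng.integers(1, 3, n)
        batch = DirectionBatch(d, subjects, visits, np.zeros(n, dtype=int))
        ours = subject_alignment_loss(batch, reduction=reduction).item()
        ref = naive_subject_alignment(d, subjects, visits, reduction)
        assert ours == pytest.approx(ref, abs=1e-6)


class TestGroupAlignment:
    def test_identical_pair_same_code_zero(self):
        # with a single positive the positive term is the whole denominator
        d = np.tile([0.0, 2.0], (2, 1))
        batch = DirectionBatch(d, list("ab"), [1] * 2, [0] * 2)
        assert group_alignment_loss(batch).item() == pytest.approx(0.0, abs=1e-10)

    def test_identical_larger_batch_hits_supcon_floor(self):
        # k identical same-label vectors floor at log(k-1), not 0 — the
        # denominator contains every positive; the naive oracle agrees
        d = np.tile([0.0, 2.0], (4, 1))
        batch = DirectionBatch(d, list("abcd"), [1] * 4, [0] * 4)
        val = group_alignment_loss(batch).item()
        assert val == pytest.approx(np.log(3), abs=1e-9)
        assert val == pytest.approx(naive_supcon(d, [0] * 4, 0.07), abs=1e-9)

    def test_matches_oracle_with_two_codes(self, rng):
        d = np.vstack(
            [rng.normal([3, 0, 0], 0.1, (4, 3)), rng.normal([0, 3, 0], 0.1, (4, 3))]
        )
        codes = np.array([0] * 4 + [2] * 4)
        batch = DirectionBatch(d, list("abcdefgh"), [1] * 8, codes)
        ours = group_alignment_loss(batch, tau=0.07).item()
        assert ours == pytest.approx(naive_supcon(d, codes, 0.07), abs=1e-6)

    def test_excluded_directions_removed_before_loss(self, rng):
        d = rng.normal(size=(5, 3))
        codes = np.array([0, 0, 2, 2, EXCLUDED])
        batch = DirectionBatch(d, list("abcde"), [1] * 5, codes)
        kept = DirectionBatch(d[:4], list("abcd"), [1] * 4, codes[:4])
        assert group_alignment_loss(batch).item() == pytest.approx(
            group_alignment_loss(kept).item(), abs=1e-12
        )

    def test_too_few_usable_warns_and_returns_zero(self, rng):
        d = rng.normal(size=(2, 3))
        batch = DirectionBatch(d, ["a", "b"], [1, 1], [EXCLUDED, 0])
        with pytest.warns(UserWarning):
            assert group_alignment_loss(batch).item() == 0.0


class TestEncoderLoss:
    def test_identical_hc_embeddings_zero(self):
        z = np.tile([1.0, 1.0], (2, 1))
        val = encoder_loss(z, [0, 0], [2, 3]).item()
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_mixed_batch_matches_oracle(self, rng):
        z = rng.normal(size=(9, 5))
        labels = rng.integers(0, 2, 9)
        labels[:2] = 0
        visits = np.array([1, 2, 3] * 3)
        ours = encoder_loss(z, labels, visits).item()
        keep = visits >= 2
        assert ours == pytest.approx(naive_supcon(z[keep], labels[keep], 0.07), abs=1e-6)

    def test_visit1_included_only_on_request(self, rng):
        z = rng.normal(size=(6, 4))
        labels = [0, 0, 1, 1, 0, 1]
        visits = [1, 1, 2, 2, 3, 3]
        narrow = encoder_loss(z, labels, visits).item()
        wide = encoder_loss(z, labels, visits, include_visit1=True).item()
        assert narrow == pytest.approx(naive_supcon(z[2:], labels[2:], 0.07), abs=1e-6)
        assert wide == pytest.approx(naive_supcon(z, labels, 0.07), abs=1e-6)


class TestTotalLoss:
    def test_default_weight_arithmetic(self):
        val = total_loss(0.7, 1.0, 2.0, 3.0).item()
        assert val == pytest.approx(0.7 + 0.01 * 1.0 + 0.001 * 2.0 + 0.001 * 3.0)

    def test_zero_weights_leave_classification_only(self):
        w = LossWeights(alpha=0, delta=0, gamma=0)
        assert total_loss(0.42, 9.0, 9.0, 9.0, w).item() == pytest.approx(0.42)

    def test_linear_in_each_component(self):
        base = total_loss(0.5, 1.0, 1.0, 1.0).item()
        bumped = total_loss(0.5, 2.0, 1.0, 1.0).item()
        assert bumped - base == pytest.approx(0.01)

    def test_nan_component_rejected_by_name(self):
        with pytest.raises(FloatingPointError, match="l_g"):
            total_loss(0.5, 1.0, float("nan"), 1.0)

    def test_losses_are_nonnegative_on_random_batches(self, rng):
        for _ in range(10):
            z = rng.normal(size=(8, 4))
            labels = rng.integers(0, 2, 8)
            labels[:2] = labels[:2] * 0
            assert supcon_loss(z, labels, 0.07).item() >= -1e-12
            batch = DirectionBatch(
                z, rng.integers(0, 3, 8), rng.integers(1, 3, 8), labels
            )
            s = subject_alignment_loss(batch, reduction="sum").item()
            assert -1e-9 <= s <= 2 * 8  # each cosine term lies in [0, 2]


class TestBce:
    def test_matches_direct_formula(self, rng):
        logits = rng.normal(size=12)
        targets = rng.integers(0, 2, 12).astype(float)
        p = 1 / (1 + np.exp(-logits))
        ref = -np.mean(targets * np.log(p) + (1 - targets) * np.log(1 - p))
        ours = binary_cross_entropy_with_logits(logits, targets).item()
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_stable_for_extreme_logits(self):
        val = binary_cross_entropy_with_logits(
            np.array([500.0, -500.0]), np.array([1.0, 0.0])
        ).item()
        assert val == pytest.approx(0.0, abs=1e-12)
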