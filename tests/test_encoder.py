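"""Acoustic CNN encoder, linguistic encoder with context embeddings, and
attention fusion."""

import numpy as np
import pytest

from ltam.data import TimedSegment, TimedTranscript
from ltam.encoder import (
    AcousticEncoder,
    FusionLayer,
    HashingTokenizer,
    LinguisticEncoder,
    TinyTransformer,
    VectorEncoder,
    acoustic_encode,
    fuse,
    linguistic_encode,
)
from ltam.linguistic import RuleTagger, build_enriched_transcript, extract_linguistic_features
from ltam.nn import Tensor


@pytest.fixture
def text_encoder(rng):
    backbone = TinyTransformer(vocab_size=64, d_model=16, n_heads=4, rng=rng)
    return LinguisticEncoder(
        backbone,
        HashingTokenizer(vocab_size=64),
        latent_dim=24,
        numeric_latent=8,
        rng=rng,
    )


@pytest.fixture
def story_text():
    tr = TimedTranscript(
        (
            TimedSegment(0.0, 1.2, "we went to the garden"),
            TimedSegment(2.5, 3.5, "it was warm"),
        )
    )
    enriched = build_enriched_transcript(tr, "garden")
    feats = extract_linguistic_features(tr, RuleTagger())
    return enriched, feats


class TestAcousticEncoder:
    def test_temporal_reduction_factor_8(self, rng):
        enc = AcousticEncoder(1024, latent_dim=128, rng=rng)
        assert enc.reduced_len == 128  # 1024 / 2 / 2 / 2

    @pytest.mark.parametrize("F", [32, 72, 1024])
    def test_reduction_is_triple_floor_halving(self, F, rng):
        enc = AcousticEncoder(F, latent_dim=16, rng=rng)
        assert enc.reduced_len == ((F // 2) // 2) // 2

    def test_output_latent_width(self, rng):
        enc = AcousticEncoder(64, latent_dim=128, rng=rng).eval()
        out = enc(Tensor(rng.normal(size=(3, 64))))
        assert out.shape == (3, 128)

    def test_zero_input_eval_mode_finite(self, rng):
        enc = AcousticEncoder(32, latent_dim=8, rng=rng).eval()
        out = acoustic_encode(np.zeros(32), enc)
        assert out.shape == (8,)
        assert np.all(np.isfinite(out.data))

    def test_too_short_input_rejected(self, rng):
        with pytest.raises(ValueError):
            AcousticEncoder(4, rng=rng)


class TestLinguisticEncoder:
    def test_output_width(self, text_encoder, story_text):
        text_encoder.eval()
        out = linguistic_encode(*story_text, text_encoder)
        assert out.shape == (24,)

    def test_context_ids_are_used(self, text_encoder, story_text):
        text_encoder.eval()
        enriched, feats = story_text
        ids, ctx = text_encoder.prepare(enriched)
        a = text_encoder(ids, ctx, feats.to_vector()).data
        b = text_encoder(ids, 1 - ctx, feats.to_vector()).data
        assert not np.allclose(a, b)

    def test_zeroed_context_table_matches_plain_encoding(self, text_encoder, story_text):
        text_encoder.eval()
        enriched, feats = story_text
        ids, ctx = text_encoder.prepare(enriched)
        text_encoder.context_emb.weight.data[:] = 0.0
        with_zeroed = text_encoder(ids, ctx, feats.to_vector()).data
        flipped = text_encoder(ids, 1 - ctx, feats.to_vector()).data
        np.testing.assert_allclose(with_zeroed, flipped, atol=1e-12)

    def test_all_context_ids_shift_by_constant_row(self, text_encoder, story_text):
        # with every token marked "content" the input-layer change versus the
        # zeroed table is exactly one constant E_c offset per position
        text_encoder.eval()
        enriched, feats = story_text
        ids, ctx = text_encoder.prepare(enriched)
        all_content = np.ones_like(ctx)
        emb_plus = text_encoder.backbone.embed_tokens(ids) + text_encoder.context_emb(
            all_content
        )
        emb_manual = text_encoder.backbone.embed_tokens(ids).data + (
            text_encoder.context_emb.weight.data[1]
        )
        np.testing.assert_allclose(emb_plus.data, emb_manual, atol=1e-12)

    def test_mismatched_context_length_rejected(self, text_encoder, story_text):
        _, feats = story_text
        with pytest.raises(ValueError, match="mismatch"):
            text_encoder(np.array([1, 2, 3]), np.array([0, 1]), feats.to_vector())

    def test_truncation_to_max_tokens(self, rng):
        backbone = TinyTransformer(vocab_size=32, d_model=8, n_heads=2, max_tokens=6, rng=rng)
        enc = LinguisticEncoder(
            backbone, HashingTokenizer(32), latent_dim=8, numeric_latent=4, rng=rng
        )
        tr = TimedTranscript((TimedSegment(0, 9, " ".join(["word"] * 40)),))
        enriched = build_enriched_transcript(tr, "trip")
        ids, ctx = enc.prepare(enriched)
        assert len(ids) == len(ctx) == 6


class TestFusion:
    def test_sum_is_commutative_before_attention(self, rng):
        fusion = FusionLayer(d_model=12, n_heads=3, rng=rng).eval()
        a = Tensor(rng.normal(size=(4, 12)))
        t = Tensor(rng.normal(size=(4, 12)))
        np.testing.assert_allclose(fusion(a, t).data, fusion(t, a).data, atol=1e-12)

    def test_identity_projections_return_the_sum(self, rng):
        fusion = FusionLayer(d_model=8, n_heads=1, rng=rng).eval()
        fusion.attn.set_identity()
        a = Tensor(rng.normal(size=(2, 8)))
        t = Tensor(rng.normal(size=(2, 8)))
        np.testing.assert_allclose(fusion(a, t).data, a.data + t.data, atol=1e-12)

    def test_dim_mismatch_rejected(self, rng):
        fusion = FusionLayer(d_model=8, n_heads=2, rng=rng)
        with pytest.raises(ValueError):
            fusion(Tensor(rng.normal(size=(2, 8))), Tensor(rng.normal(size=(2, 6))))

    def test_functional_wrapper_output_width(self, rng):
        fusion = FusionLayer(d_model=16, n_heads=4, rng=rng).eval()
        out = fuse(Tensor(rng.normal(size=16)), Tensor(rng.normal(size=16)), fusion)
        assert out.shape == (16,)


class TestDeterminism:
    def test_eval_forward_is_deterministic(self, rng, story_text):
        backbone = TinyTransformer(vocab_size=64, d_model=16, n_heads=4, rng=np.random.default_rng(3))
        enc = LinguisticEncoder(
            backbone, HashingTokenizer(64), latent_dim=24, numeric_latent=8,
            rng=np.random.default_rng(4),
        ).eval()
        enriched, feats = story_text
        a = enc.encode_story(enriched, feats).data
        b = enc.encode_story(enriched, feats).data
        np.testing.assert_array_equal(a, b)

    def test_vector_encoder_shape(self, rng):
        enc = VectorEncoder(10, latent_dim=6, rng=rng)
        assert enc(rng.normal(size=(5, 10))).shape == (5, 6)
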