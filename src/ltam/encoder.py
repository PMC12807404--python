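"""Encoder stage: story features → a fused 128-dimensional story embedding.

Three learned components:

* :class:`AcousticEncoder` — the pooled frame-feature vector (length ``F``,
  1024 with a pretrained speech backbone) is treated as a 1-channel sequence
  and passed through three 1-D convolutions (16/32/64 filters, kernel 3,
  stride 1), each followed by batch norm, ReLU and max-pool 2 — an 8× temporal
  reduction — then flattened and projected to a 128-dim latent.
* :class:`LinguisticEncoder` — the enriched transcript is tokenised and each
  token embedding receives an additive learned *context embedding* (row 0 for
  the topic span, row 1 for story content); a small bidirectional transformer
  encodes the sequence, the first-token vector is pooled, concatenated with an
  affine encoding of the standardised 9-dim numeric features, and projected to
  128 dims.
* :class:`FusionLayer` — the acoustic and linguistic embeddings are summed and
  refined by one multi-head self-attention layer (the sum treated as a
  1-token sequence), yielding the story embedding ``e``.

The text backbone is pluggable: production would bind a pretrained
bidirectional transformer checkpoint; the in-repo :class:`TinyTransformer`
is a small randomly-initialised encoder with the same interface for
desk-scale training and tests.  :class:`VectorEncoder` is the matching
desk-scale binding for precomputed story-level feature vectors.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .linguistic import EnrichedTranscript, LinguisticFeatures, whitespace_tokenize
from .nn import (
    BatchNorm1d,
    Conv1d,
    Dropout,
    Embedding,
    LayerNorm,
    Linear,
    MaxPool1d,
    Module,
    MultiheadAttention,
    Tensor,
    concat,
)

__all__ = [
    "HashingTokenizer",
    "NumericStandardizer",
    "AcousticEncoder",
    "TinyTransformer",
    "LinguisticEncoder",
    "FusionLayer",
    "StoryEncoder",
    "VectorEncoder",
    "acoustic_encode",
    "linguistic_encode",
    "fuse",
]


class HashingTokenizer:
    """Whitespace tokeniser mapping tokens to ids by a stable CRC32 hash.

    Ids 0..n_special-1 are reserved: 0 is the sequence-start token pooled by
    the linguistic encoder; pause markers hash like ordinary tokens.
    """

    BOS_ID = 0

    def __init__(self, vocab_size: int = 512, n_special: int = 1):
        if vocab_size <= n_special:
            raise ValueError("vocab_size too small")
        self.vocab_size = vocab_size
        self.n_special = n_special

    def encode(self, text: str) -> np.ndarray:
        ids = [
            self.n_special
            + zlib.crc32(tok.encode("utf-8")) % (self.vocab_size - self.n_special)
            for tok in whitespace_tokenize(text)
        ]
        return np.asarray(ids, dtype=np.intp)


class NumericStandardizer:
    """Z-scores the 9-dim numeric linguistic features with statistics fit on
    the training fold only (identity until fitted)."""

    def __init__(self):
        self.mean_ = None
        self.scale_ = None

    def fit(self, X: np.ndarray) -> "NumericStandardizer":
        X = np.asarray(X, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.mean_ is None:
            return x
        return (x - self.mean_) / self.scale_


class AcousticEncoder(Module):
    """CNN over the story-level acoustic feature vector (as a 1-channel
    sequence): 3 × [conv(k=3, s=1, same) → BN → ReLU → maxpool(2)] with
    16/32/64 filters, flatten, affine projection to ``latent_dim``."""

    def __init__(
        self, in_features: int, latent_dim: int = 128, rng: np.random.Generator = None
    ):
        super().__init__()
        if in_features < 8:
            raise ValueError("input feature length must be at least 8")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features = in_features
        self.latent_dim = latent_dim
        channels = [1, 16, 32, 64]
        self.convs = [
            Conv1d(channels[i], channels[i + 1], 3, rng) for i in range(3)
        ]
        self.bns = [BatchNorm1d(c) for c in channels[1:]]
        self.pool = MaxPool1d(2)
        reduced = in_features
        for _ in range(3):
            reduced //= 2
        self.reduced_len = reduced  # temporal length after the 8x reduction
        self.proj = Linear(64 * reduced, latent_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, F) -> (B, latent_dim)
        B, F = x.shape
        h = x.reshape(B, 1, F)
        for conv, bn in zip(self.convs, self.bns):
            h = self.pool(bn(conv(h)).relu())
        return self.proj(h.reshape(B, -1))


class TinyTransformer(Module):
    """Small bidirectional transformer text encoder (the desk-scale stand-in
    for a pretrained checkpoint): token + position embeddings, ``n_layers``
    post-norm blocks of self-attention and a feed-forward net, returning the
    full (B, T, D) sequence of contextual token vectors."""

    def __init__(
        self,
        vocab_size: int = 512,
        d_model: int = 32,
        n_heads: int = 4,
        n_layers: int = 1,
        max_tokens: int = 512,
        dropout: float = 0.0,
        rng: np.random.Generator = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d_model = d_model
        self.max_tokens = max_tokens
        self.tok_emb = Embedding(vocab_size, d_model, rng)
        self.pos_emb = Embedding(max_tokens, d_model, rng)
        self.attn = [MultiheadAttention(d_model, n_heads, rng, dropout) for _ in range(n_layers)]
        self.ln1 = [LayerNorm(d_model) for _ in range(n_layers)]
        self.ff1 = [Linear(d_model, 2 * d_model, rng) for _ in range(n_layers)]
        self.ff2 = [Linear(2 * d_model, d_model, rng) for _ in range(n_layers)]
        self.ln2 = [LayerNorm(d_model) for _ in range(n_layers)]
        self.drop = Dropout(dropout, rng)

    def forward(self, input_embeddings: Tensor) -> Tensor:
        # input_embeddings: (B, T, D) — token embeddings (plus any additive
        # context embeddings) supplied by the caller; positions added here.
        B, T, _ = input_embeddings.shape
        h = input_embeddings + self.pos_emb(np.arange(T))
        for attn, ln1, ff1, ff2, ln2 in zip(
            self.attn, self.ln1, self.ff1, self.ff2, self.ln2
        ):
            h = ln1(h + self.drop(attn(h, h, h)))
            h = ln2(h + self.drop(ff2(ff1(h).relu())))
        return h

    def embed_tokens(self, ids: np.ndarray) -> Tensor:
        return self.tok_emb(ids)


class LinguisticEncoder(Module):
    """Text branch: transformer over (token + context) embeddings with
    first-token pooling, concatenated with the numeric branch, projected to
    ``latent_dim``.  Context embedding table has exactly two rows: 0 = topic,
    1 = story content."""

    def __init__(
        self,
        backbone: TinyTransformer,
        tokenizer: HashingTokenizer,
        latent_dim: int = 128,
        numeric_dim: int = 9,
        numeric_latent: int = 16,
        max_tokens: int = 512,
        dropout: float = 0.0,
        rng: np.random.Generator = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.backbone = backbone
        self.tokenizer = tokenizer
        self.max_tokens = min(max_tokens, backbone.max_tokens)
        self.context_emb = Embedding(2, backbone.d_model, rng)
        self.numeric_encoder = Linear(numeric_dim, numeric_latent, rng)
        self.projector = Linear(backbone.d_model + numeric_latent, latent_dim, rng)
        self.drop = Dropout(dropout, rng)
        self.standardizer = NumericStandardizer()

    def prepare(self, xt: EnrichedTranscript) -> tuple[np.ndarray, np.ndarray]:
        """Tokenise and truncate text and context ids together; prepends the
        sequence-start token (context id 0)."""
        ids = self.tokenizer.encode(xt.text)
        ctx = np.asarray(xt.context_ids, dtype=np.intp)
        if ids.shape[0] != ctx.shape[0]:
            raise ValueError(
                f"context ids ({ctx.shape[0]}) do not match token count ({ids.shape[0]})"
            )
        ids = np.concatenate([[self.tokenizer.BOS_ID], ids])[: self.max_tokens]
        ctx = np.concatenate([[0], ctx])[: self.max_tokens]
        return ids, ctx

    def forward(self, token_ids: np.ndarray, context_ids: np.ndarray, numeric: np.ndarray) -> Tensor:
        # single story: token_ids (T,), numeric (9,) -> (latent_dim,)
        if token_ids.shape[0] != context_ids.shape[0]:
            raise ValueError("token/context length mismatch")
        emb = self.backbone.embed_tokens(token_ids) + self.context_emb(
            np.asarray(context_ids, dtype=np.intp)
        )
        T = token_ids.shape[0]
        seq = self.backbone(emb.reshape(1, T, -1))
        pooled = seq[:, 0, :].reshape(-1)  # first-token pooling
        num = self.numeric_encoder(Tensor(self.standardizer.transform(numeric)))
        return self.projector(self.drop(concat([pooled, num], axis=0)))

    def encode_story(self, xt: EnrichedTranscript, xl: LinguisticFeatures) -> Tensor:
        ids, ctx = self.prepare(xt)
        return self.forward(ids, ctx, xl.to_vector())


class FusionLayer(Module):
    """Sum the two modality embeddings and refine with one multi-head
    self-attention layer over the (degenerate, 1-token) fused sequence; the
    value/output projections still apply."""

    def __init__(self, d_model: int = 128, n_heads: int = 4, rng=None, dropout: float = 0.0):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.attn = MultiheadAttention(d_model, n_heads, rng, dropout)
        self.d_model = d_model

    def forward(self, a: Tensor, t: Tensor) -> Tensor:
        # a, t: (B, D) -> (B, D)
        if a.shape != t.shape:
            raise ValueError(f"modality embedding shapes differ: {a.shape} vs {t.shape}")
        s = a + t
        B, D = s.shape
        return self.attn(s.reshape(B, 1, D), s.reshape(B, 1, D), s.reshape(B, 1, D)).reshape(B, D)


@dataclass
class StoryInputs:
    """Preprocessed per-story model inputs for the dual-modal encoder."""

    acoustic: np.ndarray  # (F,)
    token_ids: np.ndarray  # (T,)
    context_ids: np.ndarray  # (T,)
    numeric: np.ndarray  # (9,)


class StoryEncoder(Module):
    """Full dual-modal story encoder: acoustic CNN + linguistic transformer
    branch + attention fusion → one embedding per story."""

    def __init__(
        self,
        acoustic: AcousticEncoder,
        linguistic: LinguisticEncoder,
        fusion: FusionLayer,
    ):
        super().__init__()
        self.acoustic = acoustic
        self.linguistic = linguistic
        self.fusion = fusion
        self.latent_dim = fusion.d_model

    def forward(self, stories: list[StoryInputs]) -> Tensor:
        from .nn import stack

        a = self.acoustic(stack([Tensor(s.acoustic) for s in stories], axis=0))
        t = stack(
            [
                self.linguistic(s.token_ids, s.context_ids, s.numeric)
                for s in stories
            ],
            axis=0,
        )
        return self.fusion(a, t)


class VectorEncoder(Module):
    """Desk-scale encoder for precomputed story-level feature vectors: a
    single affine map to the latent dimension."""

    def __init__(self, in_features: int, latent_dim: int = 32, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.lin = Linear(in_features, latent_dim, rng)
        self.latent_dim = latent_dim

    def forward(self, x) -> Tensor:
        from .nn import as_tensor

        return self.lin(as_tensor(x))


# ---------------------------------------------------------------------------
# functional wrappers


def acoustic_encode(x: np.ndarray, encoder: AcousticEncoder) -> Tensor:
    """Encode one pooled acoustic feature vector to the 128-dim latent."""
    out = encoder(Tensor(np.asarray(x)[None, :]))
    return out.reshape(-1)


def linguistic_encode(
    xt: EnrichedTranscript, xl: LinguisticFeatures, encoder: LinguisticEncoder
) -> Tensor:
    return encoder.encode_story(xt, xl)


def fuse(a: Tensor, t: Tensor, fusion: FusionLayer) -> Tensor:
    """Fuse one acoustic and one linguistic embedding (order-insensitive in
    the sum) into the story embedding."""
    return fusion(a.reshape(1, -1), t.reshape(1, -1)).reshape(-1)
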