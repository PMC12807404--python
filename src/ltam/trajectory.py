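"""Aging-trajectory module (ATM): cross-attention contrast of consecutive
visits, the direction encoder, and the triplet classifier head.

Given the embedding triplet (e1, e2, e3) of one subject's randomly paired
stories at visits 1..3:

* *contrast* enhances the current visit's embedding by cross-attending to the
  previous visit only (query = current, key/value = previous; a residual keeps
  the result anchored to the current visit) — strictly causal, later visits
  are never inputs;
* the *direction encoder* ``f_D`` maps the embedding difference
  ``e_k - e_{k-1}`` through two affine layers with a ReLU (128 → 64 → 32) to a
  32-dim aging-direction vector;
* the classifier concatenates the three enhanced embeddings and the two
  directions (3·128 + 2·32 = 448 at default widths) and applies batch norm
  plus a single affine layer to produce one logit (sigmoid probability).

Both cross-attention applications (visits 1→2 and 2→3) share one layer's
parameters, as do the two direction encodings.  ``ablate_direction=True``
reproduces the "no direction" configuration: the classifier sees only the raw
concatenated embeddings, with no cross-attention or direction input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (
    BatchNorm1d,
    Linear,
    Module,
    MultiheadAttention,
    Tensor,
    as_tensor,
    concat,
)

__all__ = [
    "ContrastAttention",
    "DirectionEncoder",
    "TripletModel",
    "CrossSectionalHead",
    "TripletOutput",
    "contrast",
    "encode_direction",
    "forward_triplet",
    "forward_cross_sectional",
]


class ContrastAttention(Module):
    """Single-layer multi-head cross-attention between consecutive visits
    with a residual connection: out = e_curr + attn(Q=e_curr, K=V=e_prev)."""

    def __init__(self, d_model: int, n_heads: int = 4, rng=None, dropout: float = 0.0):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.attn = MultiheadAttention(d_model, n_heads, rng, dropout)
        self.d_model = d_model

    def forward(self, e_curr: Tensor, e_prev: Tensor) -> Tensor:
        if e_curr.shape != e_prev.shape:
            raise ValueError(
                f"embedding shapes differ: {e_curr.shape} vs {e_prev.shape}"
            )
        B, D = e_curr.shape
        out = self.attn(
            e_curr.reshape(B, 1, D), e_prev.reshape(B, 1, D), e_prev.reshape(B, 1, D)
        )
        return e_curr + out.reshape(B, D)


class DirectionEncoder(Module):
    """f_D: two affine layers with a ReLU between (d_e → hidden → d_d)."""

    def __init__(
        self, d_model: int, direction_dim: int = 32, hidden: int = 64, rng=None
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.fc1 = Linear(d_model, hidden, rng)
        self.fc2 = Linear(hidden, direction_dim, rng)
        self.direction_dim = direction_dim

    def forward(self, e_curr: Tensor, e_prev: Tensor) -> Tensor:
        if e_curr.shape != e_prev.shape:
            raise ValueError(
                f"embedding shapes differ: {e_curr.shape} vs {e_prev.shape}"
            )
        return self.fc2(self.fc1(e_curr - e_prev).relu())


@dataclass
class TripletOutput:
    enhanced: tuple[Tensor, Tensor, Tensor]
    directions: tuple[Tensor, Tensor] | None
    logit: Tensor  # (B,)
    probability: Tensor  # (B,) = sigmoid(logit)


class TripletModel(Module):
    """ATM + classifier over an embedding triplet.

    The first visit has no predecessor, so its enhanced embedding is the
    pass-through e1.  With ``ablate_direction`` the head input is the plain
    concatenation (e1 ‖ e2 ‖ e3).
    """

    def __init__(
        self,
        d_model: int,
        direction_dim: int = 32,
        fd_hidden: int = 64,
        n_heads: int = 4,
        ablate_direction: bool = False,
        rng=None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.d_model = d_model
        self.ablate_direction = ablate_direction
        if not ablate_direction:
            self.contrast = ContrastAttention(d_model, n_heads, rng)
            self.f_d = DirectionEncoder(d_model, direction_dim, fd_hidden, rng)
            head_in = 3 * d_model + 2 * direction_dim
        else:
            head_in = 3 * d_model
        self.head_in = head_in
        self.bn = BatchNorm1d(head_in)
        self.fc = Linear(head_in, 1, rng)

    def forward(self, e1: Tensor, e2: Tensor, e3: Tensor) -> TripletOutput:
        e1, e2, e3 = as_tensor(e1), as_tensor(e2), as_tensor(e3)
        if not (e1.shape == e2.shape == e3.shape):
            raise ValueError("triplet embeddings must share one shape")
        if self.ablate_direction:
            enhanced = (e1, e2, e3)
            directions = None
            features = concat([e1, e2, e3], axis=1)
        else:
            eb2 = self.contrast(e2, e1)
            eb3 = self.contrast(e3, e2)
            d1 = self.f_d(e2, e1)
            d2 = self.f_d(e3, e2)
            enhanced = (e1, eb2, eb3)
            directions = (d1, d2)
            features = concat([e1, eb2, eb3, d1, d2], axis=1)
        logit = self.fc(self.bn(features)).reshape(-1)
        return TripletOutput(
            enhanced=enhanced,
            directions=directions,
            logit=logit,
            probability=logit.sigmoid(),
        )


class CrossSectionalHead(Module):
    """Single-visit classifier: batch norm + affine on one story embedding
    (a separate head, deliberately not the zero-padded triplet head)."""

    def __init__(self, d_model: int, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.bn = BatchNorm1d(d_model)
        self.fc = Linear(d_model, 1, rng)

    def forward(self, e: Tensor) -> tuple[Tensor, Tensor]:
        logit = self.fc(self.bn(as_tensor(e))).reshape(-1)
        return logit, logit.sigmoid()


# ---------------------------------------------------------------------------
# functional wrappers over module instances


def contrast(e_curr, e_prev, module: ContrastAttention) -> Tensor:
    return module(_as_batch(e_curr), _as_batch(e_prev)).reshape(-1)


def encode_direction(e_curr, e_prev, module: DirectionEncoder) -> Tensor:
    return module(_as_batch(e_curr), _as_batch(e_prev)).reshape(-1)


def forward_triplet(e1, e2, e3, model: TripletModel) -> TripletOutput:
    return model(_as_batch(e1), _as_batch(e2), _as_batch(e3))


def forward_cross_sectional(e, head: CrossSectionalHead) -> tuple[Tensor, Tensor]:
    return head(_as_batch(e))


def _as_batch(e) -> Tensor:
    e = as_tensor(e)
    return e.reshape(1, -1) if e.ndim == 1 else e
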