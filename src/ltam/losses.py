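"""Training losses for the longitudinal model.

Four components combine into the total objective

    L = L_class + alpha * L_E + delta * L_G + gamma * L_S

* ``L_class`` — binary cross-entropy on the triplet logit against the
  last-visit label;
* ``L_E`` (encoder loss) — supervised contrastive loss (SupCon) over story
  embeddings labelled by their visit's cognitive status, pulling same-status
  embeddings together;
* ``L_G`` (group alignment) — SupCon over direction vectors labelled by the
  cognitive-status *transition* between the two visits (HC→HC = 0,
  HC→impaired = 1, impaired→impaired = 2; impaired→HC pairs are excluded);
* ``L_S`` (subject alignment) — cosine penalty pulling each subject's
  story-pair direction vectors toward that subject's mean direction for the
  visit pair, enforcing within-subject trajectory consistency.

Default weights: alpha = 0.01, delta = 0.001, gamma = 0.001; SupCon
temperature defaults to 0.07 (the standard for the cited loss).

All losses are differentiable (autograd tensors) and each vectorised form is
tested against a naive loop oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import CognitiveLabel
from .nn import Tensor, as_tensor

__all__ = [
    "EXCLUDED",
    "TransitionCode",
    "LossWeights",
    "DirectionBatch",
    "transition_code",
    "supcon_loss",
    "subject_alignment_loss",
    "group_alignment_loss",
    "encoder_loss",
    "binary_cross_entropy_with_logits",
    "total_loss",
]

#: sentinel for label transitions outside the trained taxonomy (impaired→HC)
EXCLUDED = -1

#: transition codes: 0 = stable HC, 1 = HC→impaired conversion, 2 = stable impaired
TransitionCode = int

_EPS = 1e-8


def transition_code(
    l_prev: CognitiveLabel, l_curr: CognitiveLabel
) -> TransitionCode:
    """Encode a consecutive-visit label pair; reverse transitions
    (impaired→HC) return :data:`EXCLUDED` and are dropped from the group
    alignment loss."""
    if l_prev == CognitiveLabel.HC and l_curr == CognitiveLabel.HC:
        return 0
    if l_prev == CognitiveLabel.HC and l_curr == CognitiveLabel.IMPAIRED:
        return 1
    if l_prev == CognitiveLabel.IMPAIRED and l_curr == CognitiveLabel.IMPAIRED:
        return 2
    return EXCLUDED


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.01  # encoder loss
    delta: float = 0.001  # group alignment loss
    gamma: float = 0.001  # subject alignment loss
    temperature: float = 0.07  # SupCon temperature

    def __post_init__(self):
        if min(self.alpha, self.delta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class DirectionBatch:
    """Direction vectors with the metadata the alignment losses index over."""

    directions: Tensor  # (n, d_d)
    subject_ids: np.ndarray  # (n,) any hashable dtype
    from_visits: np.ndarray  # (n,) visit k-1 of each pair
    codes: np.ndarray  # (n,) transition codes, EXCLUDED allowed

    def __post_init__(self):
        self.directions = as_tensor(self.directions)
        n = self.directions.shape[0]
        self.subject_ids = np.asarray(self.subject_ids)
        self.from_visits = np.asarray(self.from_visits)
        self.codes = np.asarray(self.codes)
        for name in ("subject_ids", "from_visits", "codes"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match directions")


def _row_norms(x: Tensor) -> Tensor:
    return ((x**2).sum(axis=-1, keepdims=True) + _EPS**2).sqrt()


def supcon_loss(z, labels, tau: float = 0.07) -> Tensor:
    """Supervised contrastive loss over a batch of vectors.

    Vectors are L2-normalised internally.  For each anchor with at least one
    positive (same label, other index), the loss is the negative mean over
    positives of ``log(exp(z_i·z_p/tau) / sum_{a != i} exp(z_i·z_a/tau))``;
    anchors without positives are skipped and the result is the mean over
    contributing anchors.  A batch with no positives at all returns 0 with a
    warning.
    """
    z = as_tensor(z)
    labels = np.asarray(labels)
    n = z.shape[0]
    if n < 2:
        raise ValueError("SupCon needs at least 2 vectors")
    zn = z / _row_norms(z)
    sim = (zn @ zn.swapaxes(-1, -2)) / tau  # (n, n)
    offdiag = 1.0 - np.eye(n)
    pos_mask = (labels[:, None] == labels[None, :]).astype(float) * offdiag
    pos_counts = pos_mask.sum(axis=1)
    has_pos = pos_counts > 0
    if not has_pos.any():
        warnings.warn("SupCon batch has no positive pairs; loss is 0", stacklevel=2)
        return Tensor(0.0)
    row_max = Tensor(sim.data.max(axis=1, keepdims=True))  # detached, stability only
    shifted = sim - row_max
    denom = (shifted.exp() * Tensor(offdiag)).sum(axis=1, keepdims=True).log()
    log_prob = shifted - denom
    per_anchor = (Tensor(pos_mask) * log_prob).sum(axis=1) / Tensor(
        np.maximum(pos_counts, 1.0)
    )
    picked = (Tensor(has_pos.astype(float)) * per_anchor).sum() / float(has_pos.sum())
    return -1.0 * picked


def subject_alignment_loss(batch: DirectionBatch, reduction: str = "mean") -> Tensor:
    """Within-subject trajectory-consistency loss.

    For every (subject, visit-pair) group present in the batch the mean
    direction over that group's story-pair directions is formed, and each
    direction contributes ``1 - cos(mean, direction)``.  ``reduction="sum"``
    is the raw double sum; ``"mean"`` divides by the number of terms for
    batch-size independence.  Cosines are epsilon-guarded (1e-8), never NaN.
    """
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    d = batch.directions
    n = d.shape[0]
    if n == 0:
        raise ValueError("empty direction batch")
    keys = [
        (batch.subject_ids[i], batch.from_visits[i]) for i in range(n)
    ]
    uniq = list(dict.fromkeys(keys))
    group_of = np.array([uniq.index(k) for k in keys])
    n_groups = len(uniq)
    averaging = np.zeros((n_groups, n))
    for i, g in enumerate(group_of):
        averaging[g, i] = 1.0
    averaging /= averaging.sum(axis=1, keepdims=True)
    means = Tensor(averaging) @ d  # (n_groups, d_d)
    assigned = Tensor(np.eye(n_groups)[group_of]) @ means  # (n, d_d)
    cos = (assigned * d).sum(axis=1) / (
        _row_norms(assigned).reshape(n) * _row_norms(d).reshape(n)
    )
    terms = 1.0 - cos
    return terms.mean() if reduction == "mean" else terms.sum()


def group_alignment_loss(batch: DirectionBatch, tau: float = 0.07) -> Tensor:
    """SupCon over all non-excluded directions, labelled by transition code."""
    usable = np.flatnonzero(batch.codes != EXCLUDED)
    if usable.size < 2:
        warnings.warn(
            "fewer than 2 usable directions for group alignment; loss is 0",
            stacklevel=2,
        )
        return Tensor(0.0)
    return supcon_loss(batch.directions[usable], batch.codes[usable], tau=tau)


def encoder_loss(
    embeddings,
    visit_labels,
    visits,
    tau: float = 0.07,
    include_visit1: bool = False,
) -> Tensor:
    """SupCon over story embeddings labelled by their visit's cognitive
    status.  By default only embeddings from visit 2 onward contribute (the
    formulation's outer sum starts at the second visit);
    ``include_visit1=True`` widens it to all visits."""
    embeddings = as_tensor(embeddings)
    visits = np.asarray(visits)
    labels = np.asarray(visit_labels)
    mask = np.ones_like(visits, dtype=bool) if include_visit1 else visits >= 2
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        warnings.warn("fewer than 2 embeddings for encoder loss; loss is 0", stacklevel=2)
        return Tensor(0.0)
    return supcon_loss(embeddings[idx], labels[idx], tau=tau)


def binary_cross_entropy_with_logits(logits, targets) -> Tensor:
    """Numerically stable mean BCE on raw logits."""
    x = as_tensor(logits)
    t = Tensor(np.asarray(targets, dtype=np.float64))
    absx = x.relu() + (-1.0 * x).relu()
    return (x.relu() - x * t + ((-1.0 * absx).exp() + 1.0).log()).mean()


def total_loss(l_class, l_e, l_g, l_s, w: LossWeights = LossWeights()) -> Tensor:
    """Weighted combination of the four components."""
    parts = {"l_class": l_class, "l_e": l_e, "l_g": l_g, "l_s": l_s}
    for name, value in parts.items():
        data = as_tensor(value).data
        if not np.all(np.isfinite(data)):
            raise FloatingPointError(f"loss component {name} is not finite")
    return (
        as_tensor(l_class)
        + w.alpha * as_tensor(l_e)
        + w.delta * as_tensor(l_g)
        + w.gamma * as_tensor(l_s)
    )
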