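"""scikit-learn-style estimators wrapping the trainable models.

:class:`TrajectoryClassifier` is the longitudinal model: it consumes visit
triplets of story-level feature vectors, X of shape ``(n_triplets, 3,
n_features)`` (or flattened ``(n, 3*n_features)``), and predicts the
last-visit label.  Fit-time keyword metadata carries what the alignment
losses need: per-visit labels (``visit_labels``, shape ``(n, 3)``) and the
owning subject of each triplet (``groups``).  :class:`CrossSectionalVectorClassifier`
is the single-visit counterpart.

Both follow sklearn conventions (``get_params``/``set_params``,
``fit``/``partial_fit``/``predict_proba``/``predict``, fitted attributes with
a trailing underscore) and compose with sklearn model selection; the
higher-level cross-validation protocol with per-epoch story re-pairing lives
in :mod:`ltam.pipeline` and drives these estimators through ``partial_fit``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .encoder import VectorEncoder
from .losses import (
    DirectionBatch,
    LossWeights,
    binary_cross_entropy_with_logits,
    encoder_loss,
    group_alignment_loss,
    subject_alignment_loss,
    total_loss,
    transition_code,
)
from .nn import Adam, Tensor
from .trajectory import CrossSectionalHead, TripletModel

__all__ = ["TrajectoryClassifier", "CrossSectionalVectorClassifier"]


def _check_X_triplet(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2:
        if X.shape[1] % 3 != 0:
            raise ValueError("flattened triplet X must have 3*d columns")
        X = X.reshape(X.shape[0], 3, X.shape[1] // 3)
    if X.ndim != 3 or X.shape[1] != 3:
        raise ValueError(f"expected (n, 3, d) triplet array, got {X.shape}")
    return X


class TrajectoryClassifier(ClassifierMixin, BaseEstimator):
    """Longitudinal triplet classifier with the aging-trajectory module.

    Parameters mirror the published configuration (latent widths, direction
    dimension, loss weights); the defaults here are the desk-scale profile.
    ``ablate_direction`` removes cross-attention and direction embeddings
    (classifier over raw concatenated embeddings); the two alignment losses
    can be ablated independently via ``gamma``/``delta`` = 0.
    """

    def __init__(
        self,
        latent_dim: int = 32,
        direction_dim: int = 32,
        fd_hidden: int = 64,
        cross_attention_heads: int = 4,
        lr: float = 1e-2,
        batch_size: int = 8,
        max_epochs: int = 50,
        alpha: float = 0.01,
        delta: float = 0.001,
        gamma: float = 0.001,
        tau: float = 0.07,
        ablate_direction: bool = False,
        encoder_loss_include_visit1: bool = False,
        loss_reduction: str = "mean",
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.direction_dim = direction_dim
        self.fd_hidden = fd_hidden
        self.cross_attention_heads = cross_attention_heads
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.alpha = alpha
        self.delta = delta
        self.gamma = gamma
        self.tau = tau
        self.ablate_direction = ablate_direction
        self.encoder_loss_include_visit1 = encoder_loss_include_visit1
        self.loss_reduction = loss_reduction
        self.random_state = random_state

    # -- internals ----------------------------------------------------------
    def _init_model(self, n_features: int) -> None:
        rng = np.random.default_rng(self.random_state)
        self.encoder_ = VectorEncoder(n_features, self.latent_dim, rng)
        self.model_ = TripletModel(
            d_model=self.latent_dim,
            direction_dim=self.direction_dim,
            fd_hidden=self.fd_hidden,
            n_heads=self.cross_attention_heads,
            ablate_direction=self.ablate_direction,
            rng=rng,
        )
        params = self.encoder_.parameters() + self.model_.parameters()
        self.optimizer_ = Adam(params, lr=self.lr)
        self.n_features_in_ = n_features
        self.classes_ = np.array([0, 1])
        self.history_ = []
        self._epoch_rng = np.random.default_rng(self.random_state + 1)
        self.weights_ = LossWeights(
            alpha=self.alpha, delta=self.delta, gamma=self.gamma, temperature=self.tau
        )

    def _forward_losses(self, Xb, yb, visit_labels, groups, training: bool):
        """One forward pass; returns (total, components dict, probs)."""
        from .data import CognitiveLabel

        B = Xb.shape[0]
        mode = self.encoder_.train if training else self.encoder_.eval
        mode()
        (self.model_.train if training else self.model_.eval)()
        embeddings = [self.encoder_(Tensor(Xb[:, k, :])) for k in range(3)]
        out = self.model_(*embeddings)
        l_class = binary_cross_entropy_with_logits(out.logit, yb)

        from .nn import concat

        all_emb = concat(embeddings, axis=0)  # (3B, d)
        visits = np.repeat([1, 2, 3], B)
        labels_flat = np.concatenate(
            [visit_labels[:, 0], visit_labels[:, 1], visit_labels[:, 2]]
        )
        l_e = encoder_loss(
            all_emb,
            labels_flat,
            visits,
            tau=self.tau,
            include_visit1=self.encoder_loss_include_visit1,
        )
        if out.directions is not None:
            d_all = concat(list(out.directions), axis=0)  # (2B, d_d)
            subj = np.concatenate([groups, groups])
            from_v = np.repeat([1, 2], B)
            codes = np.array(
                [
                    transition_code(
                        CognitiveLabel(int(visit_labels[i, k])),
                        CognitiveLabel(int(visit_labels[i, k + 1])),
                    )
                    for k in (0, 1)
                    for i in range(B)
                ]
            )
            batch = DirectionBatch(d_all, subj, from_v, codes)
            l_g = group_alignment_loss(batch, tau=self.tau) if self.delta > 0 else Tensor(0.0)
            l_s = (
                subject_alignment_loss(batch, reduction=self.loss_reduction)
                if self.gamma > 0
                else Tensor(0.0)
            )
        else:
            l_g = Tensor(0.0)
            l_s = Tensor(0.0)
        total = total_loss(l_class, l_e, l_g, l_s, self.weights_)
        comps = {
            "class": l_class.item(),
            "encoder": l_e.item(),
            "group": l_g.item(),
            "subject": l_s.item(),
            "total": total.item(),
        }
        return total, comps, out.probability

    def _run_epoch(self, X, y, visit_labels, groups) -> dict:
        n = X.shape[0]
        order = self._epoch_rng.permutation(n)
        sums = {"class": 0.0, "encoder": 0.0, "group": 0.0, "subject": 0.0, "total": 0.0}
        n_batches = 0
        for start in range(0, n, self.batch_size):
            idx = order[start : start + self.batch_size]
            if idx.size < 2:  # contrastive terms need >= 2 items
                continue
            total, comps, _ = self._forward_losses(
                X[idx], y[idx], visit_labels[idx], groups[idx], training=True
            )
            self.optimizer_.zero_grad()
            total.backward()
            self.optimizer_.step()
            for k in sums:
                sums[k] += comps[k]
            n_batches += 1
        if n_batches == 0:
            raise ValueError("no usable batches (need >= 2 triplets)")
        return {k: v / n_batches for k, v in sums.items()}

    @staticmethod
    def _meta(X, y, visit_labels, groups):
        y = np.asarray(y, dtype=np.float64)
        n = X.shape[0]
        if visit_labels is None:
            visit_labels = np.tile(y[:, None], (1, 3))
        visit_labels = np.asarray(visit_labels, dtype=int)
        if groups is None:
            groups = np.arange(n)
        groups = np.asarray(groups)
        return y, visit_labels, groups

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y, visit_labels=None, groups=None):
        X = _check_X_triplet(X)
        y, visit_labels, groups = self._meta(X, y, visit_labels, groups)
        self._init_model(X.shape[2])
        for _ in range(self.max_epochs):
            self.history_.append(self._run_epoch(X, y, visit_labels, groups))
        return self

    def partial_fit(self, X, y, visit_labels=None, groups=None, classes=None):
        """Run one optimisation epoch on the given triplets (used by the
        cross-validation driver, which resamples story pairings per epoch)."""
        X = _check_X_triplet(X)
        y, visit_labels, groups = self._meta(X, y, visit_labels, groups)
        if not hasattr(self, "model_"):
            self._init_model(X.shape[2])
        self.history_.append(self._run_epoch(X, y, visit_labels, groups))
        return self

    def evaluation_loss(self, X, y, visit_labels=None, groups=None) -> dict:
        """Loss components on held-out triplets (eval mode, no update)."""
        X = _check_X_triplet(X)
        y, visit_labels, groups = self._meta(X, y, visit_labels, groups)
        _, comps, _ = self._forward_losses(X, y, visit_labels, groups, training=False)
        return comps

    def predict_proba(self, X) -> np.ndarray:
        X = _check_X_triplet(X)
        self.encoder_.eval()
        self.model_.eval()
        embeddings = [self.encoder_(Tensor(X[:, k, :])) for k in range(3)]
        p = self.model_(*embeddings).probability.data
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def embed(self, X_stories: np.ndarray) -> np.ndarray:
        """Story-level embeddings (n, latent_dim) for trajectory plots."""
        self.encoder_.eval()
        return self.encoder_(Tensor(np.asarray(X_stories, dtype=np.float64))).data

    def get_state(self) -> list[np.ndarray]:
        return self.encoder_.state_dict() + self.model_.state_dict()

    def set_state(self, state: list[np.ndarray]) -> None:
        n_enc = len(self.encoder_.parameters())
        self.encoder_.load_state_dict(state[:n_enc])
        self.model_.load_state_dict(state[n_enc:])


class CrossSectionalVectorClassifier(ClassifierMixin, BaseEstimator):
    """Single-visit classifier: linear encoder + batch-norm/affine head,
    trained with binary cross-entropy only (no trajectory machinery)."""

    def __init__(
        self,
        latent_dim: int = 32,
        lr: float = 1e-2,
        batch_size: int = 8,
        max_epochs: int = 50,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        rng = np.random.default_rng(self.random_state)
        self.encoder_ = VectorEncoder(X.shape[1], self.latent_dim, rng)
        self.head_ = CrossSectionalHead(self.latent_dim, rng)
        params = self.encoder_.parameters() + self.head_.parameters()
        self.optimizer_ = Adam(params, lr=self.lr)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        self.history_ = []
        epoch_rng = np.random.default_rng(self.random_state + 1)
        self.encoder_.train()
        self.head_.train()
        for _ in range(self.max_epochs):
            order = epoch_rng.permutation(X.shape[0])
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, X.shape[0], self.batch_size):
                idx = order[start : start + self.batch_size]
                if idx.size < 2:
                    continue
                logit, _ = self.head_(self.encoder_(Tensor(X[idx])))
                loss = binary_cross_entropy_with_logits(logit, y[idx])
                self.optimizer_.zero_grad()
                loss.backward()
                self.optimizer_.step()
                epoch_loss += loss.item()
                n_batches += 1
            self.history_.append(epoch_loss / max(n_batches, 1))
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        self.encoder_.eval()
        self.head_.eval()
        _, p = self.head_(self.encoder_(Tensor(X)))
        return np.column_stack([1.0 - p.data, p.data])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)
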