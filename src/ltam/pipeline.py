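"""Training protocol: triplet construction by random story pairing,
subject-wise cross-validation, majority down-sampling, the training loop with
early stopping, subject-level soft voting, metrics, and the 2-D PCA
trajectory projection.

The evaluation unit is the *subject*: folds are split by subject to prevent
leakage of a subject's other visits into training, each last-visit story
yields one triplet (its visit-1/2 partners drawn uniformly at random within
the subject, re-drawn every epoch so the model sees many sampled
transitions), and a subject's prediction is the soft-voted mean probability
over its triplets.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .data import CognitiveLabel, LongitudinalDataset, ValidationError, VisitTriplet
from .estimators import TrajectoryClassifier

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "TrajectoryProjection",
    "TrainConfig",
    "TrainResult",
    "make_triplets",
    "triplets_to_arrays",
    "split_subject_kfold",
    "downsample_majority",
    "soft_vote",
    "compute_metrics",
    "project_trajectories",
    "train",
]

#: epoch tag reserved for the deterministic validation pairing
EVAL_EPOCH = 2**20


@dataclass(frozen=True)
class SplitPlan:
    folds: list[tuple[list[str], list[str]]]
    n_folds: int
    seed: int


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    f1: float
    precision: float
    sensitivity: float
    specificity: float
    auroc: float

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "accuracy",
                "f1",
                "precision",
                "sensitivity",
                "specificity",
                "auroc",
            )
        }


@dataclass
class TrajectoryProjection:
    points: dict[tuple[str, int], np.ndarray]  # (subject, visit) -> (2,)
    arrows: list[tuple[str, np.ndarray, np.ndarray]]
    explained_variance: np.ndarray  # (2,) decreasing


def _subject_rng(seed: int, epoch: int, subject_id: str) -> np.random.Generator:
    token = zlib.crc32(subject_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, epoch, token]))


def make_triplets(
    ds: LongitudinalDataset, seed: int, epoch: int
) -> list[VisitTriplet]:
    """One triplet per last-visit story: the anchor story joined with
    independently uniform story draws from each earlier visit.  Deterministic
    in (seed, epoch, subject); a new epoch re-draws the pairings."""
    triplets: list[VisitTriplet] = []
    for subject in ds.subjects():
        per_visit = [ds.stories_at(subject, v) for v in range(1, ds.V + 1)]
        for v, stories in enumerate(per_visit, start=1):
            if not stories:
                raise ValidationError(f"subject {subject} has no stories at visit {v}")
        rng = _subject_rng(seed, epoch, subject)
        for anchor in per_visit[-1]:
            chosen = [
                stories[int(rng.integers(len(stories)))] for stories in per_visit[:-1]
            ]
            triplets.append(
                VisitTriplet(
                    subject_id=subject,
                    stories=tuple(chosen) + (anchor,),
                    target_label=anchor.label,
                )
            )
    return triplets


def triplets_to_arrays(triplets: list[VisitTriplet]):
    """Stack triplet feature vectors into (X, y, visit_labels, groups)."""
    X = np.stack(
        [np.stack([s.features for s in t.stories]) for t in triplets]
    )  # (n, V, d)
    y = np.array([int(t.target_label) for t in triplets])
    visit_labels = np.array(
        [[int(s.label) for s in t.stories] for t in triplets]
    )
    groups = np.array([t.subject_id for t in triplets])
    return X, y, visit_labels, groups


def split_subject_kfold(
    subject_ids,
    n_folds: int = 10,
    seed: int = 0,
    stratify_labels=None,
) -> SplitPlan:
    """Shuffle subjects and partition into near-equal validation folds
    (optionally stratified by a per-subject label)."""
    subject_ids = list(subject_ids)
    if len(subject_ids) < n_folds:
        raise ValueError(
            f"{len(subject_ids)} subjects cannot fill {n_folds} folds"
        )
    idx = np.arange(len(subject_ids))
    if stratify_labels is not None:
        labels = np.asarray([int(l) for l in stratify_labels])
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(idx, labels)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(idx)
    folds = [
        ([subject_ids[i] for i in tr], [subject_ids[i] for i in va])
        for tr, va in split_iter
    ]
    return SplitPlan(folds=folds, n_folds=n_folds, seed=seed)


def downsample_majority(items, labels, seed: int = 0):
    """Subsample the majority class (without replacement) down to the
    minority count.  Training-set only — never applied to validation data."""
    labels = np.asarray([int(l) for l in labels])
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("down-sampling needs exactly two classes present")
    counts = {c: int((labels == c).sum()) for c in classes}
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    if counts[minority] == counts[majority]:
        return list(items)
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(labels == majority)
    keep = set(rng.choice(maj_idx, size=counts[minority], replace=False).tolist())
    keep |= set(np.flatnonzero(labels == minority).tolist())
    return [item for i, item in enumerate(items) if i in keep]


def soft_vote(probabilities) -> tuple[float, CognitiveLabel]:
    """Subject-level decision: mean probability, impaired iff mean > 0.5
    (ties go to HC)."""
    probs = np.asarray(list(probabilities), dtype=np.float64)
    if probs.size == 0:
        raise ValueError("soft voting needs at least one probability")
    mean = float(probs.mean())
    return mean, (CognitiveLabel.IMPAIRED if mean > 0.5 else CognitiveLabel.HC)


def compute_metrics(y_true, y_prob, threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics at the given threshold plus rank-based AUROC.

    With a single-class truth vector the AUROC is undefined; the report
    carries NaN there (with a warning) while the other metrics are computed.
    """
    y_true = np.asarray([int(v) for v in y_true])
    y_prob = np.asarray(y_prob, dtype=np.float64)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must have equal length")
    y_pred = (y_prob > threshold).astype(int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    n = tp + fp + tn + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    if np.unique(y_true).size < 2:
        warnings.warn("single-class truth: AUROC undefined (NaN)", stacklevel=2)
        auroc = float("nan")
    else:
        auroc = float(roc_auc_score(y_true, y_prob))
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / n,
        f1=f1,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        auroc=auroc,
    )


def project_trajectories(embeddings: dict, labels: dict | None = None) -> TrajectoryProjection:
    """PCA (top-2, mean-centred) projection of per-(subject, visit)
    embeddings, with arrows joining each subject's consecutive visits."""
    keys = sorted(embeddings)
    if len(keys) < 3:
        raise ValueError("need at least 3 embeddings for a trajectory projection")
    M = np.stack([np.asarray(embeddings[k], dtype=np.float64) for k in keys])
    if np.unique(M, axis=0).shape[0] < 2:
        raise ValueError("degenerate input: fewer than 2 distinct vectors")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(M)
    points = {k: coords[i] for i, k in enumerate(keys)}
    arrows = []
    subjects = sorted({s for s, _ in keys})
    for s in subjects:
        visits = sorted(v for subj, v in keys if subj == s)
        for a, b in zip(visits, visits[1:]):
            if b == a + 1:
                arrows.append((s, points[(s, a)], points[(s, b)]))
    return TrajectoryProjection(
        points=points,
        arrows=arrows,
        explained_variance=pca.explained_variance_ratio_[:2],
    )


# ---------------------------------------------------------------------------
# training driver


@dataclass
class TrainConfig:
    n_folds: int = 10
    latent_dim: int = 32
    direction_dim: int = 32
    fd_hidden: int = 64
    cross_attention_heads: int = 4
    lr: float = 1e-2
    batch_size: int = 8
    max_epochs: int = 150
    patience: int = 10
    alpha: float = 0.01
    delta: float = 0.001
    gamma: float = 0.001
    tau: float = 0.07
    ablate_direction: bool = False
    encoder_loss_include_visit1: bool = False
    loss_reduction: str = "mean"
    stratify: bool = True
    #: restore the best-validation-loss checkpoint before evaluating.  Off by
    #: default: selecting a checkpoint on the same validation subjects that
    #: are then scored inflates small-sample validation metrics; the model at
    #: stopping time is the less biased estimator.
    restore_best: bool = False


@dataclass
class TrainResult:
    fold_reports: list[MetricsReport]
    pooled_report: MetricsReport
    subject_probs: dict[str, float]
    subject_truth: dict[str, int]
    histories: list[list[dict]]
    models: list[TrajectoryClassifier] = field(default_factory=list)

    def fold_average(self) -> dict:
        keys = ("accuracy", "f1", "precision", "sensitivity", "specificity", "auroc")
        return {
            k: float(np.nanmean([getattr(r, k) for r in self.fold_reports]))
            for k in keys
        }


def _subset(ds: LongitudinalDataset, subjects) -> LongitudinalDataset:
    subjects = set(subjects)
    return LongitudinalDataset(
        [s for s in ds.stories if s.subject_id in subjects], V=ds.V
    )


def train(ds: LongitudinalDataset, config: TrainConfig, seed: int = 0) -> TrainResult:
    """Subject-wise k-fold training of the longitudinal model.

    Per fold: per-epoch story re-pairing, majority-class down-sampling of the
    training triplets, one optimisation epoch, early stopping on the
    validation total loss (patience ``config.patience``, best state
    restored), then soft-voted subject-level evaluation.
    """
    subjects = ds.subjects()
    last_labels = [int(ds.visit_label(s, ds.V)) for s in subjects]
    strat = last_labels if config.stratify else None
    try:
        plan = split_subject_kfold(subjects, config.n_folds, seed, strat)
    except ValueError:
        if config.stratify:  # tiny class: fall back to unstratified
            plan = split_subject_kfold(subjects, config.n_folds, seed, None)
        else:
            raise

    fold_reports: list[MetricsReport] = []
    histories: list[list[dict]] = []
    models: list[TrajectoryClassifier] = []
    subject_probs: dict[str, float] = {}
    subject_truth: dict[str, int] = {}

    for fold_idx, (train_subjects, val_subjects) in enumerate(plan.folds):
        overlap = set(train_subjects) & set(val_subjects)
        if overlap:  # leakage guard inside the loop, not only in the split
            raise AssertionError(f"subject leakage across split: {overlap}")
        train_ds = _subset(ds, train_subjects)
        val_ds = _subset(ds, val_subjects)
        clf = TrajectoryClassifier(
            latent_dim=config.latent_dim,
            direction_dim=config.direction_dim,
            fd_hidden=config.fd_hidden,
            cross_attention_heads=config.cross_attention_heads,
            lr=config.lr,
            batch_size=config.batch_size,
            alpha=config.alpha,
            delta=config.delta,
            gamma=config.gamma,
            tau=config.tau,
            ablate_direction=config.ablate_direction,
            encoder_loss_include_visit1=config.encoder_loss_include_visit1,
            loss_reduction=config.loss_reduction,
            random_state=seed * 1009 + fold_idx,
        )
        val_triplets = make_triplets(val_ds, seed, EVAL_EPOCH)
        Xv, yv, vlv, gv = triplets_to_arrays(val_triplets)
        best_loss, best_state, wait = np.inf, None, 0
        history: list[dict] = []
        for epoch in range(config.max_epochs):
            triplets = make_triplets(train_ds, seed, epoch)
            labels = [t.target_label for t in triplets]
            if len(set(int(l) for l in labels)) == 2:
                triplets = downsample_majority(
                    triplets, labels, seed=seed * 100003 + epoch
                )
            Xt, yt, vlt, gt = triplets_to_arrays(triplets)
            clf.partial_fit(Xt, yt, visit_labels=vlt, groups=gt)
            comps = clf.evaluation_loss(Xv, yv, visit_labels=vlv, groups=gv)
            record = {"epoch": epoch, **clf.history_[-1]}
            record["val_total"] = comps["total"]
            history.append(record)
            if not np.isfinite(comps["total"]):
                raise FloatingPointError(
                    f"validation loss diverged at epoch {epoch}: {comps}"
                )
            if comps["total"] < best_loss - 1e-8:
                best_loss, best_state, wait = comps["total"], clf.get_state(), 0
            else:
                wait += 1
                if wait >= config.patience:
                    break
        if config.restore_best and best_state is not None:
            clf.set_state(best_state)

        probs = clf.predict_proba(Xv)[:, 1]
        fold_true, fold_prob = [], []
        for subject in val_subjects:
            mask = gv == subject
            mean_prob, _ = soft_vote(probs[mask])
            subject_probs[subject] = mean_prob
            subject_truth[subject] = int(val_ds.visit_label(subject, ds.V))
            fold_true.append(subject_truth[subject])
            fold_prob.append(mean_prob)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-class folds yield NaN AUROC
            fold_reports.append(compute_metrics(fold_true, fold_prob))
        histories.append(history)
        models.append(clf)

    ordered = sorted(subject_probs)
    pooled = compute_metrics(
        [subject_truth[s] for s in ordered], [subject_probs[s] for s in ordered]
    )
    return TrainResult(
        fold_reports=fold_reports,
        pooled_report=pooled,
        subject_probs=subject_probs,
        subject_truth=subject_truth,
        histories=histories,
        models=models,
    )
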