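"""Training loop for the point-cloud classifiers.

Cross-entropy minimization with Adam, gradient accumulation over a
configurable number of examples per optimizer step, optional class
re-balancing (oversampling duplicates minority-class examples within each
epoch until all classes match the majority count; undersampling caps every
class at the minority count), and a per-epoch history of training loss and
validation accuracy.  Everything is driven by one seed.
"""

from __future__ import annotations

import numpy as np

from ..errors import ValidationError
from .base import TrainConfig
from .layers import Adam

__all__ = ["train_model", "build_epoch_indices", "evaluate_accuracy"]


def build_epoch_indices(labels: np.ndarray, scheme: str, rng: np.random.Generator) -> np.ndarray:
    """Example indices visited in one epoch under the given balancing scheme."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if scheme == "none":
        idx = np.arange(labels.size)
    elif scheme == "oversample":
        target = counts.max()
        parts = []
        for c in classes:
            members = np.nonzero(labels == c)[0]
            reps = rng.choice(members, size=target, replace=True) if members.size < target else members
            parts.append(reps)
        idx = np.concatenate(parts)
    elif scheme == "undersample":
        target = counts.min()
        parts = [
            rng.choice(np.nonzero(labels == c)[0], size=target, replace=False) for c in classes
        ]
        idx = np.concatenate(parts)
    else:
        raise ValidationError(f"unknown sampling scheme {scheme!r}")
    rng.shuffle(idx)
    return idx


def evaluate_accuracy(classifier, clouds, labels) -> float:
    """Top-1 accuracy with argmax ties broken by the smallest class id."""
    correct = 0
    for cloud, label in zip(clouds, labels):
        scores = classifier.predict_proba(cloud)
        if int(np.argmax(scores)) == int(label):
            correct += 1
    return correct / max(len(labels), 1)


def train_model(classifier, dataset, cfg: TrainConfig):
    """Train a classifier on labeled point clouds.

    ``dataset`` is a sequence of ``(PointCloud, label)`` pairs; a stratified
    ``cfg.val_fraction`` of it is held out for per-epoch validation accuracy.
    Returns ``(classifier, history)`` where history is a list of per-epoch
    dicts with keys ``epoch``, ``loss`` and ``val_accuracy``.
    """
    clouds = [c for c, _ in dataset]
    labels = np.asarray([int(l) for _, l in dataset])
    if np.unique(labels).size < 2:
        raise ValidationError("training requires at least two classes")

    rng = np.random.default_rng(cfg.seed)
    # stratified train/validation split
    val_mask = np.zeros(labels.size, dtype=bool)
    for c in np.unique(labels):
        members = np.nonzero(labels == c)[0]
        n_val = max(1, int(round(cfg.val_fraction * members.size))) if members.size > 1 else 0
        if n_val:
            val_mask[rng.choice(members, size=n_val, replace=False)] = True
    train_idx = np.nonzero(~val_mask)[0]
    val_idx = np.nonzero(val_mask)[0]
    val_clouds = [clouds[i] for i in val_idx]
    val_labels = labels[val_idx]

    opt = Adam(classifier.parameters(), lr=cfg.learning_rate)
    history = []
    accum = max(1, cfg.grad_accumulation_batches)
    for epoch in range(cfg.epochs):
        classifier.set_training(True)
        order = build_epoch_indices(labels[train_idx], cfg.sampling_scheme, rng)
        epoch_loss, n_seen, pending = 0.0, 0, 0
        opt.zero_grad()
        for j in order:
            i = train_idx[j]
            logits = classifier.forward(clouds[i])
            logp = logits.log_softmax()
            # negative log-likelihood of the true class
            loss = -(logp.reshape(-1).take([int(labels[i])]).sum()) * (1.0 / accum)
            loss.backward()
            epoch_loss += float(loss.data) * accum
            n_seen += 1
            pending += 1
            if pending == accum:
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            opt.step()
            opt.zero_grad()
        val_acc = evaluate_accuracy(classifier, val_clouds, val_labels) if len(val_idx) else float("nan")
        history.append(
            {"epoch": epoch + 1, "loss": epoch_loss / max(n_seen, 1), "val_accuracy": val_acc}
        )
        if cfg.early_stop_accuracy is not None and val_acc >= cfg.early_stop_accuracy:
            break
    return classifier, history
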