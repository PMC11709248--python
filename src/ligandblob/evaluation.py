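"""Data-splitting protocols and multi-class ranking metrics.

Splits operate at the *deposit* level: all ligands from one PDB deposit land
on the same side of any split, so no structure contributes to both training
and testing.  Within that constraint, splits are stratified by ligand group,
which matters because the class distribution is strongly skewed.

Five metrics summarize classifier quality on skewed label spaces:

* accuracy - fraction of examples whose top-ranked group is correct;
* top-10 accuracy - fraction whose correct group ranks within the first ten;
* mean correct prediction rank - average position of the correct group in
  the descending score list (1 = best);
* Brier score - mean squared probability error for the correct class,
  ``mean((1 - p_true)^2)``;
* macro-averaged recall - unweighted mean of per-class recognition rates.

Argmax/rank ties are always broken toward the smallest class id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold

from .errors import ValidationError
from .models.base import PredictionResult

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "deposit_stratified_split",
    "stratified_kfold",
    "rank_of_correct",
    "compute_metrics",
]


@dataclass
class SplitPlan:
    """Assignment of example ids to partitions (or fold indices)."""

    assignment: dict  # example id -> "train" | "val" | "test" | fold int
    group_key: dict  # example id -> deposit id
    strata: dict  # example id -> ligand group

    def members(self, part) -> list:
        return [e for e, p in self.assignment.items() if p == part]


@dataclass
class MetricsReport:
    accuracy: float
    top10_accuracy: float
    mean_correct_rank: float
    brier_score: float
    macro_recall: float
    per_class_recall: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.accuracy > self.top10_accuracy + 1e-12:
            raise ValidationError("accuracy cannot exceed top-10 accuracy")
        if self.mean_correct_rank < 1.0 - 1e-12:
            raise ValidationError("mean correct rank is at least 1")


def _example_arrays(examples):
    ids = [e[0] for e in examples]
    deposits = np.asarray([e[1] for e in examples])
    groups = np.asarray([e[2] for e in examples])
    return ids, deposits, groups


def deposit_stratified_split(
    examples,
    train_frac: float = 0.7,
    val_frac_of_train: float = 0.25,
    seed: int = 0,
) -> SplitPlan:
    """Deposit-grouped, group-stratified train/val/test holdout.

    ``examples`` is a sequence of ``(example_id, deposit_id, ligand_group)``.
    Deposits are assigned whole, in seeded random order, each to the side
    (train pool vs test) that keeps the per-group train fraction closest to
    ``train_frac``; ``val_frac_of_train`` of the train pool is then carved
    out the same way as a validation set.  A warning is emitted for any
    group living entirely inside a single deposit (it cannot be split).
    """
    ids, deposits, groups = _example_arrays(examples)
    rng = np.random.default_rng(seed)

    for g in np.unique(groups):
        dep_of_g = np.unique(deposits[groups == g])
        if dep_of_g.size == 1:
            warnings.warn(
                f"ligand group {g!r} occurs in a single deposit; it will be assigned whole",
                stacklevel=2,
            )

    def greedy_assign(dep_names, dep_comp, frac, labels):
        """Assign deposits whole to side A (with target fraction ``frac``) or B."""
        totals = {g: 0.0 for g in labels}
        for comp in dep_comp.values():
            for g, c in comp.items():
                totals[g] += c
        got_a = {g: 0.0 for g in labels}
        got_b = {g: 0.0 for g in labels}
        assignment = {}
        order = list(dep_names)
        rng.shuffle(order)
        for dep in order:
            comp = dep_comp[dep]

            def err(a_add):
                e = 0.0
                for g, c in comp.items():
                    a = got_a[g] + (c if a_add else 0.0)
                    e += (a - frac * totals[g]) ** 2
                return e

            to_a = err(True) <= err(False)
            assignment[dep] = "A" if to_a else "B"
            tgt = got_a if to_a else got_b
            for g, c in comp.items():
                tgt[g] += c
        return assignment

    dep_names = list(dict.fromkeys(deposits.tolist()))
    comp = {d: {} for d in dep_names}
    for dep, g in zip(deposits, groups):
        comp[dep][g] = comp[dep].get(g, 0) + 1

    stage1 = greedy_assign(dep_names, comp, train_frac, np.unique(groups))
    train_deps = [d for d in dep_names if stage1[d] == "A"]
    comp_train = {d: comp[d] for d in train_deps}
    stage2 = greedy_assign(train_deps, comp_train, val_frac_of_train, np.unique(groups))

    assignment = {}
    for eid, dep in zip(ids, deposits):
        if stage1[dep] == "B":
            assignment[eid] = "test"
        else:
            assignment[eid] = "val" if stage2[dep] == "A" else "train"
    return SplitPlan(
        assignment=assignment,
        group_key=dict(zip(ids, deposits)),
        strata=dict(zip(ids, groups)),
    )


def stratified_kfold(examples, k: int = 3, seed: int = 0) -> SplitPlan:
    """Deposit-grouped stratified k-fold plan (fold index per example)."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    ids, deposits, groups = _example_arrays(examples)
    n_deposits = np.unique(deposits).size
    if k > n_deposits:
        raise ValidationError(f"k={k} exceeds the number of deposits ({n_deposits})")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    codes = {g: i for i, g in enumerate(np.unique(groups))}
    y = np.asarray([codes[g] for g in groups])
    assignment = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(ids)), y, groups=deposits)):
        for i in test_idx:
            assignment[ids[i]] = fold
    # sanity: a deposit must not span folds
    per_dep = {}
    for eid, dep in zip(ids, deposits):
        per_dep.setdefault(dep, set()).add(assignment[eid])
    if any(len(folds) > 1 for folds in per_dep.values()):
        raise ValidationError("internal error: deposit split across folds")
    return SplitPlan(
        assignment=assignment,
        group_key=dict(zip(ids, deposits)),
        strata=dict(zip(ids, groups)),
    )


def rank_of_correct(scores: np.ndarray, true_class: int) -> int:
    """Rank of the true class: 1 + (strictly better classes) + (tied classes
    with a smaller id).  Rank 1 is best."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if not 0 <= true_class < scores.size:
        raise ValidationError("true_class out of range")
    s = scores[true_class]
    better = int(np.sum(scores > s))
    tied_before = int(np.sum((scores == s) & (np.arange(scores.size) < true_class)))
    return 1 + better + tied_before


def compute_metrics(
    predictions: list[PredictionResult],
    truths,
    n_classes: int,
    brier_multiclass: bool = False,
) -> MetricsReport:
    """The five-metric evaluation summary.

    ``brier_multiclass=True`` switches the Brier score to the sum-over-classes
    multiclass variant; the default follows the squared-error-of-the-correct-
    class definition.  Classes absent from ``truths`` are excluded from the
    macro-recall average.
    """
    truths = np.asarray(truths, dtype=np.int64)
    if len(predictions) != truths.size:
        raise ValidationError("predictions and truths must have equal length")
    ranks = np.empty(truths.size)
    p_true = np.empty(truths.size)
    argmaxes = np.empty(truths.size, dtype=np.int64)
    brier_terms = np.empty(truths.size)
    for i, (pred, t) in enumerate(zip(predictions, truths)):
        scores = pred.class_scores
        ranks[i] = rank_of_correct(scores, int(t))
        p_true[i] = scores[t]
        argmaxes[i] = pred.ranked_labels[0]
        if brier_multiclass:
            onehot = np.zeros(n_classes)
            onehot[t] = 1.0
            brier_terms[i] = np.sum((scores - onehot) ** 2)
        else:
            brier_terms[i] = (1.0 - scores[t]) ** 2
    accuracy = float(np.mean(argmaxes == truths))
    top10 = float(np.mean(ranks <= 10))
    per_class = {}
    for c in np.unique(truths):
        mask = truths == c
        per_class[int(c)] = float(np.mean(argmaxes[mask] == c))
    macro = float(np.mean(list(per_class.values())))
    return MetricsReport(
        accuracy=accuracy,
        top10_accuracy=top10,
        mean_correct_rank=float(np.mean(ranks)),
        brier_score=float(np.mean(brier_terms)),
        macro_recall=macro,
        per_class_recall=per_class,
    )
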