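"""SGD training, early stopping, grid search and nested cross-validation.

Model selection follows a nested protocol: for each test fold t the
validation fold is (t+1) mod k and the remaining folds train. Every
(F, w, H) combination of the grid is trained; the combination with the
highest validation generalized correlation coefficient (GCC) wins, and
its already-trained model (not retrained on train+validation) scores the
test fold. Pooling predictions over all test folds gives one confusion
matrix for the whole dataset, with every protein predicted exactly once
by a model that never saw its fold.
"""
from __future__ import annotations

import itertools
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np

from .encoding import FeatureMatrix
from .metrics import ConfusionMatrix, confusion, gcc
from .model import (
    CNNModel,
    Hyperparameters,
    PredictionResult,
    forward,
    loss,
    loss_and_gradients,
)
from .partition import FoldAssignment
from .records import COMPARTMENTS


class LabeledExample(NamedTuple):
    """One training item: id, L x d features, one-hot 4-class target."""

    id: str
    features: np.ndarray
    target: np.ndarray


def make_examples(
    feature_matrices: dict[str, FeatureMatrix | np.ndarray],
    labels: dict[str, str],
    class_order: tuple[str, ...] = COMPARTMENTS,
) -> list[LabeledExample]:
    """Pair encoded features with one-hot targets, sorted by id."""
    examples = []
    for pid in sorted(feature_matrices):
        X = feature_matrices[pid]
        if isinstance(X, FeatureMatrix):
            X = X.values
        y = np.zeros(len(class_order))
        y[class_order.index(labels[pid])] = 1.0
        examples.append(LabeledExample(pid, np.asarray(X, dtype=float), y))
    return examples


class EpochStats(NamedTuple):
    epoch: int
    train_loss: float
    val_loss: float | None
    val_gcc: float | None


@dataclass
class GridSpec:
    """Candidate values for the three architecture hyperparameters.

    The default grid spans 64-256 detectors, widths 7-19 and 64-256
    hidden units; combinations enumerate in F-major, then w, then H
    order.
    """

    F_values: list[int] = field(default_factory=lambda: [64, 128, 256])
    w_values: list[int] = field(default_factory=lambda: [7, 11, 15, 19])
    H_values: list[int] = field(default_factory=lambda: [64, 128, 256])

    def __post_init__(self) -> None:
        if not (self.F_values and self.w_values and self.H_values):
            raise ValueError("grid value lists must be non-empty")
        if any(w % 2 == 0 for w in self.w_values):
            raise ValueError("all candidate motif widths must be odd")

    def combinations(self) -> Iterable[tuple[int, int, int]]:
        return itertools.product(self.F_values, self.w_values, self.H_values)


def _predict_all(
    examples: list[LabeledExample], model: CNNModel
) -> dict[str, PredictionResult]:
    return {ex.id: forward(ex.features, model) for ex in examples}


def _gcc_of(examples: list[LabeledExample], preds: dict[str, PredictionResult],
            class_order: tuple[str, ...]) -> float:
    true = [class_order[int(np.argmax(ex.target))] for ex in examples]
    predicted = [preds[ex.id].predicted for ex in examples]
    return gcc(confusion(true, predicted, class_order))


def train(
    train_set: list[LabeledExample],
    val_set: list[LabeledExample],
    hp: Hyperparameters,
    class_order: tuple[str, ...] = COMPARTMENTS,
    feature_set: str = "PSSM+PROP",
    history: list[EpochStats] | None = None,
) -> CNNModel:
    """Mini-batch SGD with early stopping on validation loss.

    The returned model carries the weights of the epoch with minimum
    validation loss; training halts once ``hp.patience`` consecutive
    epochs fail to improve validation loss, or at ``hp.max_epochs``.
    Fully reproducible given ``hp.seed``. With an empty validation set a
    warning is issued and training runs for the full epoch budget.

    Pass ``history`` (a list) to collect per-epoch statistics.
    """
    if not train_set:
        raise ValueError("empty training set")
    train_ids = {ex.id for ex in train_set}
    if train_ids & {ex.id for ex in val_set}:
        raise ValueError("training and validation sets overlap")
    d = train_set[0].features.shape[1]
    model = CNNModel.initialize(hp, d, class_order, feature_set)
    rng = np.random.default_rng(np.random.SeedSequence([hp.seed, 0xC0FFEE]))
    if not val_set:
        warnings.warn(
            "no validation set: early stopping disabled, training for "
            f"{hp.max_epochs} fixed epochs",
            stacklevel=2,
        )
    best_val = np.inf
    best_params = model.copy_parameters()
    wait = 0
    n = len(train_set)
    for epoch in range(1, hp.max_epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, hp.batch_size):
            batch = [
                (train_set[i].features, train_set[i].target)
                for i in order[start : start + hp.batch_size]
            ]
            batch_loss, grads = loss_and_gradients(batch, model)
            epoch_losses.append(batch_loss)
            for name, g in grads.items():
                getattr(model, name)[...] -= hp.learning_rate * g
        train_loss = float(np.mean(epoch_losses))
        if val_set:
            val_batch = [(ex.features, ex.target) for ex in val_set]
            val_loss = loss(val_batch, model)
            val_gcc = _gcc_of(val_set, _predict_all(val_set, model), class_order)
            if history is not None:
                history.append(EpochStats(epoch, train_loss, val_loss, val_gcc))
            if val_loss < best_val:
                best_val = val_loss
                best_params = model.copy_parameters()
                wait = 0
            else:
                wait += 1
                if wait > hp.patience:
                    break
        else:
            if history is not None:
                history.append(EpochStats(epoch, train_loss, None, None))
            best_params = model.copy_parameters()
    model.set_parameters(best_params)
    return model


def write_history_tsv(history: list[EpochStats], path: str | os.PathLike) -> None:
    """Write the per-epoch training log as TSV."""
    with open(path, "w") as fh:
        fh.write("#epoch\ttrain_loss\tval_loss\tval_gcc\n")
        for st in history:
            vl = "NA" if st.val_loss is None else f"{st.val_loss:.6f}"
            vg = "NA" if st.val_gcc is None else f"{st.val_gcc:.6f}"
            fh.write(f"{st.epoch}\t{st.train_loss:.6f}\t{vl}\t{vg}\n")


@dataclass
class GridSearchResult:
    hyperparameters: Hyperparameters
    model: CNNModel
    val_gcc: float
    all_scores: dict[tuple[int, int, int], float]


def grid_search(
    folds: FoldAssignment,
    test_fold: int,
    grid: GridSpec,
    examples: dict[str, LabeledExample],
    base_hp: Hyperparameters | None = None,
    class_order: tuple[str, ...] = COMPARTMENTS,
    feature_set: str = "PSSM+PROP",
) -> GridSearchResult:
    """Train every grid combination; select by maximum validation GCC.

    Ties break toward the smaller total parameter count, then grid
    enumeration order. Returns the winning combination's already-trained
    model (no retraining on train+validation).
    """
    if folds.k < 3:
        raise ValueError("nested protocol needs k >= 3 (train/val/test)")
    val_fold = (test_fold + 1) % folds.k
    train_ids = [
        pid for pid, f in folds.mapping.items() if f not in (test_fold, val_fold)
    ]
    val_ids = folds.fold_members(val_fold)
    train_set = [examples[i] for i in sorted(train_ids)]
    val_set = [examples[i] for i in val_ids]
    base = base_hp or Hyperparameters(F=1, w=1, H=1)
    best: tuple[float, int, int] | None = None  # (-gcc, n_params, order)
    best_result: GridSearchResult | None = None
    scores: dict[tuple[int, int, int], float] = {}
    d = train_set[0].features.shape[1]
    for order_idx, (F, w, H) in enumerate(grid.combinations()):
        hp = replace(base, F=F, w=w, H=H)
        model = train(train_set, val_set, hp, class_order, feature_set)
        val_gcc = _gcc_of(val_set, _predict_all(val_set, model), class_order)
        scores[(F, w, H)] = val_gcc
        key = (-val_gcc, model.num_parameters(), order_idx)
        if best is None or key < best:
            best = key
            best_result = GridSearchResult(hp, model, val_gcc, scores)
    assert best_result is not None
    best_result.all_scores = scores
    return best_result


@dataclass
class CVResult:
    """Pooled nested-cross-validation outcome."""

    predictions: dict[str, PredictionResult]
    chosen: dict[int, Hyperparameters]
    confusion: ConfusionMatrix

    @property
    def gcc(self) -> float:
        return gcc(self.confusion)


def cross_validate(
    folds: FoldAssignment,
    grid: GridSpec,
    examples: dict[str, LabeledExample],
    base_hp: Hyperparameters | None = None,
    class_order: tuple[str, ...] = COMPARTMENTS,
    feature_set: str = "PSSM+PROP",
) -> CVResult:
    """Nested cross-validation over all folds, pooling test predictions."""
    if folds.k < 3:
        raise ValueError("cross-validation needs k >= 3")
    missing = sorted(set(folds.mapping) - set(examples))
    if missing:
        raise ValueError(f"no features/labels for ids: {missing[:5]} ...")
    predictions: dict[str, PredictionResult] = {}
    chosen: dict[int, Hyperparameters] = {}
    for t in range(folds.k):
        result = grid_search(
            folds, t, grid, examples, base_hp, class_order, feature_set
        )
        chosen[t] = result.hyperparameters
        for pid in folds.fold_members(t):
            predictions[pid] = forward(examples[pid].features, result.model)
    true = []
    predicted = []
    for pid in sorted(predictions):
        true.append(class_order[int(np.argmax(examples[pid].target))])
        predicted.append(predictions[pid].predicted)
    return CVResult(
        predictions=predictions,
        chosen=chosen,
        confusion=confusion(true, predicted, class_order),
    )


def write_predictions_tsv(
    predictions: dict[str, PredictionResult], path: str | os.PathLike
) -> None:
    """Serialize per-id scores and predicted class as TSV."""
    with open(path, "w") as fh:
        first = next(iter(predictions.values()), None)
        order = first.class_order if first else COMPARTMENTS
        fh.write("#id\t" + "\t".join(f"score_{c}" for c in order) + "\tpredicted\n")
        for pid in sorted(predictions):
            p = predictions[pid]
            scores = "\t".join(f"{s:.6f}" for s in p.scores)
            fh.write(f"{pid}\t{scores}\t{p.predicted}\n")
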