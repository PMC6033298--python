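"""Two-stage ("stepwise") fine-tuning orchestration.

The schedule starts from an initialized model (t = 0; any pretrained or
seeded initialization), optionally fine-tunes on a medium-level dataset
(t = 1) and then on the benign/malignant dataset (t = 2).  Whenever a
stage's class count differs from the model head, the head is swapped: all
backbone weights are preserved bit-for-bit and only the head is
re-initialized.  A one-stage schedule (t = 2 only) is the baseline.

Training minimizes the mean of per-sample losses (cross-entropy on class
probabilities) by mini-batch SGD; the model returned by each stage is its
validation-best checkpoint (highest validation AUC for binary heads,
accuracy otherwise; ties broken by lower validation loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import NEGATIVE, POSITIVE, ScoredPatch, auc
from .nn import SmallCNN, cross_entropy_losses, softmax

__all__ = [
    "ModelHandle",
    "StageData",
    "Stage",
    "StageSchedule",
    "TrainingLog",
    "mean_loss",
    "swap_head",
    "run_stage",
    "run_stepwise",
]


def mean_loss(per_sample_losses) -> float:
    """Arithmetic mean of per-sample losses; the training objective."""
    losses = np.asarray(per_sample_losses, dtype=float)
    if losses.size == 0:
        raise ValueError("need at least one per-sample loss")
    if (losses < 0).any():
        raise ValueError("per-sample losses must be nonnegative")
    return float(losses.mean())


@dataclass
class ModelHandle:
    """A backbone + head pair with bookkeeping for swaps and checkpoints."""

    backbone: str
    n_classes: int
    network: SmallCNN

    @classmethod
    def initialize(cls, n_classes: int, seed: int, backbone: str = "small-cnn") -> "ModelHandle":
        if backbone != "small-cnn":
            raise ValueError(
                f"backbone {backbone!r} not available at desk scale; use 'small-cnn'"
            )
        return cls(backbone=backbone, n_classes=n_classes, network=SmallCNN(n_classes, seed=seed))

    def copy(self) -> "ModelHandle":
        return ModelHandle(self.backbone, self.n_classes, self.network.copy())


@dataclass
class StageData:
    """In-memory arrays for one stage (the CLI loads these from manifests)."""

    train_x: np.ndarray  # (N, H, W, 3) floats in [0, 1]
    train_y: np.ndarray  # (N,) int labels in [0, n_classes)
    val_x: np.ndarray
    val_y: np.ndarray


@dataclass
class Stage:
    name: str
    n_classes: int
    data: StageData
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class StageSchedule:
    """Initialization seed plus 1 (baseline) or 2 (stepwise) fine-tuning stages."""

    init_seed: int
    stages: list[Stage]
    backbone: str = "small-cnn"

    def __post_init__(self) -> None:
        if not 1 <= len(self.stages) <= 2:
            raise ValueError("schedule needs 1 or 2 fine-tuning stages")


@dataclass
class EpochRecord:
    stage: str
    epoch: int
    train_loss: float
    val_loss: float
    val_metric: float
    metric_name: str


@dataclass
class TrainingLog:
    epochs: list[EpochRecord] = field(default_factory=list)
    stage_boundaries: list[str] = field(default_factory=list)
    head_swaps: list[tuple[int, int]] = field(default_factory=list)
    selected: dict[str, int] = field(default_factory=dict)

    def extend(self, other: "TrainingLog") -> None:
        self.epochs.extend(other.epochs)
        self.stage_boundaries.extend(other.stage_boundaries)
        self.head_swaps.extend(other.head_swaps)
        self.selected.update(other.selected)


def swap_head(model: ModelHandle, new_class_count: int, seed: int) -> ModelHandle:
    """Return a copy with a freshly initialized head for ``new_class_count``.

    Backbone weights are preserved bit-for-bit.  Swapping to the current
    class count still re-initializes the head (explicitly not a no-op).
    """
    if new_class_count < 2:
        raise ValueError("new_class_count must be >= 2")
    out = model.copy()
    out.network.reinit_head(new_class_count, seed)
    out.n_classes = new_class_count
    return out


def _validation_scores(model: ModelHandle, x: np.ndarray, y: np.ndarray):
    probs = model.network.predict_proba(x)
    losses = cross_entropy_losses(probs, y)
    val_loss = mean_loss(losses)
    if model.n_classes == 2 and len(np.unique(y)) == 2:
        scored = [
            ScoredPatch(score=float(p[1]), truth=POSITIVE if t == 1 else NEGATIVE)
            for p, t in zip(probs, y)
        ]
        return val_loss, auc(scored), "auc"
    metric = float((probs.argmax(axis=1) == y).mean())
    return val_loss, metric, "accuracy"


def run_stage(model: ModelHandle, stage: Stage) -> tuple[ModelHandle, TrainingLog]:
    """Fine-tune ``model`` on one stage; returns its validation-best copy.

    Zero-epoch stages return the model unchanged with an empty log segment.
    A non-finite training loss aborts with a diagnostic.
    """
    log = TrainingLog()
    log.stage_boundaries.append(stage.name)
    if stage.data.train_x.shape[0] == 0:
        raise ValueError(f"stage {stage.name!r}: empty training dataset")
    if stage.n_classes != model.n_classes:
        old = model.n_classes
        model = swap_head(model, stage.n_classes, stage.seed)
        log.head_swaps.append((old, stage.n_classes))
    if stage.epochs == 0:
        return model, log

    work = model.copy()
    rng = np.random.default_rng(stage.seed)
    n = stage.data.train_x.shape[0]
    x32 = np.ascontiguousarray(stage.data.train_x, dtype=np.float32)
    best: tuple[float, float] | None = None  # (-metric, val_loss), lower is better
    best_model = None
    best_epoch = -1
    for epoch in range(stage.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for i in range(0, n, stage.batch_size):
            idx = order[i : i + stage.batch_size]
            xb = x32[idx]
            yb = stage.data.train_y[idx]
            cache: dict = {}
            logits = work.network.forward(xb, cache)
            probs = softmax(logits)
            losses = cross_entropy_losses(probs, yb)
            batch_losses.extend(losses.tolist())
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits = (dlogits / len(yb)).astype(np.float32)
            grads = work.network.backward(cache, dlogits)
            work.network.sgd_step(grads, stage.learning_rate)
        train_loss = mean_loss(batch_losses)
        if not np.isfinite(train_loss):
            raise RuntimeError(f"stage {stage.name!r}: non-finite training loss at epoch {epoch}")
        val_loss, val_metric, metric_name = _validation_scores(
            work, stage.data.val_x, stage.data.val_y
        )
        log.epochs.append(
            EpochRecord(stage.name, epoch, train_loss, val_loss, val_metric, metric_name)
        )
        key = (-val_metric, val_loss)
        if best is None or key < best:
            best = key
            best_model = work.copy()
            best_epoch = epoch
    log.selected[stage.name] = best_epoch
    return best_model, log


def run_stepwise(schedule: StageSchedule) -> tuple[ModelHandle, TrainingLog]:
    """Execute the full schedule: init (t=0) then each fine-tuning stage.

    Head swaps happen automatically whenever the class count changes; the
    final model is the last stage's validation-best checkpoint.
    """
    model = ModelHandle.initialize(
        schedule.stages[0].n_classes, seed=schedule.init_seed, backbone=schedule.backbone
    )
    log = TrainingLog()
    for stage in schedule.stages:
        model, seg = run_stage(model, stage)
        log.extend(seg)
    return model, log
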