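"""Training and cross-validation harness for lane classification.

Protocol: stratified five-fold rotation — per class, a seeded shuffle is
cut into k contiguous test blocks of floor(n/k) ids, a fixed number of
validation ids is taken from the remainder, and the rest train.  The
training set (and only the training set) may then be expanded 15x by the
augmentation module.  Models train with Adam at learning rate 1e-3,
batch 16, at most 15 epochs, with the learning rate cut 10x after 4
epochs without validation-loss improvement and training stopped after 5;
the weights from the best validation epoch are kept.  Test predictions
from the five folds are pooled so every retained lane is tested exactly
once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .augment import AugmentSpec, augment_set
from .core import LABELS, LaneImage
from .errors import FormatError, ParameterError
from .nn import (
    Adam,
    SequentialModel,
    build_tinycnn,
    lanes_to_batch,
    softmax_cross_entropy,
)

#: Index of the designated positive class ("thalassaemia") in LABELS.
POSITIVE_CLASS = "thalassaemia"

KNOWN_ARCHITECTURES = (
    "inceptionv3",
    "mobilenetv2",
    "densenet201",
    "resnet18",
    "resnet50",
    "resnet101",
    "squeezenet",
    "tinycnn",
)


@dataclass(frozen=True)
class ModelSpec:
    """Which architecture to train.

    ``tinycnn`` is the bundled, dependency-free reference network.  The
    seven ImageNet architecture names are reserved in the registry for
    externally provided builders; constructing them without one raises.
    """

    name: str = "tinycnn"
    pretrained: bool = False
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.name not in KNOWN_ARCHITECTURES:
            raise ParameterError(
                f"unknown architecture {self.name!r}; "
                f"known: {KNOWN_ARCHITECTURES}"
            )
        if self.name == "tinycnn" and self.pretrained:
            raise ParameterError("tinycnn has no pretrained weights")


_BUILDERS = {"tinycnn": build_tinycnn}


def register_architecture(name: str, builder) -> None:
    """Plug in an external architecture builder ``(seed, n_classes) -> model``."""
    _BUILDERS[name] = builder


def build_model(spec: ModelSpec, seed: int = 0) -> SequentialModel:
    builder = _BUILDERS.get(spec.name)
    if builder is None:
        raise ParameterError(
            f"architecture {spec.name!r} has no registered builder in this "
            "installation (external pretrained weights are not bundled); "
            "use 'tinycnn' or register_architecture()"
        )
    return builder(seed=seed, n_classes=spec.n_classes)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization parameters (defaults are the protocol values)."""

    batch_size: int = 16
    learning_rate: float = 0.001
    max_epochs: int = 15
    lr_patience: int = 4
    stop_patience: int = 5
    lr_factor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.lr_patience,
               self.stop_patience) < 1:
            raise ParameterError("TrainConfig integers must be positive")
        if self.learning_rate <= 0 or not (0 < self.lr_factor <= 1):
            raise ParameterError("invalid learning-rate settings")


@dataclass
class FoldSplit:
    """Disjoint stratified train/validation/test id lists for one fold."""

    fold_id: int
    train_ids: list
    val_ids: list
    test_ids: list


def make_folds(
    labels: dict,
    k: int = 5,
    val_per_class: int | None = None,
    seed: int = 0,
) -> list[FoldSplit]:
    """Stratified k-fold rotation over a seeded per-class shuffle.

    Per class and fold: floor(n/k) contiguous test ids rotate through
    the shuffled order (the floor remainder is never tested),
    ``val_per_class`` validation ids are drawn from the non-test
    remainder, and the rest train.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    by_class: dict[str, list] = {}
    for id_, cls in labels.items():
        by_class.setdefault(cls, []).append(id_)
    rng = np.random.default_rng(seed)
    shuffled = {}
    for cls in sorted(by_class, key=str):
        ids = sorted(by_class[cls], key=str)
        if len(ids) < k:
            raise ParameterError(
                f"class {cls!r} has {len(ids)} samples, fewer than k={k}"
            )
        shuffled[cls] = [ids[i] for i in rng.permutation(len(ids))]

    folds = []
    for f in range(k):
        train: list = []
        val: list = []
        test: list = []
        for cls, ids in shuffled.items():
            m = len(ids) // k
            block = ids[f * m : (f + 1) * m]
            rest = ids[: f * m] + ids[(f + 1) * m :]
            n_val = val_per_class
            if n_val is None:
                n_val = max(1, round(0.1 * len(rest)))
            if n_val >= len(rest):
                raise ParameterError("val_per_class leaves no training ids")
            test.extend(block)
            val.extend(rest[:n_val])
            train.extend(rest[n_val:])
        folds.append(FoldSplit(fold_id=f + 1, train_ids=train,
                               val_ids=val, test_ids=test))
    return folds


@dataclass
class EarlyStopper:
    """Best-loss tracker implementing LR-plateau reduction and stopping.

    An epoch "improves" when its validation loss is strictly below the
    best seen.  After ``lr_patience`` consecutive non-improving epochs
    the learning rate is multiplied by ``lr_factor`` (once per plateau);
    after ``stop_patience`` consecutive non-improving epochs training
    halts.
    """

    lr_patience: int
    stop_patience: int
    lr_factor: float
    best_loss: float = np.inf
    bad_epochs: int = 0
    lr_scale: float = 1.0

    def update(self, val_loss: float) -> tuple[bool, bool]:
        """Record an epoch; return (improved, should_stop)."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.bad_epochs = 0
            return True, False
        self.bad_epochs += 1
        if self.bad_epochs == self.lr_patience:
            self.lr_scale *= self.lr_factor
        return False, self.bad_epochs >= self.stop_patience


@dataclass
class TrainedModel:
    """A fitted network plus its label vocabulary and provenance."""

    model: SequentialModel
    classes: tuple[str, ...] = LABELS
    history: list[dict] = field(default_factory=list)
    config: TrainConfig | None = None
    model_name: str = "tinycnn"

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)


def _mean_loss(model: SequentialModel, X: np.ndarray, y: np.ndarray,
               batch: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, X.shape[0], batch):
        logits = model.forward(X[i:i + batch])
        loss, _ = softmax_cross_entropy(logits, y[i:i + batch])
        losses.append(loss * logits.shape[0])
        correct += int((logits.argmax(axis=1) == y[i:i + batch]).sum())
    return float(np.sum(losses) / X.shape[0]), correct / X.shape[0]


def fit(
    model: SequentialModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Train with Adam + LR plateau + early stopping; keep best weights."""
    if X_train.shape[0] == 0 or X_val.shape[0] == 0:
        raise FormatError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(lr=cfg.learning_rate)
    stopper = EarlyStopper(cfg.lr_patience, cfg.stop_patience, cfg.lr_factor)
    best_weights = model.clone_weights()
    history: list[dict] = []
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(X_train.shape[0])
        epoch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.forward(X_train[idx])
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            model.backward(dlogits)
            optimizer.lr = cfg.learning_rate * stopper.lr_scale
            optimizer.step(model.layers)
            epoch_losses.append(loss)
        val_loss, val_acc = _mean_loss(model, X_val, y_val)
        train_loss, train_acc = _mean_loss(model, X_train, y_train)
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_acc": train_acc,
                "val_loss": val_loss,
                "val_acc": val_acc,
                "lr": cfg.learning_rate * stopper.lr_scale,
            }
        )
        improved, stop = stopper.update(val_loss)
        if improved:
            best_weights = model.clone_weights()
        if stop:
            break
    model.set_weights(best_weights)
    return TrainedModel(model=model, history=history, config=cfg)


def save_model(trained: TrainedModel, path) -> None:
    """Persist a trained model's weights (npz) with its architecture name."""
    import json
    from pathlib import Path

    weights = trained.model.get_weights()
    arrays = {f"w{i}": w for i, w in enumerate(weights)}
    meta = json.dumps(
        {
            "architecture": trained.model_name,
            "classes": list(trained.classes),
            "n_weights": len(weights),
        }
    )
    np.savez(Path(path), meta=np.array(meta), **arrays)


def load_model(path) -> TrainedModel:
    """Restore a model saved by :func:`save_model`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        weights = [data[f"w{i}"] for i in range(meta["n_weights"])]
    spec = ModelSpec(name=meta["architecture"],
                     n_classes=len(meta["classes"]))
    model = build_model(spec, seed=0)
    model.set_weights(weights)
    return TrainedModel(model=model, classes=tuple(meta["classes"]))


@dataclass
class PredictionRecord:
    """One test-time decision for one lane."""

    lane_id: object
    true_label: str | None
    predicted_label: str
    score: float  # probability of the thalassaemia class
    fold_id: int | None = None


def predict(
    trained: TrainedModel,
    lanes: list[LaneImage],
    fold_id: int | None = None,
    ids: list | None = None,
) -> list[PredictionRecord]:
    """Softmax predictions for a list of lane images."""
    X = lanes_to_batch([lane.pixels for lane in lanes])
    probs = trained.predict_proba(X)
    pos = trained.classes.index(POSITIVE_CLASS)
    records = []
    for i, lane in enumerate(lanes):
        pred = trained.classes[int(np.argmax(probs[i]))]
        records.append(
            PredictionRecord(
                lane_id=ids[i] if ids is not None else i,
                true_label=lane.label,
                predicted_label=pred,
                score=float(probs[i, pos]),
                fold_id=fold_id,
            )
        )
    return records


def _encode(labels: list[str]) -> np.ndarray:
    try:
        return np.array([LABELS.index(lb) for lb in labels], dtype=np.int64)
    except ValueError as exc:
        raise FormatError(f"unknown class label in {set(labels)}") from exc


@dataclass
class CVResult:
    """Pooled predictions and per-fold training histories."""

    records: list[PredictionRecord]
    histories: list[list[dict]]
    folds: list[FoldSplit]
    trained_models: list[TrainedModel] = field(default_factory=list)


def cross_validate(
    lanes: list[LaneImage],
    model_spec: ModelSpec = ModelSpec("tinycnn"),
    cfg: TrainConfig = TrainConfig(),
    k: int = 5,
    val_per_class: int | None = None,
    augment: AugmentSpec | None = None,
) -> CVResult:
    """k-fold cross-validation over labeled lane images.

    One model trains per fold; its test-block predictions are pooled so
    each retained lane is tested exactly once.  When ``augment`` is
    given, the 15x expansion is applied to the training ids only, after
    splitting — validation and test images are never augmented.
    """
    labels = {i: lane.label for i, lane in enumerate(lanes)}
    if any(lb is None for lb in labels.values()):
        raise FormatError("every lane needs a class label for CV")
    folds = make_folds(labels, k=k, val_per_class=val_per_class,
                       seed=cfg.seed)
    all_records: list[PredictionRecord] = []
    histories: list[list[dict]] = []
    trained_models: list[TrainedModel] = []
    for fold in folds:
        train_lanes = [lanes[i] for i in fold.train_ids]
        if augment is not None:
            aug = replace(augment,
                          seed=(augment.seed * 31 + fold.fold_id) % 2**31)
            train_lanes = augment_set(train_lanes, aug)
        X_train = lanes_to_batch([ln.pixels for ln in train_lanes])
        y_train = _encode([ln.label for ln in train_lanes])
        X_val = lanes_to_batch([lanes[i].pixels for i in fold.val_ids])
        y_val = _encode([lanes[i].label for i in fold.val_ids])
        model = build_model(
            model_spec, seed=(cfg.seed * 97 + fold.fold_id) % 2**31
        )
        trained = fit(model, X_train, y_train, X_val, y_val, cfg)
        trained.model_name = model_spec.name
        test_lanes = [lanes[i] for i in fold.test_ids]
        all_records.extend(
            predict(trained, test_lanes, fold_id=fold.fold_id,
                    ids=list(fold.test_ids))
        )
        histories.append(trained.history)
        trained_models.append(trained)
    return CVResult(records=all_records, histories=histories, folds=folds,
                    trained_models=trained_models)
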