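"""Training protocol and evaluation metrics.

The protocol: stratified 60/20/20 train/validation/test split, Adam at
learning rate 0.001, a maximum of 200 training epochs with early
stopping after a patience of 20 epochs on validation loss, restoring
the best-validation weights.  Reported metrics are the mean squared
error between one-hot labels and predicted class probabilities and the
F1-score (positive-class F1 for binary problems, support-weighted mean
of per-class F1 for multiclass).

``compare_enk`` trains the identical architecture twice from one master
seed — differing only in whether the EnK layer is enabled — so the two
arms share split indices, weight initialisation and batch order, and
their metric differences isolate the effect of the layer.
"""

from __future__ import annotations

import csv
import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
import numpy as np

from .errors import ConfigurationError
from .models import Model, ModelSpec, build_model
from .nn import Adam, cross_entropy, softmax
from .simulate import EpochSet

__all__ = [
    "TrainConfig", "History", "EvalReport", "ComparisonReport", "EarlyStopper",
    "derive_seed", "stratified_split", "train", "evaluate", "compare_enk",
    "mse_score", "f1_scores",
]


def derive_seed(master: int, *labels: str) -> int:
    """Deterministic child seed (< 2**31) from a master seed and labels."""
    keys = [zlib.crc32(lab.encode()) for lab in labels]
    ss = np.random.SeedSequence([int(master)] + keys)
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class TrainConfig:
    max_epochs: int = 200
    batch_size: int = 16
    dropout: float = 0.25
    learning_rate: float = 0.001
    patience: int = 20
    split: tuple[float, float, float] = (0.60, 0.20, 0.20)
    seed: int = 0
    monitor: str = "val_loss"

    def __post_init__(self) -> None:
        if not (2 <= self.batch_size <= 16):
            raise ConfigurationError(
                f"batch_size {self.batch_size} outside [2, 16]")
        if not (0.15 <= self.dropout <= 0.75):
            raise ConfigurationError(f"dropout {self.dropout} outside [0.15, 0.75]")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigurationError(f"split {self.split} must sum to 1")
        if any(f <= 0 for f in self.split):
            raise ConfigurationError(f"split fractions must be positive: {self.split}")
        if self.patience >= self.max_epochs:
            raise ConfigurationError("patience must be smaller than max_epochs")
        if self.monitor != "val_loss":
            raise ConfigurationError("only val_loss monitoring is supported")

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based
    stopped_epoch: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "val_loss"])
            for i, (tl, vl) in enumerate(zip(self.train_loss, self.val_loss), 1):
                w.writerow([i, f"{tl:.10g}", f"{vl:.10g}"])


@dataclass
class EvalReport:
    mse: float
    f1: float
    per_class_f1: list[float]
    n_test: int
    config_hash: str = ""
    best_epoch: int = 0
    enk_enabled: bool = False
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComparisonReport:
    """Paired evaluation of one architecture with the EnK off and on.

    Deltas are (EnK on) minus (EnK off): a negative ``delta_mse`` and a
    positive ``delta_f1`` both mean the EnK arm did better.
    """

    off: EvalReport
    on: EvalReport
    delta_mse: float
    delta_f1: float
    history_off: History = None  # type: ignore[assignment]
    history_on: History = None  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------


def stratified_split(
    es: EpochSet,
    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20),
    seed: int = 0,
) -> tuple[EpochSet, EpochSet, EpochSet]:
    """Disjoint, exhaustive train/val/test partition preserving per-class
    proportions.  Validation and test sizes are floored per class; the
    remainder goes to train."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions {fractions} must sum to 1")
    rng = np.random.default_rng(seed)
    tr_idx, va_idx, te_idx = [], [], []
    for c in np.unique(es.labels):
        idx = np.flatnonzero(es.labels == c)
        n = len(idx)
        n_val = int(np.floor(fractions[1] * n))
        n_test = int(np.floor(fractions[2] * n))
        n_train = n - n_val - n_test
        if min(n_train, n_val, n_test) < 1:
            raise ConfigurationError(
                f"class {c} has only {n} epochs; cannot place it in every "
                f"partition under fractions {fractions}")
        perm = rng.permutation(idx)
        tr_idx.append(perm[:n_train])
        va_idx.append(perm[n_train:n_train + n_val])
        te_idx.append(perm[n_train + n_val:])
    order = lambda parts: np.sort(np.concatenate(parts))
    return (es.subset(order(tr_idx)), es.subset(order(va_idx)),
            es.subset(order(te_idx)))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def mse_score(probs: np.ndarray, labels: np.ndarray, n_classes: int) -> float:
    """Mean over epochs and classes of (one-hot - probability)^2."""
    return float(np.mean((_one_hot(labels, n_classes) - probs) ** 2))


def f1_scores(y_true: np.ndarray, y_pred: np.ndarray,
              n_classes: int) -> tuple[list[float], float]:
    """Per-class F1 plus the summary score: positive-class F1 when
    binary, support-weighted mean otherwise.  A class with no true and
    no predicted members scores 0."""
    per_class = []
    support = []
    for c in range(n_classes):
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        denom = 2 * tp + fp + fn
        per_class.append(2 * tp / denom if denom else 0.0)
        support.append(int(np.sum(y_true == c)))
    if n_classes == 2:
        summary = per_class[1]
    else:
        total = sum(support)
        summary = (sum(f * s for f, s in zip(per_class, support)) / total
                   if total else 0.0)
    return per_class, float(summary)


def evaluate(model: Model, test: EpochSet, config_hash: str = "",
             best_epoch: int = 0) -> EvalReport:
    if test.n_epochs == 0:
        raise ConfigurationError("test set is empty")
    n_classes = model.spec.n_classes
    probs = model.predict_proba(test.data)
    preds = probs.argmax(axis=1)
    per_class, f1 = f1_scores(test.labels, preds, n_classes)
    warnings = [
        f"class {c} absent from test set; its F1 reported as 0"
        for c in range(n_classes) if not np.any(test.labels == c)
    ]
    return EvalReport(
        mse=mse_score(probs, test.labels, n_classes),
        f1=f1, per_class_f1=per_class, n_test=test.n_epochs,
        config_hash=config_hash, best_epoch=best_epoch,
        enk_enabled=model.spec.enk_enabled, warnings=warnings)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class EarlyStopper:
    """Stop when the monitored loss has not improved for ``patience``
    epochs; remembers the best epoch (1-based).  With a strictly
    worsening loss from epoch 1 this stops at epoch ``patience + 1``."""

    patience: int
    best_loss: float = np.inf
    best_epoch: int = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record this epoch's loss; returns True if training should stop."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
        return epoch - self.best_epoch >= self.patience


def _val_loss(model: Model, val: EpochSet) -> float:
    probs = softmax(model.logits(val.data, training=False))
    return cross_entropy(probs, _one_hot(val.labels, model.spec.n_classes))


def train(model: Model, train_set: EpochSet, val_set: EpochSet,
          cfg: TrainConfig) -> tuple[Model, History]:
    """Adam + early stopping on validation loss; restores best weights."""
    n_classes = model.spec.n_classes
    onehot = _one_hot(train_set.labels, n_classes)
    x = model._as_input(train_set.data)
    opt = Adam(model.net, lr=cfg.learning_rate)
    batch_rng = np.random.default_rng(derive_seed(cfg.seed, "batch_order"))
    drop_rng = np.random.default_rng(derive_seed(cfg.seed, "dropout"))
    hist = History()
    stopper = EarlyStopper(patience=cfg.patience)
    best_state = model.net.clone_state()
    n = train_set.n_epochs
    for epoch in range(1, cfg.max_epochs + 1):
        order = batch_rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            loss = model.net.loss_and_grads(x[sel], onehot[sel],
                                            training=True, rng=drop_rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss {loss} at epoch {epoch}, "
                    f"batch starting {start}")
            opt.step()
            losses.append(loss)
        vl = _val_loss(model, val_set)
        if not np.isfinite(vl):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(float(vl))
        improved = vl < stopper.best_loss
        stop = stopper.update(epoch, vl)
        if improved:
            best_state = model.net.clone_state()
        if stop:
            break
    hist.best_epoch = stopper.best_epoch
    hist.stopped_epoch = len(hist.train_loss)
    model.net.set_state(best_state)
    return model, hist


def compare_enk(spec: ModelSpec, es: EpochSet, cfg: TrainConfig,
                return_models: bool = False):
    """Train the same architecture with and without the EnK layer from a
    shared master seed and report both test evaluations plus deltas.

    With ``return_models=True`` returns ``(report, {False: model_off,
    True: model_on})`` so callers can run Grad-CAM on the trained arms.
    """
    split_seed = derive_seed(cfg.seed, "split")
    tr, va, te = stratified_split(es, cfg.split, seed=split_seed)
    init_seed = derive_seed(cfg.seed, "init")
    reports: dict[bool, EvalReport] = {}
    histories: dict[bool, History] = {}
    models: dict[bool, Model] = {}
    base = asdict(replace(spec, dropout_rate=cfg.dropout))
    base.pop("enk_enabled")  # the hash covers everything *except* the flag
    tag = hashlib.sha256(
        (cfg.config_hash + json.dumps(base, sort_keys=True)).encode()
    ).hexdigest()[:16]
    for enk in (False, True):
        arm_spec = replace(spec, enk_enabled=enk, dropout_rate=cfg.dropout)
        model = build_model(arm_spec, init_seed=init_seed)
        model, hist = train(model, tr, va, cfg)
        reports[enk] = evaluate(model, te, config_hash=tag,
                                best_epoch=hist.best_epoch)
        histories[enk] = hist
        models[enk] = model
    report = ComparisonReport(
        off=reports[False], on=reports[True],
        delta_mse=reports[True].mse - reports[False].mse,
        delta_f1=reports[True].f1 - reports[False].f1,
        history_off=histories[False], history_on=histories[True])
    if return_models:
        return report, models
    return report
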