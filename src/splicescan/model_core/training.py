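"""Training loop with a stepped learning-rate schedule and run averaging."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ..dataset_builder import LabeledDataset
from .model import SpliceClassifier, build_model
from .specs import TrainSpec

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimization."""


class Optimizer:
    def __init__(self, params: list[np.ndarray]) -> None:
        self.params = params

    def step(self, grads: list[np.ndarray], lr: float) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(Optimizer):
    def step(self, grads, lr):
        for p, g in zip(self.params, grads):
            p -= (lr * g).astype(p.dtype)


class Adam(Optimizer):
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-7, nesterov=False):
        super().__init__(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.nesterov = nesterov
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            if self.nesterov:
                m_hat = b1 * m_hat + (1 - b1) * g / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= (lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.dtype)


def _make_optimizer(name: str, params: list[np.ndarray]) -> Optimizer:
    if name == "adam":
        return Adam(params)
    if name == "nadam":
        return Adam(params, nesterov=True)
    if name == "sgd":
        return SGD(params)
    raise ValueError(f"unsupported optimizer {name!r}")


@dataclass
class EpochRecord:
    epoch: int           # 1-based
    learning_rate: float
    train_loss: float
    train_accuracy: float
    val_loss: float | None = None
    val_accuracy: float | None = None


@dataclass
class TrainingRun:
    model: SpliceClassifier
    history: list[EpochRecord]
    seed: int

    @property
    def final(self) -> EpochRecord:
        return self.history[-1]


@dataclass
class TrainingResult:
    """One or more repeated runs plus metrics averaged across them."""

    runs: list[TrainingRun]
    averaged_history: list[dict] = field(default_factory=list)

    @property
    def model(self) -> SpliceClassifier:
        return self.runs[0].model

    @property
    def history(self) -> list[EpochRecord]:
        return self.runs[0].history


def _average_histories(runs: list[TrainingRun]) -> list[dict]:
    out = []
    for e in range(len(runs[0].history)):
        records = [r.history[e] for r in runs]
        entry = {
            "epoch": records[0].epoch,
            "learning_rate": records[0].learning_rate,
            "train_loss": float(np.mean([r.train_loss for r in records])),
            "train_accuracy": float(np.mean([r.train_accuracy for r in records])),
        }
        if records[0].val_loss is not None:
            entry["val_loss"] = float(np.mean([r.val_loss for r in records]))
            entry["val_accuracy"] = float(np.mean([r.val_accuracy for r in records]))
        out.append(entry)
    return out


def train_single(
    model: SpliceClassifier,
    x_train: np.ndarray,
    y_train: np.ndarray,
    tspec: TrainSpec,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    seed: int | None = None,
) -> TrainingRun:
    """Optimize one model in place; returns the per-epoch history."""
    if len(x_train) == 0:
        raise ValueError("training split is empty")
    seed = tspec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    optimizer = _make_optimizer(tspec.optimizer, model.params)
    history: list[EpochRecord] = []
    for epoch in range(1, tspec.epochs + 1):
        lr = tspec.learning_rate(epoch)
        order = rng.permutation(len(x_train))
        losses, accs = [], []
        for start in range(0, len(order), tspec.batch_size):
            idx = order[start : start + tspec.batch_size]
            loss, acc = model.loss_and_backward(x_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss {loss} at epoch {epoch}, "
                    f"batch {start // tspec.batch_size} (lr={lr})"
                )
            optimizer.step(model.grads, lr)
            losses.append(loss)
            accs.append(acc)
        record = EpochRecord(
            epoch=epoch,
            learning_rate=lr,
            train_loss=float(np.mean(losses)),
            train_accuracy=float(np.mean(accs)),
        )
        if x_val is not None and len(x_val):
            record.val_loss, record.val_accuracy = model.evaluate(x_val, y_val)
        history.append(record)
        logger.info(
            "epoch %d/%d lr=%g loss=%.4f acc=%.4f%s",
            epoch, tspec.epochs, lr, record.train_loss, record.train_accuracy,
            f" val_acc={record.val_accuracy:.4f}" if record.val_accuracy is not None else "",
        )
    return TrainingRun(model=model, history=history, seed=seed)


def train(model: SpliceClassifier, ds: LabeledDataset, tspec: TrainSpec) -> TrainingResult:
    """Train on a split dataset, repeating ``tspec.repetitions`` times.

    The first run optimizes the passed model; further repetitions train fresh
    models built from the same spec with derived seeds. Per-epoch metrics are
    averaged across runs.
    """
    if ds.spec.window_length != model.input_length:
        raise ValueError(
            f"dataset window length {ds.spec.window_length} does not match "
            f"model input length {model.input_length}"
        )
    x_train, y_train = ds.subset_arrays("train")
    x_val, y_val = ds.subset_arrays("validation")
    runs = []
    for rep in range(tspec.repetitions):
        rep_model = model if rep == 0 else build_model(model.spec, seed=model.seed + rep)
        runs.append(
            train_single(rep_model, x_train, y_train, tspec, x_val, y_val, seed=tspec.seed + rep)
        )
    return TrainingResult(runs=runs, averaged_history=_average_histories(runs))
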