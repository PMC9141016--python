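"""Assemble a trainable classifier from a :class:`ModelSpec`."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from ..encoding_io import MIN_VIABLE_FLANKING, WindowSpec
from . import layers as L
from .specs import CBSpec, ModelSpec


class ArchitectureError(ValueError):
    """The input window is too short for the requested block stack."""


class SpliceClassifier:
    """Sequential window classifier with softmax output.

    Built from a :class:`ModelSpec`; holds the layer list, exposes batched
    prediction, and the pieces the trainer needs (forward/backward over the
    cross-entropy loss, parameter traversal, weight persistence).
    """

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        if spec.enforce_min_flanking and spec.input_window.flanking_length < MIN_VIABLE_FLANKING:
            raise ArchitectureError(
                f"flanking length {spec.input_window.flanking_length} is below the minimum "
                f"viable {MIN_VIABLE_FLANKING}; pass enforce_min_flanking=False to override"
            )
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers: list[L.Layer] = []
        length, channels = spec.input_window.window_length, 4

        for bi, block in enumerate(spec.blocks):
            for part in spec.block_order:
                if part == "bn":
                    self.layers.append(L.BatchNorm1D(channels))
                elif part == "relu":
                    self.layers.append(L.ReLU())
                elif part == "conv":
                    self.layers.append(
                        L.Conv1D(channels, block.n_filters, block.filter_width,
                                 l1=spec.l1_strength, l2=spec.l2_strength, rng=rng)
                    )
                    channels = block.n_filters
                elif part == "pool":
                    pool = L.MaxPool1D(block.pool_window, block.pool_stride)
                    length = pool.output_length(length)
                    self.layers.append(pool)
                    if length < 1:
                        raise ArchitectureError(
                            f"block {bi + 1} (filters={block.n_filters}, "
                            f"width={block.filter_width}): length axis collapsed to {length}"
                        )

        if spec.flatten_first:
            self.layers.append(L.Flatten())
            features = length * channels
            for units in spec.dense_units:
                self.layers.append(L.Dense(features, units, rng=rng))
                if spec.dense_activation == "relu":
                    self.layers.append(L.ReLU())
                if spec.dropout_rate:
                    self.layers.append(L.Dropout(spec.dropout_rate, rng=np.random.default_rng(rng.integers(2**32))))
                features = units
        else:
            # position-wise dense head on the channel axis, then flatten
            for units in spec.dense_units:
                self.layers.append(L.Dense(channels, units, rng=rng))
                if spec.dense_activation == "relu":
                    self.layers.append(L.ReLU())
                if spec.dropout_rate:
                    self.layers.append(L.Dropout(spec.dropout_rate, rng=np.random.default_rng(rng.integers(2**32))))
                channels = units
            self.layers.append(L.Flatten())
            features = length * channels
        self.layers.append(L.Dense(features, spec.output_classes, rng=rng))

    # -- introspection ------------------------------------------------------

    @property
    def input_length(self) -> int:
        return self.spec.input_window.window_length

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for p in self.params:
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax class probabilities for a (n, window_length, 4) batch."""
        x = np.asarray(x, dtype=np.float32)
        out = np.empty((len(x), self.spec.output_classes), dtype=np.float64)
        for i in range(0, len(x), batch_size):
            out[i : i + batch_size] = L.softmax(self.forward_logits(x[i : i + batch_size], training=False))
        return out

    def loss_and_backward(self, x: np.ndarray, y_onehot: np.ndarray) -> tuple[float, float]:
        """One training forward+backward; returns (total loss, batch accuracy)."""
        logits = self.forward_logits(x, training=True)
        probs = L.softmax(logits)
        loss = L.cross_entropy(probs, y_onehot) + self.regularization_loss()
        acc = float((probs.argmax(axis=1) == y_onehot.argmax(axis=1)).mean())
        grad = ((probs - y_onehot) / len(x)).astype(np.float32)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss, acc

    def regularization_loss(self) -> float:
        return sum(layer.regularization_loss() for layer in self.layers)

    def evaluate(self, x: np.ndarray, y_onehot: np.ndarray, batch_size: int = 256) -> tuple[float, float]:
        probs = self.predict(x, batch_size=batch_size)
        loss = L.cross_entropy(probs, y_onehot) + self.regularization_loss()
        acc = float((probs.argmax(axis=1) == y_onehot.argmax(axis=1)).mean())
        return loss, acc

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: weights + running stats + embedded spec metadata."""
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                arrays[f"layer{i}_param{j}"] = p
            if isinstance(layer, L.BatchNorm1D):
                arrays[f"layer{i}_running_mean"] = layer.running_mean
                arrays[f"layer{i}_running_var"] = layer.running_var
        meta = {
            "model_spec": _spec_to_dict(self.spec),
            "seed": self.seed,
            "format": "splicescan-checkpoint-v1",
        }
        np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SpliceClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            spec = _spec_from_dict(meta["model_spec"])
            model = cls(spec, seed=meta.get("seed", 0))
            for i, layer in enumerate(model.layers):
                for j, p in enumerate(layer.params):
                    p[...] = data[f"layer{i}_param{j}"]
                if isinstance(layer, L.BatchNorm1D):
                    layer.running_mean[...] = data[f"layer{i}_running_mean"]
                    layer.running_var[...] = data[f"layer{i}_running_var"]
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> SpliceClassifier:
    """Construct an untrained classifier from a declarative spec."""
    return SpliceClassifier(spec, seed=seed)


def _spec_to_dict(spec: ModelSpec) -> dict:
    d = asdict(spec)
    d["input_window"] = spec.input_window.flanking_length
    d["blocks"] = [list(asdict(b).values()) for b in spec.blocks]
    return d


def _spec_from_dict(d: dict) -> ModelSpec:
    d = dict(d)
    d["input_window"] = WindowSpec(d["input_window"])
    d["blocks"] = tuple(CBSpec(*b) for b in d["blocks"])
    for key in ("dense_units", "block_order"):
        d[key] = tuple(d[key])
    return ModelSpec(**d)
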