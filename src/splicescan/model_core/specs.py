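"""Declarative architecture and training-schedule specifications."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..encoding_io import WindowSpec

#: Default convolutional stack: (n_filters, filter_width) per block.
DEFAULT_BLOCKS = ((16, 11), (32, 11), (64, 21), (64, 41))
DEFAULT_DENSE_UNITS = (32, 16)
DEFAULT_L1 = 7e-5


@dataclass(frozen=True)
class CBSpec:
    """One convolutional block: batch-norm, ReLU, conv, max-pool."""

    n_filters: int
    filter_width: int
    pool_window: int = 2
    pool_stride: int | None = None  # None -> stride equals pool_window

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ValueError(f"n_filters must be >= 1, got {self.n_filters}")
        if self.filter_width < 1 or self.filter_width % 2 != 1:
            raise ValueError(f"filter_width must be a positive odd integer, got {self.filter_width}")
        if self.pool_window < 1:
            raise ValueError(f"pool_window must be >= 1, got {self.pool_window}")


@dataclass(frozen=True)
class ModelSpec:
    """Full architecture: block stack, position-wise dense head, softmax output.

    ``block_order`` controls the wiring inside each block; the default
    pre-activation order is batch-norm -> ReLU -> conv -> pool. The hidden
    dense layers act position-wise on the channel axis before flattening
    (``flatten_first=True`` restores the conventional flatten-then-dense
    wiring). At most one of the L1/L2/dropout regularizers is typically set;
    L1/L2 apply to convolution kernels only, dropout follows each hidden
    dense layer.
    """

    input_window: WindowSpec
    blocks: tuple[CBSpec, ...] = tuple(CBSpec(n, w) for n, w in DEFAULT_BLOCKS)
    dense_units: tuple[int, ...] = DEFAULT_DENSE_UNITS
    output_classes: int = 3
    l1_strength: float = DEFAULT_L1
    l2_strength: float = 0.0
    dropout_rate: float = 0.0
    block_order: tuple[str, ...] = ("bn", "relu", "conv", "pool")
    flatten_first: bool = False
    dense_activation: str = "relu"
    enforce_min_flanking: bool = True

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("blocks must be non-empty")
        if self.l1_strength < 0 or self.l2_strength < 0:
            raise ValueError("regularization strengths must be non-negative")
        if sorted(self.block_order) != ["bn", "conv", "pool", "relu"]:
            raise ValueError(f"block_order must permute (bn, relu, conv, pool), got {self.block_order}")


def default_model_spec(flanking_length: int = 200, **overrides) -> ModelSpec:
    """The published default architecture at a given flanking length."""
    return ModelSpec(input_window=WindowSpec(flanking_length), **overrides)


@dataclass(frozen=True)
class TrainSpec:
    """Optimization schedule: Adam, categorical cross-entropy, stepped LR.

    The learning rate holds at ``initial_lr`` before ``lr_drop_epoch``
    (1-based) and at ``initial_lr / lr_drop_factor`` from that epoch onward;
    ``lr_mode='halve_each'`` instead divides again every epoch after the drop.
    ``repetitions`` independent trainings are averaged by the trainer.
    """

    loss: str = "categorical_crossentropy"
    optimizer: str = "adam"
    initial_lr: float = 0.001
    lr_drop_epoch: int = 7
    lr_drop_factor: float = 2.0
    lr_mode: str = "step_once"
    epochs: int = 10
    batch_size: int = 32
    repetitions: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer not in ("adam", "nadam", "sgd"):
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.lr_mode not in ("step_once", "halve_each"):
            raise ValueError(f"unsupported lr_mode {self.lr_mode!r}")

    def learning_rate(self, epoch: int) -> float:
        """Learning rate in effect for a 1-based epoch index."""
        if epoch < self.lr_drop_epoch:
            return self.initial_lr
        if self.lr_mode == "step_once":
            return self.initial_lr / self.lr_drop_factor
        return self.initial_lr / self.lr_drop_factor ** (epoch - self.lr_drop_epoch + 1)
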