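"""Random hyperparameter search space and sampler.

The space enumerates optimizers, initial learning rates, block counts,
per-block filter counts and widths, batch sizes, epoch counts, and
regularizers; a draw is one (ModelSpec, TrainSpec) pair. The search-space
data structure and sampler are provided; running a full search campaign is
the caller's business.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..encoding_io import WindowSpec
from .specs import CBSpec, ModelSpec, TrainSpec

#: Regularizer alternatives: (kind, value) with kind in {l1, l2, dropout}.
DEFAULT_REGULARIZERS = (
    ("dropout", 0.1), ("dropout", 0.2),
    ("l1", 4e-5), ("l1", 7e-5), ("l1", 1e-4),
    ("l2", 4e-5), ("l2", 7e-5), ("l2", 1e-4),
)


@dataclass(frozen=True)
class SearchSpace:
    optimizers: tuple[str, ...] = ("adam", "nadam", "sgd")
    initial_lrs: tuple[float, ...] = (0.01, 0.001)
    n_blocks: tuple[int, ...] = (3, 4, 5, 6)
    filter_counts: tuple[int, ...] = (8, 16, 32, 48, 64, 80, 96)
    filter_widths: tuple[int, ...] = tuple(range(5, 66, 2))
    batch_sizes: tuple[int, ...] = (16, 32, 64)
    epoch_counts: tuple[int, ...] = (8, 10, 12, 14)
    regularizers: tuple[tuple[str, float], ...] = DEFAULT_REGULARIZERS

    def __post_init__(self) -> None:
        for name in (
            "optimizers", "initial_lrs", "n_blocks", "filter_counts",
            "filter_widths", "batch_sizes", "epoch_counts", "regularizers",
        ):
            if not getattr(self, name):
                raise ValueError(f"search-space enumeration {name!r} is empty")

    def contains(self, mspec: ModelSpec, tspec: TrainSpec) -> bool:
        """Exhaustive membership check of a sampled configuration."""
        if tspec.optimizer not in self.optimizers or tspec.initial_lr not in self.initial_lrs:
            return False
        if tspec.batch_size not in self.batch_sizes or tspec.epochs not in self.epoch_counts:
            return False
        if len(mspec.blocks) not in self.n_blocks:
            return False
        for block in mspec.blocks:
            if block.n_filters not in self.filter_counts or block.filter_width not in self.filter_widths:
                return False
        reg = _active_regularizer(mspec)
        return reg in self.regularizers


def _active_regularizer(mspec: ModelSpec) -> tuple[str, float]:
    if mspec.dropout_rate:
        return ("dropout", mspec.dropout_rate)
    if mspec.l2_strength:
        return ("l2", mspec.l2_strength)
    return ("l1", mspec.l1_strength)


def sample_search_space(
    space: SearchSpace,
    n: int,
    seed: int = 0,
    input_window: WindowSpec | None = None,
) -> list[tuple[ModelSpec, TrainSpec]]:
    """Draw ``n`` independent uniform configurations, deterministic in seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    window = input_window or WindowSpec(200)
    rng = np.random.default_rng(seed)

    def pick(options):
        return options[int(rng.integers(len(options)))]

    configs = []
    for _ in range(n):
        blocks = tuple(
            CBSpec(n_filters=pick(space.filter_counts), filter_width=pick(space.filter_widths))
            for _ in range(pick(space.n_blocks))
        )
        kind, value = pick(space.regularizers)
        mspec = ModelSpec(
            input_window=window,
            blocks=blocks,
            l1_strength=value if kind == "l1" else 0.0,
            l2_strength=value if kind == "l2" else 0.0,
            dropout_rate=value if kind == "dropout" else 0.0,
        )
        tspec = TrainSpec(
            optimizer=pick(space.optimizers),
            initial_lr=pick(space.initial_lrs),
            batch_size=pick(space.batch_sizes),
            epochs=pick(space.epoch_counts),
        )
        configs.append((mspec, tspec))
    return configs
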