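"""Build the three-class labeled window dataset and its train/val/test split.

Labels are encoded as integers 0=donor, 1=acceptor, 2=other, matching the
one-hot convention donor=[1,0,0], acceptor=[0,1,0], other=[0,0,1]. One window
is produced per annotated site plus ``round(negatives_per_site x n_sites)``
"other" windows drawn uniformly without replacement from non-site positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding_io import GeneRecord, WindowSpec, encode_windows_dense

logger = logging.getLogger(__name__)

LABELS = ("donor", "acceptor", "other")
LABEL_ONEHOT = np.eye(3, dtype=np.float32)  # row i one-hot encodes LABELS[i]
SPLITS = ("train", "validation", "test")

#: Default other:site sampling ratio; reproduces a generic:positive class
#: balance of 496,290 : 315,898 at full scale.
DEFAULT_NEGATIVES_PER_SITE = 1.571


@dataclass(frozen=True)
class DatasetComposition:
    """Class counts of a window dataset."""

    n_donor: int
    n_acceptor: int
    n_other: int

    @property
    def total(self) -> int:
        return self.n_donor + self.n_acceptor + self.n_other

    @property
    def negatives_per_site(self) -> float:
        return self.n_other / (self.n_donor + self.n_acceptor)


@dataclass
class LabeledDataset:
    """Encoded windows with labels, provenance, and a split assignment.

    ``X`` holds the stacked one-hot window matrices; row ``i`` of every array
    describes the same window. ``split`` is empty until
    :func:`split_dataset` assigns one of ``train``/``validation``/``test``
    per window.
    """

    X: np.ndarray                 # (n, window_length, 4) float32
    labels: np.ndarray            # (n,) int, index into LABELS
    gene_ids: np.ndarray          # (n,) str
    centers: np.ndarray           # (n,) int, 0-based window centers
    spec: WindowSpec
    seed: int
    split: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    def __post_init__(self) -> None:
        n = len(self.X)
        if not (len(self.labels) == len(self.gene_ids) == len(self.centers) == n):
            raise ValueError("dataset arrays must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def labels_onehot(self) -> np.ndarray:
        return LABEL_ONEHOT[self.labels]

    @property
    def composition(self) -> DatasetComposition:
        counts = np.bincount(self.labels, minlength=3)
        return DatasetComposition(int(counts[0]), int(counts[1]), int(counts[2]))

    def indices_for(self, split_name: str) -> np.ndarray:
        if self.split.size == 0:
            raise ValueError("dataset has no split assignment; call split_dataset first")
        return np.flatnonzero(self.split == split_name)

    def subset_arrays(self, split_name: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.indices_for(split_name)
        return self.X[idx], self.labels_onehot[idx]


def build_dataset(
    genes: list[GeneRecord],
    spec: WindowSpec,
    negatives_per_site: float = DEFAULT_NEGATIVES_PER_SITE,
    seed: int = 0,
    exclusion_radius: int = 0,
) -> LabeledDataset:
    """Extract one window per annotated site plus sampled "other" windows.

    Negative centers are drawn uniformly without replacement from the pooled
    non-site positions of all genes; ``exclusion_radius`` additionally bars
    positions within that distance of any annotated site (default 0: only the
    sites themselves are excluded). Genes without any annotated site are
    skipped with a logged notice. Deterministic for a given seed.
    """
    if negatives_per_site <= 0:
        raise ValueError("negatives_per_site must be > 0")
    used_genes = []
    for gene in genes:
        if gene.donor_sites or gene.acceptor_sites:
            used_genes.append(gene)
        else:
            logger.info("gene %s has no annotated sites; skipped", gene.id)
    if not used_genes:
        raise ValueError("no gene carries an annotated splice site")

    rng = np.random.default_rng(seed)
    pos_gene_idx, pos_centers, pos_labels = [], [], []
    allowed_gene_idx, allowed_centers = [], []
    for gi, gene in enumerate(used_genes):
        for p in gene.donor_sites:
            pos_gene_idx.append(gi); pos_centers.append(p); pos_labels.append(0)
        for p in gene.acceptor_sites:
            pos_gene_idx.append(gi); pos_centers.append(p); pos_labels.append(1)
        excluded = set()
        for p in gene.site_positions:
            excluded.update(range(p - exclusion_radius, p + exclusion_radius + 1))
        allowed = np.setdiff1d(
            np.arange(len(gene.sequence)), np.fromiter(excluded, dtype=np.int64, count=len(excluded))
        )
        allowed_gene_idx.append(np.full(len(allowed), gi, dtype=np.int64))
        allowed_centers.append(allowed)

    n_sites = len(pos_centers)
    n_negatives = round(negatives_per_site * n_sites)
    pool_gene_idx = np.concatenate(allowed_gene_idx)
    pool_centers = np.concatenate(allowed_centers)
    if n_negatives > len(pool_centers):
        raise ValueError(
            f"requested {n_negatives} negative windows but only "
            f"{len(pool_centers)} non-site positions are available"
        )
    pick = rng.choice(len(pool_centers), size=n_negatives, replace=False)

    gene_idx = np.concatenate([np.asarray(pos_gene_idx, dtype=np.int64), pool_gene_idx[pick]])
    centers = np.concatenate([np.asarray(pos_centers, dtype=np.int64), pool_centers[pick]])
    labels = np.concatenate(
        [np.asarray(pos_labels, dtype=np.int64), np.full(n_negatives, 2, dtype=np.int64)]
    )

    # encode per gene to reuse each gene's padded one-hot matrix
    X = np.zeros((len(centers), spec.window_length, 4), dtype=np.float32)
    for gi, gene in enumerate(used_genes):
        rows = np.flatnonzero(gene_idx == gi)
        if rows.size:
            X[rows] = encode_windows_dense(gene, centers[rows], spec)
    gene_ids = np.array([used_genes[gi].id for gi in gene_idx], dtype=object)
    return LabeledDataset(X=X, labels=labels, gene_ids=gene_ids, centers=centers, spec=spec, seed=seed)


def split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Split ``n`` items by cumulative rounding (exact within +-1 per split)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    c1 = round(fractions[0] * n)
    c2 = round((fractions[0] + fractions[1]) * n)
    return c1, c2 - c1, n - c2


def split_dataset(
    ds: LabeledDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    stratify_by: str = "window",
    seed: int = 0,
) -> LabeledDataset:
    """Assign every window to train/validation/test.

    ``window`` mode shuffles windows independently; ``gene`` mode keeps all
    windows of a gene in a single split (assigning shuffled genes greedily to
    the split with the largest remaining window deficit). Returns a new
    dataset sharing the underlying arrays, with ``split`` populated.
    """
    n = len(ds)
    n_train, n_val, n_test = split_sizes(n, fractions)
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=object)
    if stratify_by == "window":
        order = rng.permutation(n)
        assignment[order[:n_train]] = "train"
        assignment[order[n_train : n_train + n_val]] = "validation"
        assignment[order[n_train + n_val :]] = "test"
    elif stratify_by == "gene":
        targets = {"train": n_train, "validation": n_val, "test": n_test}
        filled = {s: 0 for s in SPLITS}
        unique_genes = rng.permutation(np.unique(ds.gene_ids.astype(str)))
        for gene_id in unique_genes:
            mask = ds.gene_ids == gene_id
            deficit = {s: targets[s] - filled[s] for s in SPLITS}
            best = max(SPLITS, key=lambda s: deficit[s])
            assignment[mask] = best
            filled[best] += int(mask.sum())
    else:
        raise ValueError(f"unknown stratify_by {stratify_by!r}")
    return LabeledDataset(
        X=ds.X, labels=ds.labels, gene_ids=ds.gene_ids, centers=ds.centers,
        spec=ds.spec, seed=ds.seed, split=assignment,
    )


# ---------------------------------------------------------------------------
# Serialization: compressed arrays + sidecar JSON manifest
# ---------------------------------------------------------------------------

def save_dataset(ds: LabeledDataset, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out_dir / "windows.npz",
        X=ds.X,
        labels=ds.labels,
        centers=ds.centers,
        gene_ids=ds.gene_ids.astype(str),
        split=ds.split.astype(str) if ds.split.size else np.array([], dtype=str),
    )
    comp = ds.composition
    manifest = {
        "flanking_length": ds.spec.flanking_length,
        "window_length": ds.spec.window_length,
        "seed": ds.seed,
        "n_windows": len(ds),
        "composition": {"donor": comp.n_donor, "acceptor": comp.n_acceptor, "other": comp.n_other},
        "labels": list(LABELS),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def load_dataset(in_dir: str | Path) -> LabeledDataset:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    with np.load(in_dir / "windows.npz", allow_pickle=False) as data:
        split = data["split"].astype(object) if data["split"].size else np.array([], dtype=object)
        return LabeledDataset(
            X=data["X"],
            labels=data["labels"],
            gene_ids=data["gene_ids"].astype(object),
            centers=data["centers"],
            spec=WindowSpec(manifest["flanking_length"]),
            seed=manifest["seed"],
            split=split,
        )
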