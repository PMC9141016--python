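"""Per-nucleotide sliding-window scanning and site calling.

``scan`` classifies the window centered on every position of a sequence —
edge windows are zero-padded, never skipped — and returns a
:class:`PredictionTrack` with one probability row per position (columns:
donor, acceptor, other). ``call_sites`` is a pure function of the track, so a
stub object with a ``predict`` method is enough to exercise the whole module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding_io import GeneRecord, WindowSpec, encode_sequence

CLASS_NAMES = ("donor", "acceptor", "other")


@dataclass
class PredictionTrack:
    """Per-position class probabilities for one scanned sequence."""

    gene_id: str
    probabilities: np.ndarray  # (length, 3): donor, acceptor, other

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 3:
            raise ValueError(f"probabilities must be (length, 3), got {self.probabilities.shape}")
        sums = self.probabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-5):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"probability row {bad} sums to {sums[bad]}, expected 1")

    @property
    def length(self) -> int:
        return len(self.probabilities)

    @property
    def called_class(self) -> np.ndarray:
        """Argmax class name per position."""
        return np.array(CLASS_NAMES, dtype=object)[self.probabilities.argmax(axis=1)]

    def called_positions(self, site_type: str) -> np.ndarray:
        """Positions whose argmax class equals ``site_type`` (sorted ascending)."""
        col = CLASS_NAMES.index(site_type)
        return np.flatnonzero(self.probabilities.argmax(axis=1) == col)


def scan(
    gene: GeneRecord,
    model,
    spec: WindowSpec,
    batch_size: int = 128,
    reverse_complement: bool = False,
) -> PredictionTrack:
    """Classify the centered window at every position of ``gene``.

    ``model`` needs a ``predict(batch) -> (n, 3)`` method; if it exposes
    ``input_length`` it must match ``spec.window_length``. Windows are
    streamed in batches of ``batch_size``; the full window tensor for the
    gene never exists at once. Results are independent of ``batch_size``.
    """
    model_length = getattr(model, "input_length", None)
    if model_length is not None and model_length != spec.window_length:
        raise ValueError(
            f"model input length {model_length} does not match window length {spec.window_length}"
        )
    sequence = gene.sequence
    if reverse_complement:
        complement = str.maketrans("ACGTN", "TGCAN")
        sequence = sequence.translate(complement)[::-1]
    n = len(sequence)
    f = spec.flanking_length
    padded = np.zeros((n + 2 * f, 4), dtype=np.float32)
    padded[f : f + n] = encode_sequence(sequence)
    view = np.lib.stride_tricks.sliding_window_view(padded, spec.window_length, axis=0)
    probs = np.empty((n, 3), dtype=np.float64)
    for start in range(0, n, batch_size):
        stop = min(start + batch_size, n)
        batch = np.ascontiguousarray(view[start:stop].transpose(0, 2, 1))
        out = np.asarray(model.predict(batch))
        if out.shape != (stop - start, 3):
            raise ValueError(f"model returned shape {out.shape}, expected {(stop - start, 3)}")
        probs[start:stop] = out
    if reverse_complement:
        probs = probs[::-1].copy()
    return PredictionTrack(gene_id=gene.id, probabilities=probs)


def rank_positions(track: PredictionTrack, site_type: str) -> np.ndarray:
    """All positions ordered by the site_type probability, descending;
    ties broken by ascending position."""
    col = CLASS_NAMES.index(site_type)
    probs = track.probabilities[:, col]
    return np.lexsort((np.arange(track.length), -probs))


def call_sites(
    track: PredictionTrack, site_type: str, min_probability: float = 0.0
) -> list[tuple[int, float]]:
    """Positions called as ``site_type`` by argmax, sorted by probability.

    Descending probability; ties broken by ascending position. An optional
    ``min_probability`` additionally filters weak calls (off by default).
    """
    if site_type not in CLASS_NAMES[:2]:
        raise ValueError(f"site_type must be 'donor' or 'acceptor', got {site_type!r}")
    col = CLASS_NAMES.index(site_type)
    positions = track.called_positions(site_type)
    probs = track.probabilities[positions, col]
    keep = probs >= min_probability
    positions, probs = positions[keep], probs[keep]
    order = np.lexsort((positions, -probs))
    return [(int(p), float(q)) for p, q in zip(positions[order], probs[order])]


# ---------------------------------------------------------------------------
# Track and call output formats
# ---------------------------------------------------------------------------

def write_track_tsv(track: PredictionTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": track.gene_id,
            "position": np.arange(track.length),
            "p_donor": track.probabilities[:, 0],
            "p_acceptor": track.probabilities[:, 1],
            "p_other": track.probabilities[:, 2],
            "call": track.called_class,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_track_tsv(path: str | Path) -> PredictionTrack:
    df = pd.read_csv(path, sep="\t")
    probs = df[["p_donor", "p_acceptor", "p_other"]].to_numpy(dtype=np.float64)
    probs /= probs.sum(axis=1, keepdims=True)  # undo rounding drift from the text format
    return PredictionTrack(gene_id=str(df["gene_id"].iloc[0]), probabilities=probs)


def write_calls_bed(track: PredictionTrack, path: str | Path, min_probability: float = 0.0) -> None:
    """Called sites as single-base BED intervals, score = prob * 1000."""
    with open(path, "w") as fh:
        for site_type in ("donor", "acceptor"):
            for pos, prob in call_sites(track, site_type, min_probability):
                score = int(min(max(round(prob * 1000), 0), 1000))
                fh.write(f"{track.gene_id}\t{pos}\t{pos + 1}\t{site_type}\t{score}\t+\n")


def write_calls_gff3(track: PredictionTrack, path: str | Path, min_probability: float = 0.0) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for site_type, feature in (("donor", "splice_donor_site"), ("acceptor", "splice_acceptor_site")):
            for pos, prob in call_sites(track, site_type, min_probability):
                fh.write(
                    f"{track.gene_id}\tsplicescan\t{feature}\t{pos + 1}\t{pos + 1}\t"
                    f"{prob:.4f}\t+\t.\tID={track.gene_id}:{feature}:{pos + 1}\n"
                )
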