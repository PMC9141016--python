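"""Synthetic gene generator with planted splice signals.

Genes alternate exon/intron segments. Each intron begins with a donor signal
(canonical GT at its first two bases) and ends with an acceptor signal
(canonical AG at its last two bases); a position-weight matrix plants
consensus context around each dinucleotide. Background sequence is sampled
i.i.d. at a configurable GC fraction, so decoy GT/AG dinucleotides arise
naturally and are not suppressed.

The ``motif_information_content`` dial interpolates the context PWM between
the background distribution (0.0) and a strong consensus (1.0). At exactly
0.0 the canonical dinucleotide is no longer forced either, so planted sites
are statistically indistinguishable from background — the negative control
for learnability tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .encoding_io import (
    BASES,
    GeneRecord,
    write_fasta,
    write_site_table,
    write_sites_gff3,
)

# consensus context planted around the splice dinucleotides (positions are
# relative to the anchored site); loosely modeled on eukaryotic consensus
DONOR_CONTEXT = "CAGGTAAGT"       # exon|GT aagt...   anchor = index 3 (G of GT)
DONOR_ANCHOR_IN_CONTEXT = 3
ACCEPTOR_CONTEXT = "TTTTCAGGT"    # ...ttttcAG|exon  anchor = index 6 (G of AG)
ACCEPTOR_ANCHOR_IN_CONTEXT = 6

_MIN_EXON = 20
_MIN_INTRON = 30


@dataclass
class SyntheticGenomeConfig:
    n_genes: int = 5
    gene_length_range: tuple[int, int] = (800, 2000)
    exons_per_gene_range: tuple[int, int] = (2, 5)
    motif_information_content: float = 1.0
    context_width: int = 13  # total PWM width, centered on the dinucleotide signal
    background_gc: float = 0.5
    seed: int = 0
    donor_pwm: np.ndarray | None = None     # (context_width, 4) probabilities
    acceptor_pwm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gene_length_range[0] > self.gene_length_range[1] or self.gene_length_range[0] < 1:
            raise ValueError(f"invalid gene_length_range {self.gene_length_range}")
        if self.exons_per_gene_range[0] < 2:
            raise ValueError("need at least 2 exons per gene to contain an intron")
        if not 0.0 <= self.motif_information_content <= 1.0:
            raise ValueError("motif_information_content must lie in [0, 1]")
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must lie in (0, 1)")

    @property
    def background_probs(self) -> np.ndarray:
        gc, at = self.background_gc / 2.0, (1.0 - self.background_gc) / 2.0
        return np.array([at, gc, gc, at])  # A, C, G, T

    @property
    def force_canonical_dinucleotide(self) -> bool:
        return self.motif_information_content > 0.0


def consensus_pwm(
    consensus: str, information: float, background: np.ndarray, match_prob: float = 0.9
) -> np.ndarray:
    """Build a PWM interpolating between background (information=0) and a
    consensus with per-position match probability ``match_prob``
    (information=1). Off-consensus mass is split proportional to background."""
    pwm = np.zeros((len(consensus), 4))
    for i, base in enumerate(consensus):
        b = BASES.index(base)
        target = np.array(background)
        others = [j for j in range(4) if j != b]
        target[b] = match_prob
        rest = background[others] / background[others].sum() * (1.0 - match_prob)
        target[others] = rest
        pwm[i] = background + information * (target - background)
    pwm /= pwm.sum(axis=1, keepdims=True)
    return pwm


def _default_pwms(config: SyntheticGenomeConfig) -> tuple[np.ndarray, np.ndarray]:
    bg = config.background_probs
    w = config.context_width
    info = config.motif_information_content

    def build(context: str) -> np.ndarray:
        left = (w - len(context)) // 2
        right = w - len(context) - left
        core = consensus_pwm(context, info, bg)
        return np.vstack([np.tile(bg, (left, 1)), core, np.tile(bg, (right, 1))])

    donor = config.donor_pwm if config.donor_pwm is not None else build(DONOR_CONTEXT)
    acceptor = config.acceptor_pwm if config.acceptor_pwm is not None else build(ACCEPTOR_CONTEXT)
    for name, pwm in (("donor", donor), ("acceptor", acceptor)):
        pwm = np.asarray(pwm)
        if pwm.ndim != 2 or pwm.shape[1] != 4 or not np.allclose(pwm.sum(axis=1), 1.0):
            raise ValueError(f"{name}_pwm columns must be probability distributions over ACGT")
    return np.asarray(donor), np.asarray(acceptor)


def _pwm_anchor_column(config: SyntheticGenomeConfig, which: str) -> int:
    left = (config.context_width - len(DONOR_CONTEXT if which == "donor" else ACCEPTOR_CONTEXT)) // 2
    anchor = DONOR_ANCHOR_IN_CONTEXT if which == "donor" else ACCEPTOR_ANCHOR_IN_CONTEXT
    return left + anchor


def _sample_segments(rng: np.random.Generator, length: int, n_exons: int) -> list[int]:
    """Split ``length`` into alternating exon/intron segment lengths
    (n_exons exons, n_exons - 1 introns) respecting minimum sizes."""
    n_segments = 2 * n_exons - 1
    minima = [_MIN_EXON if i % 2 == 0 else _MIN_INTRON for i in range(n_segments)]
    slack = length - sum(minima)
    if slack < 0:
        raise ValueError(
            f"gene length {length} cannot fit {n_exons} exons "
            f"(minimum {sum(minima)} nucleotides)"
        )
    # distribute slack over segments via a random composition
    cuts = np.sort(rng.integers(0, slack + 1, size=n_segments - 1))
    extras = np.diff(np.concatenate([[0], cuts, [slack]]))
    return [m + int(e) for m, e in zip(minima, extras)]


def _overlay(seq: np.ndarray, pwm_sample: np.ndarray, start: int) -> None:
    lo, hi = max(start, 0), min(start + len(pwm_sample), len(seq))
    if lo < hi:
        seq[lo:hi] = pwm_sample[lo - start : hi - start]


def generate(config: SyntheticGenomeConfig) -> list[GeneRecord]:
    """Generate annotated genes; deterministic for a given config seed."""
    rng = np.random.default_rng(config.seed)
    donor_pwm, acceptor_pwm = _default_pwms(config)
    d_anchor = _pwm_anchor_column(config, "donor")
    a_anchor = _pwm_anchor_column(config, "acceptor")
    base_codes = np.arange(4)
    genes = []
    for g in range(config.n_genes):
        length = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        n_exons = int(rng.integers(config.exons_per_gene_range[0], config.exons_per_gene_range[1] + 1))
        segments = _sample_segments(rng, length, n_exons)
        seq = rng.choice(base_codes, size=length, p=config.background_probs)

        donors, acceptors = [], []
        pos = 0
        for i, seg_len in enumerate(segments):
            if i % 2 == 1:  # intron
                intron_start, intron_end = pos, pos + seg_len - 1
                donors.append(intron_start)
                acceptors.append(intron_end)
                d_sample = _sample_pwm(rng, donor_pwm)
                a_sample = _sample_pwm(rng, acceptor_pwm)
                if config.force_canonical_dinucleotide:
                    d_sample[d_anchor], d_sample[d_anchor + 1] = 2, 3      # G, T
                    a_sample[a_anchor - 1], a_sample[a_anchor] = 0, 2      # A, G
                _overlay(seq, d_sample, intron_start - d_anchor)
                _overlay(seq, a_sample, intron_end - a_anchor)
            pos += seg_len
        genes.append(
            GeneRecord(
                id=f"synth_gene_{g:04d}",
                sequence="".join(BASES[c] for c in seq),
                donor_sites=donors,
                acceptor_sites=acceptors,
                source=f"synthetic(seed={config.seed})",
            )
        )
    return genes


def _sample_pwm(rng: np.random.Generator, pwm: np.ndarray) -> np.ndarray:
    cum = pwm.cumsum(axis=1)
    u = rng.random(len(pwm))
    return (u[:, None] > cum).sum(axis=1)


def write_truth(genes: list[GeneRecord], out_dir: str | Path, prefix: str = "synthetic") -> dict[str, Path]:
    """Write FASTA + site table + truth GFF3 for a generated gene set."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / f"{prefix}.fasta",
        "site_table": out_dir / f"{prefix}.sites.tsv",
        "gff3": out_dir / f"{prefix}.truth.gff3",
    }
    write_fasta(genes, paths["fasta"])
    write_site_table(genes, paths["site_table"])
    write_sites_gff3(genes, paths["gff3"])
    return paths


UNIT_FIXTURE = SyntheticGenomeConfig(
    n_genes=5, gene_length_range=(600, 2000), exons_per_gene_range=(2, 4), seed=1234
)
# sized to yield >= 20,000 windows at the default negative ratio:
# ~1550 genes x ~5.1 sites x (1 + 1.571) windows per site
TRAINING_FIXTURE = SyntheticGenomeConfig(
    n_genes=1550,
    gene_length_range=(700, 1600),
    exons_per_gene_range=(2, 5),
    seed=1234,
)


def make_fixture(scale: str = "unit", out_dir: str | Path | None = None,
                 information: float | None = None, seed: int | None = None):
    """Build a canned gene set (``unit`` or ``training`` scale).

    Returns the list of GeneRecords; when ``out_dir`` is given, also writes
    FASTA/site-table/GFF3 there and returns ``(genes, paths)``.
    """
    if scale == "unit":
        config = UNIT_FIXTURE
    elif scale == "training":
        config = TRAINING_FIXTURE
    else:
        raise ValueError(f"unknown fixture scale {scale!r}")
    if information is not None:
        config = replace(config, motif_information_content=information)
    if seed is not None:
        config = replace(config, seed=seed)
    genes = generate(config)
    if out_dir is not None:
        return genes, write_truth(genes, out_dir, prefix=f"fixture_{scale}")
    return genes
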