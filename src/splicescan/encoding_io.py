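"""Sequence/annotation readers, centered-window extraction, and one-hot encoding.

Conventions
-----------
* All positions are 0-based into the gene's own sequence. GFF3/GTF input is
  1-based inclusive and converted on read; the site-table dialect carries an
  explicit ``coordinate_base`` column (0 or 1).
* A base is encoded as a 4-vector over (A, C, G, T); any other character —
  N, IUPAC ambiguity codes, gaps — and positions outside the sequence encode
  as the all-zero vector.
* The splice-site anchor nucleotide is the first intron base for donors (the
  G of GT) and the last intron base for acceptors (the G of AG). Readers that
  derive sites from exon structure accept an offset pair for other anchoring
  conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Smallest flanking length for which the default convolutional stack is
#: considered viable; enforced when a model is built, not on window extraction.
MIN_VIABLE_FLANKING = 130

BASES = "ACGT"
_BASE_INDEX = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_INDEX[ord(_b)] = _i
# rows 0..3 are A/C/G/T; row 4 is the zero vector for everything else
_ONEHOT_ROWS = np.vstack([np.eye(4, dtype=np.float32), np.zeros(4, dtype=np.float32)])

LABEL_DONOR = "donor"
LABEL_ACCEPTOR = "acceptor"
LABEL_OTHER = "other"
LABEL_UNLABELED = "unlabeled"


class AnnotationError(ValueError):
    """A splice-site annotation is inconsistent with its sequence."""


class FastaParseError(ValueError):
    """The FASTA input is malformed."""


@dataclass
class GeneRecord:
    """A DNA sequence with annotated donor/acceptor positions.

    Positions are 0-based indices into ``sequence``. The sequence is
    upper-cased on construction and both site lists are validated to lie in
    bounds and be mutually disjoint.
    """

    id: str
    sequence: str
    donor_sites: list[int] = field(default_factory=list)
    acceptor_sites: list[int] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"gene {self.id!r}: sequence is empty")
        self.sequence = self.sequence.upper()
        self.donor_sites = sorted(int(p) for p in self.donor_sites)
        self.acceptor_sites = sorted(int(p) for p in self.acceptor_sites)
        n = len(self.sequence)
        for kind, sites in ((LABEL_DONOR, self.donor_sites), (LABEL_ACCEPTOR, self.acceptor_sites)):
            for p in sites:
                if not 0 <= p < n:
                    raise AnnotationError(
                        f"gene {self.id!r}: {kind} position {p} outside sequence of length {n}"
                    )
        overlap = set(self.donor_sites) & set(self.acceptor_sites)
        if overlap:
            raise AnnotationError(
                f"gene {self.id!r}: positions annotated as both donor and acceptor: {sorted(overlap)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def site_positions(self) -> set[int]:
        return set(self.donor_sites) | set(self.acceptor_sites)

    def label_at(self, position: int) -> str:
        if position in set(self.donor_sites):
            return LABEL_DONOR
        if position in set(self.acceptor_sites):
            return LABEL_ACCEPTOR
        return LABEL_OTHER


@dataclass(frozen=True)
class WindowSpec:
    """Flanking-length convention for centered windows.

    ``window_length`` is always ``2 * flanking_length + 1`` (odd by
    construction). Small flanking lengths are permitted for toy inputs; the
    model builder separately enforces :data:`MIN_VIABLE_FLANKING`.
    """

    flanking_length: int

    def __post_init__(self) -> None:
        if self.flanking_length < 1:
            raise ValueError(f"flanking_length must be >= 1, got {self.flanking_length}")

    @property
    def window_length(self) -> int:
        return 2 * self.flanking_length + 1


@dataclass
class EncodedWindow:
    """One-hot matrix of a window centered on a sequence position."""

    matrix: np.ndarray  # (window_length, 4), values in {0, 1}
    center_position: int
    label: str = LABEL_UNLABELED

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float32)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"window matrix must be (L, 4), got {self.matrix.shape}")


def encode_base(base: str) -> np.ndarray:
    """One-hot encode a single character; non-ACGT characters map to zeros."""
    if len(base) != 1:
        raise ValueError(f"expected a single character, got {base!r}")
    code = ord(base.upper())
    if code >= 256:
        return np.zeros(4, dtype=np.float32)
    return _ONEHOT_ROWS[_BASE_INDEX[code]].copy()


def decode_row(row: Sequence[float]) -> str:
    """Inverse of :func:`encode_base` on the ACGT alphabet; zero rows give 'N'."""
    row = np.asarray(row)
    if row.shape != (4,):
        raise ValueError(f"expected a 4-vector, got shape {row.shape}")
    if row.sum() == 0:
        return "N"
    return BASES[int(np.argmax(row))]


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a whole string to an (L, 4) float32 one-hot matrix."""
    raw = np.frombuffer(sequence.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    return _ONEHOT_ROWS[_BASE_INDEX[raw]]


def decode_matrix(matrix: np.ndarray) -> str:
    """Decode an (L, 4) one-hot matrix back to a string (zero rows -> 'N')."""
    matrix = np.asarray(matrix)
    idx = np.where(matrix.sum(axis=1) == 0, 4, matrix.argmax(axis=1))
    return "".join(("ACGTN")[i] for i in idx)


def extract_window(gene: GeneRecord, center: int, spec: WindowSpec) -> EncodedWindow:
    """Encode the window of ``spec.window_length`` centered at ``center``.

    Positions falling outside the sequence contribute all-zero rows.
    """
    n = len(gene.sequence)
    if not 0 <= center < n:
        raise ValueError(f"gene {gene.id!r}: center {center} out of bounds [0, {n})")
    f = spec.flanking_length
    lo, hi = center - f, center + f + 1
    matrix = np.zeros((spec.window_length, 4), dtype=np.float32)
    src_lo, src_hi = max(lo, 0), min(hi, n)
    matrix[src_lo - lo : src_hi - lo] = encode_sequence(gene.sequence[src_lo:src_hi])
    return EncodedWindow(matrix=matrix, center_position=center, label=gene.label_at(center))


def encode_windows_dense(gene: GeneRecord, centers: Sequence[int], spec: WindowSpec) -> np.ndarray:
    """Vectorized window extraction: (len(centers), window_length, 4).

    Equivalent to stacking :func:`extract_window` matrices; used by the
    dataset builder and scanner where per-window object overhead matters.
    """
    f = spec.flanking_length
    padded = np.zeros((len(gene.sequence) + 2 * f, 4), dtype=np.float32)
    padded[f : f + len(gene.sequence)] = encode_sequence(gene.sequence)
    centers = np.asarray(centers, dtype=np.int64)
    if centers.size == 0:
        return np.zeros((0, spec.window_length, 4), dtype=np.float32)
    if centers.min() < 0 or centers.max() >= len(gene.sequence):
        raise ValueError(f"gene {gene.id!r}: window center out of bounds")
    view = np.lib.stride_tricks.sliding_window_view(padded, spec.window_length, axis=0)
    # view is (L, 4, W); transpose windows to (W, 4)
    return np.ascontiguousarray(view[centers].transpose(0, 2, 1))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

SITE_TABLE_COLUMNS = ["gene_id", "site_type", "position", "coordinate_base"]


def _read_fasta(fasta_source: str | Path) -> dict[str, str]:
    path = Path(fasta_source)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header starting with '>', "
                        f"got {line.strip()[:40]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: no sequences found")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def _sites_from_site_table(path: str | Path) -> dict[str, dict[str, list[int]]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: site table missing columns {missing}")
    out: dict[str, dict[str, list[int]]] = {}
    for row in df.itertuples(index=False):
        kind = str(row.site_type).lower()
        if kind not in (LABEL_DONOR, LABEL_ACCEPTOR):
            raise AnnotationError(f"{path}: unknown site_type {row.site_type!r}")
        base = int(row.coordinate_base)
        if base not in (0, 1):
            raise AnnotationError(f"{path}: coordinate_base must be 0 or 1, got {base}")
        gene = out.setdefault(str(row.gene_id), {LABEL_DONOR: [], LABEL_ACCEPTOR: []})
        gene[kind].append(int(row.position) - base)
    return out


def _sites_from_gff(
    path: str | Path, dialect: str, anchor_offsets: tuple[int, int]
) -> dict[str, dict[str, list[int]]]:
    """Derive splice sites from intron features, or from exon adjacency.

    Coordinates in the annotation are interpreted as 1-based inclusive within
    the named sequence. ``anchor_offsets`` shifts the (donor, acceptor) anchor
    relative to the default first/last-intron-base convention.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    d_off, a_off = anchor_offsets
    out: dict[str, dict[str, list[int]]] = {}

    def add_intron(seqid: str, start1: int, end1: int) -> None:
        gene = out.setdefault(seqid, {LABEL_DONOR: [], LABEL_ACCEPTOR: []})
        gene[LABEL_DONOR].append(start1 - 1 + d_off)
        gene[LABEL_ACCEPTOR].append(end1 - 1 + a_off)

    intron_feats = list(db.features_of_type("intron"))
    if intron_feats:
        for feat in intron_feats:
            add_intron(feat.seqid, feat.start, feat.end)
    else:
        # group exons by parent transcript and read introns off the gaps
        exons_by_parent: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for feat in db.features_of_type("exon"):
            if dialect == "gtf":
                parent = feat.attributes.get("transcript_id", [feat.seqid])[0]
            else:
                parent = feat.attributes.get("Parent", [feat.seqid])[0]
            exons_by_parent.setdefault((feat.seqid, parent), []).append((feat.start, feat.end))
        seen: dict[str, set[tuple[int, int]]] = {}
        for (seqid, _parent), exons in exons_by_parent.items():
            exons.sort()
            for (_, left_end), (right_start, _) in zip(exons, exons[1:]):
                intron = (left_end + 1, right_start - 1)
                if intron[1] < intron[0]:
                    continue
                if intron not in seen.setdefault(seqid, set()):
                    seen[seqid].add(intron)
                    add_intron(seqid, *intron)
    for gene in out.values():
        gene[LABEL_DONOR] = sorted(set(gene[LABEL_DONOR]))
        gene[LABEL_ACCEPTOR] = sorted(set(gene[LABEL_ACCEPTOR]))
    return out


def read_genes(
    fasta_source: str | Path,
    annotation_source: str | Path,
    dialect: str = "site_table",
    anchor_offsets: tuple[int, int] = (0, 0),
) -> list[GeneRecord]:
    """Read FASTA sequences plus splice-site annotations into GeneRecords.

    Parameters
    ----------
    dialect:
        ``site_table`` — tab-separated ``gene_id, site_type, position,
        coordinate_base``; ``gff3`` / ``gtf`` — sites derived from ``intron``
        features or, failing those, from exon adjacency per transcript.
    anchor_offsets:
        (donor, acceptor) shifts applied to the default anchor convention
        (first / last intron base). Ignored for ``site_table`` input, which is
        taken to already carry anchored positions.

    Annotations whose sequence id has no FASTA entry are reported via a
    logger warning, not silently dropped.
    """
    if dialect not in ("gff3", "gtf", "site_table"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    sequences = _read_fasta(fasta_source)
    if dialect == "site_table":
        sites = _sites_from_site_table(annotation_source)
    else:
        sites = _sites_from_gff(annotation_source, dialect, anchor_offsets)

    orphans = sorted(set(sites) - set(sequences))
    if orphans:
        logger.warning(
            "%d annotated sequence id(s) have no FASTA entry and were skipped: %s",
            len(orphans),
            ", ".join(orphans[:10]),
        )
    records = []
    for seq_id, seq in sequences.items():
        gene_sites = sites.get(seq_id, {LABEL_DONOR: [], LABEL_ACCEPTOR: []})
        records.append(
            GeneRecord(
                id=seq_id,
                sequence=seq,
                donor_sites=gene_sites[LABEL_DONOR],
                acceptor_sites=gene_sites[LABEL_ACCEPTOR],
                source=f"{fasta_source}+{annotation_source}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Writers (round-trip counterparts of the readers)
# ---------------------------------------------------------------------------

def write_fasta(genes: Iterable[GeneRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            fh.write(f">{gene.id}\n")
            for i in range(0, len(gene.sequence), width):
                fh.write(gene.sequence[i : i + width] + "\n")


def write_site_table(genes: Iterable[GeneRecord], path: str | Path, coordinate_base: int = 1) -> None:
    rows = []
    for gene in genes:
        for p in gene.donor_sites:
            rows.append((gene.id, LABEL_DONOR, p + coordinate_base, coordinate_base))
        for p in gene.acceptor_sites:
            rows.append((gene.id, LABEL_ACCEPTOR, p + coordinate_base, coordinate_base))
    pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_sites_gff3(genes: Iterable[GeneRecord], path: str | Path, source: str = "splicescan") -> None:
    """Write each anchored site as a single-base GFF3 feature (1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            for kind, positions in (
                ("splice_donor_site", gene.donor_sites),
                ("splice_acceptor_site", gene.acceptor_sites),
            ):
                for p in positions:
                    fh.write(
                        f"{gene.id}\t{source}\t{kind}\t{p + 1}\t{p + 1}\t.\t+\t.\t"
                        f"ID={gene.id}:{kind}:{p + 1}\n"
                    )
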