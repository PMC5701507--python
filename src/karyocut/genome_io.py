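"""Genome and annotation-mask I/O.

All coordinates in this package are 0-based, half-open ([start, end)),
matching the BED convention; VCF positions are converted from 1-based on
read.  Sequences are normalized to the {A, C, G, T, N} alphabet: lowercase
(soft-masked) bases are uppercased and any other IUPAC ambiguity code
becomes N.  N never participates in target-site matching downstream.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "Genome",
    "GenomicInterval",
    "MaskSet",
    "FastaError",
    "BedError",
    "read_fasta",
    "write_fasta",
    "read_bed_mask",
    "read_gff_features",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Characters accepted in input sequences.  ACGT (either case) survive;
# every other IUPAC nucleotide code, gaps and RNA U collapse to N.
_AMBIGUOUS = "NRYSWKMBDHVUX"
_NORMALIZE = str.maketrans(
    "acgt" + _AMBIGUOUS.lower() + _AMBIGUOUS + "-.",
    "ACGT" + "N" * (2 * len(_AMBIGUOUS) + 2),
)
_ALLOWED_INPUT = set("ACGTacgt" + _AMBIGUOUS + _AMBIGUOUS.lower() + "-.")


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


class BedError(ValueError):
    """Raised for malformed BED input."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN sequence (an involution)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, context: str = "sequence") -> str:
    """Uppercase and collapse non-ACGT IUPAC codes to N.

    Raises :class:`FastaError` if a character outside the IUPAC nucleotide
    alphabet is present.
    """
    bad = set(seq) - _ALLOWED_INPUT
    if bad:
        raise FastaError(
            f"invalid characters {sorted(bad)!r} in {context}; expected IUPAC nucleotides"
        )
    return seq.translate(_NORMALIZE)


@dataclass
class Genome:
    """An in-memory genome: chromosome name -> normalized ACGTN sequence."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not name:
                raise FastaError("empty chromosome name")
            self.sequences[name] = normalize_sequence(seq, context=f"chromosome {name!r}")

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def chromosomes(self) -> List[str]:
        return list(self.sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the half-open interval [start, end) on ``chrom``."""
        return self.sequences[chrom][start:end]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share >= 1 base (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class MaskSet:
    """A named set of genomic intervals indexed for overlap queries.

    Overlap means sharing at least one base; all interval arithmetic is
    half-open, so a query ending exactly where a mask interval starts does
    not overlap it.
    """

    def __init__(self, name: str, intervals: Iterable[GenomicInterval]):
        self.name = name
        self._trees: Dict[str, IntervalTree] = {}
        self._intervals: List[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        for iv in self._intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    @property
    def intervals(self) -> List[GenomicInterval]:
        return list(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def query(self, interval: GenomicInterval) -> List[GenomicInterval]:
        """All mask intervals overlapping ``interval`` (sorted)."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(interval.start, interval.end)]
        return sorted(hits, key=lambda iv: (iv.start, iv.end))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff any mask interval shares >= 1 base with [start, end)."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix in (".gz", ".bgz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: Union[str, Path]) -> Genome:
    """Read a (possibly gzipped) FASTA file into a :class:`Genome`.

    The chromosome name is the header token before the first whitespace.
    Lowercase bases are uppercased; non-ACGT IUPAC codes become N.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # Structural pre-check so garbage before the first record is reported
    # with its line number (SeqIO silently skips it).
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()[:30]!r}"
                    )
                break
        else:
            raise FastaError(f"{path}: empty FASTA file")
    sequences: Dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if not name:
                raise FastaError(f"{path}: record with empty name")
            if name in sequences:
                raise FastaError(f"{path}: duplicate chromosome name {name!r}")
            sequences[name] = str(record.seq)
    return Genome(sequences)


def write_fasta(genome: Genome, path: Union[str, Path], line_width: int = 60) -> None:
    """Write a genome as (optionally gzipped) FASTA, ``line_width`` bases per line."""
    with _open_text(path, "wt") as handle:
        for name, seq in genome.sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                handle.write(seq[i : i + line_width] + "\n")


def read_bed_mask(path: Union[str, Path], name: str) -> MaskSet:
    """Read a BED3+ file (0-based, half-open) into a :class:`MaskSet`."""
    path = Path(path)
    intervals: List[GenomicInterval] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedError(f"{path}: line {lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise BedError(
                    f"{path}: line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return MaskSet(name, intervals)


def read_gff_features(
    path: Union[str, Path],
    feature_types: Iterable[str] = ("CDS", "exon"),
    name: str = "coding",
) -> MaskSet:
    """Extract features of the given types from a GFF3 file as a MaskSet.

    GFF3 coordinates are 1-based inclusive and are converted to 0-based
    half-open on read.
    """
    wanted = set(feature_types)
    intervals: List[GenomicInterval] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise BedError(f"{path}: line {lineno}: expected >= 8 GFF3 columns")
            if fields[2] not in wanted:
                continue
            try:
                start, end = int(fields[3]) - 1, int(fields[4])
            except ValueError as exc:
                raise BedError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise BedError(f"{path}: line {lineno}: invalid feature span")
            strand = fields[6] if fields[6] in ("+", "-") else "."
            intervals.append(GenomicInterval(fields[0], start, end, strand))
    return MaskSet(name, intervals)
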