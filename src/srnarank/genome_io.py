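"""Genomic intervals, BED and FASTA I/O.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
Bacterial chromosomes are treated as circular by default, so sequence
windows may wrap around the origin; set ``circular=False`` for draft
contigs or plasmid fragments where wrapping is not meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_RESIDUES = frozenset("ACGTN")
STRANDS = ("+", "-")


class BedParseError(ValueError):
    """Raised when a BED line violates the format contract."""


class FastaError(ValueError):
    """Raised for empty, duplicated or non-nucleotide FASTA records."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open genomic region (sRNA, ORF, promoter or terminator)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.name:
            object.__setattr__(
                self, "name", f"{self.chrom}:{self.start}-{self.end}({self.strand})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Genome coordinate of the 5' end (first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime(self) -> int:
        """Genome coordinate of the 3' end (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeSequence:
    """One replicon: identifier, uppercase DNA residues and topology."""

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace("U", "T")
        if not self.residues:
            raise FastaError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise FastaError(
                f"sequence {self.id!r} contains non-IUPAC residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class AnnotationSet:
    """A collection of intervals kept sorted by (chrom, start).

    ``role`` records what the intervals are (ORF, sRNA, promoter, terminator,
    negative); it is informational and does not alter behaviour.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), role: str = "") -> None:
        self.role = role
        self._intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name)
        )

    def add(self, iv: GenomicInterval) -> None:
        self._intervals.append(iv)
        self._intervals.sort(key=lambda v: (v.chrom, v.start, v.end, v.name))

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def by_chrom(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self._intervals if iv.chrom == chrom]

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self._intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)


def read_bed(path: str | Path, role: str = "") -> AnnotationSet:
    """Read a 3-6 column BED file into an :class:`AnnotationSet`.

    BED semantics are preserved exactly (0-based half-open). A missing or
    ``.`` strand is recorded as ``+`` with a logged warning; ``track``,
    ``browser`` and ``#`` lines are skipped. Malformed coordinates raise
    :class:`BedParseError` naming the offending line.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path.name}:{lineno}: non-integer coordinate"
                ) from exc
            if not (0 <= start < end):
                raise BedParseError(
                    f"{path.name}:{lineno}: invalid coordinates {start}..{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] else ""
            strand = fields[5] if len(fields) > 5 else "."
            if strand == ".":
                logger.warning(
                    "%s:%d: missing/'.' strand recorded as '+'", path.name, lineno
                )
                strand = "+"
            if strand not in STRANDS:
                raise BedParseError(
                    f"{path.name}:{lineno}: unknown strand symbol {strand!r}"
                )
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
    return AnnotationSet(intervals, role=role)


def write_bed(annots: Iterable[GenomicInterval], path: str | Path, score: int = 0) -> None:
    """Write intervals as 6-column BED (tab-separated, Unix newlines)."""
    with Path(path).open("w", newline="\n") as fh:
        for iv in annots:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n"
            )


def read_fasta(path: str | Path, circular: bool = True) -> dict[str, GenomeSequence]:
    """Read a multi-record FASTA file.

    The header token before the first whitespace becomes the id; residues
    are upper-cased and U is mapped to T. Duplicate ids and empty files
    raise :class:`FastaError`.
    """
    genomes: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genomes:
            raise FastaError(f"duplicate FASTA id {record.id!r}")
        genomes[record.id] = GenomeSequence(record.id, str(record.seq), circular=circular)
    if not genomes:
        raise FastaError(f"no FASTA records found in {path}")
    return genomes


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w", newline="\n") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.residues), width):
                fh.write(g.residues[i : i + width] + "\n")


def extract_sequence(genome: GenomeSequence, iv: GenomicInterval) -> str:
    """Strand-correct sequence of ``iv``; wraps around the origin if circular.

    ``iv.start`` may be negative and ``iv.end`` may exceed the genome length
    on circular genomes (callers construct such unnormalized windows near the
    origin); the window length must not exceed the genome length.
    """
    n = len(genome)
    start, end = iv.start, iv.end
    if end - start > n:
        raise ValueError(f"window {iv.name} longer than genome {genome.id}")
    if 0 <= start and end <= n:
        seq = genome.residues[start:end]
    elif genome.circular:
        s = start % n
        doubled = genome.residues + genome.residues
        seq = doubled[s : s + (end - start)]
    else:
        raise ValueError(
            f"interval {iv.name} out of bounds for linear genome {genome.id} "
            f"(length {n})"
        )
    return reverse_complement(seq) if iv.strand == "-" else seq
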