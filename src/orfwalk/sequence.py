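"""Core sequence records and readers/writers for FASTQ and FASTA.

Reads carry per-base Phred qualities (integer scale, Phred+33 on disk).
Everything downstream -- grooming, the identical-read census, walking
assembly and frame matching -- operates on these records, so parsing is
strict: a base outside {A, C, G, T, N} or a length mismatch between
sequence and quality lines is an error, never a silent conversion.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "ProteinQuery",
    "FastqParseError",
    "parse_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_protein_queries",
    "reverse_complement",
    "translate",
    "six_frame_translations",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Standard genetic code; stop codons render as '*', codons containing N as 'X'.
_CODON_TABLE: dict[str, str] = dict(CodonTable.standard_dna_table.forward_table)
for _stop in CodonTable.standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FastqParseError(ValueError):
    """Raised for a malformed FASTQ record, naming the offending record."""


@dataclass(frozen=True)
class Read:
    """One sequencing read with per-base quality.

    ``mate`` is 1 or 2 for paired reads, 0 for unpaired.
    """

    id: str
    sequence: str
    qualities: tuple[int, ...]
    mate: int = 0

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality values"
            )
        if not _VALID_BASES.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(f"read {self.id!r}: invalid base(s) {bad}")
        if self.qualities and not all(0 <= q <= 60 for q in self.qualities):
            raise ValueError(f"read {self.id!r}: Phred quality outside [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


@dataclass(frozen=True)
class ProteinQuery:
    """A query protein for the translated similarity screen."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein query {self.id!r} is empty")
        if not _AA_LETTERS.issuperset(self.residues):
            bad = sorted(set(self.residues) - _AA_LETTERS)
            raise ValueError(f"protein query {self.id!r}: invalid residue(s) {bad}")

    def __len__(self) -> int:
        return len(self.residues)


def _mate_from_title(title: str) -> tuple[str, int]:
    name = title.split()[0]
    if name.endswith("/1"):
        return name[:-2], 1
    if name.endswith("/2"):
        return name[:-2], 2
    return name, 0


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_fastq(path: str | Path) -> Iterator[Read]:
    """Stream Reads from a 4-line FASTQ file (Phred+33), plain or gzipped."""
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                seq = seq.upper()
                if len(seq) != len(qual):
                    raise FastqParseError(
                        f"record {title!r}: sequence/quality length mismatch"
                    )
                name, mate = _mate_from_title(title)
                try:
                    yield Read(
                        id=name,
                        sequence=seq,
                        qualities=tuple(ord(c) - 33 for c in qual),
                        mate=mate,
                    )
                except ValueError as exc:
                    raise FastqParseError(str(exc)) from exc
        except ValueError as exc:  # biopython structural errors
            if isinstance(exc, FastqParseError):
                raise
            raise FastqParseError(str(exc)) from exc


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as 4-line Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as out:
        for read in reads:
            name = read.id + (f"/{read.mate}" if read.mate else "")
            qual = "".join(chr(q + 33) for q in read.qualities)
            out.write(f"@{name}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA into an ordered {id: uppercase sequence} map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> int:
    n = 0
    with open(path, "w") as out:
        for header, seq in records:
            out.write(f">{header}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")
            n += 1
    return n


def read_protein_queries(path: str | Path) -> list[ProteinQuery]:
    return [
        ProteinQuery(id=rec.id, residues=str(rec.seq).upper().rstrip("*"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over {A, C, G, T, N}."""
    if not _VALID_BASES.issuperset(sequence):
        bad = sorted(set(sequence) - _VALID_BASES)
        raise ValueError(f"invalid base(s) in sequence: {bad}")
    return sequence.translate(_COMPLEMENT)[::-1]


def translate(sequence: str) -> str:
    """Translate a nucleotide string, dropping any trailing partial codon.

    Stop codons become '*'; codons containing N become 'X'.
    """
    end = len(sequence) - len(sequence) % 3
    return "".join(
        _CODON_TABLE.get(sequence[i:i + 3], "X") for i in range(0, end, 3)
    )


def six_frame_translations(sequence: str) -> list[str]:
    """All six translation frames: +1, +2, +3 then -1, -2, -3.

    Reverse frames are translations of the reverse complement, so frame -k
    of a read equals frame +k of its reverse complement.
    """
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = reverse_complement(sequence)
    return [translate(sequence[off:]) for off in range(3)] + [
        translate(rc[off:]) for off in range(3)
    ]
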