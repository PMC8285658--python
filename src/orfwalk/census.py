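"""Identical-read census: the untargeted discovery path.

Counts exact-duplicate reads within the leading segment of each library,
matches read sequences across the two libraries, and ranks candidates by
how far their count ratio departs from 1:1. Reads present in only one
library have an undefined ratio; they are reported but excluded from
ratio ranking by default. Identity means identical orientation -- no
reverse-complement collapsing -- and mates are counted individually.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .sequence import Read

__all__ = [
    "CensusParams",
    "CensusEntry",
    "count_identical_reads",
    "cross_census",
    "select_candidates",
]


@dataclass(frozen=True)
class CensusParams:
    head_limit: int = 10_000_000
    ratio_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.head_limit < 1:
            raise ValueError("head_limit must be >= 1")
        if self.ratio_threshold < 1:
            raise ValueError("ratio_threshold must be >= 1")


@dataclass(frozen=True)
class CensusEntry:
    """Counts of one read sequence in libraries A and B.

    ``ratio`` is count_b / count_a; infinite when the sequence is absent
    from A, and NaN is never produced (at least one count is positive).
    """

    sequence: str
    count_a: int
    count_b: int

    def __post_init__(self) -> None:
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError("counts must be non-negative")
        if self.count_a == 0 and self.count_b == 0:
            raise ValueError("at least one count must be positive")

    @property
    def ratio(self) -> float:
        return self.count_b / self.count_a if self.count_a else math.inf

    @property
    def in_both(self) -> bool:
        return self.count_a > 0 and self.count_b > 0

    @property
    def extremity(self) -> float:
        r = self.ratio
        return max(r, 1.0 / r) if 0 < r < math.inf else math.inf


def count_identical_reads(reads: Iterable[Read],
                          head_limit: int = 10_000_000) -> Counter[str]:
    """Exact-string multiplicity over the first ``head_limit`` reads."""
    counts: Counter[str] = Counter()
    for i, read in enumerate(reads):
        if i >= head_limit:
            break
        counts[read.sequence] += 1
    return counts


def cross_census(counts_a: Mapping[str, int],
                 counts_b: Mapping[str, int]) -> list[CensusEntry]:
    """One entry per distinct sequence seen in either library.

    Sequences in both libraries carry a finite ratio; single-library
    sequences are kept for reporting (``in_both`` is False).
    """
    entries = [
        CensusEntry(sequence=seq, count_a=ca, count_b=counts_b.get(seq, 0))
        for seq, ca in counts_a.items()
    ]
    entries.extend(
        CensusEntry(sequence=seq, count_a=0, count_b=cb)
        for seq, cb in counts_b.items()
        if seq not in counts_a
    )
    return entries


def select_candidates(entries: Iterable[CensusEntry],
                      ratio_threshold: float = 3.0) -> list[CensusEntry]:
    """Entries with ratio beyond the threshold in either direction.

    Ordered by extremity (max(ratio, 1/ratio)) descending; ties broken by
    higher total count, then lexicographic sequence. Entries present in
    only one library are excluded (their ratio is undefined).
    """
    chosen = [
        e for e in entries
        if e.in_both and (e.ratio > ratio_threshold or e.ratio < 1.0 / ratio_threshold)
    ]
    chosen.sort(key=lambda e: (-e.extremity, -(e.count_a + e.count_b), e.sequence))
    return chosen
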