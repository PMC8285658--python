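"""Quality grooming: keep reads with a long contiguous run of high-quality calls.

A read passes when its longest contiguous run of positions with Phred
quality >= ``min_phred`` spans at least ``min_run_length`` nucleotides
(defaults 20 and 80: "80 or more contiguous bases above Q19"). By default
the read is trimmed to that run so that the downstream exact-identity
census and overlap assembly see only trusted sequence; ``trim_to_run=False``
keeps whole reads. Ties between equal-length runs go to the leftmost run.
Mates are groomed independently; a pair may lose one mate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .sequence import Read

__all__ = ["GroomingParams", "GroomedLibrary", "groom_read", "groom_library"]


@dataclass(frozen=True)
class GroomingParams:
    min_run_length: int = 80
    min_phred: int = 20
    trim_to_run: bool = True

    def __post_init__(self) -> None:
        if self.min_run_length <= 0:
            raise ValueError("min_run_length must be positive")
        if self.min_phred < 0:
            raise ValueError("min_phred must be non-negative")


@dataclass
class GroomedLibrary:
    reads: list[Read]
    n_input: int
    n_kept: int
    params: GroomingParams

    @property
    def fraction_kept(self) -> float:
        return self.n_kept / self.n_input if self.n_input else 0.0


def _longest_run(qualities: tuple[int, ...], min_phred: int) -> tuple[int, int]:
    """(start, length) of the longest run with quality >= min_phred, leftmost on ties."""
    best_start, best_len = 0, 0
    run_start, run_len = 0, 0
    for i, q in enumerate(qualities):
        if q >= min_phred:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    return best_start, best_len


def groom_read(read: Read, params: GroomingParams = GroomingParams()) -> Optional[Read]:
    """Return the groomed read, or None when it fails the run rule."""
    start, length = _longest_run(read.qualities, params.min_phred)
    if length < params.min_run_length:
        return None
    if not params.trim_to_run:
        return read
    if length == len(read):
        return read
    return Read(
        id=read.id,
        sequence=read.sequence[start:start + length],
        qualities=read.qualities[start:start + length],
        mate=read.mate,
    )


def groom_library(reads: Iterable[Read],
                  params: GroomingParams = GroomingParams()) -> GroomedLibrary:
    """Groom each read independently, preserving input order."""
    kept: list[Read] = []
    n_input = 0
    for read in reads:
        n_input += 1
        groomed = groom_read(read, params)
        if groomed is not None:
            kept.append(groomed)
    return GroomedLibrary(reads=kept, n_input=n_input, n_kept=len(kept), params=params)
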