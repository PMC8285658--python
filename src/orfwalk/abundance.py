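"""Read-count abundance of each transcript's reading frame, reference-normalized.

A read is scored as derived from a transcript when some ungapped placement
of the read (either orientation) against the ORF achieves at least
``min_identity`` identical bases out of an ``identity_window`` (default
90/100, i.e. at least 90 identical positions for a 100-nt read; reads
trimmed shorter by grooming scale the threshold to 90% of their length).
Placements overhanging the ORF ends count the overhang as mismatches.
Matching is a pure identity count -- no gaps -- and a read matching
several transcripts counts once for each (no competitive assignment).

Per-library abundance is (matching reads / total reads) / frame length,
expressed as log10 relative to a designated reference transcript, which
is therefore exactly 0 in every library.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .assembly import Transcript
from .sequence import Read, reverse_complement

__all__ = [
    "QuantParams",
    "AbundanceRecord",
    "read_matches_frame",
    "best_placement_identity",
    "FrameMatcher",
    "count_matching_reads",
    "records_from_counts",
    "quantify_library",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantParams:
    min_identity: int = 90
    identity_window: int = 100
    reference_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= self.identity_window:
            raise ValueError("require 0 < min_identity <= identity_window")

    def threshold_for(self, read_length: int) -> int:
        """Identity threshold, scaled proportionally for short reads."""
        if read_length >= self.identity_window:
            return self.min_identity
        return math.ceil(self.min_identity * read_length / self.identity_window)


@dataclass(frozen=True)
class AbundanceRecord:
    """One transcript's abundance in one library (one table row)."""

    transcript_id: str
    library_id: str
    matching_reads: int
    total_reads: int
    frame_length: int
    raw_abundance: float
    log10_relative: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def best_placement_identity(read_seq: str, orf_seq: str) -> int:
    """Maximum identical-base count over every ungapped placement and both
    orientations; the definitional brute force the fast path must agree with."""
    orf = _encode(orf_seq)
    best = 0
    for seq in (read_seq, reverse_complement(read_seq)):
        arr = _encode(seq)
        n = len(arr)
        padded = np.zeros(len(orf) + 2 * (n - 1), dtype=np.uint8)
        padded[n - 1:n - 1 + len(orf)] = orf
        windows = np.lib.stride_tricks.sliding_window_view(padded, n)
        matches = (windows == arr).sum(axis=1)
        best = max(best, int(matches.max()))
    return best


def read_matches_frame(read: Read, transcript: Transcript,
                       params: QuantParams = QuantParams()) -> bool:
    """True when the read places on the transcript's ORF at or above threshold."""
    return best_placement_identity(read.sequence, transcript.orf) >= \
        params.threshold_for(len(read))


class FrameMatcher:
    """K-mer-anchored matcher agreeing with :func:`best_placement_identity`.

    Anchors are disjoint k-mers along the read; any anchor hit proposes an
    ungapped offset that is then verified by an exact identity count, so a
    match is only missed when every disjoint anchor carries an error --
    negligible at the error rates the identity threshold itself tolerates.
    """

    def __init__(self, transcripts: Sequence[Transcript],
                 params: QuantParams = QuantParams(), k: int = 8):
        self.params = params
        self.k = k
        self.transcripts = list(transcripts)
        self._orfs = [_encode(t.orf) for t in self.transcripts]
        self._index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ti, t in enumerate(self.transcripts):
            orf = t.orf
            for p in range(len(orf) - k + 1):
                self._index[orf[p:p + k]].append((ti, p))

    def matching_transcripts(self, read: Read) -> set[int]:
        """Indices of transcripts the read matches."""
        k = self.k
        threshold = self.params.threshold_for(len(read))
        result: set[int] = set()
        for seq in (read.sequence, reverse_complement(read.sequence)):
            arr = _encode(seq)
            n = len(arr)
            candidates: dict[int, set[int]] = defaultdict(set)
            for a in range(0, n - k + 1, k):
                for ti, p in self._index.get(seq[a:a + k], ()):
                    candidates[ti].add(p - a)
            for ti, offsets in candidates.items():
                if ti in result:
                    continue
                orf = self._orfs[ti]
                for off in sorted(offsets):
                    lo = max(0, -off)
                    hi = min(n, len(orf) - off)
                    if hi - lo < k:
                        continue
                    matches = int((arr[lo:hi] == orf[off + lo:off + hi]).sum())
                    if matches >= threshold:
                        result.add(ti)
                        break
        return result


def count_matching_reads(
    transcripts: Sequence[Transcript],
    reads: Iterable[Read],
    params: QuantParams = QuantParams(),
    matcher: Optional[FrameMatcher] = None,
) -> tuple[list[int], int]:
    """Per-transcript matching-read counts and the total reads scanned."""
    if matcher is None:
        matcher = FrameMatcher(transcripts, params)
    counts = [0] * len(transcripts)
    total = 0
    for read in reads:
        total += 1
        for ti in matcher.matching_transcripts(read):
            counts[ti] += 1
    return counts, total


def records_from_counts(
    transcripts: Sequence[Transcript],
    counts: Sequence[int],
    total: int,
    library_id: str,
    params: QuantParams,
) -> list[AbundanceRecord]:
    """Normalize raw counts into :class:`AbundanceRecord` rows.

    The reference transcript (``params.reference_id``) must be present and
    matched by at least one read, otherwise normalization is undefined.
    Transcripts with zero matching reads get ``raw_abundance`` 0 and a
    ``log10_relative`` of -inf, and are flagged with a warning.
    """
    ids = [t.id for t in transcripts]
    if params.reference_id is None:
        raise ValueError("QuantParams.reference_id is required")
    try:
        ref_index = ids.index(params.reference_id)
    except ValueError:
        raise ValueError(
            f"reference transcript {params.reference_id!r} not among transcripts"
        ) from None
    if total == 0:
        raise ValueError(f"library {library_id!r} contains no reads")
    if counts[ref_index] == 0:
        raise ValueError(
            f"reference {params.reference_id!r} has zero matching reads in "
            f"library {library_id!r}: normalization undefined"
        )

    ref_raw = (counts[ref_index] / total) / transcripts[ref_index].frame_length
    records: list[AbundanceRecord] = []
    for t, m in zip(transcripts, counts):
        raw = (m / total) / t.frame_length
        if m == 0:
            logger.warning(
                "transcript %s: zero matching reads in library %s", t.id, library_id
            )
            log_rel = -math.inf
        elif t.id == params.reference_id:
            log_rel = 0.0  # exact self-normalization
        else:
            log_rel = math.log10(raw / ref_raw)
        records.append(
            AbundanceRecord(
                transcript_id=t.id,
                library_id=library_id,
                matching_reads=m,
                total_reads=total,
                frame_length=t.frame_length,
                raw_abundance=raw,
                log10_relative=log_rel,
            )
        )
    return records


def quantify_library(
    transcripts: Sequence[Transcript],
    reads: Iterable[Read],
    library_id: str,
    params: QuantParams,
) -> list[AbundanceRecord]:
    """One :class:`AbundanceRecord` per transcript for one groomed library."""
    counts, total = count_matching_reads(transcripts, reads, params)
    return records_from_counts(transcripts, counts, total, library_id, params)
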