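"""Transcriptome walking: greedy overlap-consensus assembly of complete ORFs.

A seed read is extended one base at a time. At each step, every read whose
prefix exactly matches a suffix of the growing contig over at least
``min_overlap`` bases (both orientations are indexed; the library is
treated as non-stranded) contributes its next base as an observation. Up
to ``column_pool`` observations are examined per column -- preferring the
longest overlaps, then the highest mean read quality -- and the
``column_top`` highest-quality observations vote. The majority base is
appended; any alternate base exceeding ``snp_fraction`` of the voters is
recorded as a SNP, while the contig keeps the canonical base.

Walking continues in both directions until no qualifying reads remain, a
repeated suffix state is detected (a repeat longer than ``min_overlap``),
the walk-length bound is hit, or -- the normal outcome -- the contig holds
a complete open reading frame (ATG through an in-frame stop) with a
configurable flank past each end. The finished contig is then polished by
re-piling every placeable read and re-calling each column with the same
pool/vote rule, which also yields the final SNP records (the seed read's
own errors are corrected by this pass, since seed bases are otherwise
never re-called). The reported ORF is the longest on either strand and
the contig is re-oriented so the ORF runs forward.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

from .sequence import Read, reverse_complement, translate

__all__ = [
    "WalkParams",
    "SnpRecord",
    "Transcript",
    "AssemblyFailure",
    "OverlapIndex",
    "build_overlap_index",
    "call_consensus_column",
    "extend_contig",
    "find_complete_orf",
    "polish_contig",
    "assemble_transcript",
]

_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class WalkParams:
    """Assembly controls.

    ``min_overlap`` defaults to 80 nt and is the user-facing control for
    repeat separation: raise it (up to read length - 5 or so, 95 for
    100-nt reads) to split transcripts sharing a long motif, lower it
    (to ~60) to walk through thin coverage.
    """

    min_overlap: int = 80
    column_pool: int = 40
    column_top: int = 20
    snp_fraction: float = 0.10
    max_walk_length: int = 20_000
    orf_flank: int = 200
    orf_check_interval: int = 25
    min_orf_length: int = 300

    def __post_init__(self) -> None:
        if self.column_top > self.column_pool:
            raise ValueError("column_top must not exceed column_pool")
        if not 0 < self.snp_fraction < 1:
            raise ValueError("snp_fraction must be in (0, 1)")
        if self.min_overlap <= 0:
            raise ValueError("min_overlap must be positive")


@dataclass(frozen=True)
class SnpRecord:
    """An alternate base exceeding the SNP fraction at an assembled column."""

    canonical_base: str
    alternate_base: str
    alternate_fraction: float
    position: int = -1  # 0-based on the contig; -1 until placed

    def __post_init__(self) -> None:
        if self.alternate_base == self.canonical_base:
            raise ValueError("alternate base equals canonical base")


@dataclass(frozen=True)
class Transcript:
    """An assembled contig containing one complete forward-strand ORF."""

    id: str
    sequence: str
    orf_start: int
    orf_end: int
    translation: str
    snps: tuple[SnpRecord, ...] = ()

    def __post_init__(self) -> None:
        if (self.orf_end - self.orf_start) % 3:
            raise ValueError("ORF length not a multiple of 3")
        orf = self.orf
        if orf[:3] != "ATG":
            raise ValueError("ORF does not begin with ATG")
        if orf[-3:] not in _STOPS:
            raise ValueError("ORF does not end with a stop codon")
        if len(self.translation) != (self.orf_end - self.orf_start) // 3 - 1:
            raise ValueError("translation length inconsistent with ORF span")

    @property
    def orf(self) -> str:
        return self.sequence[self.orf_start:self.orf_end]

    @property
    def frame_length(self) -> int:
        return self.orf_end - self.orf_start


@dataclass(frozen=True)
class AssemblyFailure:
    seed_id: str
    partial_contig: str
    reason: str


@dataclass(frozen=True)
class _Oriented:
    sequence: str
    qualities: tuple[int, ...]
    mean_quality: float


class OverlapIndex:
    """Exact prefix-k-mer lookup over both orientations of every read."""

    def __init__(self, reads: Iterable[Read], k: int):
        self.k = k
        self.entries: list[_Oriented] = []
        self._by_prefix: dict[str, list[int]] = defaultdict(list)
        for read in reads:
            if len(read) < k:
                continue
            mq = read.mean_quality
            fwd = _Oriented(read.sequence, read.qualities, mq)
            rev = _Oriented(
                reverse_complement(read.sequence), read.qualities[::-1], mq
            )
            for entry in (fwd, rev):
                self._by_prefix[entry.sequence[:k]].append(len(self.entries))
                self.entries.append(entry)
        self.max_length = max((len(e.sequence) for e in self.entries), default=k)

    def starting_with(self, kmer: str) -> list[_Oriented]:
        """All oriented reads whose first k bases equal ``kmer``."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != index k {self.k}")
        return [self.entries[i] for i in self._by_prefix.get(kmer, ())]


def build_overlap_index(reads: Iterable[Read], min_overlap: int = 80) -> OverlapIndex:
    return OverlapIndex(reads, k=min_overlap)


def call_consensus_column(
    observations: Sequence[tuple[str, int]],
    params: WalkParams = WalkParams(),
) -> tuple[str, Optional[SnpRecord]]:
    """Vote one column from (base, quality) observations.

    The first ``column_pool`` observations are examined and the
    ``column_top`` highest-quality of those vote. The canonical base is
    the majority; ties go to the higher summed quality, then alphabetic.
    The most frequent alternate is reported as a SNP when it exceeds
    ``snp_fraction`` of the voters.
    """
    if not observations:
        raise ValueError("no observations: end of walk")
    pool = list(observations[:params.column_pool])
    pool.sort(key=lambda bq: -bq[1])
    voters = pool[:params.column_top]
    count: dict[str, int] = defaultdict(int)
    sumq: dict[str, int] = defaultdict(int)
    for base, qual in voters:
        count[base] += 1
        sumq[base] += qual
    ranked = sorted(count, key=lambda b: (-count[b], -sumq[b], b))
    canonical = ranked[0]
    snp = None
    if len(ranked) > 1:
        alternate = ranked[1]
        fraction = count[alternate] / len(voters)
        if fraction > params.snp_fraction:
            snp = SnpRecord(
                canonical_base=canonical,
                alternate_base=alternate,
                alternate_fraction=fraction,
            )
    return canonical, snp


def extend_contig(
    contig: str,
    index: OverlapIndex,
    params: WalkParams = WalkParams(),
    max_steps: Optional[int] = None,
) -> tuple[str, list[SnpRecord], str]:
    """Extend the 3' end of ``contig`` by repeated one-base consensus calls.

    Returns ``(extended_contig, snps, reason)`` where ``reason`` is one of
    ``no_reads``, ``repeat``, ``max_walk_length`` or ``max_steps``. SNP
    positions are 0-based on the returned contig. To extend the 5' end,
    pass the reverse complement and flip the result.
    """
    if len(contig) < params.min_overlap:
        raise ValueError("contig shorter than min_overlap")
    k = params.min_overlap
    seen_states: set[str] = set()
    snps: list[SnpRecord] = []
    appended = 0
    while True:
        if appended >= params.max_walk_length:
            return contig, snps, "max_walk_length"
        if max_steps is not None and appended >= max_steps:
            return contig, snps, "max_steps"
        state = contig[-k:]
        if state in seen_states:
            return contig, snps, "repeat"
        seen_states.add(state)
        length = len(contig)
        observations: list[tuple[str, int, int, float]] = []
        for p in range(max(0, length - index.max_length + 1), length - k + 1):
            overlap = length - p
            for entry in index.starting_with(contig[p:p + k]):
                if len(entry.sequence) > overlap and (
                    overlap == k or entry.sequence[:overlap] == contig[p:]
                ):
                    observations.append(
                        (
                            entry.sequence[overlap],
                            entry.qualities[overlap],
                            overlap,
                            entry.mean_quality,
                        )
                    )
        if not observations:
            return contig, snps, "no_reads"
        # pool preference: longest overlap first, then highest mean quality
        observations.sort(key=lambda o: (-o[2], -o[3]))
        pooled = [(base, qual) for base, qual, _, _ in
                  observations[:params.column_pool]]
        base, snp = call_consensus_column(pooled, params)
        if snp is not None:
            snps.append(replace(snp, position=length))
        contig += base
        appended += 1


def find_complete_orf(contig: str) -> Optional[tuple[int, int, str]]:
    """Longest ATG..in-frame-stop span on either strand.

    Returns ``(orf_start, orf_end, strand)`` with 0-based half-open
    coordinates on the strand carrying the ORF (i.e. on
    ``reverse_complement(contig)`` when strand is '-'). Ties prefer the
    forward strand, then the smallest start. None when no complete ORF
    exists.
    """
    if len(contig) < 6:
        return None
    best: Optional[tuple[int, int, str]] = None

    def consider(start: int, end: int, strand: str) -> None:
        nonlocal best
        if best is None:
            best = (start, end, strand)
            return
        length, best_length = end - start, best[1] - best[0]
        if length > best_length:
            best = (start, end, strand)
        elif length == best_length:
            if (strand, best[2]) == ("+", "-"):
                best = (start, end, strand)
            elif strand == best[2] and start < best[0]:
                best = (start, end, strand)

    for strand, seq in (("+", contig), ("-", reverse_complement(contig))):
        for frame in range(3):
            open_start: Optional[int] = None
            for pos in range(frame, len(seq) - 2, 3):
                codon = seq[pos:pos + 3]
                if codon == "ATG" and open_start is None:
                    open_start = pos
                elif codon in _STOPS:
                    if open_start is not None:
                        consider(open_start, pos + 3, strand)
                    open_start = None
    return best


def _orf_span_forward(contig: str) -> Optional[tuple[int, int]]:
    """Span of the best complete ORF in forward coordinates of ``contig``."""
    orf = find_complete_orf(contig)
    if orf is None:
        return None
    start, end, strand = orf
    if strand == "+":
        return start, end
    return len(contig) - end, len(contig) - start


def _anchored_orf_span(contig: str) -> Optional[tuple[int, int, bool, bool]]:
    """Best complete ORF span plus whether each contig side is final.

    The stop-codon side of an ORF cannot move with further extension, but
    the ATG side can: a longer ORF may appear if walking uncovers an
    earlier in-frame ATG. The ATG side only becomes final once an
    in-frame stop codon lies upstream of the start within the contig.
    Returns ``(lo, hi, left_final, right_final)`` in forward coordinates.
    """
    orf = find_complete_orf(contig)
    if orf is None:
        return None
    start, end, strand = orf
    seq = contig if strand == "+" else reverse_complement(contig)
    upstream_stop = any(
        seq[p:p + 3] in _STOPS for p in range(start - 3, -1, -3)
    )
    if strand == "+":
        return start, end, upstream_stop, True
    return len(contig) - end, len(contig) - start, True, upstream_stop


def polish_contig(
    contig: str,
    index: OverlapIndex,
    params: WalkParams = WalkParams(),
    seed_k: int = 15,
    min_identity: float = 0.8,
) -> tuple[str, list[SnpRecord]]:
    """Re-call every column of ``contig`` from a pileup of placed reads.

    Reads are placed by exact ``seed_k``-mer anchors and accepted at their
    best ungapped offset when identity over the overlap reaches
    ``min_identity``. Columns with no coverage keep the walked base.
    Substitution-only placement: the error model upstream and the
    exact-overlap walk make indels out of scope.
    """
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(len(contig) - seed_k + 1):
        positions[contig[i:i + seed_k]].append(i)

    pileup: list[list[tuple[str, int]]] = [[] for _ in contig]
    for entry in index.entries:
        seq = entry.sequence
        if len(seq) < seed_k:
            continue
        offsets: set[int] = set()
        anchors = list(range(0, len(seq) - seed_k + 1, seed_k))
        for a in anchors:
            for p in positions.get(seq[a:a + seed_k], ()):
                offsets.add(p - a)
        best_offset, best_matches, best_overlap = None, -1, 0
        for off in sorted(offsets):
            lo = max(0, -off)
            hi = min(len(seq), len(contig) - off)
            if hi - lo < seed_k:
                continue
            matches = sum(
                1 for i in range(lo, hi) if seq[i] == contig[off + i]
            )
            if matches > best_matches:
                best_offset, best_matches, best_overlap = off, matches, hi - lo
        if best_offset is None or best_matches < min_identity * best_overlap:
            continue
        lo = max(0, -best_offset)
        hi = min(len(seq), len(contig) - best_offset)
        for i in range(lo, hi):
            pileup[best_offset + i].append((seq[i], entry.qualities[i]))

    out: list[str] = []
    snps: list[SnpRecord] = []
    for pos, column in enumerate(pileup):
        if not column:
            out.append(contig[pos])
            continue
        column.sort(key=lambda bq: -bq[1])
        base, snp = call_consensus_column(column, params)
        out.append(base)
        if snp is not None:
            snps.append(replace(snp, position=pos))
    return "".join(out), snps


def _flip_snps(snps: Sequence[SnpRecord], length: int) -> list[SnpRecord]:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return [
        SnpRecord(
            canonical_base=comp[s.canonical_base],
            alternate_base=comp[s.alternate_base],
            alternate_fraction=s.alternate_fraction,
            position=length - 1 - s.position,
        )
        for s in snps
    ]


def assemble_transcript(
    seed: Read,
    reads: Union[Iterable[Read], OverlapIndex],
    params: WalkParams = WalkParams(),
    transcript_id: Optional[str] = None,
) -> Union[Transcript, AssemblyFailure]:
    """Walk outward from ``seed`` until the contig holds a complete ORF.

    ``reads`` may be a prebuilt :class:`OverlapIndex` (reused across
    seeds) or any iterable of groomed reads. Extension alternates with
    ORF checks every ``orf_check_interval`` columns and each direction
    stops once the ORF is complete with ``orf_flank`` bases beyond its
    end, or when reads run out. The contig is then polished, re-oriented
    so the ORF is forward, and returned as a :class:`Transcript`; if no
    complete ORF is found the partial contig comes back attached to an
    :class:`AssemblyFailure`.
    """
    if len(seed) < params.min_overlap:
        raise ValueError(
            f"seed {seed.id!r} shorter than min_overlap ({params.min_overlap})"
        )
    index = reads if isinstance(reads, OverlapIndex) else build_overlap_index(
        reads, params.min_overlap
    )

    # consensus-correct the seed span first: a high-quality miscall inside
    # the seed would otherwise defeat every exact overlap at that end
    contig, _ = polish_contig(seed.sequence, index, params)
    budget = params.max_walk_length
    snps: list[SnpRecord] = []

    def walk(direction: str, contig: str, budget: int) -> tuple[str, int]:
        # right walks extend the 3' end; left walks operate on the revcomp
        while budget > 0:
            work = contig if direction == "right" else reverse_complement(contig)
            step = min(params.orf_check_interval, budget)
            extended, _, reason = extend_contig(work, index, params, max_steps=step)
            grown = len(extended) - len(work)
            budget -= grown
            contig = extended if direction == "right" else reverse_complement(extended)
            span = _anchored_orf_span(contig)
            if span is not None and span[1] - span[0] < params.min_orf_length:
                span = None  # short chance ORFs never justify an early stop
            if span is not None:
                lo, hi, left_final, right_final = span
                if (direction == "right" and right_final
                        and len(contig) - hi >= params.orf_flank):
                    break
                if direction == "left" and left_final and lo >= params.orf_flank:
                    break
            if reason != "max_steps":
                break
        return contig, budget

    # walk and polish to a fixpoint: polishing can correct a miscalled end
    # base that had stalled a walk, letting extension resume
    for _ in range(3):
        before = contig
        contig, budget = walk("right", contig, budget)
        contig, budget = walk("left", contig, budget)
        contig, snps = polish_contig(contig, index, params)
        if contig == before:
            break

    polished = contig
    orf = find_complete_orf(polished)
    if orf is None or orf[1] - orf[0] < params.min_orf_length:
        return AssemblyFailure(
            seed_id=seed.id, partial_contig=polished, reason="no_complete_orf"
        )
    start, end, strand = orf
    if strand == "-":
        polished = reverse_complement(polished)
        snps = _flip_snps(snps, len(polished))
    snps = sorted(snps, key=lambda s: s.position)
    orf_seq = polished[start:end]
    return Transcript(
        id=transcript_id or f"contig_{seed.id}",
        sequence=polished,
        orf_start=start,
        orf_end=end,
        translation=translate(orf_seq)[:-1],
        snps=tuple(snps),
    )
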