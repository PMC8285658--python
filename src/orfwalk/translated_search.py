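"""Targeted discovery: BLOSUM screening of translated reads against query proteins.

Each read is translated in all six frames and scored against each query
with the standard ungapped local-segment recurrence (a running sum that
resets at zero), so the result is the maximum-scoring ungapped window
between the translated read and the query. Gapped alignment is
deliberately out of scope: reads are short, and determinism matters more
than a marginal sensitivity gain. The stringency is a raw-score threshold
(default 40 with BLOSUM62, roughly 8-10 identical residues) -- low enough
to admit distant relatives, and false positives are expected and accepted
at this stage; assembly and identification sort them out later.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio.Align import substitution_matrices

from .sequence import ProteinQuery, Read, six_frame_translations

__all__ = ["BlosumHit", "best_window_score", "screen_library", "load_matrix"]

FRAME_LABELS = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class BlosumHit:
    read_id: str
    frame: int
    query_id: str
    score: int
    query_offset: int
    read_offset: int
    window_length: int


@lru_cache(maxsize=8)
def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _pair_scores(name: str) -> dict[tuple[str, str], int]:
    """Dense pair-score lookup. A stop symbol scores the matrix minimum of
    its partner's column, so any window crossing a stop is heavily penalized."""
    mat = load_matrix(name)
    letters = [a for a in mat.alphabet if a != "*"]
    table: dict[tuple[str, str], int] = {}
    for a in letters:
        for b in letters:
            table[(a, b)] = int(mat[a, b])
    for b in letters:
        col_min = min(int(mat[a, b]) for a in letters)
        table[("*", b)] = col_min
        table[(b, "*")] = col_min
    table[("*", "*")] = min(table[("*", b)] for b in letters)
    return table


def best_window_score(peptide: str, query: ProteinQuery | str,
                      matrix_name: str = "BLOSUM62") -> tuple[int, int, int, int]:
    """Maximum-scoring ungapped local segment between peptide and query.

    Returns ``(score, query_offset, peptide_offset, window_length)``; the
    empty segment scores 0, so the result is never negative.
    """
    residues = query.residues if isinstance(query, ProteinQuery) else query
    scores = _pair_scores(matrix_name)
    fallback = ("X", "X")
    best = (0, 0, 0, 0)
    n, m = len(peptide), len(residues)
    for diag in range(-(n - 1), m):
        p0 = max(0, -diag)
        q0 = p0 + diag
        running = 0
        seg_start = p0
        p, q = p0, q0
        while p < n and q < m:
            pair = (peptide[p], residues[q])
            s = scores.get(pair)
            if s is None:
                s = scores[fallback]
            running += s
            if running <= 0:
                running = 0
                seg_start = p + 1
            elif running > best[0]:
                best = (running, seg_start + diag, seg_start, p - seg_start + 1)
            p += 1
            q += 1
    return best


def screen_library(reads: Iterable[Read], queries: Sequence[ProteinQuery],
                   matrix_name: str = "BLOSUM62",
                   min_score: int = 40) -> list[BlosumHit]:
    """All (read, frame, query) triples whose best window reaches ``min_score``."""
    hits: list[BlosumHit] = []
    for read in reads:
        if len(read) < 3:
            continue
        frames = six_frame_translations(read.sequence)
        for frame_label, peptide in zip(FRAME_LABELS, frames):
            if not peptide:
                continue
            for query in queries:
                score, q_off, p_off, length = best_window_score(
                    peptide, query, matrix_name
                )
                if score >= min_score:
                    hits.append(
                        BlosumHit(
                            read_id=read.id,
                            frame=frame_label,
                            query_id=query.id,
                            score=score,
                            query_offset=q_off,
                            read_offset=p_off,
                            window_length=length,
                        )
                    )
    return hits
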