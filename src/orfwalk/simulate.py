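"""Synthetic transcriptomes and paired-end read libraries with known truth.

The generator emulates the statistical structure the analysis assumes:
a set of transcripts each carrying one complete ORF (ATG ... stop) between
random UTRs; per-transcript abundances spanning about a log unit around a
designated reference transcript; a heavy-tailed (truncated Cauchy, median
1) null law for between-condition abundance ratios with a small set of
planted outliers well outside the null range; and two libraries of
paired 100-nt reads with i.i.d. substitution errors whose Phred
qualities are drawn lower for erroneous calls than for correct ones.
Transcripts are rejection-sampled so that no two share an exact 80-mer on
either strand (so overlap walks cannot cross between them) unless a
repeat fixture is explicitly requested. Everything is deterministic
under the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .assembly import Transcript, find_complete_orf
from .sequence import Read, reverse_complement, translate, write_fasta, write_fastq

__all__ = [
    "SimConfig",
    "TranscriptTruth",
    "GroundTruth",
    "generate_transcriptome",
    "assign_abundances",
    "simulate_reads",
    "simulate_study",
    "write_study",
]

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the simulator.

    ``coverage`` is the mean fold-coverage of a transcript at relative
    abundance 1 (the reference); a transcript at log10 abundance a is
    covered ``coverage * 10**a`` fold in expectation. Ratios are
    noise/control; the null law is a Cauchy(ratio_x0, ratio_gamma)
    truncated to ``ratio_bounds``, and planted outliers sit outside those
    bounds by construction.
    """

    n_transcripts: int = 50
    orf_length_range: tuple[int, int] = (300, 900)
    utr_length_range: tuple[int, int] = (50, 150)
    log10_abundance_range: tuple[float, float] = (-0.5, 0.5)
    ratio_x0: float = 1.0
    ratio_gamma: float = 0.087
    ratio_bounds: tuple[float, float] = (0.7, 1.3)
    n_outliers_up: int = 3
    outlier_up_ratio: float = 3.0
    n_outliers_down: int = 5
    outlier_down_ratio: float = 0.07
    read_length: int = 100
    fragment_length_range: tuple[int, int] = (180, 320)
    coverage: float = 30.0
    error_rate: float = 0.005
    q_correct_mean: float = 38.0
    q_correct_sd: float = 3.0
    q_error_mean: float = 14.0
    q_error_sd: float = 6.0
    shared_kmer: int = 80
    allow_shared_motifs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.orf_length_range
        if lo % 3 or hi % 3 or lo > hi or lo < 9:
            raise ValueError(
                "orf_length_range must be multiples of 3 with 9 <= min <= max"
            )
        if self.n_outliers_up + self.n_outliers_down >= self.n_transcripts:
            raise ValueError("more outliers than transcripts")
        blo, bhi = self.ratio_bounds
        if not blo < bhi:
            raise ValueError("invalid ratio truncation bounds")
        if blo <= self.outlier_down_ratio or bhi >= self.outlier_up_ratio:
            raise ValueError("planted outlier ratios must lie outside ratio_bounds")


@dataclass(frozen=True)
class TranscriptTruth:
    transcript_id: str
    log10_control: float
    log10_noise: float
    ratio: float
    outlier: str  # "", "up" or "down"


@dataclass
class GroundTruth:
    reference_id: str
    records: list[TranscriptTruth]

    def by_id(self, transcript_id: str) -> TranscriptTruth:
        for rec in self.records:
            if rec.transcript_id == transcript_id:
                return rec
        raise KeyError(transcript_id)

    @property
    def outlier_ids(self) -> set[str]:
        return {r.transcript_id for r in self.records if r.outlier}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def generate_transcriptome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> list[Transcript]:
    """Transcripts of the form UTR + ATG + sense codons + stop + UTR.

    Each candidate is resampled until its longest-ORF call matches the
    designed coordinates exactly and (by default) it shares no exact
    ``shared_kmer``-mer with any already-accepted transcript on either
    strand.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    olo, ohi = config.orf_length_range
    ulo, uhi = config.utr_length_range
    k = config.shared_kmer
    seen_kmers: set[str] = set()
    transcripts: list[Transcript] = []
    for i in range(config.n_transcripts):
        while True:
            orf_len = 3 * int(rng.integers(olo // 3, ohi // 3 + 1))
            n_codons = orf_len // 3 - 2
            orf = (
                "ATG"
                + "".join(rng.choice(_SENSE_CODONS, size=n_codons))
                + str(rng.choice(_STOPS))
            )
            utr5 = _random_seq(rng, int(rng.integers(ulo, uhi + 1)))
            utr3 = _random_seq(rng, int(rng.integers(ulo, uhi + 1)))
            seq = utr5 + orf + utr3
            if find_complete_orf(seq) != (len(utr5), len(utr5) + orf_len, "+"):
                continue
            kmers = {
                seq[j:j + k] for j in range(len(seq) - k + 1)
            }
            rc = reverse_complement(seq)
            kmers |= {rc[j:j + k] for j in range(len(rc) - k + 1)}
            if not config.allow_shared_motifs and kmers & seen_kmers:
                continue
            seen_kmers |= kmers
            start = len(utr5)
            transcripts.append(
                Transcript(
                    id=f"TRS_{i + 1:04d}",
                    sequence=seq,
                    orf_start=start,
                    orf_end=start + orf_len,
                    translation=translate(orf)[:-1],
                )
            )
            break
    return transcripts


def _truncated_cauchy(rng: np.random.Generator, x0: float, gamma: float,
                      bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    while True:
        x = x0 + gamma * math.tan(math.pi * (rng.random() - 0.5))
        if lo <= x <= hi:
            return x


def assign_abundances(
    transcripts: Sequence[Transcript],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruth:
    """Control abundances uniform in range; noise = control + log10(ratio).

    The first transcript is the reference: abundance 0 (by definition of
    "relative") and ratio exactly 1. Planted outliers take the last
    ``n_outliers_up + n_outliers_down`` slots.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    alo, ahi = config.log10_abundance_range
    n = len(transcripts)
    n_out = config.n_outliers_up + config.n_outliers_down
    records: list[TranscriptTruth] = []
    for i, t in enumerate(transcripts):
        if i == 0:
            control, ratio, outlier = 0.0, 1.0, ""
        else:
            control = float(rng.uniform(alo, ahi))
            if i >= n - config.n_outliers_down:
                ratio, outlier = config.outlier_down_ratio, "down"
            elif i >= n - n_out:
                ratio, outlier = config.outlier_up_ratio, "up"
            else:
                ratio = _truncated_cauchy(
                    rng, config.ratio_x0, config.ratio_gamma, config.ratio_bounds
                )
                outlier = ""
        records.append(
            TranscriptTruth(
                transcript_id=t.id,
                log10_control=control,
                log10_noise=control + math.log10(ratio),
                ratio=ratio,
                outlier=outlier,
            )
        )
    return GroundTruth(reference_id=transcripts[0].id, records=records)


def _apply_errors(
    seq: str, rng: np.random.Generator, config: SimConfig
) -> tuple[str, tuple[int, ...]]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = len(arr)
    err = rng.random(n) < config.error_rate
    if err.any():
        lut = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}
        for i in np.flatnonzero(err):
            arr[i] = lut[int(arr[i])][rng.integers(0, 3)]
    quals = np.where(
        err,
        rng.normal(config.q_error_mean, config.q_error_sd, n),
        rng.normal(config.q_correct_mean, config.q_correct_sd, n),
    )
    quals = np.clip(np.rint(quals), 2, 41).astype(int)
    return arr.tobytes().decode("ascii"), tuple(int(q) for q in quals)


def simulate_reads(
    transcripts: Sequence[Transcript],
    truth: GroundTruth,
    condition: str,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Read], list[Read]]:
    """Paired 100-nt reads for one condition: (mate-1 list, mate-2 list).

    Pair count per transcript is Poisson with mean
    ``coverage * 10**log10_abundance * len / (2 * read_length)``; fragment
    positions are uniform, mate 2 is the reverse complement of the
    fragment's other end, and either mate may come from either strand.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if condition not in ("control", "noise"):
        raise ValueError("condition must be 'control' or 'noise'")
    rl = config.read_length
    flo, fhi = config.fragment_length_range
    reads1: list[Read] = []
    reads2: list[Read] = []
    for t in transcripts:
        rec = truth.by_id(t.id)
        log_ab = rec.log10_control if condition == "control" else rec.log10_noise
        lam = config.coverage * (10.0 ** log_ab) * len(t.sequence) / (2 * rl)
        n_pairs = int(rng.poisson(lam))
        for j in range(n_pairs):
            frag_len = int(rng.integers(max(flo, rl), max(fhi, rl) + 1))
            frag_len = min(frag_len, len(t.sequence))
            start = int(rng.integers(0, len(t.sequence) - frag_len + 1))
            frag = t.sequence[start:start + frag_len]
            fwd, rev = frag[:rl], reverse_complement(frag)[:rl]
            if rng.random() < 0.5:
                fwd, rev = rev, fwd
            name = f"{condition}:{t.id}:{j}"
            s1, q1 = _apply_errors(fwd, rng, config)
            s2, q2 = _apply_errors(rev, rng, config)
            reads1.append(Read(id=name, sequence=s1, qualities=q1, mate=1))
            reads2.append(Read(id=name, sequence=s2, qualities=q2, mate=2))
    return reads1, reads2


def simulate_study(config: SimConfig) -> dict:
    """Generate a full two-condition study: transcripts, truth, both libraries."""
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    transcripts = generate_transcriptome(config, np.random.default_rng(seeds[0]))
    truth = assign_abundances(transcripts, config, np.random.default_rng(seeds[1]))
    control = simulate_reads(
        transcripts, truth, "control", config, np.random.default_rng(seeds[2])
    )
    noise = simulate_reads(
        transcripts, truth, "noise", config, np.random.default_rng(seeds[3])
    )
    return {
        "transcripts": transcripts,
        "truth": truth,
        "control": control,
        "noise": noise,
    }


def write_study(study: dict, outdir: str | Path) -> dict[str, Path]:
    """Write transcripts.fasta, truth.tsv and {condition}_R{1,2}.fastq."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    fasta = outdir / "transcripts.fasta"
    write_fasta(
        (
            (f"{t.id} orf={t.orf_start}..{t.orf_end}", t.sequence)
            for t in study["transcripts"]
        ),
        fasta,
    )
    paths["transcripts"] = fasta
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("transcript_id\tlog10_control\tlog10_noise\tratio\toutlier\n")
        for rec in study["truth"].records:
            fh.write(
                f"{rec.transcript_id}\t{rec.log10_control:.6f}\t"
                f"{rec.log10_noise:.6f}\t{rec.ratio:.6f}\t{rec.outlier}\n"
            )
    paths["truth"] = truth_path
    for condition in ("control", "noise"):
        for mate, reads in zip((1, 2), study[condition]):
            p = outdir / f"{condition}_R{mate}.fastq"
            write_fastq(reads, p)
            paths[f"{condition}_R{mate}"] = p
    return paths
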