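"""End-to-end orchestration: groom -> census/screen -> walk -> quantify -> select.

`run_full` sequences the stages over two condition libraries, writes every
intermediate artifact into the output directory, and records a manifest
with parameters, per-stage counts and a SHA-256 hash of every output file
so that reruns can be verified byte-for-byte. All stages are
deterministic given the same inputs and parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .abundance import (
    QuantParams,
    count_matching_reads,
    records_from_counts,
)
from .assembly import (
    AssemblyFailure,
    Transcript,
    WalkParams,
    build_overlap_index,
    assemble_transcript,
)
from .census import CensusParams, count_identical_reads, cross_census, select_candidates
from .grooming import GroomingParams, groom_library
from .ratio_stats import (
    build_histogram,
    fit_cauchy,
    ratios_from_log_table,
    select_tails,
)
from .sequence import Read, parse_fastq, read_fasta, read_protein_queries, \
    translate, write_fasta, write_fastq
from .translated_search import screen_library

__all__ = ["PipelineConfig", "run_full", "transcripts_to_fasta",
           "transcripts_from_fasta"]

logger = logging.getLogger(__name__)

_ORF_RE = re.compile(r"orf=(\d+)\.\.(\d+)")


@dataclass(frozen=True)
class PipelineConfig:
    library_a: tuple[str, ...]
    library_b: tuple[str, ...]
    outdir: str
    queries: Optional[str] = None
    grooming: GroomingParams = GroomingParams()
    census: CensusParams = CensusParams()
    walk: WalkParams = WalkParams()
    min_identity: int = 90
    identity_window: int = 100
    reference_id: Optional[str] = None  # None: most-matched transcript in library A
    max_census_seeds: int = 20
    blosum_matrix: str = "BLOSUM62"
    min_blosum_score: int = 40
    max_search_seeds: int = 20
    bin_width: float = 0.2
    bin_origin: float = 0.0
    p_low: float = 0.05
    p_high: float = 0.95

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        for key, klass in (
            ("grooming", GroomingParams),
            ("census", CensusParams),
            ("walk", WalkParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        for key in ("library_a", "library_b"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


def transcripts_to_fasta(transcripts: Sequence[Transcript], path: str | Path) -> None:
    write_fasta(
        ((f"{t.id} orf={t.orf_start}..{t.orf_end}", t.sequence) for t in transcripts),
        path,
    )


def transcripts_from_fasta(path: str | Path) -> list[Transcript]:
    """Read transcripts written by :func:`transcripts_to_fasta` (or any FASTA
    whose description carries ``orf=start..end`` 0-based half-open coords)."""
    from Bio import SeqIO

    out: list[Transcript] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _ORF_RE.search(rec.description)
        if not m:
            raise ValueError(f"record {rec.id!r}: no orf=start..end in description")
        start, end = int(m.group(1)), int(m.group(2))
        seq = str(rec.seq).upper()
        out.append(
            Transcript(
                id=rec.id,
                sequence=seq,
                orf_start=start,
                orf_end=end,
                translation=translate(seq[start:end])[:-1],
            )
        )
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_and_groom(paths: Sequence[str], params: GroomingParams):
    reads: list[Read] = []
    for p in paths:
        reads.extend(parse_fastq(p))
    return groom_library(reads, params)


def run_full(config: PipelineConfig) -> dict:
    """Execute the whole pipeline; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "orfwalk",
        "version": __version__,
        "config": _config_dict(config),
        "stages": {},
        "outputs": {},
    }

    # -- grooming ---------------------------------------------------------
    lib_a = _load_and_groom(config.library_a, config.grooming)
    lib_b = _load_and_groom(config.library_b, config.grooming)
    write_fastq(lib_a.reads, outdir / "groomed_a.fastq")
    write_fastq(lib_b.reads, outdir / "groomed_b.fastq")
    manifest["stages"]["grooming"] = {
        "a": {"input": lib_a.n_input, "kept": lib_a.n_kept},
        "b": {"input": lib_b.n_input, "kept": lib_b.n_kept},
    }

    # -- seed discovery ---------------------------------------------------
    counts_a = count_identical_reads(lib_a.reads, config.census.head_limit)
    counts_b = count_identical_reads(lib_b.reads, config.census.head_limit)
    entries = cross_census(counts_a, counts_b)
    candidates = select_candidates(entries, config.census.ratio_threshold)
    n_single = sum(1 for e in entries if not e.in_both)
    pd.DataFrame(
        [
            {
                "sequence": e.sequence,
                "count_a": e.count_a,
                "count_b": e.count_b,
                "ratio": e.ratio,
                "extremity": e.extremity,
            }
            for e in candidates
        ]
    ).to_csv(outdir / "census_candidates.tsv", sep="\t", index=False)
    seeds: list[Read] = [
        Read(
            id=f"census_seed_{i + 1}",
            sequence=e.sequence,
            qualities=(40,) * len(e.sequence),
        )
        for i, e in enumerate(candidates[: config.max_census_seeds])
    ]
    manifest["stages"]["census"] = {
        "entries": len(entries),
        "single_library": n_single,
        "candidates": len(candidates),
        "seeds": len(seeds),
    }

    if config.queries:
        queries = read_protein_queries(config.queries)
        hits = screen_library(
            lib_a.reads, queries, config.blosum_matrix, config.min_blosum_score
        )
        by_id = {r.id: r for r in lib_a.reads}
        seen: set[str] = set()
        for hit in sorted(hits, key=lambda h: -h.score):
            if hit.read_id not in seen and len(seen) < config.max_search_seeds:
                seen.add(hit.read_id)
                seeds.append(by_id[hit.read_id])
        manifest["stages"]["translated_search"] = {
            "hits": len(hits), "seed_reads": len(seen),
        }

    # -- walking assembly -------------------------------------------------
    index = build_overlap_index(
        lib_a.reads + lib_b.reads, config.walk.min_overlap
    )
    transcripts: list[Transcript] = []
    seen_orfs: set[str] = set()
    failures = 0
    for seed in seeds:
        if len(seed) < config.walk.min_overlap:
            continue
        result = assemble_transcript(seed, index, config.walk)
        if isinstance(result, AssemblyFailure):
            failures += 1
            continue
        if result.orf in seen_orfs:
            continue
        seen_orfs.add(result.orf)
        transcripts.append(
            dataclasses.replace(result, id=f"TR_{len(transcripts) + 1:04d}")
        )
    transcripts_to_fasta(transcripts, outdir / "transcripts.fasta")
    with open(outdir / "snps.tsv", "w") as fh:
        fh.write("transcript_id\tposition\tcanonical\talternate\tfraction\n")
        for t in transcripts:
            for s in t.snps:
                fh.write(
                    f"{t.id}\t{s.position}\t{s.canonical_base}\t"
                    f"{s.alternate_base}\t{s.alternate_fraction:.4f}\n"
                )
    manifest["stages"]["assembly"] = {
        "seeds": len(seeds),
        "transcripts": len(transcripts),
        "failures": failures,
    }
    if not transcripts:
        raise RuntimeError("assembly produced no transcripts; nothing to quantify")

    # -- quantification ---------------------------------------------------
    qp = QuantParams(
        min_identity=config.min_identity, identity_window=config.identity_window
    )
    counts_lib_a, total_a = count_matching_reads(transcripts, lib_a.reads, qp)
    counts_lib_b, total_b = count_matching_reads(transcripts, lib_b.reads, qp)
    reference = config.reference_id
    if reference is None:
        reference = transcripts[
            max(range(len(transcripts)), key=lambda i: counts_lib_a[i])
        ].id
    qp = QuantParams(
        min_identity=config.min_identity,
        identity_window=config.identity_window,
        reference_id=reference,
    )
    rec_a = records_from_counts(transcripts, counts_lib_a, total_a, "library_a", qp)
    rec_b = records_from_counts(transcripts, counts_lib_b, total_b, "library_b", qp)
    table = pd.DataFrame(
        {
            "transcript_id": [t.id for t in transcripts],
            "matching_a": [r.matching_reads for r in rec_a],
            "matching_b": [r.matching_reads for r in rec_b],
            "frame_length": [t.frame_length for t in transcripts],
            "log10_control": [r.log10_relative for r in rec_a],
            "log10_noise": [r.log10_relative for r in rec_b],
        }
    )
    table.to_csv(outdir / "abundances.tsv", sep="\t", index=False)
    manifest["stages"]["quantification"] = {
        "reference": reference,
        "total_reads_a": total_a,
        "total_reads_b": total_b,
    }

    # -- ratio statistics -------------------------------------------------
    finite = table[
        (table.log10_control > float("-inf")) & (table.log10_noise > float("-inf"))
    ]
    dropped = len(table) - len(finite)
    if dropped:
        logger.warning("%d transcript(s) with zero matches excluded from ratios",
                       dropped)
    ratios = ratios_from_log_table(finite)
    histogram = build_histogram(ratios, config.bin_width, config.bin_origin)
    selection = None
    fit = None
    occupied = sum(1 for c in histogram.counts if c)
    if occupied >= 3:
        fit = fit_cauchy(histogram)
        selection = select_tails(ratios, fit, config.p_low, config.p_high)
        with open(outdir / "fit.json", "w") as fh:
            json.dump(dataclasses.asdict(fit), fh, indent=2)
        with open(outdir / "selection.json", "w") as fh:
            json.dump(
                {
                    "lower_cutoff": selection.lower_cutoff,
                    "upper_cutoff": selection.upper_cutoff,
                    "decreased": [
                        {"transcript_id": r.transcript_id, "ratio": r.rounded}
                        for r in selection.decreased
                    ],
                    "increased": [
                        {"transcript_id": r.transcript_id, "ratio": r.rounded}
                        for r in selection.increased
                    ],
                },
                fh,
                indent=2,
            )
    manifest["stages"]["ratio_stats"] = {
        "ratios": len(ratios),
        "excluded_zero_match": dropped,
        "fit": dataclasses.asdict(fit) if fit else None,
        "n_decreased": len(selection.decreased) if selection else None,
        "n_increased": len(selection.increased) if selection else None,
    }

    for p in sorted(outdir.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
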