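"""Walking assembly: consensus calls, overlap extension, ORF finding."""

import pytest

from orfwalk.assembly import (
    AssemblyFailure,
    Transcript,
    WalkParams,
    assemble_transcript,
    build_overlap_index,
    call_consensus_column,
    extend_contig,
    find_complete_orf,
)
from orfwalk.sequence import Read, reverse_complement

from conftest import make_read, random_dna


def tile_reads(sequence, read_len=100, step=3, quality=40, prefix="t"):
    """Error-free reads tiling a template at a fixed stride."""
    reads = []
    for i, start in enumerate(range(0, len(sequence) - read_len + 1, step)):
        reads.append(make_read(sequence[start:start + read_len], quality,
                               f"{prefix}{i}"))
    return reads


def make_template(rng, orf_codons=120, utr=120):
    """Random template with one designed ORF and stop-free interior."""
    from orfwalk.simulate import _SENSE_CODONS

    interior = "".join(rng.choice(_SENSE_CODONS, size=orf_codons))
    return random_dna(rng, utr) + "ATG" + interior + "TAA" + random_dna(rng, utr)


class TestConsensusColumn:
    def test_unanimous(self):
        base, snp = call_consensus_column([("A", 40)] * 20)
        assert (base, snp) == ("A", None)

    def test_snp_above_ten_percent(self):
        base, snp = call_consensus_column([("A", 40)] * 17 + [("G", 40)] * 3)
        assert base == "A"
        assert snp is not None
        assert snp.alternate_base == "G"
        assert snp.alternate_fraction == pytest.approx(0.15)

    def test_minor_base_below_threshold_not_reported(self):
        base, snp = call_consensus_column([("A", 40)] * 19 + [("G", 40)])
        assert (base, snp[0] if snp else None) == ("A", None)

    def test_alphabetic_tie_break(self):
        base, snp = call_consensus_column([("C", 40)] * 2 + [("T", 40)] * 2)
        assert base == "C"
        assert snp.alternate_base == "T"
        assert snp.alternate_fraction == pytest.approx(0.5)

    def test_quality_breaks_count_tie(self):
        base, _ = call_consensus_column([("T", 40), ("T", 40), ("G", 30), ("G", 30)])
        assert base == "T"

    def test_pool_and_top_limits(self):
        # 45 observations: only the first 40 examined, top 20 by quality vote
        obs = [("A", 10)] * 20 + [("G", 40)] * 20 + [("T", 41)] * 5
        base, _ = call_consensus_column(obs, WalkParams())
        assert base == "G"

    def test_empty_column_raises(self):
        with pytest.raises(ValueError):
            call_consensus_column([])


class TestOverlapIndex:
    def test_empty_read_set(self):
        index = build_overlap_index([], 80)
        assert index.starting_with("A" * 80) == []

    def test_single_read_prefix_query(self, rng):
        read = make_read(random_dna(rng, 100))
        index = build_overlap_index([read], 80)
        hits = index.starting_with(read.sequence[:80])
        assert [h.sequence for h in hits] == [read.sequence]

    def test_matches_brute_force_scan(self, rng):
        reads = [make_read(random_dna(rng, 90), read_id=f"r{i}") for i in range(60)]
        k = 60
        index = build_overlap_index(reads, k)
        oriented = [r.sequence for r in reads] + [
            reverse_complement(r.sequence) for r in reads
        ]
        for probe in [reads[7].sequence[:k], reverse_complement(reads[3].sequence)[:k],
                      random_dna(rng, k)]:
            expected = sorted(s for s in oriented if s.startswith(probe))
            got = sorted(h.sequence for h in index.starting_with(probe))
            assert got == expected


class TestExtendContig:
    def test_clean_tiling_reconstructs_template(self, rng):
        template = make_template(rng, orf_codons=150, utr=100)
        reads = tile_reads(template, step=4)
        params = WalkParams(min_overlap=80)
        index = build_overlap_index(reads, 80)
        contig, snps, reason = extend_contig(template[:100], index, params)
        assert contig == template
        assert reason == "no_reads"
        assert snps == []

    def test_stops_at_coverage_gap(self, rng):
        template = random_dna(rng, 600)
        reads = [r for r in tile_reads(template, step=4)
                 if not 200 <= int(r.id[1:]) * 4 <= 250]  # 50-nt hole in starts
        index = build_overlap_index(reads, 80)
        contig, _, reason = extend_contig(template[:100], index,
                                          WalkParams(min_overlap=80))
        assert reason == "no_reads"
        assert len(contig) < len(template)

    def test_planted_variant_recorded_not_assembled(self, rng):
        template = random_dna(rng, 400)
        variant_pos = 250
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[template[variant_pos]]
        variant = template[:variant_pos] + alt + template[variant_pos + 1:]
        reads = tile_reads(template, step=2, prefix="maj")
        reads += tile_reads(variant, step=8, prefix="min")  # ~20% of coverage
        index = build_overlap_index(reads, 80)
        contig, snps, _ = extend_contig(template[:100], index,
                                        WalkParams(min_overlap=80))
        assert contig == template
        assert any(
            s.position == variant_pos and s.alternate_base == alt for s in snps
        )

    def test_repeat_detection_terminates(self):
        unit = "ACGTTGCAAT" * 10  # 100-nt repeat unit
        template = unit * 4
        reads = tile_reads(template, read_len=100, step=5)
        index = build_overlap_index(reads, 80)
        contig, _, reason = extend_contig(template[:100], index,
                                          WalkParams(min_overlap=80))
        assert reason in ("repeat", "max_walk_length")


class TestFindCompleteOrf:
    def test_minimal_orf(self):
        assert find_complete_orf("ATGAAATAG") == (0, 9, "+")

    def test_outermost_atg_wins(self):
        seq = "ATGCCCATGAAATAG"
        assert find_complete_orf(seq) == (0, 15, "+")

    def test_reverse_strand_orf(self):
        fwd = "ATGAAACCCTAG"
        seq = reverse_complement("GG" + fwd + "AA")
        start, end, strand = find_complete_orf(seq)
        assert strand == "-"
        assert reverse_complement(seq)[start:end] == fwd

    def test_no_orf_returns_none(self):
        assert find_complete_orf("ACCACCACCACC") is None

    def test_agrees_with_brute_force_enumeration(self, rng):
        stops = {"TAA", "TAG", "TGA"}

        def brute(seq):
            best = None
            for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                for start in range(len(s) - 5):
                    if s[start:start + 3] != "ATG":
                        continue
                    for end in range(start + 3, len(s) - 2, 3):
                        codon = s[end:end + 3]
                        if codon in stops:
                            span = (start, end + 3, strand)
                            if (best is None
                                    or span[1] - span[0] > best[1] - best[0]
                                    or (span[1] - span[0] == best[1] - best[0]
                                        and (strand, start) < (best[2], best[0]))):
                                # forward ('+') sorts before reverse ('-')
                                best = span
                            break
            return best

        for _ in range(40):
            seq = random_dna(rng, 120)
            assert find_complete_orf(seq) == brute(seq)


class TestAssembleTranscript:
    def test_clean_library_recovers_orf_and_invariants(self, rng):
        template = make_template(rng, orf_codons=140, utr=150)
        reads = tile_reads(template, step=3)
        params = WalkParams(min_overlap=80)
        seed = next(r for r in reads if int(r.id[1:]) * 3 > 400)
        result = assemble_transcript(seed, reads, params)
        assert isinstance(result, Transcript)
        true_orf = find_complete_orf(template)
        assert result.orf == template[true_orf[0]:true_orf[1]]
        assert (result.orf_end - result.orf_start) % 3 == 0
        assert result.orf[:3] == "ATG" and result.orf[-3:] in {"TAA", "TAG", "TGA"}
        assert len(result.translation) == (result.orf_end - result.orf_start) // 3 - 1

    def test_deterministic(self, rng):
        template = make_template(rng, orf_codons=120, utr=120)
        reads = tile_reads(template, step=3)
        seed = reads[len(reads) // 2]
        first = assemble_transcript(seed, reads, WalkParams(min_overlap=80))
        second = assemble_transcript(seed, reads, WalkParams(min_overlap=80))
        assert first == second

    def test_orientation_invariance(self, rng):
        template = make_template(rng, orf_codons=120, utr=120)
        reads = tile_reads(template, step=3)
        seed = reads[len(reads) // 2]
        flipped = [
            Read(id=r.id, sequence=reverse_complement(r.sequence),
                 qualities=r.qualities[::-1], mate=r.mate)
            for r in reads
        ]
        flipped_seed = next(r for r in flipped if r.id == seed.id)
        fwd = assemble_transcript(seed, reads, WalkParams(min_overlap=80))
        rev = assemble_transcript(flipped_seed, flipped, WalkParams(min_overlap=80))
        assert fwd.orf == rev.orf

    def test_seed_without_overlaps_fails_with_seed_contig(self, rng):
        library = tile_reads(make_template(rng, 100, 100), step=3)
        orphan = make_read(random_dna(rng, 100), read_id="orphan")
        result = assemble_transcript(orphan, library, WalkParams(min_overlap=80))
        assert isinstance(result, AssemblyFailure)
        assert result.partial_contig == orphan.sequence

    def test_short_seed_rejected(self, rng):
        with pytest.raises(ValueError):
            assemble_transcript(make_read(random_dna(rng, 50)), [],
                                WalkParams(min_overlap=80))

    def test_shared_motif_not_crossed_at_min_overlap_80(self, rng):
        motif = random_dna(rng, 70)
        t1 = make_template(rng, 100, 100)
        t2 = make_template(rng, 100, 100)
        # plant the motif in both UTE-free interiors, outside the ORFs
        a = t1[:40] + motif + t1[110:]
        b = t2[:500] + motif + t2[570:]
        reads = tile_reads(a, step=3, prefix="a") + tile_reads(b, step=3, prefix="b")
        params = WalkParams(min_overlap=80)
        seed = next(r for r in reads if r.id == "a40")
        result = assemble_transcript(seed, reads, params)
        contig = result.sequence if isinstance(result, Transcript) else \
            result.partial_contig
        # the walk must never splice b-only sequence onto the a contig
        b_only = b[300:380]
        assert b_only not in contig
        assert b_only not in reverse_complement(contig)
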