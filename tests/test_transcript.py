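"""Transcript structure validation and strand-aware coordinate mapping."""

import dataclasses

import pytest

from exonskip.errors import CoordinateError, NotExonicError, ReferenceMismatchError
from exonskip.simulate import SimulationConfig, simulate_transcript, write_fasta, write_gtf
from exonskip.transcript import (
    GenomicInterval,
    InMemorySource,
    TranscriptModel,
    exon_info,
    map_coordinate,
    read_bed12,
    read_gtf,
    transcript_summary,
    validate_transcript,
    variant_context,
)


class TestValidateTranscript:
    def test_consistent_fixture_is_clean(self, t1):
        assert validate_transcript(t1) == []

    def test_swapped_exons_flag_ordering(self, t1):
        swapped = dataclasses.replace(t1, exons=list(t1.exons)[::-1])
        violations = validate_transcript(swapped)
        assert len(violations) == 1
        assert "out of order" in violations[0]

    def test_cds_end_beyond_exons_flags_bounds(self, t1):
        bad = dataclasses.replace(t1, cds_end_t=181)
        violations = validate_transcript(bad)
        assert len(violations) == 1
        assert "exceeds total exonic length" in violations[0]

    def test_incomplete_cds_length_flagged_only_when_complete(self, t1):
        bad = dataclasses.replace(t1, cds_end_t=179)
        assert any("divisible by 3" in v for v in validate_transcript(bad))
        ok = dataclasses.replace(t1, cds_end_t=179, complete=False)
        assert validate_transcript(ok) == []


class TestMapCoordinate:
    @pytest.mark.parametrize(
        "cds_pos,genomic",
        [(1, 1001), (90, 1090), (91, 2001), (180, 2090)],
    )
    def test_plus_strand_mapping(self, t1, cds_pos, genomic):
        assert map_coordinate(t1, cds_pos, "cds_to_genomic") == genomic
        assert map_coordinate(t1, genomic, "genomic_to_cds") == cds_pos

    @pytest.mark.parametrize("cds_pos,genomic", [(1, 5090), (90, 5001)])
    def test_minus_strand_reverses(self, t2, cds_pos, genomic):
        assert map_coordinate(t2, cds_pos, "cds_to_genomic") == genomic
        assert map_coordinate(t2, genomic, "genomic_to_cds") == cds_pos

    def test_minus_strand_monotone_decreasing(self, t2):
        g = [map_coordinate(t2, c, "cds_to_genomic") for c in range(1, 91)]
        assert g == sorted(g, reverse=True)

    def test_out_of_cds_position_raises_with_bounds(self, t1):
        with pytest.raises(CoordinateError, match="T1.*1..180"):
            map_coordinate(t1, 181, "cds_to_genomic")

    def test_intronic_genomic_position_raises(self, t1):
        with pytest.raises(NotExonicError):
            map_coordinate(t1, 1500, "genomic_to_cds")

    def test_mirror_symmetry(self):
        """Reflecting all coordinates and flipping strand preserves the
        c. mapping of every CDS position."""
        t, _ = simulate_transcript(SimulationConfig(seed=11, n_exons=4, strand="+"))
        C = max(ex.end for ex in t.exons) + 17
        mirrored = TranscriptModel(
            transcript_id=t.transcript_id,
            gene=t.gene,
            chrom=t.chrom,
            strand="-",
            exons=[
                GenomicInterval(ex.chrom, C - ex.end, C - ex.start, "-")
                for ex in t.exons
            ],
            cds_start_t=t.cds_start_t,
            cds_end_t=t.cds_end_t,
        )
        assert validate_transcript(mirrored) == []
        for c in range(1, t.cds_length + 1):
            g = map_coordinate(t, c, "cds_to_genomic")
            gm = map_coordinate(mirrored, c, "cds_to_genomic")
            assert gm == C - g + 1

    @pytest.mark.parametrize("seed", range(12))
    def test_round_trip_identity_on_fuzzed_transcripts(self, seed):
        t, _ = simulate_transcript(SimulationConfig(seed=seed, n_exons=3 + seed % 3))
        for c in range(1, t.cds_length + 1):
            g = map_coordinate(t, c, "cds_to_genomic")
            assert map_coordinate(t, g, "genomic_to_cds") == c


class TestExonInfo:
    def test_in_frame_exon(self, t1):
        info = exon_info(t1, 1)
        assert info.cds_overlap_length == 90
        assert not info.out_of_frame
        assert info.start_phase == 0

    def test_out_of_frame_exon(self, toy3):
        info = exon_info(toy3, 2)
        assert info.cds_overlap_length == 4
        assert info.out_of_frame

    def test_fully_utr_exon_has_no_phase(self, t1):
        # restrict the CDS to exon 2 only: exon 1 becomes pure 5'UTR
        t = dataclasses.replace(t1, cds_start_t=91, cds_end_t=180)
        info = exon_info(t, 1)
        assert info.cds_overlap_length == 0
        assert info.start_phase is None
        assert not info.out_of_frame

    def test_overlap_sums_to_cds_length(self):
        for seed in range(8):
            t, _ = simulate_transcript(SimulationConfig(seed=seed, n_exons=5))
            total = sum(exon_info(t, i).cds_overlap_length for i in range(1, 6))
            assert total == t.cds_length

    def test_ordinal_out_of_range(self, t1):
        with pytest.raises(CoordinateError):
            exon_info(t1, 3)


class TestVariantContext:
    def test_position_arithmetic_exon1(self, t1):
        ctx = variant_context(t1, 5, "A", "G")
        assert ctx.exon_ordinal == 1
        assert ctx.dist_to_acceptor == 4
        assert ctx.dist_to_donor == 85
        assert ctx.genomic_pos == 1005

    def test_first_base_of_exon2(self, t1):
        ctx = variant_context(t1, 91, "A", "G")
        assert ctx.exon_ordinal == 2
        assert ctx.dist_to_acceptor == 0

    def test_distances_sum_to_exon_length_minus_one(self, t1):
        ctx = variant_context(t1, 130, "A", "G")
        assert ctx.dist_to_acceptor + ctx.dist_to_donor == 90 - 1

    def test_ref_mismatch_reports_expected_base(self, toy3):
        with pytest.raises(ReferenceMismatchError, match="expected reference base G"):
            variant_context(toy3, 4, "C", "T")  # c.4 is the G of GAA

    def test_ref_checked_against_sequence(self, toy3):
        ctx = variant_context(toy3, 9, "A", "G")  # c.9 in exon 2 (AAAA)
        assert ctx.exon_ordinal == 2
        assert ctx.ref_allele == "A"

    def test_inclusive_distances_in_dict(self, t1):
        d = variant_context(t1, 5, "A", "G").to_dict()
        assert d["dist_to_acceptor_inclusive"] == d["dist_to_acceptor"] + 1
        assert d["dist_to_donor_inclusive"] == d["dist_to_donor"] + 1


class TestReaders:
    def test_gtf_round_trip_preserves_structure(self, tmp_path):
        cfg = SimulationConfig(seed=21, n_exons=4, strand="-")
        t, genome = simulate_transcript(cfg)
        fa, gtf = tmp_path / "g.fa", tmp_path / "t.gtf"
        write_fasta(genome, str(fa))
        write_gtf(t, str(gtf))
        from exonskip.transcript import FastaSource

        t2 = read_gtf(str(gtf), t.transcript_id, genome=FastaSource(str(fa)))
        assert validate_transcript(t2) == []
        assert [(e.start, e.end) for e in t2.exons] == [
            (e.start, e.end) for e in t.exons
        ]
        assert (t2.cds_start_t, t2.cds_end_t) == (t.cds_start_t, t.cds_end_t)
        assert t2.cds_sequence() == t.cds_sequence()

    def test_bed12_reader_minus_strand(self, tmp_path):
        # two blocks on the minus strand; thick region = CDS incl. stop
        line = "\t".join(
            [
                "chrB", "100", "400", "TX", "0", "-", "130", "370",
                "0", "2", "100,100,", "0,200,",
            ]
        )
        bed = tmp_path / "t.bed"
        bed.write_text(line + "\n")
        t = read_bed12(str(bed), "TX")
        assert t.strand == "-"
        assert validate_transcript(t) == []
        # exons in transcript order: genomic starts decrease
        assert t.exons[0].start > t.exons[1].start
        assert t.cds_length == (200 - 130) + (370 - 300)

    def test_summary_uses_one_based_inclusive(self, t1):
        s = transcript_summary(t1)
        assert s["exons"][0]["start"] == 1001
        assert s["exons"][0]["end"] == 1090
        assert s["n_exons"] == 2
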