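"""Skip-consequence annotation: translation, HGVS diffing, NMD rule."""

import dataclasses

import pytest

from exonskip.consequence import (
    SkipEvent,
    annotate_consequence,
    apply_skip,
    hgvs_from_proteins,
    translate,
)
from exonskip.errors import (
    AlphabetError,
    NoCodingEffectError,
    UnsupportedConsequenceError,
)
from exonskip.simulate import SimulationConfig, simulate_transcript
from exonskip.transcript import GenomicInterval, InMemorySource, TranscriptModel

# independent mini codon table for oracle translation (subset is enough to
# cross-check a few fixed strings without touching the implementation path)
_ORACLE_CODONS = {
    "ATG": "M", "GAA": "E", "CGT": "R", "TGA": "*", "AAA": "K",
    "ACG": "T", "TTG": "L", "ATA": "I", "GCT": "A", "TAA": "*",
}


def _oracle_translate(cds):
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = _ORACLE_CODONS[cds[i : i + 3]]
        out.append(aa)
        if aa == "*":
            break
    return "".join(out)


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,expected",
        [
            ("ATGGAACGTTGA", "MER*"),
            ("ATG", "M"),
            ("ATGGAAAAAACGTTGATAGCTAAATAA", "MEKTLIAK*"),
            ("ATGGAACG", "ME"),  # trailing partial codon ignored
        ],
    )
    def test_standard_code_stops_at_first_stop(self, cds, expected):
        assert translate(cds) == expected
        if set(cds[i : i + 3] for i in range(0, len(cds) - 2, 3)) <= set(
            _ORACLE_CODONS
        ):
            assert translate(cds) == _oracle_translate(cds)

    def test_non_acgt_raises(self):
        with pytest.raises(AlphabetError):
            translate("ATGNNN")

    def test_too_short_raises(self):
        with pytest.raises(AlphabetError):
            translate("AT")


class TestApplySkip:
    def test_string_excision(self, toy3):
        mutant, junctions = apply_skip(toy3, SkipEvent("TOY3", 2))
        assert mutant == "ATGGAACGTTGATAGCTAAATAA"
        assert junctions == [6]  # retained junction after exon 1 (6 nt)

    def test_in_frame_skip_shortens_by_exon_length(self):
        t, _ = simulate_transcript(SimulationConfig(seed=7, n_exons=4, strand="+"))
        from exonskip.transcript import exon_info

        # find an internal in-frame coding exon, if the draw provides one
        for ordinal in (2, 3):
            info = exon_info(t, ordinal)
            if info.cds_overlap_length and not info.out_of_frame:
                mutant, _ = apply_skip(t, SkipEvent(t.transcript_id, ordinal))
                assert len(mutant) == t.cds_length - info.cds_overlap_length
                return
        pytest.skip("no in-frame internal exon at this seed")

    def test_utr_only_exon_has_no_coding_effect(self, t1):
        t = dataclasses.replace(t1, cds_start_t=91, cds_end_t=180)
        with pytest.raises(NoCodingEffectError):
            apply_skip(t, SkipEvent("T1", 1))

    def test_start_codon_exon_unsupported(self, toy3):
        with pytest.raises(UnsupportedConsequenceError):
            apply_skip(toy3, SkipEvent("TOY3", 1))


def _make_transcript(exon_seqs, strand="+", cds_start=1, cds_end=None):
    """Single-chromosome transcript from explicit exon sequences."""
    spacer = "G" * 5
    genome_plus = spacer + spacer.join(exon_seqs) + spacer
    coords = []
    cursor = len(spacer)
    for s in exon_seqs:
        coords.append((cursor, cursor + len(s)))
        cursor += len(s) + len(spacer)
    total = sum(len(s) for s in exon_seqs)
    if cds_end is None:
        cds_end = total
    if strand == "-":
        from exonskip.transcript import reverse_complement

        G = len(genome_plus)
        genome = reverse_complement(genome_plus)
        exons = [GenomicInterval("chrX", G - e, G - s, "-") for s, e in coords]
    else:
        genome = genome_plus
        exons = [GenomicInterval("chrX", s, e, "+") for s, e in coords]
    return TranscriptModel(
        transcript_id="TX",
        gene="TX",
        chrom="chrX",
        strand=strand,
        exons=exons,
        cds_start_t=cds_start,
        cds_end_t=cds_end,
        sequence_source=InMemorySource({"chrX": genome}),
        complete=(cds_end - cds_start + 1) % 3 == 0,
    )


class TestAnnotateConsequence:
    def test_out_of_frame_toy_matches_hand_translation(self, toy3):
        rep = annotate_consequence(toy3, SkipEvent("TOY3", 2))
        assert rep.frameshift
        assert rep.mutant_protein == "MER*"
        assert translate(toy3.cds_sequence()).startswith("MEK")
        assert rep.hgvs_p == "p.Lys3ArgfsTer2"
        assert rep.stop_codon == "TGA"
        # stop first base: mutant c.10 -> original c.14 (4 nt exon excised)
        assert rep.new_stop_cds_pos == 10
        assert rep.new_stop_cds_pos_original == 14

    def test_in_frame_skip_is_clean_deletion(self):
        # exon 2 encodes residues 3-4 exactly (6 nt, codon-aligned)
        t = _make_transcript(["ATGGAA", "AAACCC", "CGTTGA"])
        rep = annotate_consequence(t, SkipEvent("TX", 2))
        assert not rep.frameshift
        assert rep.hgvs_p == "p.Lys3_Pro4del"
        assert rep.mutant_protein == "MER*"
        assert not rep.nmd_predicted  # stop in the last exon

    def test_in_frame_skip_with_changed_fusion_residue_is_delins(self):
        # exon 2 is 9 nt but not codon-aligned: the junction fuses exon 1's
        # trailing AA with exon 3's leading G into AAG (Lys), replacing the
        # original AAC (Asn), so the deletion carries a delins
        t = _make_transcript(["ATGGAAAA", "CCCGGGACC", "GGTTTGA"])
        assert translate(t.cds_sequence()) == "MENPGPV*"
        rep = annotate_consequence(t, SkipEvent("TX", 2))
        assert not rep.frameshift
        assert rep.mutant_protein == "MEKV*"
        assert rep.hgvs_p == "p.Asn3_Pro6delinsLys"
        mutant, _ = apply_skip(t, SkipEvent("TX", 2))
        assert rep.mutant_protein == translate(mutant)

    def test_minus_strand_stop_reported_descending(self):
        t = _make_transcript(["ATGGAA", "AAAA", "CGTTGATAGCTAAATAA"], strand="-")
        rep = annotate_consequence(t, SkipEvent("TX", 2))
        assert rep.frameshift
        chrom, span = rep.new_stop_genomic.split(":")
        g_first, g_last = (int(x) for x in span.split("-"))
        assert g_first > g_last  # reading order descends on the minus strand
        assert g_first - g_last == 2

    def test_no_stop_reported_as_extension_not_error(self):
        # skipping exon 2 (4 nt) shifts the frame; downstream has no
        # in-frame stop in the shifted frame and translation runs off
        t = _make_transcript(["ATGGAA", "AAAA", "CACCACCACCAC"])
        rep = annotate_consequence(t, SkipEvent("TX", 2))
        assert rep.new_stop_cds_pos is None
        assert rep.new_stop_genomic is None
        assert rep.hgvs_p.endswith("fsTer?")

    def test_nmd_requires_50nt_to_last_junction(self):
        # stop lands far upstream of the final junction -> NMD predicted
        e3 = "CGTTGA" + "TGC" * 30  # stop early in exon 3, exon 3 is long
        t = _make_transcript(["ATGGAA", "AAAA", e3 + "TTC", "GGGTAA"])
        rep = annotate_consequence(t, SkipEvent("TX", 2))
        assert rep.frameshift
        last_junction = 6 + 4 - 4 + len(e3 + "TTC")  # retained exons 1+3
        stop_end = rep.new_stop_cds_pos + 2
        assert (last_junction - stop_end) >= 50
        assert rep.nmd_predicted

    def test_nmd_monotone_in_stop_position(self):
        """Moving the premature stop 3'-ward (with the retained junctions
        fixed) never switches the NMD prediction from off to on."""
        preds = []
        for lead_codons in range(0, 31, 3):
            # after skipping the 4 nt exon 2 the mutant reads
            # ATG GAA (ACC)*lead TGA ..., so the stop sits lead_codons
            # codons into exon 3 while the junctions stay fixed
            e3 = "ACC" * lead_codons + "TGA" + "ACC" * (40 - lead_codons)
            t = _make_transcript(["ATGGAA", "AAAA", e3, "GGGTAA"])
            rep = annotate_consequence(t, SkipEvent("TX", 2))
            assert rep.frameshift
            preds.append(rep.nmd_predicted)
        seen_false = False
        for p in preds:
            if not p:
                seen_false = True
            # once off while the stop moves 3'-ward, it must stay off
            assert not (seen_false and p)

    def test_new_stop_maps_into_a_retained_exon(self):
        from exonskip.transcript import exon_of_cds_position

        for seed in range(15):
            t, _ = simulate_transcript(
                SimulationConfig(seed=seed, n_exons=4, force_out_of_frame_exon=2)
            )
            rep = annotate_consequence(t, SkipEvent(t.transcript_id, 2))
            if rep.new_stop_cds_pos_original is None:
                continue
            ordinal = exon_of_cds_position(t, rep.new_stop_cds_pos_original)
            assert ordinal != 2


class TestHgvsFromProteins:
    @pytest.mark.parametrize(
        "orig,mut,fs,expected",
        [
            ("MEKTLIAK*", "MER*", True, "p.Lys3ArgfsTer2"),
            ("MEKTLIAK*", "MEK*", True, "p.Thr4Ter"),
            ("MEKTL*", "MEKL*", False, "p.Thr4del"),
            ("MEKTLIA*", "MEA*", False, "p.Lys3_Ile6del"),
            ("MEKTL*", "MENL*", False, "p.Lys3_Thr4delinsAsn"),
            ("MEKTL*", "MEQTL*", False, "p.Lys3Gln"),
            ("MEKTL*", "MEKTL*", False, "p.(=)"),
            ("MEKTLIAK*", "MERGGG", True, "p.Lys3ArgfsTer?"),
        ],
    )
    def test_notation_from_protein_diff(self, orig, mut, fs, expected):
        assert hgvs_from_proteins(orig, mut, fs) == expected
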