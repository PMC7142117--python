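"""Shared fixtures: small hand-checkable transcripts."""

import pytest

from exonskip.transcript import GenomicInterval, InMemorySource, TranscriptModel


@pytest.fixture
def t1():
    """Two-exon plus-strand toy: exons g1001..1090 and g2001..2090
    (1-based inclusive), CDS = whole transcript (180 nt)."""
    exons = [
        GenomicInterval("chrT", 1000, 1090, "+"),
        GenomicInterval("chrT", 2000, 2090, "+"),
    ]
    return TranscriptModel(
        transcript_id="T1",
        gene="TOY1",
        chrom="chrT",
        strand="+",
        exons=exons,
        cds_start_t=1,
        cds_end_t=180,
    )


@pytest.fixture
def t2():
    """Minus-strand single-exon toy: exon g5001..5090, CDS = whole (90 nt)."""
    exons = [GenomicInterval("chrT", 5000, 5090, "-")]
    return TranscriptModel(
        transcript_id="T2",
        gene="TOY2",
        chrom="chrT",
        strand="-",
        exons=exons,
        cds_start_t=1,
        cds_end_t=90,
    )


TOY3_EXONS = ("ATGGAA", "AAAA", "CGTTGATAGCTAAATAA")


@pytest.fixture
def toy3():
    """Three-exon plus-strand transcript with sequence access.

    Coding exons ATGGAA / AAAA / CGTTGATAGCTAAATAA; CDS = whole
    transcript (27 nt); exon 2 (4 nt) is out of frame.
    """
    e1, e2, e3 = TOY3_EXONS
    genome = "GG" + e1 + "GGGG" + e2 + "GGGG" + e3 + "GG"
    exons = [
        GenomicInterval("chr3", 2, 8, "+"),
        GenomicInterval("chr3", 12, 16, "+"),
        GenomicInterval("chr3", 20, 37, "+"),
    ]
    return TranscriptModel(
        transcript_id="TOY3",
        gene="TOY3",
        chrom="chr3",
        strand="+",
        exons=exons,
        cds_start_t=1,
        cds_end_t=27,
        sequence_source=InMemorySource({"chr3": genome}),
    )
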