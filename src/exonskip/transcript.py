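"""Protein-coding transcript models and strand-aware coordinate mapping.

The central object is :class:`TranscriptModel`: an ordered list of exons in
transcript (5'->3') order together with the transcript coordinates of the
coding sequence.  All internal coordinates are 0-based half-open; every
value that crosses the API boundary in HGVS- or GTF-facing form (c.
positions, genomic positions in reports, GTF/BED readers and the JSON
writer) is 1-based inclusive.

CDS ("c.") positions count from 1 at the A of the start codon and include
the stop codon.  Genomic positions on the minus strand decrease as c.
positions increase; reference/alternate alleles are always expressed on the
transcript (sense) strand, and genomic I/O reverse-complements on the minus
strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence

from .errors import CoordinateError, NotExonicError, ReferenceMismatchError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceSource(Protocol):
    """Random-access genomic sequence: plus-strand bases, 0-based half-open."""

    def fetch(self, chrom: str, start: int, end: int) -> str: ...


class InMemorySource:
    """Sequence accessor over a plain ``{chrom: sequence}`` mapping."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = dict(sequences)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq):
            raise CoordinateError(
                f"fetch [{start}, {end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end].upper()


class FastaSource:
    """pyfaidx-backed accessor with per-chromosome random access."""

    def __init__(self, path: str):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(path)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fasta[chrom][start:end]).upper()


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExonInfo:
    """Frame bookkeeping for one exon.

    ``start_phase`` is the reading-frame phase at the exon's first coding
    base (0 means a codon starts there); ``None`` for fully non-coding
    exons.  ``out_of_frame`` is the property that makes skipping the exon a
    frameshift: its CDS overlap is not a multiple of three.
    """

    ordinal: int
    length: int
    cds_overlap_length: int
    start_phase: Optional[int]
    out_of_frame: bool


@dataclass(frozen=True)
class VariantContext:
    """A single-nucleotide variant located on its transcript.

    Distances are in exonic bases with the variant base itself excluded:
    the first base of an exon has ``dist_to_acceptor == 0`` and the last
    base has ``dist_to_donor == 0``.  Some sources count inclusively
    (variant base = 1); that convention equals these distances plus one and
    both are emitted by :meth:`to_dict`.
    """

    cds_pos: int
    ref_allele: str
    alt_allele: str
    exon_ordinal: int
    dist_to_acceptor: int
    dist_to_donor: int
    genomic_pos: int
    chrom: str
    strand: str

    def to_dict(self) -> dict:
        return {
            "cds_pos": self.cds_pos,
            "ref_allele": self.ref_allele,
            "alt_allele": self.alt_allele,
            "exon_ordinal": self.exon_ordinal,
            "dist_to_acceptor": self.dist_to_acceptor,
            "dist_to_donor": self.dist_to_donor,
            "dist_to_acceptor_inclusive": self.dist_to_acceptor + 1,
            "dist_to_donor_inclusive": self.dist_to_donor + 1,
            "genomic_pos": self.genomic_pos,
            "chrom": self.chrom,
            "strand": self.strand,
        }


@dataclass
class TranscriptModel:
    """Exon structure plus CDS bounds for one protein-coding transcript.

    ``exons`` are listed in transcript order: genomic starts strictly
    increase along the list on the plus strand and strictly decrease on the
    minus strand.  ``cds_start_t``/``cds_end_t`` are 1-based inclusive
    transcript coordinates of the first and last CDS base (stop codon
    included).  ``sequence_source`` is optional; pure coordinate operations
    never touch it.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: Sequence[GenomicInterval]
    cds_start_t: int
    cds_end_t: int
    sequence_source: Optional[SequenceSource] = None
    complete: bool = True
    _cum: Sequence[int] = field(init=False, repr=False, default=())

    def __post_init__(self) -> None:
        cum = [0]
        for ex in self.exons:
            cum.append(cum[-1] + ex.length)
        self._cum = tuple(cum)

    # -- basic geometry -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def total_exonic_length(self) -> int:
        return self._cum[-1]

    @property
    def cds_length(self) -> int:
        return self.cds_end_t - self.cds_start_t + 1

    def exon_transcript_span(self, ordinal: int) -> tuple[int, int]:
        """1-based inclusive transcript coordinates covered by an exon."""
        self._check_ordinal(ordinal)
        return self._cum[ordinal - 1] + 1, self._cum[ordinal]

    def _check_ordinal(self, ordinal: int) -> None:
        if not 1 <= ordinal <= self.n_exons:
            raise CoordinateError(
                f"{self.transcript_id}: exon ordinal {ordinal} outside 1..{self.n_exons}"
            )

    # -- sequence access ------------------------------------------------

    def exon_sequence(self, ordinal: int) -> str:
        """Transcript-strand sequence of one exon."""
        self._check_ordinal(ordinal)
        if self.sequence_source is None:
            raise ValueError(f"{self.transcript_id} has no sequence source")
        ex = self.exons[ordinal - 1]
        seq = self.sequence_source.fetch(self.chrom, ex.start, ex.end)
        return reverse_complement(seq) if self.strand == "-" else seq

    def transcript_sequence(self) -> str:
        return "".join(self.exon_sequence(i) for i in range(1, self.n_exons + 1))

    def cds_sequence(self) -> str:
        return self.transcript_sequence()[self.cds_start_t - 1 : self.cds_end_t]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def validate_transcript(t: TranscriptModel) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    Validation never raises: an empty list means the transcript is
    internally consistent.
    """
    violations: list[str] = []
    if t.strand not in {"+", "-"}:
        violations.append(f"strand must be '+' or '-', got {t.strand!r}")
    if not t.exons:
        violations.append("transcript has no exons")
        return violations
    for i, (a, b) in enumerate(zip(t.exons, t.exons[1:]), start=1):
        if t.strand == "+" and b.start < a.end:
            violations.append(
                f"exons {i} and {i + 1} overlap or are out of order for + strand"
            )
        if t.strand == "-" and b.end > a.start:
            violations.append(
                f"exons {i} and {i + 1} overlap or are out of order for - strand"
            )
    for i, ex in enumerate(t.exons, start=1):
        if ex.chrom != t.chrom:
            violations.append(f"exon {i} chrom {ex.chrom} != transcript chrom {t.chrom}")
        if ex.strand != t.strand:
            violations.append(f"exon {i} strand {ex.strand} != transcript strand {t.strand}")
    if t.cds_start_t < 1:
        violations.append(f"cds_start_t must be >= 1, got {t.cds_start_t}")
    if t.cds_end_t < t.cds_start_t:
        violations.append(f"cds_end_t ({t.cds_end_t}) < cds_start_t ({t.cds_start_t})")
    if t.cds_end_t > t.total_exonic_length:
        violations.append(
            f"cds_end_t ({t.cds_end_t}) exceeds total exonic length "
            f"({t.total_exonic_length})"
        )
    elif t.complete and t.cds_length % 3 != 0:
        violations.append(
            f"CDS length {t.cds_length} not divisible by 3 for a complete transcript"
        )
    return violations


def map_coordinate(t: TranscriptModel, pos: int, direction: str) -> int:
    """Convert between 1-based CDS (c.) and 1-based genomic coordinates.

    ``direction`` is ``"cds_to_genomic"`` or ``"genomic_to_cds"``.  The
    mapping is a strand-aware bijection between CDS positions and the
    genomic bases they occupy, so the round trip is the identity.
    """
    if direction == "cds_to_genomic":
        if not 1 <= pos <= t.cds_length:
            raise CoordinateError(
                f"{t.transcript_id}: c.{pos} outside CDS 1..{t.cds_length}"
            )
        tpos = t.cds_start_t + pos - 1
        for i, ex in enumerate(t.exons):
            lo, hi = t._cum[i], t._cum[i + 1]
            if lo < tpos <= hi:
                offset = tpos - lo  # 1-based offset into the exon
                if t.strand == "+":
                    return ex.start + offset
                return ex.end - offset + 1
        raise CoordinateError(f"{t.transcript_id}: c.{pos} not covered by exons")

    if direction == "genomic_to_cds":
        g0 = pos - 1
        for i, ex in enumerate(t.exons):
            if ex.start <= g0 < ex.end:
                offset = (g0 - ex.start + 1) if t.strand == "+" else (ex.end - g0)
                tpos = t._cum[i] + offset
                c = tpos - t.cds_start_t + 1
                if not 1 <= c <= t.cds_length:
                    raise CoordinateError(
                        f"{t.transcript_id}: g.{pos} is exonic but outside the CDS "
                        f"(c. range 1..{t.cds_length})"
                    )
                return c
        raise NotExonicError(
            f"{t.transcript_id}: g.{pos} does not fall in any exon"
        )

    raise ValueError(f"unknown direction {direction!r}")


def exon_info(t: TranscriptModel, ordinal: int) -> ExonInfo:
    """Length, CDS overlap and frame phase for one exon."""
    t._check_ordinal(ordinal)
    span_lo, span_hi = t.exon_transcript_span(ordinal)
    ov_lo = max(span_lo, t.cds_start_t)
    ov_hi = min(span_hi, t.cds_end_t)
    overlap = max(0, ov_hi - ov_lo + 1)
    phase = (ov_lo - t.cds_start_t) % 3 if overlap > 0 else None
    return ExonInfo(
        ordinal=ordinal,
        length=span_hi - span_lo + 1,
        cds_overlap_length=overlap,
        start_phase=phase,
        out_of_frame=overlap % 3 != 0,
    )


def exon_of_cds_position(t: TranscriptModel, cds_pos: int) -> int:
    """1-based ordinal of the exon containing a CDS position."""
    if not 1 <= cds_pos <= t.cds_length:
        raise CoordinateError(
            f"{t.transcript_id}: c.{cds_pos} outside CDS 1..{t.cds_length}"
        )
    tpos = t.cds_start_t + cds_pos - 1
    for i in range(t.n_exons):
        if t._cum[i] < tpos <= t._cum[i + 1]:
            return i + 1
    raise CoordinateError(f"{t.transcript_id}: c.{cds_pos} not covered by exons")


def variant_context(
    t: TranscriptModel, cds_pos: int, ref: str, alt: str
) -> VariantContext:
    """Locate a SNV on its exon and report splice-site distances.

    Alleles are transcript-strand bases.  When the transcript has sequence
    access the stated reference allele is checked against the transcript
    and a mismatch is an error, not a warning.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt alleles must differ")
    ordinal = exon_of_cds_position(t, cds_pos)
    span_lo, span_hi = t.exon_transcript_span(ordinal)
    tpos = t.cds_start_t + cds_pos - 1
    if t.sequence_source is not None:
        found = t.transcript_sequence()[tpos - 1]
        if found != ref:
            raise ReferenceMismatchError(
                f"{t.transcript_id} c.{cds_pos}: expected reference base {found}, "
                f"got {ref}"
            )
    return VariantContext(
        cds_pos=cds_pos,
        ref_allele=ref,
        alt_allele=alt,
        exon_ordinal=ordinal,
        dist_to_acceptor=tpos - span_lo,
        dist_to_donor=span_hi - tpos,
        genomic_pos=map_coordinate(t, cds_pos, "cds_to_genomic"),
        chrom=t.chrom,
        strand=t.strand,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def transcript_summary(t: TranscriptModel) -> dict:
    """JSON-ready summary: ids plus a 1-based inclusive exon table."""
    rows = []
    for i in range(1, t.n_exons + 1):
        ex = t.exons[i - 1]
        info = exon_info(t, i)
        rows.append(
            {
                "ordinal": i,
                "start": ex.start + 1,
                "end": ex.end,
                "length": info.length,
                "cds_overlap_length": info.cds_overlap_length,
                "start_phase": info.start_phase,
                "out_of_frame": info.out_of_frame,
            }
        )
    return {
        "transcript_id": t.transcript_id,
        "gene": t.gene,
        "chrom": t.chrom,
        "strand": t.strand,
        "n_exons": t.n_exons,
        "cds_start_t": t.cds_start_t,
        "cds_end_t": t.cds_end_t,
        "exons": rows,
    }


def write_transcript_summary(t: TranscriptModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(transcript_summary(t), fh, indent=2)
        fh.write("\n")


def read_gtf(
    path: str,
    transcript_id: str,
    genome: Optional[SequenceSource] = None,
    gene: str = "",
) -> TranscriptModel:
    """Build a TranscriptModel from GTF exon/CDS features.

    Exon and CDS features carrying the requested ``transcript_id``
    attribute are used; ``stop_codon`` features, when present, are folded
    into the CDS so that c. coordinates include the stop codon.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exon_ivs, cds_spans, gene_name, strand, chrom = [], [], gene, None, None
    for feat in db.all_features():
        attrs = dict(feat.attributes)
        tids = attrs.get("transcript_id", [])
        if transcript_id not in tids:
            continue
        strand, chrom = feat.strand, feat.seqid
        if not gene_name:
            gene_name = (attrs.get("gene_id") or attrs.get("gene_name") or [""])[0]
        if feat.featuretype == "exon":
            exon_ivs.append((feat.start - 1, feat.end))
        elif feat.featuretype in {"CDS", "stop_codon"}:
            cds_spans.append((feat.start - 1, feat.end))
    if not exon_ivs:
        raise ValueError(f"transcript {transcript_id!r} not found in {path}")
    if strand not in {"+", "-"}:
        raise ValueError(f"transcript {transcript_id!r} has no usable strand")
    exon_ivs.sort(reverse=(strand == "-"))
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_ivs]
    t = TranscriptModel(
        transcript_id=transcript_id,
        gene=gene_name,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start_t=1,
        cds_end_t=3,  # placeholder until CDS bounds resolved below
        sequence_source=genome,
        complete=False,
    )
    if not cds_spans:
        raise ValueError(f"transcript {transcript_id!r} has no CDS features")
    cds_len = sum(e - s for s, e in cds_spans)
    # first CDS base in transcript order: highest genomic coord on -, lowest on +
    if strand == "+":
        first_cds_g = min(s for s, _ in cds_spans) + 1
    else:
        first_cds_g = max(e for _, e in cds_spans)
    cds_start_t = _genomic_to_transcript(t, first_cds_g)
    return TranscriptModel(
        transcript_id=transcript_id,
        gene=gene_name,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start_t=cds_start_t,
        cds_end_t=cds_start_t + cds_len - 1,
        sequence_source=genome,
        complete=(cds_len % 3 == 0),
    )


def _genomic_to_transcript(t: TranscriptModel, gpos: int) -> int:
    """1-based genomic -> 1-based transcript coordinate (exonic only)."""
    g0 = gpos - 1
    for i, ex in enumerate(t.exons):
        if ex.start <= g0 < ex.end:
            offset = (g0 - ex.start + 1) if t.strand == "+" else (ex.end - g0)
            return t._cum[i] + offset
    raise NotExonicError(f"{t.transcript_id}: g.{gpos} not exonic")


def read_bed12(
    path: str,
    transcript_id: Optional[str] = None,
    genome: Optional[SequenceSource] = None,
) -> TranscriptModel:
    """Read one transcript from a BED12 line (thickStart/thickEnd = CDS).

    BED thick bounds conventionally include the stop codon, matching this
    package's stop-inclusive c. coordinates.
    """
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 columns, got {len(f)}")
            name = f[3]
            if transcript_id is not None and name != transcript_id:
                continue
            chrom, chrom_start = f[0], int(f[1])
            thick_start, thick_end, strand = int(f[6]), int(f[7]), f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            ivs = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            if strand == "-":
                ivs = ivs[::-1]
            exons = [GenomicInterval(chrom, s, e, strand) for s, e in ivs]
            t = TranscriptModel(
                transcript_id=name,
                gene=name,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start_t=1,
                cds_end_t=3,
                sequence_source=genome,
                complete=False,
            )
            first_cds_g = thick_start + 1 if strand == "+" else thick_end
            cds_len = sum(
                max(0, min(e, thick_end) - max(s, thick_start)) for s, e in ivs
            )
            cds_start_t = _genomic_to_transcript(t, first_cds_g)
            return TranscriptModel(
                transcript_id=name,
                gene=name,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start_t=cds_start_t,
                cds_end_t=cds_start_t + cds_len - 1,
                sequence_source=genome,
                complete=(cds_len % 3 == 0),
            )
    raise ValueError(f"transcript {transcript_id!r} not found in {path}")
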