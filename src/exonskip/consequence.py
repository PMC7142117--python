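"""Molecular consequence of skipping one exon.

Skipping an internal exon whose CDS overlap is not a multiple of three
shifts the downstream reading frame; translation of the mutant CDS then
usually runs into a premature termination codon (PTC).  This module excises
the skipped exon's CDS bases, translates the mutant CDS, expresses the
outcome in HGVS p. notation, and applies the classic exon-junction rule for
nonsense-mediated decay (NMD): a stop codon lying at least ``NMD_RULE_NT``
(default 50) nucleotides upstream of the last retained exon-exon junction
is predicted to trigger NMD.

The protein-level annotation is produced by diffing the translated
reference and mutant proteins; translation is the single source of truth,
so junction-spanning codons after an in-frame skip are handled naturally
(a changed fusion residue yields delins notation).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .errors import (
    AlphabetError,
    NoCodingEffectError,
    UnsupportedConsequenceError,
)
from .transcript import TranscriptModel, exon_info, map_coordinate

NMD_RULE_NT = 50

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SkipEvent:
    """A single-exon skip on a named transcript."""

    transcript_id: str
    skipped_exon_ordinal: int


@dataclass(frozen=True)
class ConsequenceReport:
    """Outcome of one exon skip.

    ``new_stop_cds_pos`` is the 1-based position of the first base of the
    first in-frame stop in the *mutant* CDS; ``new_stop_cds_pos_original``
    re-expresses that base in the original transcript's c. numbering (bases
    downstream of the skipped exon shift by its CDS overlap length).
    ``new_stop_genomic`` gives the three stop-codon bases in reading order,
    which on the minus strand is a descending genomic range.
    """

    transcript_id: str
    skipped_exon_ordinal: int
    frameshift: bool
    mutant_cds_length: int
    new_stop_cds_pos: Optional[int]
    new_stop_cds_pos_original: Optional[int]
    new_stop_genomic: Optional[str]
    stop_codon: Optional[str]
    hgvs_p: str
    nmd_predicted: bool
    mutant_protein: str

    def to_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "skipped_exon_ordinal": self.skipped_exon_ordinal,
            "frameshift": self.frameshift,
            "mutant_cds_length": self.mutant_cds_length,
            "new_stop_cds_pos": self.new_stop_cds_pos,
            "new_stop_cds_pos_original": self.new_stop_cds_pos_original,
            "new_stop_genomic": self.new_stop_genomic,
            "stop_codon": self.stop_codon,
            "hgvs_p": self.hgvs_p,
            "nmd_predicted": self.nmd_predicted,
            "mutant_protein": self.mutant_protein,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def translate(cds: str) -> str:
    """Translate a CDS with the standard code, stopping at the first stop.

    Returns residues up to and including a terminal ``*`` when a stop codon
    is reached; otherwise all complete codons.  A trailing partial codon is
    ignored.  Non-ACGT characters are an error.
    """
    cds = cds.upper()
    if re.search(r"[^ACGT]", cds):
        bad = re.search(r"[^ACGT]", cds).group(0)
        raise AlphabetError(f"non-ACGT character {bad!r} in CDS")
    if len(cds) < 3:
        raise AlphabetError(f"CDS length {len(cds)} < 3")
    usable = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(usable).translate(table=1))
    stop = prot.find("*")
    return prot[: stop + 1] if stop >= 0 else prot


def apply_skip(t: TranscriptModel, e: SkipEvent) -> tuple[str, list[int]]:
    """Excise the skipped exon's CDS bases; return mutant CDS + junctions.

    The second element lists, for every retained exon-exon junction, the
    position (in mutant-CDS coordinates, 1-based) of the last base of the
    upstream exon.  Junctions upstream of the CDS start come out <= 0 and
    are harmless for NMD, which only looks at the last junction.
    """
    info = exon_info(t, e.skipped_exon_ordinal)
    if info.cds_overlap_length == 0:
        raise NoCodingEffectError(
            f"exon {e.skipped_exon_ordinal} of {t.transcript_id} is fully "
            "non-coding; skipping it has no coding effect"
        )
    span_lo, span_hi = t.exon_transcript_span(e.skipped_exon_ordinal)
    # any overlap with the three start-codon bases makes the skip a start-loss
    if span_lo <= t.cds_start_t + 2 and span_hi >= t.cds_start_t:
        raise UnsupportedConsequenceError(
            f"exon {e.skipped_exon_ordinal} of {t.transcript_id} contains the "
            "start codon; skip consequence would be start-loss (unsupported)"
        )
    cds = t.cds_sequence()
    # CDS coordinates (1-based) of the skipped exon's CDS overlap
    skip_lo = max(span_lo, t.cds_start_t) - t.cds_start_t + 1
    skip_hi = min(span_hi, t.cds_end_t) - t.cds_start_t + 1
    mutant = cds[: skip_lo - 1] + cds[skip_hi:]

    junctions = []
    retained = [i for i in range(1, t.n_exons + 1) if i != e.skipped_exon_ordinal]
    mutant_end_t = 0
    for ordinal in retained[:-1]:
        mutant_end_t += exon_info(t, ordinal).length
        junctions.append(mutant_end_t - (t.cds_start_t - 1))
    return mutant, junctions


def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def hgvs_from_proteins(original: str, mutant: str, frameshift: bool) -> str:
    """Build HGVS p. notation by diffing two translated proteins.

    Frameshifts use ``p.Xaa{n}Yaa fsTer{N}`` where ``N`` counts the stop
    with the first changed residue as position 1 (``fsTer?`` when the
    mutant never reaches a stop).  In-frame changes come out as del,
    delins, a plain substitution, or nonsense when the first changed
    residue is itself a stop.
    """
    if original == mutant:
        return "p.(=)"
    cp = _common_prefix_len(original, mutant)
    if cp >= len(mutant):
        # mutant is a strict prefix of original: everything after cp deleted
        # (can only arise from an in-frame skip removing the C-terminus)
        first, last = cp + 1, len(original)
        if first == last:
            return f"p.{AA3[original[cp]]}{first}del"
        return f"p.{AA3[original[cp]]}{first}_{AA3[original[last - 1]]}{last}del"

    if frameshift:
        orig_res = original[cp] if cp < len(original) else "?"
        new_res = mutant[cp]
        if new_res == "*":
            return f"p.{AA3[orig_res]}{cp + 1}Ter"
        if mutant.endswith("*"):
            ter = len(mutant) - cp  # stop position counting changed residue as 1
            return f"p.{AA3[orig_res]}{cp + 1}{AA3[new_res]}fsTer{ter}"
        return f"p.{AA3[orig_res]}{cp + 1}{AA3[new_res]}fsTer?"

    # in-frame: align a common suffix as well
    cs = 0
    while (
        cs < min(len(original), len(mutant)) - cp
        and original[len(original) - 1 - cs] == mutant[len(mutant) - 1 - cs]
    ):
        cs += 1
    deleted = original[cp : len(original) - cs]
    inserted = mutant[cp : len(mutant) - cs]
    first = cp + 1
    last = len(original) - cs
    if not inserted:
        if first == last:
            return f"p.{AA3[deleted[0]]}{first}del"
        return f"p.{AA3[deleted[0]]}{first}_{AA3[deleted[-1]]}{last}del"
    ins3 = "".join(AA3[r] for r in inserted)
    if len(deleted) == 1 and len(inserted) == 1:
        return f"p.{AA3[deleted[0]]}{first}{ins3}"
    if first == last:
        return f"p.{AA3[deleted[0]]}{first}delins{ins3}"
    return f"p.{AA3[deleted[0]]}{first}_{AA3[deleted[-1]]}{last}delins{ins3}"


def annotate_consequence(
    t: TranscriptModel, e: SkipEvent, nmd_rule_nt: int = NMD_RULE_NT
) -> ConsequenceReport:
    """Full consequence annotation for one exon skip.

    The mutant protein always equals ``translate(mutant CDS)``; the HGVS
    notation is derived from the protein diff so the two can never
    disagree.
    """
    info = exon_info(t, e.skipped_exon_ordinal)
    mutant_cds, junctions = apply_skip(t, e)
    original_protein = translate(t.cds_sequence())
    mutant_protein = translate(mutant_cds)
    frameshift = info.out_of_frame

    span_lo, _ = t.exon_transcript_span(e.skipped_exon_ordinal)
    skip_lo_c = max(span_lo, t.cds_start_t) - t.cds_start_t + 1

    new_stop_pos = None
    new_stop_orig = None
    new_stop_genomic = None
    stop_codon = None
    nmd = False
    if mutant_protein.endswith("*"):
        new_stop_pos = 3 * (len(mutant_protein) - 1) + 1
        stop_codon = mutant_cds[new_stop_pos - 1 : new_stop_pos + 2]
        new_stop_orig = (
            new_stop_pos
            if new_stop_pos < skip_lo_c
            else new_stop_pos + info.cds_overlap_length
        )
        g_first = map_coordinate(t, new_stop_orig, "cds_to_genomic")
        g_last = map_coordinate(t, new_stop_orig + 2, "cds_to_genomic")
        new_stop_genomic = f"{t.chrom}:{g_first}-{g_last}"
        if junctions:
            last_junction = max(junctions)
            stop_last_base = new_stop_pos + 2
            nmd = (last_junction - stop_last_base) >= nmd_rule_nt

    hgvs_p = hgvs_from_proteins(original_protein, mutant_protein, frameshift)
    return ConsequenceReport(
        transcript_id=t.transcript_id,
        skipped_exon_ordinal=e.skipped_exon_ordinal,
        frameshift=frameshift,
        mutant_cds_length=len(mutant_cds),
        new_stop_cds_pos=new_stop_pos,
        new_stop_cds_pos_original=new_stop_orig,
        new_stop_genomic=new_stop_genomic,
        stop_codon=stop_codon,
        hgvs_p=hgvs_p,
        nmd_predicted=nmd,
        mutant_protein=mutant_protein,
    )


def write_mutant_cds_fasta(
    t: TranscriptModel, e: SkipEvent, path: str
) -> None:
    """Write the mutant CDS as a one-record FASTA file."""
    mutant, _ = apply_skip(t, e)
    header = f">{t.transcript_id}|skip_exon_{e.skipped_exon_ordinal}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(0, len(mutant), 60):
            fh.write(mutant[i : i + 60] + "\n")
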