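"""Exonic splicing enhancer (ESE) k-mer scanning at a variant position.

A point mutation can weaken exon recognition by destroying ESE motifs even
when it sits outside the splice-site consensus.  Published ESE catalogues
are plain sets of k-mers (hexamers or octamers); the quantity of interest
at a variant is how many of the k overlapping length-k windows covering
the variant base are catalogue members, before and after the substitution.
Only the +/-(k-1) bases around the variant can influence this count, so
the scan window follows directly from k and needs no separate flag.

Scanning is performed on the transcript (sense) strand: ESEs act on the
pre-mRNA, so genomic input for minus-strand genes must be
reverse-complemented before calling into this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import CoordinateError, MotifFormatError, ReferenceMismatchError

logger = logging.getLogger(__name__)

_VALID = set("ACGT")


@dataclass(frozen=True)
class MotifSet:
    """A labelled set of distinct k-mers over {A, C, G, T}."""

    label: str
    k: int
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        for m in self.members:
            if len(m) != self.k:
                raise ValueError(f"motif {m!r} has length {len(m)}, expected {self.k}")
            if set(m) - _VALID:
                raise ValueError(f"motif {m!r} contains non-ACGT characters")


@dataclass(frozen=True)
class EseDelta:
    """Overlapping-motif counts at one position, reference vs mutant."""

    motif_label: str
    k: int
    ref_count: int
    alt_count: int
    delta: int
    truncated: bool = False


def load_motif_set(path: str, label: str, k: int) -> MotifSet:
    """Read a one-k-mer-per-line motif file ('#' comments allowed).

    Lines are upper-cased; duplicates are removed with a logged count; a
    line of the wrong length or alphabet is a format error naming the line.
    """
    members: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip().upper()
            if not line:
                continue
            if len(line) != k:
                raise MotifFormatError(
                    f"{path}:{lineno}: {line!r} has length {len(line)}, expected {k}"
                )
            if set(line) - _VALID:
                raise MotifFormatError(
                    f"{path}:{lineno}: {line!r} contains non-ACGT characters"
                )
            members.append(line)
    unique = frozenset(members)
    if not unique:
        raise MotifFormatError(f"{path}: no motifs found")
    dups = len(members) - len(unique)
    if dups:
        logger.info("%s: removed %d duplicate motif lines", path, dups)
    return MotifSet(label=label, k=k, members=unique)


def overlapping_kmer_count(seq: str, pos: int, m: MotifSet) -> int:
    """Number of member k-mers among the windows covering position ``pos``.

    ``pos`` is 1-based into ``seq``.  Windows truncated by the sequence
    ends do not exist and are not counted; the result is between 0 and k.
    """
    if not 1 <= pos <= len(seq):
        raise CoordinateError(f"pos {pos} outside sequence of length {len(seq)}")
    seq = seq.upper()
    k = m.k
    first = max(1, pos - k + 1)
    last = min(pos, len(seq) - k + 1)
    count = 0
    for start in range(first, last + 1):
        if seq[start - 1 : start - 1 + k] in m.members:
            count += 1
    return count


def ese_delta(
    ref_seq: str,
    pos: int,
    ref_base: str,
    alt_base: str,
    sets: Iterable[MotifSet],
) -> list[EseDelta]:
    """Motif gain/loss at a substitution, one row per motif set.

    The mutant counts are computed on ``ref_seq`` with the base at ``pos``
    replaced by ``alt_base``.  When fewer than k-1 context bases flank the
    position the counts are computed over the truncated context and the
    row is flagged rather than rejected, so short minigene fragments remain
    usable.
    """
    ref_seq = ref_seq.upper()
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if not 1 <= pos <= len(ref_seq):
        raise CoordinateError(f"pos {pos} outside sequence of length {len(ref_seq)}")
    if ref_seq[pos - 1] != ref_base:
        raise ReferenceMismatchError(
            f"position {pos}: sequence has {ref_seq[pos - 1]}, stated ref is {ref_base}"
        )
    alt_seq = ref_seq[: pos - 1] + alt_base + ref_seq[pos:]
    out = []
    for m in sets:
        truncated = (pos - 1 < m.k - 1) or (len(ref_seq) - pos < m.k - 1)
        ref_count = overlapping_kmer_count(ref_seq, pos, m)
        alt_count = overlapping_kmer_count(alt_seq, pos, m)
        out.append(
            EseDelta(
                motif_label=m.label,
                k=m.k,
                ref_count=ref_count,
                alt_count=alt_count,
                delta=alt_count - ref_count,
                truncated=truncated,
            )
        )
    return out


def write_delta_tsv(deltas: Sequence[EseDelta], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("label\tk\tref_count\talt_count\tdelta\ttruncated_flag\n")
        for d in deltas:
            fh.write(
                f"{d.motif_label}\t{d.k}\t{d.ref_count}\t{d.alt_count}\t"
                f"{d.delta}\t{int(d.truncated)}\n"
            )
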