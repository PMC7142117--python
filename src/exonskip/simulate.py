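"""Seeded generators for every input the pipeline consumes.

Three simulators share one master seed but draw from independent child
streams (so adding draws to one never shifts another):

* multi-exon protein-coding transcripts on either strand, with a genomic
  sequence, controllable exon frame, and plantable motif occurrences;
* case/control allele-count tables drawn binomially at stated
  frequencies;
* diploid Hardy-Weinberg populations carrying a focal pathogenic allele
  (frequency q) and an aggregate class of other pathogenic alleles
  (frequency Q), where affected status requires a pathogenic allele in
  trans with an "other" allele — the sampling model behind the
  prevalence-implied frequency estimator.

Identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConstraintError
from .stats import CountTable2x2
from .transcript import (
    GenomicInterval,
    InMemorySource,
    TranscriptModel,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}

# child-stream indices of the master seed
_STREAM_TRANSCRIPT = 0
_STREAM_COHORT = 1
_STREAM_POPULATION = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all three simulators; unused fields are ignored."""

    seed: int = 0
    # transcript
    n_exons: int = 3
    exon_length_range: tuple[int, int] = (60, 150)
    force_out_of_frame_exon: Optional[int] = None
    strand: str = "random"  # '+', '-' or 'random'
    gc_content: float = 0.5
    motif_plants: tuple[tuple[str, int], ...] = ()
    utr5_range: tuple[int, int] = (6, 30)
    utr3_range: tuple[int, int] = (6, 30)
    intron_length_range: tuple[int, int] = (60, 200)
    chrom: str = "chrSim"
    # cohort table
    q_case: float = 0.01
    q_ctrl: float = 0.01
    n_case: int = 100
    n_ctrl: int = 1000
    # population
    pop_q: float = 1e-3
    pop_Q: float = 1e-3
    pop_N: int = 1_000_000


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p)) if n > 0 else ""


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    """n sense (non-stop) codons, base composition near gc_content.

    Stop codons are rejected and resampled rather than edited, keeping the
    composition of accepted codons unbiased within the sense set.
    """
    out = []
    while len(out) < n:
        codon = _random_bases(rng, 3, gc)
        if codon not in STOPS:
            out.append(codon)
    return "".join(out)


def _has_internal_stop(cds: str) -> bool:
    return any(cds[i : i + 3] in STOPS for i in range(0, len(cds) - 3, 3))


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------


def simulate_transcript(cfg: SimulationConfig) -> tuple[TranscriptModel, dict]:
    """Generate a valid protein-coding transcript plus its genome.

    The CDS starts with ATG, ends with a stop codon, and contains no
    internal in-frame stop.  When ``force_out_of_frame_exon`` names an
    internal exon, that exon's CDS overlap is made indivisible by 3 (by
    nudging its sampled length within the allowed range); UTR lengths on
    the terminal exons absorb the adjustment needed to keep the CDS length
    a multiple of three.  Returns the transcript (with an in-memory
    sequence source attached) and the ``{chrom: sequence}`` genome dict.
    """
    rng = _rng(cfg, _STREAM_TRANSCRIPT)
    lo, hi = cfg.exon_length_range
    if cfg.n_exons < 2:
        raise ConstraintError("need at least 2 exons")
    if lo < 1 or hi < lo:
        raise ConstraintError(f"bad exon_length_range {cfg.exon_length_range}")

    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_exons)]

    force = cfg.force_out_of_frame_exon
    if force is not None:
        if not 1 <= force <= cfg.n_exons:
            raise ConstraintError(f"forced exon {force} outside 1..{cfg.n_exons}")
        if force in (1, cfg.n_exons):
            # terminal exons contain UTR; their CDS overlap is set below
            pass
        elif lengths[force - 1] % 3 == 0:
            for cand in (lengths[force - 1] + 1, lengths[force - 1] - 1):
                if lo <= cand <= hi:
                    lengths[force - 1] = cand
                    break
            else:
                raise ConstraintError(
                    f"exon_length_range {cfg.exon_length_range} cannot give "
                    f"exon {force} a length not divisible by 3"
                )

    total = sum(lengths)
    utr5 = int(rng.integers(*_clamped(cfg.utr5_range, lengths[0] - 1)))
    utr3 = int(rng.integers(*_clamped(cfg.utr3_range, lengths[-1] - 1)))

    def _acceptable(u5: int, u3: int) -> bool:
        cds = total - u5 - u3
        if cds < 9 or cds % 3 != 0:
            return False
        if not (0 <= u5 < lengths[0] and 0 <= u3 < lengths[-1]):
            return False
        if force == 1 and (lengths[0] - u5) % 3 == 0:
            return False
        if force == cfg.n_exons and (lengths[-1] - u3) % 3 == 0:
            return False
        return True

    # nudge the sampled UTRs to the nearest pair meeting frame constraints
    found = None
    for d5 in range(0, 9):
        for d3 in range(0, 9):
            for s5 in (1, -1):
                for s3 in (1, -1):
                    u5, u3 = utr5 + s5 * d5, utr3 + s3 * d3
                    if _acceptable(u5, u3):
                        found = (u5, u3)
                        break
                if found:
                    break
            if found:
                break
        if found:
            break
    if found is None:
        raise ConstraintError(
            "exon lengths and UTR ranges cannot satisfy the CDS/frame constraints"
        )
    utr5, utr3 = found
    cds_len = total - utr5 - utr3

    n_codons = cds_len // 3
    cds = "ATG" + _random_codons(rng, n_codons - 2, cfg.gc_content)
    cds += ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    tx_seq = (
        _random_bases(rng, utr5, cfg.gc_content)
        + cds
        + _random_bases(rng, utr3, cfg.gc_content)
    )

    for kmer, pos in cfg.motif_plants:
        kmer = kmer.upper()
        if not 1 <= pos <= len(tx_seq) - len(kmer) + 1:
            raise ConstraintError(f"plant {kmer!r} at {pos} outside transcript")
        tx_seq = tx_seq[: pos - 1] + kmer + tx_seq[pos - 1 + len(kmer) :]
    planted_cds = tx_seq[utr5 : utr5 + cds_len]
    if not planted_cds.startswith("ATG") or planted_cds[-3:] not in STOPS:
        raise ConstraintError("motif plant destroyed the start or stop codon")
    if _has_internal_stop(planted_cds):
        raise ConstraintError("motif plant introduced an internal in-frame stop")

    strand = cfg.strand
    if strand == "random":
        strand = "+" if rng.integers(0, 2) == 0 else "-"
    if strand not in {"+", "-"}:
        raise ConstraintError(f"bad strand {cfg.strand!r}")

    # lay out a plus-strand genome, then mirror for minus-strand genes
    ilo, ihi = cfg.intron_length_range
    flank = int(rng.integers(ilo, ihi + 1))
    pieces, coords, cursor = [], [], 0
    pieces.append(_random_bases(rng, flank, cfg.gc_content))
    cursor += flank
    offset = 0
    for i, L in enumerate(lengths):
        pieces.append(tx_seq[offset : offset + L])
        coords.append((cursor, cursor + L))
        cursor += L
        offset += L
        intron = int(rng.integers(ilo, ihi + 1))
        pieces.append(_random_bases(rng, intron, cfg.gc_content))
        cursor += intron
    genome_seq = "".join(pieces)
    G = len(genome_seq)

    if strand == "+":
        exons = [GenomicInterval(cfg.chrom, s, e, "+") for s, e in coords]
    else:
        genome_seq = reverse_complement(genome_seq)
        exons = [GenomicInterval(cfg.chrom, G - e, G - s, "-") for s, e in coords]

    genome = {cfg.chrom: genome_seq}
    t = TranscriptModel(
        transcript_id=f"SIM_{cfg.seed}",
        gene=f"GENE_{cfg.seed}",
        chrom=cfg.chrom,
        strand=strand,
        exons=exons,
        cds_start_t=utr5 + 1,
        cds_end_t=utr5 + cds_len,
        sequence_source=InMemorySource(genome),
    )
    if force is not None:
        from .transcript import exon_info

        if not exon_info(t, force).out_of_frame:
            raise ConstraintError(
                f"constraints leave exon {force} in frame; widen the ranges"
            )
    return t, genome


def _clamped(rng_range: tuple[int, int], upper: int) -> tuple[int, int]:
    lo, hi = rng_range
    lo = max(0, min(lo, upper))
    hi = max(lo, min(hi, upper))
    return lo, hi + 1


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------


def simulate_cohort_table(cfg: SimulationConfig) -> CountTable2x2:
    """Binomial allele counts at stated case/control frequencies."""
    for name, v in (("q_case", cfg.q_case), ("q_ctrl", cfg.q_ctrl)):
        if not 0.0 <= v <= 1.0:
            raise ConstraintError(f"{name} must be in [0, 1], got {v}")
    if cfg.n_case <= 0 or cfg.n_ctrl <= 0:
        raise ConstraintError("allele totals must be positive")
    rng = _rng(cfg, _STREAM_COHORT)
    case_alt = int(rng.binomial(cfg.n_case, cfg.q_case))
    ctrl_alt = int(rng.binomial(cfg.n_ctrl, cfg.q_ctrl))
    return CountTable2x2(
        case_alt=case_alt,
        case_ref=cfg.n_case - case_alt,
        ctrl_alt=ctrl_alt,
        ctrl_ref=cfg.n_ctrl - ctrl_alt,
    )


# ---------------------------------------------------------------------------
# diploid populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSim:
    """Genotype-class counts plus the observed epidemiological summaries.

    Genotypes are unordered pairs over the allele classes focal (q),
    other-pathogenic (Q) and benign; affected = focal/other or
    other/other (focal homozygotes are unaffected by model assumption).
    """

    n_focal_focal: int
    n_focal_other: int
    n_other_other: int
    n_focal_benign: int
    n_other_benign: int
    n_benign_benign: int
    pop_N: int
    observed_prevalence: float = field(init=False)
    observed_f: float = field(init=False)

    def __post_init__(self) -> None:
        affected = self.n_focal_other + self.n_other_other
        object.__setattr__(self, "observed_prevalence", affected / self.pop_N)
        object.__setattr__(
            self,
            "observed_f",
            self.n_focal_other / affected if affected else float("nan"),
        )


def simulate_population(cfg: SimulationConfig) -> PopulationSim:
    """Hardy-Weinberg diploid population with two pathogenic allele classes."""
    q, Q, N = cfg.pop_q, cfg.pop_Q, cfg.pop_N
    if q < 0 or Q < 0 or q + Q >= 1:
        raise ConstraintError(f"need q, Q >= 0 and q + Q < 1, got q={q}, Q={Q}")
    if N <= 0:
        raise ConstraintError("pop_N must be positive")
    b = 1.0 - q - Q
    probs = np.array([q * q, 2 * q * Q, Q * Q, 2 * q * b, 2 * Q * b, b * b])
    rng = _rng(cfg, _STREAM_POPULATION)
    counts = rng.multinomial(N, probs / probs.sum())
    return PopulationSim(
        n_focal_focal=int(counts[0]),
        n_focal_other=int(counts[1]),
        n_other_other=int(counts[2]),
        n_focal_benign=int(counts[3]),
        n_other_benign=int(counts[4]),
        n_benign_benign=int(counts[5]),
        pop_N=N,
    )


# ---------------------------------------------------------------------------
# fixture writers
# ---------------------------------------------------------------------------


def write_fasta(genome: dict, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(t: TranscriptModel, path: str) -> None:
    """Write exon + CDS (+ stop_codon) features for one transcript."""
    from .transcript import map_coordinate

    attrs = f'gene_id "{t.gene}"; transcript_id "{t.transcript_id}";'
    rows = [
        f"{t.chrom}\texonskip_sim\texon\t{ex.start + 1}\t{ex.end}\t.\t{t.strand}\t.\t{attrs}"
        for ex in t.exons
    ]
    # CDS excluding the stop codon, stop_codon separately (GTF convention)
    cds_pairs = []
    for c_lo, c_hi, feat in [
        (1, t.cds_length - 3, "CDS"),
        (t.cds_length - 2, t.cds_length, "stop_codon"),
    ]:
        for c in range(c_lo, c_hi + 1):
            g = map_coordinate(t, c, "cds_to_genomic")
            cds_pairs.append((g, feat))
    for feat in ("CDS", "stop_codon"):
        gs = sorted(g for g, f in cds_pairs if f == feat)
        # merge consecutive genomic positions into intervals
        runs: list[list[int]] = []
        for g in gs:
            if runs and g == runs[-1][1] + 1:
                runs[-1][1] = g
            else:
                runs.append([g, g])
        for s, e in runs:
            rows.append(
                f"{t.chrom}\texonskip_sim\t{feat}\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")


def write_table_tsv(tab: CountTable2x2, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("group\talt\tref\n")
        fh.write(f"case\t{tab.case_alt}\t{tab.case_ref}\n")
        fh.write(f"control\t{tab.ctrl_alt}\t{tab.ctrl_ref}\n")
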