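"""One-variant orchestration: run every analysis and emit one report.

``run_variant_report`` composes the standalone modules without adding any
logic of its own, so each section of the report is identical to what the
corresponding module produces on the same inputs.  Sections are present
exactly when their inputs were supplied in the configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

from . import acmg, consequence, ese, prevalence, stats
from .transcript import (
    FastaSource,
    TranscriptModel,
    read_bed12,
    read_gtf,
    variant_context,
    VariantContext,
)


@dataclass(frozen=True)
class VariantReport:
    variant: VariantContext
    consequence: Optional[consequence.ConsequenceReport]
    ese: Optional[list[ese.EseDelta]]
    freq_stats: Optional[stats.FreqStats]
    prevalence_estimate: Optional[prevalence.PrevalenceModelParams]
    acmg: Optional[acmg.Classification]

    def to_dict(self) -> dict:
        out: dict = {"variant": self.variant.to_dict()}
        if self.consequence is not None:
            out["consequence"] = self.consequence.to_dict()
        if self.ese is not None:
            out["ese"] = [
                {
                    "label": d.motif_label,
                    "k": d.k,
                    "ref_count": d.ref_count,
                    "alt_count": d.alt_count,
                    "delta": d.delta,
                    "truncated_flag": d.truncated,
                }
                for d in self.ese
            ]
        if self.freq_stats is not None:
            out["freq_stats"] = self.freq_stats.to_dict()
        if self.prevalence_estimate is not None:
            out["prevalence_estimate"] = self.prevalence_estimate.to_dict()
        if self.acmg is not None:
            out["acmg"] = self.acmg.to_dict()
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def load_transcript_from_config(config: dict) -> TranscriptModel:
    """Resolve the transcript named by the configuration.

    Accepts a ready TranscriptModel under ``transcript_model`` (library
    use) or file inputs: ``gtf`` or ``bed12`` plus optional ``fasta``.
    """
    if "transcript_model" in config:
        return config["transcript_model"]
    genome = FastaSource(config["fasta"]) if config.get("fasta") else None
    if config.get("gtf"):
        return read_gtf(config["gtf"], config["transcript_id"], genome=genome)
    if config.get("bed12"):
        return read_bed12(config["bed12"], config.get("transcript_id"), genome=genome)
    raise ValueError("config must provide transcript_model, gtf or bed12")


def run_variant_report(config: dict) -> VariantReport:
    """Assemble the full report for one variant.

    Required config keys: a transcript source (see
    :func:`load_transcript_from_config`) and ``variant`` =
    ``{"cds_pos", "ref", "alt"}``.  Optional sections: ``skip_exon``
    (defaults to the variant's exon), ``motif_sets`` (list of loaded
    MotifSet objects or ``{"path", "label", "k"}`` dicts), ``counts``
    (2x2 allele counts), ``prevalence`` (``{"P", "f"}``), ``evidence``
    (ACMG items).
    """
    t = load_transcript_from_config(config)
    v = config["variant"]
    ctx = variant_context(t, int(v["cds_pos"]), v["ref"], v["alt"])

    cons: Optional[consequence.ConsequenceReport] = None
    if t.sequence_source is not None:
        skip_exon = int(config.get("skip_exon", ctx.exon_ordinal))
        cons = consequence.annotate_consequence(
            t,
            consequence.SkipEvent(t.transcript_id, skip_exon),
            nmd_rule_nt=int(config.get("nmd_rule_nt", consequence.NMD_RULE_NT)),
        )

    deltas: Optional[list[ese.EseDelta]] = None
    if config.get("motif_sets"):
        sets: list[ese.MotifSet] = []
        for m in config["motif_sets"]:
            if isinstance(m, ese.MotifSet):
                sets.append(m)
            else:
                sets.append(ese.load_motif_set(m["path"], m["label"], int(m["k"])))
        tx_seq = t.transcript_sequence()
        tpos = t.cds_start_t + ctx.cds_pos - 1
        deltas = ese.ese_delta(tx_seq, tpos, ctx.ref_allele, ctx.alt_allele, sets)

    freq: Optional[stats.FreqStats] = None
    if config.get("counts"):
        c = config["counts"]
        tab = stats.CountTable2x2(
            int(c["case_alt"]), int(c["case_ref"]), int(c["ctrl_alt"]), int(c["ctrl_ref"])
        )
        freq = stats.odds_ratio_with_ci(
            tab,
            alpha=float(c.get("alpha", 0.05)),
            ci_method=c.get("ci_method", "woolf"),
        )

    prev: Optional[prevalence.PrevalenceModelParams] = None
    if config.get("prevalence"):
        p = config["prevalence"]
        P = prevalence.parse_fraction(str(p["P"]))
        f = prevalence.parse_fraction(str(p["f"]))
        prev = prevalence.estimate_variant_allele_frequency(P, f)

    cls: Optional[acmg.Classification] = None
    if config.get("evidence") is not None:
        items = [
            it
            if isinstance(it, acmg.EvidenceItem)
            else acmg.EvidenceItem(
                it["code"], it.get("strength", ""), it.get("note", "")
            )
            for it in config["evidence"]
        ]
        cls = acmg.classify(items)

    return VariantReport(
        variant=ctx,
        consequence=cons,
        ese=deltas,
        freq_stats=freq,
        prevalence_estimate=prev,
        acmg=cls,
    )


def read_report(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_report(report: VariantReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(report.to_json())
        fh.write("\n")
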