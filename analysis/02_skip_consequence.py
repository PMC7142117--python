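#!/usr/bin/env python
"""Annotate the molecular consequence of skipping the out-of-frame exon.

Loads the fixture written by 01_simulate_fixtures.py through the GTF/FASTA
readers (exercising the same input path a user would take), skips exon 2,
and reports frameshift status, the premature stop, HGVS p. notation and
the NMD prediction.  Writes results/consequence_demo.json.
"""

import pathlib

from exonskip.consequence import SkipEvent, annotate_consequence
from exonskip.transcript import FastaSource, read_gtf

ROOT = pathlib.Path(__file__).resolve().parent.parent
FIX = ROOT / "results" / "fixtures"
SEED = 13


def main() -> None:
    t = read_gtf(
        str(FIX / "transcript.gtf"),
        f"SIM_{SEED}",
        genome=FastaSource(str(FIX / "genome.fa")),
    )
    rep = annotate_consequence(t, SkipEvent(t.transcript_id, 2))
    out = ROOT / "results" / "consequence_demo.json"
    out.write_text(rep.to_json() + "\n")

    print(f"skip exon 2 of {t.transcript_id}:")
    print(f"  frameshift:      {rep.frameshift}")
    print(f"  new stop:        {rep.stop_codon} at mutant c.{rep.new_stop_cds_pos}"
          f" (original c.{rep.new_stop_cds_pos_original}, {rep.new_stop_genomic})")
    print(f"  HGVS protein:    {rep.hgvs_p}")
    print(f"  NMD predicted:   {rep.nmd_predicted}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
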