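#!/usr/bin/env python
"""Generate the synthetic study transcript used by the downstream scripts.

Builds a four-exon protein-coding transcript whose second exon is out of
frame (its CDS overlap is not a multiple of three), mirroring the
situation where skipping a variant's exon shifts the reading frame.
Writes genome FASTA, transcript GTF and a JSON structure summary under
results/fixtures/.
"""

import json
import pathlib

from exonskip.simulate import SimulationConfig, simulate_transcript, write_fasta, write_gtf
from exonskip.transcript import exon_info, transcript_summary, validate_transcript

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "fixtures"
SEED = 13


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED, n_exons=4, strand="+", force_out_of_frame_exon=2)
    t, genome = simulate_transcript(cfg)
    assert validate_transcript(t) == []

    write_fasta(genome, str(OUT / "genome.fa"))
    write_gtf(t, str(OUT / "transcript.gtf"))
    (OUT / "transcript.json").write_text(
        json.dumps(transcript_summary(t), indent=2) + "\n"
    )

    info = exon_info(t, 2)
    print(f"transcript {t.transcript_id}: {t.n_exons} exons, CDS {t.cds_length} nt")
    print(
        f"exon 2: {info.length} nt, CDS overlap {info.cds_overlap_length} nt, "
        f"out_of_frame={info.out_of_frame}"
    )
    print(f"wrote {OUT}/genome.fa, transcript.gtf, transcript.json")


if __name__ == "__main__":
    main()
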