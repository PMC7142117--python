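#!/usr/bin/env python
"""Motif gain/loss at a substitution inside a planted ESE cluster.

Plants a hexamer cluster in a synthetic transcript, then substitutes its
central base and counts how many overlapping catalogue hexamers cover the
position before and after — the same computation that, on the real
variant, quantifies enhancer loss.  Writes results/ese_demo.tsv.
"""

import pathlib

from exonskip.ese import MotifSet, ese_delta, write_delta_tsv
from exonskip.simulate import SimulationConfig, simulate_transcript

ROOT = pathlib.Path(__file__).resolve().parent.parent
PLANT_POS = 60
PLANT = "GAAGAAGAAGA"  # 11 nt purine cluster: overlapping GAA-repeat hexamers


def main() -> None:
    cfg = SimulationConfig(seed=29, n_exons=3, motif_plants=((PLANT, PLANT_POS),))
    t, _ = simulate_transcript(cfg)
    tx = t.transcript_sequence()
    pos = PLANT_POS + 5  # central base of the planted cluster
    catalogue = MotifSet(
        "demo_6mers",
        6,
        frozenset({"GAAGAA", "AAGAAG", "AGAAGA"}),
    )
    deltas = ese_delta(tx, pos, tx[pos - 1], "T", [catalogue])
    out = ROOT / "results" / "ese_demo.tsv"
    out.parent.mkdir(exist_ok=True)
    write_delta_tsv(deltas, str(out))

    d = deltas[0]
    print(f"context {tx[pos - 8 : pos + 7]} (variant base {tx[pos - 1]}>{'T'})")
    print(
        f"{d.motif_label}: ref_count={d.ref_count}, alt_count={d.alt_count}, "
        f"delta={d.delta}"
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
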