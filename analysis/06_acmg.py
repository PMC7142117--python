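#!/usr/bin/env python
"""ACMG classification under the two published evidence scenarios.

Functional studies (PS3) plus case-control enrichment (PS4) at full
strength, and the same with PS4 downgraded to moderate to reflect
residual uncertainty in population matching.  Writes results/acmg.json.
"""

import json
import pathlib

from exonskip.acmg import EvidenceItem, classify

ROOT = pathlib.Path(__file__).resolve().parent.parent

SCENARIOS = {
    "ps3_ps4_full_strength": [
        EvidenceItem("PS3", note="reduced intact transcript in edited cells"),
        EvidenceItem("PS4", note="allele enriched in affected vs reference"),
    ],
    "ps4_downgraded_to_moderate": [
        EvidenceItem("PS3", note="reduced intact transcript in edited cells"),
        EvidenceItem("PS4", "moderate", note="residual population-matching uncertainty"),
    ],
}


def main() -> None:
    payload = {}
    for name, items in SCENARIOS.items():
        res = classify(items)
        payload[name] = res.to_dict()
        print(f"{name}: {res.value}")
        for rule in res.fired_rules:
            print(f"    {rule}")
    out = ROOT / "results" / "acmg.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
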