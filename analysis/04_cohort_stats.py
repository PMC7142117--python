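#!/usr/bin/env python
"""Case-control allele statistics for the published count tables.

Compares the Spanish Wilson-disease cohort allele count (22 of 80) with
the gnomAD v2.1.1 Latino population (79 of 35376): Fisher exact test,
cross-product odds ratio, and both confidence-interval methods.  Writes
results/cohort_stats.json.
"""

import json
import pathlib

from exonskip.stats import CountTable2x2, allele_frequency, odds_ratio_with_ci

ROOT = pathlib.Path(__file__).resolve().parent.parent

CASE_ALT, CASE_TOTAL = 22, 80
REF_ALT, REF_TOTAL = 79, 35376


def main() -> None:
    tab = CountTable2x2(CASE_ALT, CASE_TOTAL - CASE_ALT, REF_ALT, REF_TOTAL - REF_ALT)
    woolf = odds_ratio_with_ci(tab, ci_method="woolf")
    exact = odds_ratio_with_ci(tab, ci_method="exact")

    payload = {
        "case_allele_frequency": allele_frequency(CASE_ALT, CASE_TOTAL),
        "reference_allele_frequency": allele_frequency(REF_ALT, REF_TOTAL),
        "odds_ratio": woolf.odds_ratio,
        "fisher_p_two_sided": woolf.p_two_sided,
        "ci_woolf": [woolf.ci_low, woolf.ci_high],
        "ci_exact_conditional": [exact.ci_low, exact.ci_high],
        "alpha": 0.05,
    }
    out = ROOT / "results" / "cohort_stats.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(payload, indent=2) + "\n")

    print(f"allele frequency, cohort:    {payload['case_allele_frequency']:.4g}")
    print(f"allele frequency, reference: {payload['reference_allele_frequency']:.4g}")
    print(f"odds ratio (cross-product):  {woolf.odds_ratio:.4g}")
    print(f"Fisher two-sided p:          {woolf.p_two_sided:.3g}")
    print(f"95% CI (Woolf):              {woolf.ci_low:.4g}-{woolf.ci_high:.4g}")
    print(f"95% CI (exact conditional):  {exact.ci_low:.4g}-{exact.ci_high:.4g}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
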