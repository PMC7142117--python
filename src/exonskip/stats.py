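"""Case-control allele-count statistics for a single variant.

A 2x2 allele-count table (cases vs controls, alternate vs reference
alleles) is summarised by the two-sided Fisher exact test, the
cross-product odds ratio, and a confidence interval.  Two CI methods are
offered because published intervals rarely state their method: the Woolf
log-interval (default) and the exact conditional interval of the
noncentral hypergeometric model.  The reported ``ci_method`` makes every
output self-describing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .errors import UndefinedOddsRatioError


@dataclass(frozen=True)
class CountTable2x2:
    """Allele counts: rows = cases/controls, columns = alt/ref."""

    case_alt: int
    case_ref: int
    ctrl_alt: int
    ctrl_ref: int

    def __post_init__(self) -> None:
        for name in ("case_alt", "case_ref", "ctrl_alt", "ctrl_ref"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.case_alt + self.case_ref + self.ctrl_alt + self.ctrl_ref

    def as_rows(self) -> list[list[int]]:
        return [[self.case_alt, self.case_ref], [self.ctrl_alt, self.ctrl_ref]]


@dataclass(frozen=True)
class FreqStats:
    odds_ratio: float
    p_two_sided: float
    ci_low: float
    ci_high: float
    ci_method: str
    alpha: float
    zero_cell_corrected: bool = False

    def to_dict(self) -> dict:
        return {
            "or": self.odds_ratio,
            "p": self.p_two_sided,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
            "alpha": self.alpha,
            "zero_cell_corrected": self.zero_cell_corrected,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def allele_frequency(alt_count: int, total_alleles: int) -> float:
    """Alternate-allele frequency as an exact quotient."""
    if total_alleles <= 0:
        raise ValueError(f"total_alleles must be positive, got {total_alleles}")
    if not 0 <= alt_count <= total_alleles:
        raise ValueError(
            f"alt_count {alt_count} outside 0..{total_alleles}"
        )
    return alt_count / total_alleles


def fisher_exact_two_sided(tab: CountTable2x2) -> float:
    """Two-sided Fisher exact p-value under the minimum-likelihood rule.

    The p-value is the sum of hypergeometric probabilities, over all
    tables with the observed margins, of tables no more probable than the
    observed one.  The underlying log-gamma arithmetic keeps the value
    accurate for extreme tables (magnitudes of 1e-38 and below).
    """
    return float(sps.fisher_exact(tab.as_rows(), alternative="two-sided").pvalue)


def odds_ratio_with_ci(
    tab: CountTable2x2, alpha: float = 0.05, ci_method: str = "woolf"
) -> FreqStats:
    """Cross-product odds ratio with a Woolf or exact-conditional CI.

    The point estimate is always the sample cross-product ratio
    (case_alt * ctrl_ref) / (case_ref * ctrl_alt), +inf when only the
    denominator vanishes.  For the Woolf interval a Haldane-Anscombe 0.5
    is added to every cell when any cell is zero — for the interval only,
    never for the point estimate or the p-value — and the output is
    flagged.  ``ci_method="exact"`` uses the conditional noncentral
    hypergeometric interval instead.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    a, b, c, d = tab.case_alt, tab.case_ref, tab.ctrl_alt, tab.ctrl_ref
    num, den = a * d, b * c
    if num == 0 and den == 0:
        raise UndefinedOddsRatioError(
            "both cross products are zero; odds ratio is undefined"
        )
    point = math.inf if den == 0 else num / den
    p = fisher_exact_two_sided(tab)
    corrected = False

    if ci_method == "woolf":
        cells = [a, b, c, d]
        if 0 in cells:
            cells = [x + 0.5 for x in cells]
            corrected = True
        aa, bb, cc, dd = cells
        log_or = math.log((aa * dd) / (bb * cc))
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        z = sps.norm.ppf(1 - alpha / 2)
        ci_low = math.exp(log_or - z * se)
        ci_high = math.exp(log_or + z * se)
    elif ci_method == "exact":
        res = _scipy_odds_ratio(tab.as_rows(), kind="conditional")
        ci = res.confidence_interval(confidence_level=1 - alpha)
        ci_low, ci_high = float(ci.low), float(ci.high)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return FreqStats(
        odds_ratio=point,
        p_two_sided=p,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_method=ci_method,
        alpha=alpha,
        zero_cell_corrected=corrected,
    )
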