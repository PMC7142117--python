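"""Prevalence-implied allele frequency under a compound-het-only model.

For a recessive disease, suppose a focal variant (population allele
frequency q) is pathogenic only when in trans with some other pathogenic
allele (aggregate frequency Q), and that focal homozygotes are unaffected.
Under Hardy-Weinberg the disease prevalence and the fraction of patients
who are compound heterozygous for the focal variant are

    P = 2*q*Q + Q**2          (compound hets plus other/other homozygotes)
    f = 2*q*Q / (2*q*Q + Q**2)

Given observed P and f the system inverts in closed form: with
g = 2*(1 - f)/f one has Q = g*q and

    q = sqrt( P / (2*g + g**2) ).

This lets a disease's consensus prevalence plus a cohort's compound-het
fraction imply the variant's general-population allele frequency, a
useful sanity check against reference databases when the cohort's source
population is poorly represented there.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .errors import DegenerateModelError

_TOL = 1e-12


@dataclass(frozen=True)
class PrevalenceModelParams:
    """A consistent parameter set (P, f, q, Q) of the model above.

    ``hom_focal_freq`` is the expected frequency q**2 of focal homozygotes,
    excluded from the affected pool by assumption; it is reported so the
    size of that approximation is visible.
    """

    P: float
    f: float
    q: float
    Q: float

    def __post_init__(self) -> None:
        for name in ("P", "f", "q", "Q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DegenerateModelError(
                    f"{name} must lie in the open interval (0, 1), got {v}"
                )
        if abs(2 * self.q * self.Q + self.Q**2 - self.P) > _TOL * max(self.P, 1e-300):
            raise ValueError("parameters violate P = 2qQ + Q^2")
        if abs(2 * self.q * self.Q / self.P - self.f) > 1e-9:
            raise ValueError("parameters violate f = 2qQ / P")

    @property
    def hom_focal_freq(self) -> float:
        return self.q**2

    def to_dict(self) -> dict:
        P_check, f_check = expected_prevalence(self.q, self.Q)
        return {
            "q": self.q,
            "Q": self.Q,
            "P_check": P_check,
            "f_check": f_check,
            "hom_focal_freq": self.hom_focal_freq,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def estimate_variant_allele_frequency(P: float, f: float) -> PrevalenceModelParams:
    """Solve the model for (q, Q) from prevalence P and compound-het fraction f.

    Closed form: f = 2qQ/(2qQ + Q^2) rearranges to Q = 2q(1-f)/f; writing
    g = 2(1-f)/f and substituting into P = 2qQ + Q^2 yields
    q = sqrt(P / (2g + g^2)).  The returned parameters satisfy both model
    identities to within 1e-12 relative tolerance.
    """
    if not 0.0 < P < 1.0:
        raise DegenerateModelError(f"P must be in (0, 1), got {P}")
    if not 0.0 < f < 1.0:
        raise DegenerateModelError(
            f"f must be in (0, 1), got {f} "
            "(f=0: no compound hets; f=1: no other pathogenic alleles)"
        )
    g = 2.0 * (1.0 - f) / f
    q = math.sqrt(P / (2.0 * g + g * g))
    Q = g * q
    return PrevalenceModelParams(P=P, f=f, q=q, Q=Q)


def expected_prevalence(q: float, Q: float) -> tuple[float, float]:
    """Forward model: (P, f) implied by allele frequencies (q, Q)."""
    if not 0.0 < q < 1.0 or not 0.0 < Q < 1.0:
        raise DegenerateModelError(f"q and Q must be in (0, 1), got q={q}, Q={Q}")
    P = 2.0 * q * Q + Q * Q
    f = 2.0 * q * Q / P
    return P, f


def parse_fraction(text: str) -> float:
    """Parse '0.55', '22/40' or '3.3/100000' into a float."""
    text = text.strip()
    if "/" in text:
        num, den = text.split("/", 1)
        return float(num) / float(den)
    return float(text)
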