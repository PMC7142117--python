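"""ACMG/AMP 2015 evidence-combining engine.

Evidence codes (PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7) carry a
native strength; a code may be applied at a *lower* strength (a downgrade,
e.g. PS4 applied as moderate when the case-control comparison has residual
confounding) but never upgraded.  The full pathogenic and benign
combining-rule tables are evaluated independently on the counts of applied
strengths; when both sides fire, the classification is a variant of
uncertain significance (VUS) with both rule lists recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import EvidenceError

# strength ordering, strongest first
STRENGTHS = ("stand_alone", "very_strong", "strong", "moderate", "supporting")
_RANK = {s: i for i, s in enumerate(STRENGTHS)}

PATHOGENIC_CODES = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
BENIGN_CODES = ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]

NATIVE_STRENGTH = {
    **{"PVS1": "very_strong"},
    **{f"PS{i}": "strong" for i in range(1, 5)},
    **{f"PM{i}": "moderate" for i in range(1, 7)},
    **{f"PP{i}": "supporting" for i in range(1, 6)},
    **{"BA1": "stand_alone"},
    **{f"BS{i}": "strong" for i in range(1, 5)},
    **{f"BP{i}": "supporting" for i in range(1, 8)},
}

CLASS_ORDER = ("benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic")


@dataclass(frozen=True)
class EvidenceItem:
    """One applied evidence code, possibly at a downgraded strength."""

    code: str
    applied_strength: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if self.code not in NATIVE_STRENGTH:
            raise EvidenceError(f"unknown ACMG code {self.code!r}")
        strength = self.applied_strength or NATIVE_STRENGTH[self.code]
        if strength not in _RANK:
            raise EvidenceError(f"unknown strength {strength!r}")
        if _RANK[strength] < _RANK[NATIVE_STRENGTH[self.code]]:
            raise EvidenceError(
                f"{self.code} cannot be upgraded from "
                f"{NATIVE_STRENGTH[self.code]} to {strength}"
            )
        object.__setattr__(self, "applied_strength", strength)

    @property
    def is_pathogenic_side(self) -> bool:
        return self.code in set(PATHOGENIC_CODES)


@dataclass(frozen=True)
class Classification:
    value: str
    fired_rules: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {"classification": self.value, "fired_rules": list(self.fired_rules)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _counts(items: list[EvidenceItem], pathogenic: bool) -> dict[str, int]:
    out = {s: 0 for s in STRENGTHS}
    for it in items:
        if it.is_pathogenic_side == pathogenic:
            out[it.applied_strength] += 1
    return out


def _pathogenic_rules(pvs: int, ps: int, pm: int, pp: int) -> list[str]:
    fired = []
    if pvs >= 1 and ps >= 1:
        fired.append("P1a: 1 Very strong AND >=1 Strong")
    if pvs >= 1 and pm >= 2:
        fired.append("P1b: 1 Very strong AND >=2 Moderate")
    if pvs >= 1 and pm == 1 and pp == 1:
        fired.append("P1c: 1 Very strong AND 1 Moderate AND 1 Supporting")
    if pvs >= 1 and pp >= 2:
        fired.append("P1d: 1 Very strong AND >=2 Supporting")
    if ps >= 2:
        fired.append("P2: >=2 Strong")
    if ps >= 1 and pm >= 3:
        fired.append("P3a: 1 Strong AND >=3 Moderate")
    if ps >= 1 and pm == 2 and pp >= 2:
        fired.append("P3b: 1 Strong AND 2 Moderate AND >=2 Supporting")
    if ps >= 1 and pm == 1 and pp >= 4:
        fired.append("P3c: 1 Strong AND 1 Moderate AND >=4 Supporting")
    return fired


def _likely_pathogenic_rules(pvs: int, ps: int, pm: int, pp: int) -> list[str]:
    fired = []
    if pvs >= 1 and pm >= 1:
        fired.append("LP1: 1 Very strong AND 1 Moderate")
    if ps == 1 and 1 <= pm <= 2:
        fired.append("LP2: 1 Strong AND 1-2 Moderate")
    if ps == 1 and pp >= 2:
        fired.append("LP3: 1 Strong AND >=2 Supporting")
    if pm >= 3:
        fired.append("LP4: >=3 Moderate")
    if pm == 2 and pp >= 2:
        fired.append("LP5: 2 Moderate AND >=2 Supporting")
    if pm == 1 and pp >= 4:
        fired.append("LP6: 1 Moderate AND >=4 Supporting")
    return fired


def _benign_rules(ba: int, bs: int) -> list[str]:
    fired = []
    if ba >= 1:
        fired.append("B1: 1 Stand-alone (BA1)")
    if bs >= 2:
        fired.append("B2: >=2 Strong")
    return fired


def _likely_benign_rules(bs: int, bp: int) -> list[str]:
    fired = []
    if bs == 1 and bp == 1:
        fired.append("LB1: 1 Strong AND 1 Supporting")
    if bp >= 2:
        fired.append("LB2: >=2 Supporting")
    return fired


def classify(evidence: list[EvidenceItem]) -> Classification:
    """Evaluate the full 2015 combining table on a list of evidence items.

    Pathogenic and benign branches are scored independently; a conflict
    between them yields VUS with both branches' fired rules recorded, as
    does evidence insufficient for any rule.
    """
    codes = [it.code for it in evidence]
    if len(codes) != len(set(codes)):
        dup = sorted({c for c in codes if codes.count(c) > 1})
        raise EvidenceError(f"duplicate evidence codes: {', '.join(dup)}")

    pc = _counts(evidence, pathogenic=True)
    bc = _counts(evidence, pathogenic=False)
    pvs, ps, pm, pp = (
        pc["very_strong"],
        pc["strong"],
        pc["moderate"],
        pc["supporting"],
    )
    ba, bs, bp = bc["stand_alone"], bc["strong"], bc["supporting"]

    path_rules = _pathogenic_rules(pvs, ps, pm, pp)
    lp_rules = _likely_pathogenic_rules(pvs, ps, pm, pp)
    ben_rules = _benign_rules(ba, bs)
    lb_rules = _likely_benign_rules(bs, bp)

    path_side = "pathogenic" if path_rules else ("likely_pathogenic" if lp_rules else None)
    ben_side = "benign" if ben_rules else ("likely_benign" if lb_rules else None)

    if path_side and ben_side:
        return Classification(
            "VUS", tuple(path_rules + lp_rules + ben_rules + lb_rules)
        )
    if path_side == "pathogenic":
        return Classification("pathogenic", tuple(path_rules))
    if path_side == "likely_pathogenic":
        return Classification("likely_pathogenic", tuple(lp_rules))
    if ben_side == "benign":
        return Classification("benign", tuple(ben_rules))
    if ben_side == "likely_benign":
        return Classification("likely_benign", tuple(lb_rules))
    return Classification("VUS", ())
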