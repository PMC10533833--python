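"""Node roster for the attitude network.

The network spans the variables collected at each 6-monthly questionnaire
wave: two biomedical prevention behaviours (PrEP use and viral load
sorting), having a steady partner, age, HIV risk perception, 21 PrEP
beliefs and 9 VLS beliefs.  Behaviours and steady partner are binary
(0/1); beliefs are treated as gaussian nodes on a 1-7 agreement scale,
and age as an open-scale gaussian node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

__all__ = ["NodeSpec", "make_default_roster", "roster_to_json", "roster_from_json"]

GAUSSIAN = "gaussian"
BINARY = "binary"

#: short code -> description for the 21 PrEP belief items
_PREP_BELIEFS = {
    "prep1": "Impact quality of sex life",
    "prep2": "Impact on serodiscordant couples",
    "prep3": "Solidarity towards HIV-positive individuals",
    "prep4": "Efficacy",
    "prep5": "Essential for high-risk",
    "prep6": "Redundant",
    "prep7": "Affordability",
    "prep8": "Expectation HIV drug resistance",
    "prep9": "Burden side-effects",
    "prep10": "Burden PrEP procedures",
    "prep11": "Impact on sex life",
    "prep12": "Opinion relevant others PrEP use for HIV prevention",
    "prep13": "Gay friends use PrEP",
    "prep14": "Opinion gay friends PrEP use",
    "prep15": "PrEP associated with high-risk",
    "prep16": "PrEP associated with sexual health",
    "prep17": "PrEP associated with better sex life",
    "prep18": "PrEP associated with promiscuity",
    "prep19": "Easier to use than condoms",
    "prep20": "Self-efficacy daily PrEP",
    "prep21": "Self-efficacy event-driven PrEP",
}

#: short code -> description for the 9 VLS belief items
_VLS_BELIEFS = {
    "vls1": "Prevents HIV transmission",
    "vls2": "Protects serodiscordant couples",
    "vls3": "Efficacy",
    "vls4": "Easier to use than condoms",
    "vls5": "Impact quality sex life",
    "vls6": "Opinion others to use viral load sorting for HIV prevention",
    "vls7": "Gay friends use viral load sorting",
    "vls8": "Opinion gay friends application of viral load sorting",
    "vls9": "Self-efficacy",
}


@dataclass(frozen=True)
class NodeSpec:
    """One network node: short code, variable family, and admissible range."""

    code: str
    family: str  # "gaussian" or "binary"
    scale_range: tuple[float, float] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.family not in (GAUSSIAN, BINARY):
            raise ValueError(f"unknown family {self.family!r} for node {self.code!r}")
        if self.family == BINARY and self.scale_range is not None:
            raise ValueError(f"binary node {self.code!r} must not have a scale_range")

    @property
    def is_binary(self) -> bool:
        return self.family == BINARY


def make_default_roster() -> list[NodeSpec]:
    """Build the default 35-node roster.

    Three binary nodes (``PrEP``, ``VLS``, ``sp``) and 32 gaussian nodes:
    ``age`` (open scale), ``riskHIV`` and the 30 belief nodes on a 1-7
    scale.  Codes are unique and stable; downstream estimation relies on
    this ordering.
    """
    roster: list[NodeSpec] = [
        NodeSpec("PrEP", BINARY, description="Used PrEP in the past 6 months"),
        NodeSpec("VLS", BINARY, description="Applied viral load sorting in the past 6 months"),
        NodeSpec("sp", BINARY, description="Had a steady partner in the past 6 months"),
        NodeSpec("age", GAUSSIAN, scale_range=None, description="Age (standardized)"),
        NodeSpec("riskHIV", GAUSSIAN, scale_range=(1.0, 7.0), description="HIV risk perception"),
    ]
    for code, desc in _PREP_BELIEFS.items():
        roster.append(NodeSpec(code, GAUSSIAN, scale_range=(1.0, 7.0), description=desc))
    for code, desc in _VLS_BELIEFS.items():
        roster.append(NodeSpec(code, GAUSSIAN, scale_range=(1.0, 7.0), description=desc))
    codes = [n.code for n in roster]
    assert len(set(codes)) == len(codes)
    return roster


def codes(roster: Iterable[NodeSpec]) -> list[str]:
    return [n.code for n in roster]


def binary_codes(roster: Iterable[NodeSpec]) -> list[str]:
    return [n.code for n in roster if n.is_binary]


def gaussian_codes(roster: Iterable[NodeSpec]) -> list[str]:
    return [n.code for n in roster if not n.is_binary]


def roster_to_json(roster: Iterable[NodeSpec], path: str | Path) -> None:
    payload = [asdict(n) for n in roster]
    Path(path).write_text(json.dumps(payload, indent=2))


def roster_from_json(path: str | Path) -> list[NodeSpec]:
    payload = json.loads(Path(path).read_text())
    out = []
    for entry in payload:
        rng = entry.get("scale_range")
        out.append(
            NodeSpec(
                entry["code"],
                entry["family"],
                tuple(rng) if rng is not None else None,
                entry.get("description", ""),
            )
        )
    return out
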