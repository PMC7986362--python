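"""Scoring for the KCCQ and EQ-5D-3L self-report instruments.

The KCCQ (Kansas City Cardiomyopathy Questionnaire) is scored on four
domains — physical limitation, symptom severity, quality of life and
social limitation — each rescaled to 0–100 (higher = better health).
Two composites are derived: the Functional Status Score (FSS), the mean
of the physical-limitation and symptom domains, and the Clinical Status
Score, the mean of FSS, quality of life and social limitation.

The EQ-5D-3L records five domains at three ordinal disability levels
(1 = none, 3 = severe) plus a 1–100 visual analogue scale (VAS); no
tariff/index valuation is applied here, only validation and passthrough.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "KCCQResponse",
    "EQ5DResponse",
    "KCCQScores",
    "score_kccq",
    "score_eq5d",
    "KCCQ_DOMAINS",
]

# Domain -> (number of items, maximum ordinal level). Item counts follow the
# instrument's standard layout: 6 physical-limitation items on a 5-point scale
# ("extremely limited" ... "not at all limited"), 8 symptom frequency/burden
# items, 3 quality-of-life items and 4 social-limitation items.
KCCQ_DOMAINS: dict[str, tuple[int, int]] = {
    "physical_limitation": (6, 5),
    "symptom": (8, 5),
    "quality_of_life": (3, 5),
    "social_limitation": (4, 5),
}


@dataclass
class KCCQResponse:
    """Raw ordinal item levels per domain; ``None`` marks a skipped item."""

    physical_limitation: list[int | None] = field(default_factory=list)
    symptom: list[int | None] = field(default_factory=list)
    quality_of_life: list[int | None] = field(default_factory=list)
    social_limitation: list[int | None] = field(default_factory=list)

    def items(self, domain: str) -> list[int | None]:
        return getattr(self, domain)


@dataclass
class EQ5DResponse:
    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int
    vas: int

    DOMAINS = ("mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression")


@dataclass
class KCCQScores:
    """Domain and composite scores on a 0–100 scale; ``nan`` = not computable."""

    physical_limitation: float
    symptom: float
    quality_of_life: float
    social_limitation: float
    fss: float
    clinical_status: float

    def as_dict(self) -> dict[str, float]:
        return {
            "kccq_physical_limitation": self.physical_limitation,
            "kccq_symptom": self.symptom,
            "kccq_quality_of_life": self.quality_of_life,
            "kccq_social_limitation": self.social_limitation,
            "kccq_fss": self.fss,
            "kccq_clinical_status": self.clinical_status,
        }


def _score_domain(levels: list[int | None], n_items: int, max_level: int) -> float:
    """Mean of items rescaled to 0–100; missing if under half answered."""
    if len(levels) != n_items:
        raise ValueError(f"expected {n_items} items, got {len(levels)}")
    answered = []
    for i, lev in enumerate(levels):
        if lev is None:
            continue
        if not (1 <= lev <= max_level):
            raise ValueError(f"item {i + 1} level {lev} outside 1..{max_level}")
        answered.append((lev - 1) / (max_level - 1) * 100.0)
    if len(answered) < math.ceil(n_items / 2):
        return float("nan")
    return sum(answered) / len(answered)


def score_kccq(response: KCCQResponse) -> KCCQScores:
    """Score KCCQ domains and composites.

    Each item level is linearly rescaled so level 1 -> 0 and the maximum
    level -> 100; a domain is the mean of its answered items, and is
    missing (nan) when fewer than half are answered. FSS averages the
    physical-limitation and symptom domains; Clinical Status averages
    FSS, quality of life and social limitation. Any missing constituent
    makes the composite missing.
    """
    dom = {
        name: _score_domain(response.items(name), n, mx)
        for name, (n, mx) in KCCQ_DOMAINS.items()
    }
    pl, sym = dom["physical_limitation"], dom["symptom"]
    fss = (pl + sym) / 2.0  # nan propagates
    clinical = (fss + dom["quality_of_life"] + dom["social_limitation"]) / 3.0
    return KCCQScores(
        physical_limitation=pl,
        symptom=sym,
        quality_of_life=dom["quality_of_life"],
        social_limitation=dom["social_limitation"],
        fss=fss,
        clinical_status=clinical,
    )


def score_eq5d(response: EQ5DResponse) -> tuple[dict[str, int], int]:
    """Validate an EQ-5D-3L response and return (domain levels, VAS).

    Levels must be 1, 2 or 3; the VAS runs from 1 to 100 (0 is invalid).
    """
    levels = {}
    for name in EQ5DResponse.DOMAINS:
        lev = getattr(response, name)
        if lev not in (1, 2, 3):
            raise ValueError(f"EQ-5D domain {name!r} level {lev} outside {{1,2,3}}")
        levels[name] = int(lev)
    if not (1 <= response.vas <= 100):
        raise ValueError(f"VAS {response.vas} outside 1..100")
    return levels, int(response.vas)
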