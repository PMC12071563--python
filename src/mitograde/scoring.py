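"""Mitotic count in a selected counting zone and Elston-Ellis mitotic score.

The mitotic score (MS) is the ordinal grade 1/2/3 assigned from the mitotic
count (MC) performed in a 2 mm² counting zone — one of the three components
of the Elston-Ellis (Nottingham) histoprognostic grade. Count-to-score
cut-offs depend on the counting area and local protocol, so they are
explicit configuration surfaced in every report; the defaults (7, 14) per
2 mm² follow the convention of the 2 mm² hotspot literature
(MC ≤ 7 → MS 1; 8–14 → MS 2; ≥ 15 → MS 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .geometry import CircleZone, PointUm
from .hotspots import count_in_radius

__all__ = ["ScoreThresholds", "MitoticAssessment", "mitotic_count", "assign_score", "assess_zone"]


@dataclass(frozen=True)
class ScoreThresholds:
    """Count cut-offs for the three mitotic-score grades.

    score 1 iff count ≤ t1; score 2 iff t1 < count ≤ t2; score 3 otherwise.
    reference_area_mm2 documents the counting area the cut-offs assume.
    """

    t1: int = 7
    t2: int = 14
    reference_area_mm2: float = 2.0

    def __post_init__(self) -> None:
        if self.t1 < 0 or self.t2 < 0:
            raise ValueError("thresholds must be non-negative")
        if not (self.t1 < self.t2):
            raise ValueError(f"require t1 < t2, got ({self.t1}, {self.t2})")
        if not (self.reference_area_mm2 > 0):
            raise ValueError("reference area must be positive")


@dataclass(frozen=True)
class MitoticAssessment:
    """Count and score in one counting zone, with the thresholds used."""

    zone: CircleZone
    mitotic_count: int
    mitotic_score: int
    thresholds: ScoreThresholds
    slide_id: str = ""


def mitotic_count(zone: CircleZone, mitoses: Sequence[PointUm]) -> int:
    """Mitoses inside the zone (inclusive boundary)."""
    return count_in_radius(zone.center, zone.radius_um, mitoses)


def assign_score(count: int, thresholds: ScoreThresholds | None = None) -> int:
    """Map a mitotic count to grade 1, 2 or 3."""
    if thresholds is None:
        thresholds = ScoreThresholds()
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    if count <= thresholds.t1:
        return 1
    if count <= thresholds.t2:
        return 2
    return 3


def assess_zone(
    zone: CircleZone,
    mitoses: Sequence[PointUm],
    thresholds: ScoreThresholds | None = None,
    slide_id: str = "",
) -> MitoticAssessment:
    """Count within the zone and assign the mitotic score."""
    if thresholds is None:
        thresholds = ScoreThresholds()
    mc = mitotic_count(zone, mitoses)
    return MitoticAssessment(
        zone=zone,
        mitotic_count=mc,
        mitotic_score=assign_score(mc, thresholds),
        thresholds=thresholds,
        slide_id=slide_id,
    )
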