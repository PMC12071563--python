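"""Mitotic hotspot scoring and selection.

A hotspot score blends the mitosis count inside a core circular zone
(default 1 mm²) with the count in a broader context zone (default 2 mm²)
centered on the same patch:

    h(p) = n_core(p) + ε · (n_context(p) − n_core(p)),   ε ∈ [0, 1]

ε = 0 scores by core density alone; ε = 1 scores by the full context count.
Candidates are every tumor patch center; the top-k mutually non-overlapping
display zones (context area) are selected greedily by descending score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .geometry import (
    CircleZone,
    PatchGrid,
    PointUm,
    SlideFrame,
    area_to_radius,
    build_patch_grid,
    circles_intersect,
)

__all__ = [
    "MitosisDetection",
    "HotspotParams",
    "HotspotCandidate",
    "HotspotResult",
    "filter_detections",
    "count_in_radius",
    "hotspot_scores",
    "rank_and_select",
    "compute_hotspots",
]


@dataclass(frozen=True)
class MitosisDetection:
    """A candidate mitotic figure: position (µm) and classifier confidence."""

    pos: PointUm
    confidence: float = 1.0
    id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class HotspotParams:
    """Tunable parameters of the hotspot engine.

    core_area_mm2 / context_area_mm2 define the two concentric counting
    zones; epsilon weights the surrounding activity; confidence_threshold is
    the strict lower bound a detection must exceed to be counted; top_k caps
    the number of non-overlapping hotspots returned.
    """

    core_area_mm2: float = 1.0
    context_area_mm2: float = 2.0
    epsilon: float = 0.5
    confidence_threshold: float = 0.5
    top_k: int = 1

    def __post_init__(self) -> None:
        if not (self.core_area_mm2 > 0):
            raise ValueError("core_area_mm2 must be positive")
        if self.context_area_mm2 < self.core_area_mm2:
            raise ValueError("context area must be >= core area")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must be in [0, 1]")
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must be in [0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @property
    def core_radius_um(self) -> float:
        return area_to_radius(self.core_area_mm2)

    @property
    def context_radius_um(self) -> float:
        return area_to_radius(self.context_area_mm2)


@dataclass(frozen=True)
class HotspotCandidate:
    """A scored patch center: counts in core/context zones and the blend."""

    center: PointUm
    n_core: int
    n_context: int
    score: float


@dataclass(frozen=True)
class HotspotResult:
    """Ranked, mutually non-overlapping hotspots with display zones."""

    selected: tuple[HotspotCandidate, ...]
    params: HotspotParams
    slide_id: str = ""

    @property
    def display_zones(self) -> tuple[CircleZone, ...]:
        r = self.params.context_radius_um
        return tuple(CircleZone(c.center, r) for c in self.selected)

    @property
    def top(self) -> HotspotCandidate | None:
        return self.selected[0] if self.selected else None


def filter_detections(
    dets: Sequence[MitosisDetection], threshold: float
) -> list[MitosisDetection]:
    """Keep detections whose confidence strictly exceeds the threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    return [d for d in dets if d.confidence > threshold]


def count_in_radius(
    center: PointUm, radius_um: float, mitoses: Sequence[PointUm]
) -> int:
    """Number of mitoses at Euclidean distance ≤ radius from center."""
    if not (radius_um > 0):
        raise ValueError("radius must be positive")
    if len(mitoses) == 0:
        return 0
    pts = np.asarray(mitoses, dtype=float)
    d2 = (pts[:, 0] - center[0]) ** 2 + (pts[:, 1] - center[1]) ** 2
    return int(np.count_nonzero(d2 <= radius_um**2))


def hotspot_scores(
    centers: Sequence[PointUm],
    mitoses: Sequence[PointUm],
    params: HotspotParams,
) -> list[HotspotCandidate]:
    """Score every candidate patch center against the mitosis set.

    For each center p, n_core and n_context are the inclusive-radius counts
    at the core and context radii and the score is
    n_core + ε·(n_context − n_core). Counting is exact Euclidean distance
    via a k-d tree (an index, not an approximation).
    """
    if not centers:
        return []
    r1 = params.core_radius_um
    r2 = params.context_radius_um
    cpts = np.asarray(centers, dtype=float)
    if len(mitoses) == 0:
        return [HotspotCandidate(PointUm(*c), 0, 0, 0.0) for c in cpts]
    tree = cKDTree(np.asarray(mitoses, dtype=float))
    n1 = tree.query_ball_point(cpts, r1, return_length=True)
    n2 = tree.query_ball_point(cpts, r2, return_length=True)
    eps = params.epsilon
    out = []
    for c, a, b in zip(cpts, n1, n2):
        out.append(
            HotspotCandidate(PointUm(*c), int(a), int(b), float(a + eps * (b - a)))
        )
    return out


def rank_and_select(
    cands: Sequence[HotspotCandidate], params: HotspotParams
) -> HotspotResult:
    """Rank candidates and greedily pick non-overlapping display zones.

    Sort is descending by score, then n_core, then ascending x, y — the
    last two are deterministic tie-breakers. A candidate is accepted iff its
    context-area display circle intersects no already-accepted circle
    (greedy non-maximum suppression); selection stops after top_k
    acceptances or when the list is exhausted.
    """
    if params.top_k < 1:
        raise ValueError("top_k must be >= 1")
    order = sorted(
        cands, key=lambda c: (-c.score, -c.n_core, c.center.x, c.center.y)
    )
    r = params.context_radius_um
    selected: list[HotspotCandidate] = []
    zones: list[CircleZone] = []
    for cand in order:
        zone = CircleZone(cand.center, r)
        if any(circles_intersect(zone, z) for z in zones):
            continue
        selected.append(cand)
        zones.append(zone)
        if len(selected) >= params.top_k:
            break
    return HotspotResult(selected=tuple(selected), params=params)


def compute_hotspots(
    dets: Sequence[MitosisDetection],
    regions: Sequence[Polygon],
    frame: SlideFrame,
    params: HotspotParams | None = None,
    patch_px: int = 256,
    level_mpp: float | None = None,
    grid: PatchGrid | None = None,
) -> HotspotResult:
    """End-to-end hotspot computation for one slide.

    Composition of confidence filtering, patch-grid generation over the
    tumor regions, per-center scoring, and ranked non-overlapping selection.
    Zero retained detections yield an empty result, not an error.

    level_mpp defaults to 2·frame.mpp (256 px patches at 20× for a slide
    whose level 0 is the 40×-equivalent plane).
    """
    if params is None:
        params = HotspotParams()
    kept = filter_detections(dets, params.confidence_threshold)
    if grid is None:
        if level_mpp is None:
            level_mpp = 2.0 * frame.mpp
        grid = build_patch_grid(
            regions, patch_px=patch_px, level_mpp=level_mpp, frame=frame
        )
    if not kept or not grid.centers:
        return HotspotResult(selected=(), params=params, slide_id=frame.slide_id)
    cands = hotspot_scores(grid.centers, [d.pos for d in kept], params)
    result = rank_and_select(cands, params)
    return replace(result, slide_id=frame.slide_id)
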